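species:
- S
- A
- R
- F
initial_state:
  S: 0.0
  A: 0.0
  R: 0.0
  F: 0.0
reactions:
- reactants: {}
  products:
    A: 1
  modifiers:
  - S
  param: k_sa
- reactants:
    A: 1
  products: {}
  modifiers: []
  param: k_a0
- reactants: {}
  products:
    R: 1
  modifiers:
  - A
  param: k_ar
- reactants:
    R: 1
  products: {}
  modifiers: []
  param: k_r0
- reactants: {}
  products:
    F: 1
  modifiers:
  - A
  param: k_af
- reactants:
    A: 1
  products: {}
  modifiers:
  - F
  param: k_fa
input_species:
- S
modules:
  activation:
  - k_sa
  - k_a0
  response:
  - k_ar
  - k_r0
  feedback:
  - k_af
  - k_fa
name: modular-toy
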