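species:
- S
- R
- X
initial_state:
  S: 0.0
  R: 0.0
  X: 0.0
reactions:
- reactants: {}
  products:
    R: 1
  modifiers:
  - S
  param: k_s-rs
- reactants:
    R: 1
  products: {}
  modifiers: []
  param: k_r-0
- reactants: {}
  products:
    X: 1
  modifiers:
  - S
  param: k_s-xs
- reactants:
    X: 1
  products: {}
  modifiers: []
  param: k_x-0
- reactants:
    R: 1
  products: {}
  modifiers:
  - X
  param: k_xr-x
- reactants: {}
  products:
    R: 1
  modifiers: []
  param: k_0-r
input_species:
- S
name: dose-response-prior
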