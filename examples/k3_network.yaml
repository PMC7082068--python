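species:
- A
- B
- C
initial_state:
  A: 100.0
  B: 0.0
  C: 0.0
reactions:
- reactants:
    A: 1
  products:
    B: 1
  modifiers: []
  param: k_AB
- reactants:
    A: 1
  products:
    C: 1
  modifiers: []
  param: k_AC
- reactants:
    B: 1
  products:
    A: 1
  modifiers: []
  param: k_BA
- reactants:
    B: 1
  products:
    C: 1
  modifiers: []
  param: k_BC
- reactants:
    C: 1
  products:
    A: 1
  modifiers: []
  param: k_CA
- reactants:
    C: 1
  products:
    B: 1
  modifiers: []
  param: k_CB
name: complete-3-node
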