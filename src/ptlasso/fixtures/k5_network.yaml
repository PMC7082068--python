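species:
- A
- B
- C
- D
- E
initial_state:
  A: 100.0
  B: 0.0
  C: 0.0
  D: 0.0
  E: 0.0
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
    A: 1
  products:
    D: 1
  modifiers: []
  param: k_AD
- reactants:
    A: 1
  products:
    E: 1
  modifiers: []
  param: k_AE
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
    B: 1
  products:
    D: 1
  modifiers: []
  param: k_BD
- reactants:
    B: 1
  products:
    E: 1
  modifiers: []
  param: k_BE
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
- reactants:
    C: 1
  products:
    D: 1
  modifiers: []
  param: k_CD
- reactants:
    C: 1
  products:
    E: 1
  modifiers: []
  param: k_CE
- reactants:
    D: 1
  products:
    A: 1
  modifiers: []
  param: k_DA
- reactants:
    D: 1
  products:
    B: 1
  modifiers: []
  param: k_DB
- reactants:
    D: 1
  products:
    C: 1
  modifiers: []
  param: k_DC
- reactants:
    D: 1
  products:
    E: 1
  modifiers: []
  param: k_DE
- reactants:
    E: 1
  products:
    A: 1
  modifiers: []
  param: k_EA
- reactants:
    E: 1
  products:
    B: 1
  modifiers: []
  param: k_EB
- reactants:
    E: 1
  products:
    C: 1
  modifiers: []
  param: k_EC
- reactants:
    E: 1
  products:
    D: 1
  modifiers: []
  param: k_ED
name: complete-5-node
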