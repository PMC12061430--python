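signatures:
- module: EMT
  name: Epithelial
  priority: 0
  states:
    SNAI1: 0
    ZEB1: 0
    miR200: 1
    Ecadherin: 1
- module: EMT
  name: Hybrid
  priority: 0
  states:
    SNAI1: 1
    ZEB1: 0
    Ecadherin: 1
- module: EMT
  name: Mesenchymal
  priority: 1
  states:
    ZEB1: 1
    miR200: 0
    Ecadherin: 0
- module: cycle
  name: Cycling
  priority: 0
  states:
    CellCycle: 1
- module: cycle
  name: Quiescent
  priority: 0
  states:
    CellCycle: 0
- module: death
  name: Apoptotic
  priority: 0
  states:
    Apoptosis: 1
    Src: 0
    Ecadherin: 1
- module: death
  name: Alive
  priority: 0
  states:
    Apoptosis: 0
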