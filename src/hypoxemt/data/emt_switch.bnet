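name: emt_switch
inputs: EMT_signal
module: EMT = SNAI1, miR34, ZEB1, miR200, Ecadherin
SNAI1 *= (EMT_signal or ZEB1) and not miR34
miR34 *= not SNAI1 and not ZEB1 and not EMT_signal
ZEB1 *= (SNAI1 or ZEB1) and not miR200
miR200 *= not ZEB1 and (miR200 or not SNAI1)
Ecadherin *= miR200 and not ZEB1
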