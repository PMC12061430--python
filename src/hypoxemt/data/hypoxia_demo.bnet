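name: hypoxia_demo
inputs: Hypoxia, GF, TGFb_ext, Stiff_ECM, ECM_attached, Density_High
module: EMT = SNAI1, miR200, ZEB1, Ecadherin, TGFb_secr, TGFbR
module: cycle = Myc, CyclinD, CellCycle
module: death = Apoptosis
module: oxygen = PHD, VHL, Hif1a_basal, Hif1a_High
PHD *= not Hypoxia
VHL *= True
Hif1a_basal *= GF or Hif1a_High
Hif1a_High *= not (PHD and VHL)
Src *= Hypoxia or Stiff_ECM
SNAI1 *= not Density_High and Stiff_ECM and (GF or Hif1a_High or TGFbR)
miR200 *= not ZEB1 and not (SNAI1 and (Hif1a_High or TGFbR))
ZEB1 *= (SNAI1 or ZEB1) and (Hif1a_High or TGFbR) and not miR200 and not Density_High
Ecadherin *= not ZEB1
TGFb_secr *= ZEB1
TGFbR *= TGFb_ext or TGFb_secr
Myc *= GF and not Hif1a_High
CyclinD *= GF and not Hif1a_High and not TGFbR
CellCycle *= Myc and CyclinD and Hif1a_basal and Stiff_ECM and ECM_attached and not Density_High
Apoptosis *= Ecadherin and not Src and (not ECM_attached or (TGFbR and not Stiff_ECM))
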