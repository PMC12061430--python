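assay_id,source,perturb_node,perturb_mode,perturb_level,environment,control_environment,readout,direction,experiment,window,contradictory
HYP-EMT-1,hif-emt,Hypoxia,on,1.0,Hypoxia=1;GF=1;TGFb_ext=0;Stiff_ECM=1;ECM_attached=1;Density_High=0,Hypoxia=0;GF=1;TGFb_ext=0;Stiff_ECM=1;ECM_attached=1;Density_High=0,ZEB1,increase,,-1,False
HYP-EMT-1,hif-emt,Hypoxia,on,1.0,Hypoxia=1;GF=1;TGFb_ext=0;Stiff_ECM=1;ECM_attached=1;Density_High=0,Hypoxia=0;GF=1;TGFb_ext=0;Stiff_ECM=1;ECM_attached=1;Density_High=0,Ecadherin,decrease,,-1,False
HYP-EMT-2,hif-emt,Hypoxia,on,1.0,Hypoxia=1;GF=1;TGFb_ext=0;Stiff_ECM=1;ECM_attached=1;Density_High=0,Hypoxia=0;GF=1;TGFb_ext=0;Stiff_ECM=1;ECM_attached=1;Density_High=0,phenotype:EMT:Mesenchymal,increase,,-1,False
HYP-CC-1,hif-cycle,Hypoxia,on,1.0,Hypoxia=1;GF=1;TGFb_ext=0;Stiff_ECM=1;ECM_attached=1;Density_High=0,Hypoxia=0;GF=1;TGFb_ext=0;Stiff_ECM=1;ECM_attached=1;Density_High=0,CellCycle,decrease,,-1,False
HYP-CC-2,hif-cycle,Hif1a_High,on,1.0,Hypoxia=0;GF=1;TGFb_ext=0;Stiff_ECM=1;ECM_attached=1;Density_High=0,Hypoxia=0;GF=1;TGFb_ext=0;Stiff_ECM=1;ECM_attached=1;Density_High=0,CellCycle,decrease,,-1,False
HYP-CC-3,hif-cycle,Hif1a_basal,off,1.0,Hypoxia=0;GF=1;TGFb_ext=0;Stiff_ECM=1;ECM_attached=1;Density_High=0,Hypoxia=0;GF=1;TGFb_ext=0;Stiff_ECM=1;ECM_attached=1;Density_High=0,CellCycle,decrease,,-1,False
VHL-1,vhl,VHL,off,1.0,Hypoxia=0;GF=1;TGFb_ext=0;Stiff_ECM=1;ECM_attached=1;Density_High=0,Hypoxia=0;GF=1;TGFb_ext=0;Stiff_ECM=1;ECM_attached=1;Density_High=0,phenotype:EMT:Mesenchymal,increase,,-1,False
VHL-2,vhl,VHL,off,1.0,Hypoxia=0;GF=1;TGFb_ext=0;Stiff_ECM=1;ECM_attached=1;Density_High=0,Hypoxia=0;GF=1;TGFb_ext=0;Stiff_ECM=1;ECM_attached=1;Density_High=0,CellCycle,decrease,,-1,False
TGFBR-KO-1,tgfb,TGFbR,off,1.0,Hypoxia=1;GF=1;TGFb_ext=0;Stiff_ECM=1;ECM_attached=1;Density_High=0,Hypoxia=0;GF=1;TGFb_ext=0;Stiff_ECM=1;ECM_attached=1;Density_High=0,ZEB1,increase,,-1,False
TGFB-EMT-1,tgfb,TGFb_ext,on,1.0,Hypoxia=0;GF=1;TGFb_ext=1;Stiff_ECM=1;ECM_attached=1;Density_High=0,Hypoxia=0;GF=1;TGFb_ext=0;Stiff_ECM=1;ECM_attached=1;Density_High=0,ZEB1,increase,,-1,False
SNAI1-KD-1,emt-core,SNAI1,off,1.0,Hypoxia=1;GF=1;TGFb_ext=0;Stiff_ECM=1;ECM_attached=1;Density_High=0,Hypoxia=1;GF=1;TGFb_ext=0;Stiff_ECM=1;ECM_attached=1;Density_High=0,ZEB1,decrease,,-1,False
MIR200-1,emt-core,miR200,on,1.0,Hypoxia=1;GF=1;TGFb_ext=0;Stiff_ECM=1;ECM_attached=1;Density_High=0,Hypoxia=1;GF=1;TGFb_ext=0;Stiff_ECM=1;ECM_attached=1;Density_High=0,Ecadherin,increase,,-1,False
SRC-1,anoikis,Src,off,1.0,Hypoxia=1;GF=1;TGFb_ext=0;Stiff_ECM=0;ECM_attached=0;Density_High=0,Hypoxia=1;GF=1;TGFb_ext=0;Stiff_ECM=0;ECM_attached=0;Density_High=0,Apoptosis,increase,,-1,False
PHD-1,hif-core,PHD,off,1.0,Hypoxia=0;GF=1;TGFb_ext=0;Stiff_ECM=1;ECM_attached=1;Density_High=0,Hypoxia=0;GF=1;TGFb_ext=0;Stiff_ECM=1;ECM_attached=1;Density_High=0,Hif1a_High,increase,,-1,False
PHD-1,hif-core,PHD,off,1.0,Hypoxia=0;GF=1;TGFb_ext=0;Stiff_ECM=1;ECM_attached=1;Density_High=0,Hypoxia=0;GF=1;TGFb_ext=0;Stiff_ECM=1;ECM_attached=1;Density_High=0,phenotype:EMT:Mesenchymal,increase,,-1,False
MYC-1,oncogene,Myc,on,1.0,Hypoxia=1;GF=1;TGFb_ext=0;Stiff_ECM=1;ECM_attached=1;Density_High=0,Hypoxia=1;GF=1;TGFb_ext=0;Stiff_ECM=1;ECM_attached=1;Density_High=0,ZEB1,no-change,,-1,False
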