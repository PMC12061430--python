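# Seven-pulse metastatic-cascade preset on the hypoxia demo model:
# primary epithelium -> hypoxic tumor core -> density drop (EMT) ->
# invasion -> intravasation (circulation) -> extravasation -> MET.
name: metastatic_cascade
model: fixture:hypoxia_demo
signatures: fixture:hypoxia_demo
initial:
  phenotype: Epithelial
  env: {Hypoxia: 0, GF: 1, TGFb_ext: 0, Stiff_ECM: 1, ECM_attached: 1, Density_High: 1}
windows:
  - steps: 20
    env: {Hypoxia: 0, GF: 1, TGFb_ext: 0, Stiff_ECM: 1, ECM_attached: 1, Density_High: 1}
  - steps: 20
    env: {Hypoxia: 1, GF: 1, TGFb_ext: 0, Stiff_ECM: 1, ECM_attached: 1, Density_High: 1}
  - steps: 20
    env: {Hypoxia: 1, GF: 1, TGFb_ext: 0, Stiff_ECM: 1, ECM_attached: 1, Density_High: 0}
  - steps: 20
    env: {Hypoxia: 0, GF: 1, TGFb_ext: 0, Stiff_ECM: 1, ECM_attached: 1, Density_High: 0}
  - steps: 20
    env: {Hypoxia: 0, GF: 1, TGFb_ext: 0, Stiff_ECM: 0, ECM_attached: 0, Density_High: 0}
  - steps: 20
    env: {Hypoxia: 0, GF: 1, TGFb_ext: 0, Stiff_ECM: 0, ECM_attached: 1, Density_High: 0}
  - steps: 20
    env: {Hypoxia: 0, GF: 1, TGFb_ext: 0, Stiff_ECM: 1, ECM_attached: 1, Density_High: 1}
ensemble: 50
death: Apoptotic
seed: 0
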