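# Hypoxia dose series on the demo model: epithelial cells on a stiff,
# attached matrix at low density, saturating growth factor, the autocrine
# TGF-beta loop weakened by a 5% secretion knockdown.
name: hypoxia_dose
model: fixture:hypoxia_demo
signatures: fixture:hypoxia_demo
initial:
  phenotype: Epithelial
  env: {Hypoxia: 0, GF: 1, TGFb_ext: 0, Stiff_ECM: 1, ECM_attached: 1, Density_High: 1}
windows:
  - steps: 60
    env: {Hypoxia: 0, GF: 1, TGFb_ext: 0, Stiff_ECM: 1, ECM_attached: 1, Density_High: 0}
    clamps:
      - {node: TGFb_secr, mode: off, level: 0.05}
    noise: 0.02
ensemble: 150
death: Apoptotic
seed: 3
series:
  - {kind: env, node: Hypoxia, levels: [0, 0.25, 0.5, 0.75, 1]}
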