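"""Self-contained models, signature sets and generators.

Everything here is constructed in code so the whole package is testable
without downloads:

* :func:`toggle_switch` — the minimal two-node mutual-repression circuit;
* :func:`emt_switch_fixture` — the isolated EMT switch built around the
  two double-negative feedback loops (SNAI1 ⊣ miR-34 and ZEB1 ⊣ miR-200),
  with epithelial / hybrid E/M / mesenchymal stable states;
* :func:`hypoxia_demo_model` — a 21-node demonstration network coupling
  oxygen sensing (PHD/VHL → HIF-1α), mechanosensing (ECM stiffness,
  attachment, cell density), growth-factor signaling, the EMT switch with
  its autocrine TGF-β loop, cell-cycle entry and apoptosis/anoikis;
* :func:`random_boolean_network` — seeded random networks for property
  tests;
* :func:`load_published_model` — loader for externally supplied rule
  files in the same dialect.

The two biological fixtures are synthetic stand-ins: compact rule sets
written to exhibit the canonical circuit logic (double-negative EMT loops,
hybrid-state stability, TGF-β hysteresis, oxygen-dependent HIF-1α
degradation), not transcriptions of any published full-scale model.
"""

from __future__ import annotations

import itertools
from pathlib import Path

import numpy as np

from .model_io import BooleanModel, parse_model
from .phenotypes import PhenotypeSignature, SignatureSet

__all__ = [
    "toggle_switch",
    "emt_switch_fixture",
    "emt_switch_signatures",
    "hypoxia_demo_model",
    "hypoxia_demo_signatures",
    "random_boolean_network",
    "load_published_model",
    "get_fixture",
    "fixture_signatures",
    "export_fixtures",
    "FIXTURES",
]


def toggle_switch() -> BooleanModel:
    """Two mutually repressing nodes: two fixed points plus one 2-cycle."""
    return parse_model("A *= not B\nB *= not A\n", name="toggle")


_EMT_SWITCH_TEXT = """\
name: emt_switch
inputs: EMT_signal
module: EMT = SNAI1, miR34, ZEB1, miR200, Ecadherin
SNAI1 *= (EMT_signal or ZEB1) and not miR34
miR34 *= not SNAI1 and not ZEB1 and not EMT_signal
ZEB1 *= (SNAI1 or ZEB1) and not miR200
miR200 *= not ZEB1 and (miR200 or not SNAI1)
Ecadherin *= miR200 and not ZEB1
"""


def emt_switch_fixture() -> BooleanModel:
    """The isolated six-node EMT switch.

    An external EMT signal feeds the SNAI1 ⊣ miR-34 loop, which feeds the
    ZEB1 ⊣ miR-200 loop; E-cadherin reports the epithelial state.  Without
    the signal the stable states are epithelial and mesenchymal; with it,
    hybrid E/M and mesenchymal — three distinct phenotypes in total.
    """
    return parse_model(_EMT_SWITCH_TEXT)


def emt_switch_signatures(model: BooleanModel | None = None) -> SignatureSet:
    model = model or emt_switch_fixture()
    sigs = [
        PhenotypeSignature("Epithelial", "EMT",
                           {"miR200": 1, "Ecadherin": 1, "SNAI1": 0, "ZEB1": 0}),
        PhenotypeSignature("Hybrid", "EMT",
                           {"SNAI1": 1, "ZEB1": 0, "Ecadherin": 1}),
        PhenotypeSignature("Mesenchymal", "EMT",
                           {"ZEB1": 1, "miR200": 0, "Ecadherin": 0}, priority=1),
    ]
    return SignatureSet(sigs, model)


_HYPOXIA_DEMO_TEXT = """\
name: hypoxia_demo
inputs: Hypoxia, GF, TGFb_ext, Stiff_ECM, ECM_attached, Density_High
module: oxygen = PHD, VHL, Hif1a_basal, Hif1a_High
module: EMT = SNAI1, miR200, ZEB1, Ecadherin, TGFb_secr, TGFbR
module: cycle = Myc, CyclinD, CellCycle
module: death = Apoptosis
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
"""


def hypoxia_demo_model() -> BooleanModel:
    """The 21-node hypoxia–EMT demonstration network.

    Six environmental inputs (Hypoxia, GF, TGFb_ext, Stiff_ECM,
    ECM_attached, Density_High; sensible environments keep
    Stiff_ECM=1 ⇒ ECM_attached=1) drive fifteen internal nodes: oxygen
    sensing degrades HIF-1α through PHD hydroxylation and constitutive
    VHL; strong HIF-1α stabilization or TGF-β signaling flips the
    ZEB1 ⊣ miR-200 switch (gated by matrix stiffness and contact
    inhibition); ZEB1 drives autocrine TGF-β secretion that locks the
    mesenchymal state in; strong HIF-1α represses Myc/Cyclin D and thereby
    cell-cycle entry; apoptosis fires in E-cadherin-positive cells without
    Src survival signaling upon detachment (anoikis) or soft-matrix TGF-β
    exposure.
    """
    return parse_model(_HYPOXIA_DEMO_TEXT)


def hypoxia_demo_signatures(model: BooleanModel | None = None) -> SignatureSet:
    model = model or hypoxia_demo_model()
    sigs = [
        PhenotypeSignature("Epithelial", "EMT",
                           {"SNAI1": 0, "ZEB1": 0, "miR200": 1, "Ecadherin": 1}),
        PhenotypeSignature("Hybrid", "EMT",
                           {"SNAI1": 1, "ZEB1": 0, "Ecadherin": 1}),
        PhenotypeSignature("Mesenchymal", "EMT",
                           {"ZEB1": 1, "miR200": 0, "Ecadherin": 0}, priority=1),
        PhenotypeSignature("Cycling", "cycle", {"CellCycle": 1}),
        PhenotypeSignature("Quiescent", "cycle", {"CellCycle": 0}),
        # apoptosis execution is identified by its full context (no Src
        # survival signal, adherens junctions present), so a single noise
        # flip of the executioner node cannot fake a death event
        PhenotypeSignature("Apoptotic", "death",
                           {"Apoptosis": 1, "Src": 0, "Ecadherin": 1}),
        PhenotypeSignature("Alive", "death", {"Apoptosis": 0}),
    ]
    return SignatureSet(sigs, model)


def random_boolean_network(
    n: int, k: int, n_inputs: int = 0, seed: int = 0
) -> BooleanModel:
    """Seeded random Boolean network for property testing.

    Each of the ``n - n_inputs`` free nodes receives ``k`` distinct
    regulators drawn uniformly from all nodes and a uniform random
    non-constant truth table, rendered as a disjunction of minterms so all
    ``k`` regulators appear syntactically.  Constant tables are redrawn:
    they would silently drop regulators from the rule text.
    """
    if not (n >= k >= 1):
        raise ValueError(f"need n >= k >= 1, got n={n}, k={k}")
    if not 0 <= n_inputs <= n - 1:
        raise ValueError("n_inputs must leave at least one free node")
    rng = np.random.default_rng(seed)
    names = [f"I{i}" for i in range(n_inputs)] + [f"N{i}" for i in range(n - n_inputs)]
    lines = [f"name: random_{n}_{k}_{seed}"]
    if n_inputs:
        lines.append("inputs: " + ", ".join(names[:n_inputs]))
    for name in names[n_inputs:]:
        regs = [names[i] for i in rng.choice(n, size=k, replace=False)]
        while True:
            table = rng.integers(0, 2, size=2**k)
            if 0 < table.sum() < 2**k:
                break
        minterms = []
        for bits in itertools.product((0, 1), repeat=k):
            if table[sum(b << i for i, b in enumerate(bits))]:
                lits = [r if b else f"not {r}" for r, b in zip(regs, bits)]
                minterms.append("(" + " and ".join(lits) + ")")
        lines.append(f"{name} *= " + " or ".join(minterms))
    return parse_model("\n".join(lines) + "\n")


def load_published_model(path: str | Path) -> BooleanModel:
    """Load an externally supplied rule file (e.g. a published full-scale
    model in BooleanNet dialect).  Self-assignments ``X *= X`` are read as
    input declarations; unparseable lines raise with their line number."""
    path = Path(path)
    return parse_model(path.read_text(), name=path.stem)


FIXTURES = {
    "toggle": toggle_switch,
    "emt_switch": emt_switch_fixture,
    "hypoxia_demo": hypoxia_demo_model,
}

_SIGNATURES = {
    "emt_switch": emt_switch_signatures,
    "hypoxia_demo": hypoxia_demo_signatures,
}


def get_fixture(name: str) -> BooleanModel:
    try:
        return FIXTURES[name]()
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; available: {sorted(FIXTURES)}") from None


def fixture_signatures(name: str) -> SignatureSet:
    try:
        return _SIGNATURES[name]()
    except KeyError:
        raise KeyError(f"no bundled signatures for fixture {name!r}") from None


def export_fixtures(outdir: str | Path) -> list[Path]:
    """Write the bundled fixtures as rule-dialect and signature YAML files."""
    from .model_io import write_model
    from .phenotypes import dump_signatures

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, factory in FIXTURES.items():
        p = outdir / f"{name}.bnet"
        p.write_text(write_model(factory()))
        written.append(p)
        if name in _SIGNATURES:
            q = outdir / f"{name}_signatures.yaml"
            q.write_text(dump_signatures(_SIGNATURES[name]()))
            written.append(q)
    return written
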