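"""Mapping states and trajectories to named cell phenotypes.

A phenotype signature is a partial node-state pattern attached to a
regulatory module — e.g. ``Mesenchymal = {ZEB1: 1, miR200: 0, Ecadherin: 0}``
on the EMT module.  Classification picks, per module, the highest-priority
signature satisfied by a state; mutually exclusive signature sets make the
priority ranks a safety net rather than a decision rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .dynamics import Trajectory
from .model_io import BooleanModel

__all__ = [
    "PhenotypeSignature",
    "SignatureSet",
    "classify_state",
    "window_statistics",
    "load_signatures",
    "dump_signatures",
]

UNCLASSIFIED = "unclassified"

State = tuple[int, ...]


@dataclass(frozen=True)
class PhenotypeSignature:
    """A named partial assignment: the state pattern defining a phenotype."""

    name: str
    module: str
    states: Mapping[str, int] = field(default_factory=dict)
    priority: int = 0

    def matches(self, state: State, model: BooleanModel) -> bool:
        return all(state[model.index[n]] == v for n, v in self.states.items())


class SignatureSet:
    """Validated collection of signatures, grouped by module."""

    def __init__(self, signatures: Iterable[PhenotypeSignature], model: BooleanModel):
        self.signatures = tuple(signatures)
        self.model = model
        for sig in self.signatures:
            for node in sig.states:
                if node not in model.index:
                    raise KeyError(
                        f"signature {sig.name!r} references unknown node {node!r}"
                    )
        self.by_module: dict[str, tuple[PhenotypeSignature, ...]] = {}
        for sig in self.signatures:
            self.by_module.setdefault(sig.module, ())
            self.by_module[sig.module] += (sig,)

    @property
    def modules(self) -> tuple[str, ...]:
        return tuple(self.by_module)

    def phenotypes(self, module: str) -> tuple[str, ...]:
        return tuple(s.name for s in self.by_module[module])

    def get(self, name: str) -> PhenotypeSignature:
        for sig in self.signatures:
            if sig.name == name:
                return sig
        raise KeyError(f"no signature named {name!r}")


def classify_state(
    state: State,
    signatures: SignatureSet,
    model: BooleanModel | None = None,
) -> dict[str, str]:
    """Per-module phenotype of one state.

    Returns ``{module: phenotype-name or "unclassified"}``.  Two satisfied
    signatures of equal priority within one module mean the signature set
    is ill-formed and raise ``ValueError``.
    """
    model = model or signatures.model
    profile: dict[str, str] = {}
    for module, sigs in signatures.by_module.items():
        satisfied = [s for s in sigs if s.matches(state, model)]
        if not satisfied:
            profile[module] = UNCLASSIFIED
            continue
        top = max(s.priority for s in satisfied)
        winners = [s for s in satisfied if s.priority == top]
        if len(winners) > 1:
            raise ValueError(
                f"ambiguous phenotype in module {module!r}: "
                + ", ".join(s.name for s in winners)
            )
        profile[module] = winners[0].name
    return profile


def window_statistics(
    trajectories: Sequence[Trajectory],
    signatures: SignatureSet,
    windows: Sequence[slice] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Ensemble statistics per window: phenotype fractions and node means.

    All trajectories must share the schedule.  Fractions are computed over
    the live states each trajectory actually contains (trajectories
    truncated at death simply contribute fewer states).  For an exhaustive
    signature set the per-module fractions (including "unclassified") sum
    to 1 per window.

    Returns ``(fractions, node_means)``: long-format frames with columns
    ``window, module, phenotype, fraction`` and ``window, node, mean``.
    """
    if not trajectories:
        raise ValueError("empty ensemble")
    model = trajectories[0].model
    ref_windows = trajectories[0].windows
    for traj in trajectories:
        if traj.windows != ref_windows:
            raise ValueError("trajectories do not share a schedule")
    if windows is None:
        windows = trajectories[0].window_slices()

    frac_rows, mean_rows = [], []
    names = model.names
    for w_idx, sl in enumerate(windows):
        counts: dict[str, dict[str, int]] = {
            m: {p: 0 for p in signatures.phenotypes(m)} | {UNCLASSIFIED: 0}
            for m in signatures.modules
        }
        node_sums = [0] * len(model)
        total = 0
        for traj in trajectories:
            for state in traj.states[sl]:
                total += 1
                for i, v in enumerate(state):
                    node_sums[i] += v
                for module, phen in classify_state(state, signatures, model).items():
                    counts[module][phen] += 1
        for module, phens in counts.items():
            for phen, c in phens.items():
                frac_rows.append(
                    {
                        "window": w_idx,
                        "module": module,
                        "phenotype": phen,
                        "fraction": c / total if total else float("nan"),
                    }
                )
        for name, s in zip(names, node_sums):
            mean_rows.append(
                {"window": w_idx, "node": name,
                 "mean": s / total if total else float("nan")}
            )
    return pd.DataFrame(frac_rows), pd.DataFrame(mean_rows)


# -- YAML serialization ----------------------------------------------------

def load_signatures(text: str, model: BooleanModel) -> SignatureSet:
    """Load a signature set from YAML.

    Schema::

        signatures:
          - module: EMT
            name: Epithelial
            priority: 0
            states: {miR200: 1, Ecadherin: 1, SNAI1: 0, ZEB1: 0}
    """
    doc = yaml.safe_load(text)
    sigs = []
    for entry in doc["signatures"]:
        sigs.append(
            PhenotypeSignature(
                name=str(entry["name"]),
                module=str(entry["module"]),
                states={str(k): int(v) for k, v in entry["states"].items()},
                priority=int(entry.get("priority", 0)),
            )
        )
    return SignatureSet(sigs, model)


def dump_signatures(signatures: SignatureSet) -> str:
    doc = {
        "signatures": [
            {
                "module": s.module,
                "name": s.name,
                "priority": s.priority,
                "states": dict(s.states),
            }
            for s in signatures.signatures
        ]
    }
    return yaml.safe_dump(doc, sort_keys=False)
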