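"""Assay-matching statistics: simulated perturbations vs. curated
in vitro observations.

Each assay record names a perturbation (node clamp), an environment, a
readout (node activity or module phenotype fraction) and the in vitro
direction of change.  The harness simulates matched control and perturbed
ensembles, computes per-cell readout values, applies an unpaired
two-sample t-test with a minimum-relative-change rule, and summarizes
match rates at the test and assay level.

A simulation matches an observation when either (i) there is a
significant change (p < α) in the in vitro direction of at least 5% of
the average of the two compared values, or (ii) there is no change, no
significant change, or a sub-5% difference, matching an in vitro result
that itself showed no significant change.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dynamics import Clamp, Window
from .model_io import BooleanModel
from .phenotypes import SignatureSet, classify_state
from .protocols import ExperimentSpec, run_experiment

__all__ = [
    "AssayRecord",
    "MatchRule",
    "MatchResult",
    "load_assays",
    "compare_assay",
    "simulate_assay",
    "run_validation",
    "summarize_validation",
    "ValidationSummary",
]

DIRECTIONS = ("increase", "decrease", "no-change")


@dataclass(frozen=True)
class AssayRecord:
    """One curated in vitro observation (one statistical test)."""

    assay_id: str
    source: str
    node: str                      # perturbed node
    mode: str                      # "on" | "off"
    level: float                   # clamp level in [0, 1]
    environment: Mapping[str, int] = field(default_factory=dict)
    readout: str = ""              # node name, or "phenotype:<module>:<name>"
    direction: str = "no-change"
    control_environment: Mapping[str, int] | None = None
    experiment: str = ""           # simulation pointer
    window: int = -1               # window index the readout averages over
    contradictory: bool = False    # flagged as contradicting other sources

    def __post_init__(self):
        if self.direction not in DIRECTIONS:
            raise ValueError(
                f"direction must be one of {DIRECTIONS}, got {self.direction!r}"
            )
        if not 0.0 <= self.level <= 1.0:
            raise ValueError("perturbation level must be in [0, 1]")


@dataclass(frozen=True)
class MatchRule:
    """Decision rule for one comparison."""

    alpha: float = 0.05
    min_relative_change: float = 0.05  # of the average of the two values
    test: str = "welch"                # "welch" | "student"


@dataclass(frozen=True)
class MatchResult:
    assay_id: str
    control_mean: float
    perturbed_mean: float
    statistic: float
    p_value: float
    relative_change: float
    direction: str       # detected: increase | decrease | no-change
    expected: str
    verdict: str         # match | mismatch | contradictory-source

    @property
    def matched(self) -> bool:
        return self.verdict == "match"


def _env_string(env: Mapping[str, int] | None) -> str:
    return ";".join(f"{k}={int(v)}" for k, v in (env or {}).items())


def _parse_env(text) -> dict[str, int]:
    if text is None or (isinstance(text, float) and np.isnan(text)) or text == "":
        return {}
    env = {}
    for part in str(text).split(";"):
        part = part.strip()
        if part:
            k, v = part.split("=")
            env[k.strip()] = int(float(v))
    return env


ASSAY_COLUMNS = [
    "assay_id", "source", "perturb_node", "perturb_mode", "perturb_level",
    "environment", "control_environment", "readout", "direction",
    "experiment", "window", "contradictory",
]


def load_assays(source: str | Path) -> list[AssayRecord]:
    """Read assay records from CSV text or a file path.

    The header must carry the schema columns (``assay_id, source,
    perturb_node, perturb_mode, perturb_level, environment, readout,
    direction, ...``); environments are ``Name=0;Name=1`` strings.  An
    unknown direction token raises with its row number.
    """
    if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source
                                    and source.endswith(".csv")):
        text = Path(source).read_text()
    else:
        text = str(source)
    df = pd.read_csv(StringIO(text))
    missing = {"assay_id", "perturb_node", "perturb_mode", "readout", "direction"} - set(df.columns)
    if missing:
        raise ValueError(f"assay table lacks columns: {sorted(missing)}")
    records = []
    for i, row in df.iterrows():
        direction = str(row["direction"]).strip()
        if direction not in DIRECTIONS:
            raise ValueError(f"row {i + 2}: unknown direction {direction!r}")
        ctrl = row.get("control_environment")
        records.append(
            AssayRecord(
                assay_id=str(row["assay_id"]),
                source=str(row.get("source", "")),
                node=str(row["perturb_node"]),
                mode=str(row["perturb_mode"]),
                level=float(row.get("perturb_level", 1.0)),
                environment=_parse_env(row.get("environment")),
                readout=str(row["readout"]),
                direction=direction,
                control_environment=_parse_env(ctrl) or None,
                experiment=("" if pd.isna(row.get("experiment", ""))
                            else str(row.get("experiment", ""))),
                window=int(row.get("window", -1)) if not pd.isna(row.get("window", -1)) else -1,
                contradictory=bool(row.get("contradictory", False)),
            )
        )
    return records


def dump_assays(records: Sequence[AssayRecord]) -> str:
    rows = []
    for r in records:
        rows.append({
            "assay_id": r.assay_id, "source": r.source, "perturb_node": r.node,
            "perturb_mode": r.mode, "perturb_level": r.level,
            "environment": _env_string(r.environment),
            "control_environment": _env_string(r.control_environment),
            "readout": r.readout, "direction": r.direction,
            "experiment": r.experiment, "window": r.window,
            "contradictory": r.contradictory,
        })
    return pd.DataFrame(rows, columns=ASSAY_COLUMNS).to_csv(index=False)


def compare_assay(
    control: Sequence[float],
    perturbed: Sequence[float],
    expected: str,
    rule: MatchRule = MatchRule(),
    assay_id: str = "",
    contradictory: bool = False,
) -> MatchResult:
    """Apply the match rule to per-cell readout values.

    Degenerate variance (all values equal in both samples, as Boolean
    ensembles can saturate) falls back to exact equality of means.
    """
    control = np.asarray(control, dtype=float)
    perturbed = np.asarray(perturbed, dtype=float)
    if control.size == 0 or perturbed.size == 0:
        raise ValueError("empty sample")
    mc, mp = control.mean(), perturbed.mean()
    diff = mp - mc
    avg = (mc + mp) / 2.0
    if control.std() == 0.0 and perturbed.std() == 0.0:
        statistic = float("inf") if diff else 0.0
        p = 0.0 if diff else 1.0
    else:
        statistic, p = stats.ttest_ind(
            perturbed, control, equal_var=(rule.test == "student")
        )
        statistic, p = float(statistic), float(p)
    rel = abs(diff) / avg if avg else (float("inf") if diff else 0.0)
    detected = "increase" if diff > 0 else ("decrease" if diff < 0 else "no-change")
    significant = p < rule.alpha and rel >= rule.min_relative_change and diff != 0
    if expected == "no-change":
        matched = not significant
    else:
        matched = significant and detected == expected
    verdict = "match" if matched else ("contradictory-source" if contradictory else "mismatch")
    return MatchResult(
        assay_id=assay_id, control_mean=mc, perturbed_mean=mp,
        statistic=statistic, p_value=p, relative_change=rel,
        direction=detected, expected=expected, verdict=verdict,
    )


def _readout_values(result, record: AssayRecord, signatures: SignatureSet) -> list[float]:
    """Per-cell readout: mean activity of a node, or fraction of window
    steps matching a phenotype, over the assay's window."""
    model = result.spec.model
    values = []
    for traj in result.trajectories:
        slices = traj.window_slices()
        sl = slices[record.window if record.window >= 0 else len(slices) + record.window]
        states = traj.states[sl]
        if not states:
            continue
        if record.readout.startswith("phenotype:"):
            _, module, name = record.readout.split(":")
            hits = sum(
                1 for s in states
                if classify_state(s, signatures, model).get(module) == name
            )
            values.append(hits / len(states))
        else:
            idx = model.index[record.readout]
            values.append(sum(s[idx] for s in states) / len(states))
    return values


def simulate_assay(
    model: BooleanModel,
    record: AssayRecord,
    signatures: SignatureSet,
    n_cells: int = 30,
    steps: int = 40,
    noise: float = 0.02,
    seed: int = 0,
    initial_phenotype: str = "Epithelial",
    initial_env: Mapping[str, int] | None = None,
) -> tuple[list[float], list[float]]:
    """Simulate control and perturbed ensembles for one assay.

    Both ensembles start from the same resolved phenotype — looked up in
    ``initial_env`` (default: the control environment) — and share the
    window structure; the perturbed ensemble adds the record's clamp.
    Returns (control, perturbed) per-cell readout values.
    """
    ctrl_env = dict(record.control_environment or record.environment)
    pert_env = dict(record.environment)
    init_env = dict(initial_env) if initial_env is not None else ctrl_env

    def build(env, clamps, salt):
        window = Window(steps, env, clamps, noise)
        spec = ExperimentSpec(
            model=model, windows=(window,), signatures=signatures,
            initial_phenotype=initial_phenotype, initial_env=init_env,
            ensemble=n_cells, seed=seed + salt, name=record.assay_id,
        )
        return run_experiment(spec)

    control = build(ctrl_env, {}, 0)
    perturbed = build(pert_env, {record.node: Clamp(record.mode, record.level)}, 1)
    return (
        _readout_values(control, record, signatures),
        _readout_values(perturbed, record, signatures),
    )


@dataclass
class ValidationSummary:
    results: list[MatchResult]
    tests_total: int
    tests_matched: int
    assays_total: int
    assays_matched: int
    contradictory_assays: list[str]
    by_source: pd.DataFrame

    @property
    def test_match_pct(self) -> float:
        return 100.0 * self.tests_matched / self.tests_total

    @property
    def assay_match_pct(self) -> float:
        return 100.0 * self.assays_matched / self.assays_total

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.results])

    def report(self) -> str:
        lines = [
            f"assays matched: {self.assays_matched}/{self.assays_total} "
            f"({self.assay_match_pct:.1f}%)",
            f"tests matched:  {self.tests_matched}/{self.tests_total} "
            f"({self.test_match_pct:.1f}%)",
        ]
        if self.contradictory_assays:
            lines.append(
                "contradictory-source assays: " + ", ".join(self.contradictory_assays)
            )
        return "\n".join(lines)


def summarize_validation(
    results: Sequence[MatchResult],
    sources: Mapping[str, str] | None = None,
) -> ValidationSummary:
    """Assay- and test-level match percentages with per-source breakdown.

    An assay (a group of tests sharing an assay id) counts as matched when
    every one of its tests matched; assays whose failures are flagged
    contradictory-source are listed separately.
    """
    if not results:
        raise ValueError("no results to summarize")
    tests_matched = sum(r.matched for r in results)
    by_assay: dict[str, list[MatchResult]] = {}
    for r in results:
        by_assay.setdefault(r.assay_id, []).append(r)
    assays_matched = sum(all(r.matched for r in rs) for rs in by_assay.values())
    contradictory = sorted(
        aid for aid, rs in by_assay.items()
        if any(r.verdict == "contradictory-source" for r in rs)
    )
    rows = []
    if sources:
        per_source: dict[str, list[MatchResult]] = {}
        for r in results:
            per_source.setdefault(sources.get(r.assay_id, ""), []).append(r)
        for src, rs in sorted(per_source.items()):
            rows.append({"source": src, "tests": len(rs),
                         "matched": sum(r.matched for r in rs)})
    return ValidationSummary(
        results=list(results),
        tests_total=len(results),
        tests_matched=tests_matched,
        assays_total=len(by_assay),
        assays_matched=assays_matched,
        contradictory_assays=contradictory,
        by_source=pd.DataFrame(rows, columns=["source", "tests", "matched"]),
    )


def run_validation(
    model: BooleanModel,
    records: Sequence[AssayRecord],
    signatures: SignatureSet,
    rule: MatchRule = MatchRule(),
    n_cells: int = 30,
    steps: int = 40,
    noise: float = 0.02,
    seed: int = 0,
    initial_phenotype: str = "Epithelial",
    initial_env: Mapping[str, int] | None = None,
) -> ValidationSummary:
    """Simulate and score every assay record; reproducible for a fixed seed."""
    results = []
    for i, record in enumerate(records):
        control, perturbed = simulate_assay(
            model, record, signatures, n_cells=n_cells, steps=steps,
            noise=noise, seed=seed + 1000 * i, initial_phenotype=initial_phenotype,
            initial_env=initial_env,
        )
        results.append(
            compare_assay(control, perturbed, record.direction, rule,
                          assay_id=record.assay_id, contradictory=record.contradictory)
        )
    return summarize_validation(results, {r.assay_id: r.source for r in records})
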