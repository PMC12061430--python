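"""Experiment protocols over cell ensembles.

An :class:`ExperimentSpec` declares a model, an initial condition (an
explicit state, or a named phenotype resolved against the attractors of an
initial environment), an ordered list of windows (environment, clamps,
noise), ensemble size or a live-step budget, a signature set, and an
optional death signature.  :func:`run_experiment` executes it with
apoptosis-aware live-time accounting; :func:`run_grid` sweeps input or
clamp levels, optionally across mutation backgrounds; and
:func:`run_cascade_preset` executes the seven-pulse metastatic-cascade
environment sequence.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .dynamics import (
    Clamp,
    Trajectory,
    Window,
    substream,
    synchronous_step,
)
from .attractors import enumerate_attractors, sample_attractors, SamplingConfig
from .model_io import BooleanModel
from .phenotypes import (
    PhenotypeSignature,
    SignatureSet,
    classify_state,
    load_signatures,
    window_statistics,
)

__all__ = [
    "ExperimentSpec",
    "EnsembleResult",
    "GridAxis",
    "resolve_initial_state",
    "run_experiment",
    "run_grid",
    "run_cascade_preset",
    "cascade_windows",
    "count_divisions",
    "load_protocol",
    "DEFAULT_DOSE_LADDER",
]

State = tuple[int, ...]

# log2-style dose ladder (fractions of full knockdown/activation)
DEFAULT_DOSE_LADDER = (0.0, 0.00625, 0.0125, 0.025, 0.05, 0.10, 0.20, 0.40, 0.80)


def resolve_initial_state(
    model: BooleanModel,
    phenotype: str,
    env: Mapping[str, int],
    signatures: SignatureSet,
    clamps: Mapping[str, Clamp] | None = None,
    enumeration_cap: int = 22,
) -> State:
    """The state of the unique attractor matching a named phenotype.

    Attractors of ``env`` are enumerated (or sampled, beyond the
    enumeration cap) and filtered by the phenotype of their first cycle
    state in the signature's module; exactly one attractor must match.
    For cyclic attractors the canonical first state is returned.
    """
    sig = signatures.get(phenotype)
    free = [i for i in model.free_indices]
    if len(free) <= enumeration_cap:
        attrs = enumerate_attractors(model, env, clamps, cap=enumeration_cap)
    else:
        config = SamplingConfig(environments=(dict(env),))
        attrs = sample_attractors(model, config, seed=0).entries[0][1]
    matching = [
        a for a in attrs
        if classify_state(a.states[0], signatures, model).get(sig.module) == phenotype
    ]
    if not matching:
        raise ValueError(
            f"no attractor matching phenotype {phenotype!r} in environment {dict(env)!r}"
        )
    if len(matching) > 1:
        raise ValueError(
            f"multiple attractors match phenotype {phenotype!r}: "
            + "; ".join(str(a.states[0]) for a in matching)
        )
    return matching[0].states[0]


@dataclass(frozen=True)
class ExperimentSpec:
    """Declarative description of one ensemble experiment."""

    model: BooleanModel
    windows: tuple[Window, ...]
    signatures: SignatureSet
    initial_state: State | None = None
    initial_phenotype: str | None = None
    initial_env: Mapping[str, int] = field(default_factory=dict)
    ensemble: int = 1
    budget: int | None = None  # live-step budget => continuous mode
    death_signature: str | None = None  # phenotype name, e.g. "Apoptotic"
    seed: int = 0
    name: str = ""

    def __post_init__(self):
        if not self.windows:
            raise ValueError("experiment needs at least one window")
        if self.initial_state is None and self.initial_phenotype is None:
            raise ValueError("need an initial state or an initial phenotype")
        if self.budget is None and self.ensemble <= 0:
            raise ValueError("ensemble size must be positive")

    def resolve_initial(self) -> State:
        if self.initial_state is not None:
            return tuple(int(v) for v in self.initial_state)
        return resolve_initial_state(
            self.model, self.initial_phenotype, self.initial_env, self.signatures
        )


@dataclass
class EnsembleResult:
    """Aggregated outcome of :func:`run_experiment`.

    ``fractions``/``node_means`` are the long-format frames of
    :func:`hypoxemt.phenotypes.window_statistics`; live-step accounting
    guarantees ``live_steps`` equals the budget in continuous mode.
    """

    spec: ExperimentSpec
    fractions: pd.DataFrame
    node_means: pd.DataFrame
    deaths: int
    restarts: int
    live_steps: int
    trajectories: list[Trajectory] = field(default_factory=list)

    def fraction(self, module: str, phenotype: str, window: int = -1) -> float:
        df = self.fractions
        if window < 0:
            window = df["window"].max() + 1 + window
        row = df[(df["window"] == window) & (df["module"] == module)
                 & (df["phenotype"] == phenotype)]
        return float(row["fraction"].iloc[0])


def _death_sig(spec: ExperimentSpec) -> PhenotypeSignature | None:
    if spec.death_signature is None:
        return None
    return spec.signatures.get(spec.death_signature)


def _run_cell(
    spec: ExperimentSpec,
    initial: State,
    cell_idx: int,
    death: PhenotypeSignature | None,
    max_live: int | None = None,
) -> tuple[Trajectory, bool, int]:
    """One cell through the schedule; truncated at death or live budget.

    Returns (trajectory, died, live_steps).  The death-matching state ends
    the trajectory and is not counted as live.
    """
    model = spec.model
    rng = substream(spec.seed, cell_idx)
    states = [initial]
    live = 0
    died = False
    state = initial
    for win in spec.windows:
        for _ in range(win.steps):
            if max_live is not None and live >= max_live:
                return Trajectory(model, tuple(states), spec.windows, spec.seed), died, live
            state = synchronous_step(model, state, win.env, win.clamps, win.noise, rng)
            states.append(state)
            if death is not None and death.matches(state, model):
                died = True
                return Trajectory(model, tuple(states), spec.windows, spec.seed), died, live
            live += 1
    return Trajectory(model, tuple(states), spec.windows, spec.seed), died, live


def run_experiment(spec: ExperimentSpec) -> EnsembleResult:
    """Run an ensemble of non-interacting cells.

    Ensemble mode (``budget is None``): ``ensemble`` cells each run the
    schedule once; a cell matching the death signature is terminated there
    (its trajectory never contains post-death states).

    Continuous mode (``budget`` set): cells run the schedule repeatedly —
    a cell that dies is replaced by a fresh cell starting from the initial
    condition, a cell that completes the schedule restarts it — until the
    total live-step budget is consumed exactly.
    """
    initial = spec.resolve_initial()
    death = _death_sig(spec)
    trajectories: list[Trajectory] = []
    deaths = restarts = 0

    if spec.budget is None:
        live_total = 0
        for c in range(spec.ensemble):
            traj, died, live = _run_cell(spec, initial, c, death)
            trajectories.append(traj)
            deaths += died
            live_total += live
    else:
        schedule_steps = sum(w.steps for w in spec.windows)
        if spec.budget < spec.windows[0].steps:
            raise ValueError(
                f"budget {spec.budget} cannot complete the first window "
                f"({spec.windows[0].steps} steps); increase the budget"
            )
        live_total = 0
        cell = 0
        while live_total < spec.budget:
            traj, died, live = _run_cell(
                spec, initial, cell, death, max_live=spec.budget - live_total
            )
            trajectories.append(traj)
            deaths += died
            live_total += live
            cell += 1
            if live == 0 and not died:
                raise RuntimeError("cell produced no live steps; aborting")
            if cell > 100 + 10 * spec.budget:
                raise RuntimeError(
                    "ensemble makes no live progress (cells die immediately); "
                    "check the death signature and initial condition"
                )
        restarts = cell - 1

    fractions, node_means = _live_window_statistics(trajectories, spec.signatures, death)
    return EnsembleResult(
        spec, fractions, node_means, deaths, restarts, live_total, trajectories
    )


def _live_window_statistics(
    trajectories: Sequence[Trajectory],
    signatures: SignatureSet,
    death: PhenotypeSignature | None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Window statistics over live states only (death states excluded)."""
    if death is None:
        return window_statistics(trajectories, signatures)
    model = trajectories[0].model
    trimmed = []
    for traj in trajectories:
        states = traj.states
        if states and death.matches(states[-1], model) and len(states) > 1:
            states = states[:-1]
        trimmed.append(Trajectory(model, states, traj.windows, traj.seed))
    return window_statistics(trimmed, signatures)


# -- grids and dose series -------------------------------------------------

@dataclass(frozen=True)
class GridAxis:
    """One swept dimension: an input level or a clamp level."""

    kind: str  # "env" | "clamp"
    node: str
    levels: tuple[float, ...]
    mode: str = "on"  # clamp direction, for kind="clamp"

    def __post_init__(self):
        if self.kind not in ("env", "clamp"):
            raise ValueError("axis kind must be 'env' or 'clamp'")


def _apply_axis(windows: tuple[Window, ...], axis: GridAxis, level: float):
    out = []
    for win in windows:
        if axis.kind == "env":
            env = dict(win.env)
            env[axis.node] = level
            out.append(replace(win, env=env))
        else:
            clamps = dict(win.clamps)
            clamps[axis.node] = Clamp(axis.mode, level)
            out.append(replace(win, clamps=clamps))
    return tuple(out)


def _apply_background(windows: tuple[Window, ...], background: Mapping[str, Clamp]):
    out = []
    for win in windows:
        clamps = dict(win.clamps)
        clamps.update(background)
        out.append(replace(win, clamps=clamps))
    return tuple(out)


def run_grid(
    spec: ExperimentSpec,
    axes: Sequence[GridAxis],
    backgrounds: Mapping[str, Mapping[str, Clamp]] | None = None,
) -> pd.DataFrame:
    """Sweep 1–2 axes (input or clamp levels), per mutation background.

    Returns a long-format frame with one row per (background, axis levels,
    window, module, phenotype): the phenotype fraction at that grid point.
    A single-point grid reproduces :func:`run_experiment` on the same spec.
    """
    if not 1 <= len(axes) <= 2:
        raise ValueError("grids support one or two axes")
    backgrounds = backgrounds or {"wild-type": {}}
    rows = []
    for bg_name, bg_clamps in backgrounds.items():
        for levels in itertools.product(*(ax.levels for ax in axes)):
            windows = _apply_background(spec.windows, bg_clamps)
            for ax, level in zip(axes, levels):
                windows = _apply_axis(windows, ax, level)
            point = replace(spec, windows=windows)
            result = run_experiment(point)
            for _, r in result.fractions.iterrows():
                row = {"background": bg_name}
                for ax, level in zip(axes, levels):
                    row[ax.node] = level
                row.update(window=int(r["window"]), module=r["module"],
                           phenotype=r["phenotype"], fraction=r["fraction"])
                rows.append(row)
    return pd.DataFrame(rows)


# -- the metastatic-cascade preset ----------------------------------------

_CASCADE_PULSES = (
    # (label, Hypoxia, Stiff_ECM, ECM_attached, Density_High)
    ("primary epithelium",      0, 1, 1, 1),
    ("hypoxic tumor core",      1, 1, 1, 1),
    ("hypoxia, density drop",   1, 1, 1, 0),
    ("invasion",                0, 1, 1, 0),
    ("intravasation",           0, 0, 0, 0),
    ("extravasation",           0, 0, 1, 0),
    ("secondary site (MET)",    0, 1, 1, 1),
)


def cascade_windows(
    steps_per_pulse: int = 20,
    noise: float = 0.0,
    tgfb_secr_knockdown: float = 0.0,
) -> tuple[Window, ...]:
    """The seven-pulse environment sequence of the metastatic cascade.

    Growth factor is saturating throughout and external TGF-β absent; an
    optional partial TGFb_secr knockdown weakens the autocrine loop.
    """
    windows = []
    for _, hyp, stiff, attached, dense in _CASCADE_PULSES:
        env = {
            "Hypoxia": hyp, "GF": 1, "TGFb_ext": 0,
            "Stiff_ECM": stiff, "ECM_attached": attached, "Density_High": dense,
        }
        clamps = {}
        if tgfb_secr_knockdown > 0:
            clamps["TGFb_secr"] = Clamp("off", tgfb_secr_knockdown)
        windows.append(Window(steps_per_pulse, env, clamps, noise))
    return tuple(windows)


def run_cascade_preset(
    model: BooleanModel,
    signatures: SignatureSet,
    ensemble: int = 50,
    steps_per_pulse: int = 20,
    noise: float = 0.0,
    tgfb_secr_knockdown: float = 0.0,
    seed: int = 0,
) -> EnsembleResult:
    """Execute the metastatic cascade on a model with the six
    microenvironment inputs, starting from the epithelial attractor of the
    primary epithelium (normoxia, stiff ECM, high density)."""
    required = {"Hypoxia", "GF", "TGFb_ext", "Stiff_ECM", "ECM_attached", "Density_High"}
    missing = required - set(model.input_names)
    if missing:
        raise ValueError(f"model lacks required inputs: {sorted(missing)}")
    windows = cascade_windows(steps_per_pulse, noise, tgfb_secr_knockdown)
    spec = ExperimentSpec(
        model=model,
        windows=windows,
        signatures=signatures,
        initial_phenotype="Epithelial",
        initial_env=dict(windows[0].env),
        ensemble=ensemble,
        death_signature="Apoptotic" if "death" in signatures.modules else None,
        seed=seed,
        name="metastatic_cascade",
    )
    return run_experiment(spec)


# -- division counting -----------------------------------------------------

def count_divisions(
    trajectories: Sequence[Trajectory],
    marker: PhenotypeSignature,
    windows: Sequence[slice] | None = None,
) -> pd.DataFrame:
    """Count division events as rising edges of a mitotic-exit marker.

    Returns one row per window: mean divisions per cell and the implied
    mean cycle length (window steps / mean divisions; NaN when no
    divisions occurred, e.g. for a constantly ON marker after its first
    edge).
    """
    if not trajectories:
        raise ValueError("empty ensemble")
    model = trajectories[0].model
    if windows is None:
        windows = trajectories[0].window_slices()
    rows = []
    for w_idx, sl in enumerate(windows):
        total_edges = 0
        for traj in trajectories:
            prev_match = marker.matches(traj.states[max(sl.start - 1, 0)], model)
            for state in traj.states[sl]:
                match = marker.matches(state, model)
                if match and not prev_match:
                    total_edges += 1
                prev_match = match
        steps = sl.stop - sl.start
        mean_div = total_edges / len(trajectories)
        rows.append(
            {
                "window": w_idx,
                "divisions_mean": mean_div,
                "cycle_length": steps / mean_div if mean_div > 0 else float("nan"),
            }
        )
    return pd.DataFrame(rows)


# -- protocol files --------------------------------------------------------

def _clamp_mode(token) -> str:
    # YAML 1.1 reads bare on/off as booleans
    if isinstance(token, bool):
        return "on" if token else "off"
    return str(token)


def _parse_clamps(entries) -> dict[str, Clamp]:
    clamps = {}
    for e in entries or []:
        clamps[str(e["node"])] = Clamp(_clamp_mode(e["mode"]), float(e.get("level", 1.0)))
    return clamps


def load_protocol(
    text: str,
    model: BooleanModel | None = None,
    signatures: SignatureSet | None = None,
) -> tuple[ExperimentSpec, list[GridAxis]]:
    """Build an :class:`ExperimentSpec` (plus any series axes) from YAML.

    Schema (`model`/`signatures` may be `fixture:NAME` or file paths, or
    supplied in-memory by the caller)::

        name: hypoxia_dose
        model: fixture:hypoxia_demo
        signatures: fixture:hypoxia_demo
        initial: {phenotype: Epithelial, env: {Hypoxia: 0, GF: 1, ...}}
        windows:
          - steps: 60
            env: {Hypoxia: 0, GF: 1, Stiff_ECM: 1, ECM_attached: 1,
                  TGFb_ext: 0, Density_High: 0}
            clamps: [{node: TGFb_secr, mode: off, level: 0.05}]
            noise: 0.02
        ensemble: 200
        budget: null
        death: Apoptotic
        seed: 7
        series:
          - {kind: env, node: Hypoxia, levels: [0, 0.25, 0.5, 0.75, 1]}
    """
    from . import fixtures as _fixtures

    doc = yaml.safe_load(text)

    def _resolve_model(ref):
        if model is not None:
            return model
        if isinstance(ref, str) and ref.startswith("fixture:"):
            return _fixtures.get_fixture(ref.split(":", 1)[1])
        return _fixtures.load_published_model(ref)

    mdl = _resolve_model(doc.get("model"))

    sig_ref = doc.get("signatures")
    if signatures is not None:
        sigs = signatures
    elif isinstance(sig_ref, str) and sig_ref.startswith("fixture:"):
        sigs = _fixtures.fixture_signatures(sig_ref.split(":", 1)[1])
    elif sig_ref is not None:
        sigs = load_signatures(Path(sig_ref).read_text(), mdl)
    else:
        raise ValueError("protocol needs a 'signatures' entry")

    windows = tuple(
        Window(
            steps=int(w["steps"]),
            env={str(k): float(v) for k, v in (w.get("env") or {}).items()},
            clamps=_parse_clamps(w.get("clamps")),
            noise=float(w.get("noise", 0.0)),
        )
        for w in doc["windows"]
    )

    init = doc.get("initial") or {}
    spec = ExperimentSpec(
        model=mdl,
        windows=windows,
        signatures=sigs,
        initial_state=(mdl.state_from(init["state"]) if "state" in init else None),
        initial_phenotype=init.get("phenotype"),
        initial_env={str(k): int(v) for k, v in (init.get("env") or {}).items()},
        ensemble=int(doc.get("ensemble", 1)),
        budget=doc.get("budget"),
        death_signature=doc.get("death"),
        seed=int(doc.get("seed", 0)),
        name=str(doc.get("name", "")),
    )
    axes = [
        GridAxis(
            kind=str(a["kind"]),
            node=str(a["node"]),
            levels=tuple(float(x) for x in a.get("levels", DEFAULT_DOSE_LADDER)),
            mode=_clamp_mode(a.get("mode", "on")),
        )
        for a in doc.get("series") or []
    ]
    return spec, axes
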