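"""Synchronous update dynamics with stochastic layers.

One synchronous step applies, in order:

1. every non-input node's rule, evaluated simultaneously on the previous
   state;
2. resampling of each environmental input as Bernoulli(level) — levels of
   0/1 mean always OFF/ON, intermediate levels model non-saturating
   environments;
3. clamp overrides: each clamped node is forced to its target value with
   per-step probability ``q`` (partial knockdown / hyper-activation);
4. flip noise: each non-input, non-clamped node is inverted with
   probability ``p``.

With ``p = 0``, binary input levels and binary clamp levels the step is a
deterministic function of the previous state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .model_io import BooleanModel

__all__ = [
    "Clamp",
    "NoiseSpec",
    "Window",
    "Trajectory",
    "clamp_on",
    "clamp_off",
    "compile_rules",
    "compiled_step",
    "synchronous_step",
    "simulate_trajectory",
    "substream",
]

State = tuple[int, ...]


@dataclass(frozen=True)
class Clamp:
    """Override of one node: force ON or OFF with per-step probability q."""

    mode: str  # "on" | "off"
    level: float = 1.0

    def __post_init__(self):
        if self.mode not in ("on", "off"):
            raise ValueError(f"clamp mode must be 'on' or 'off', got {self.mode!r}")
        if not 0.0 <= self.level <= 1.0:
            raise ValueError(f"clamp level must be in [0, 1], got {self.level}")

    @property
    def value(self) -> int:
        return 1 if self.mode == "on" else 0


def clamp_on(level: float = 1.0) -> Clamp:
    return Clamp("on", level)


def clamp_off(level: float = 1.0) -> Clamp:
    return Clamp("off", level)


@dataclass(frozen=True)
class NoiseSpec:
    """Per-node, per-step flip probability for free (rule-driven) nodes."""

    p: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"noise probability must be in [0, 1], got {self.p}")


def _as_noise(noise) -> float:
    if noise is None:
        return 0.0
    if isinstance(noise, NoiseSpec):
        return noise.p
    return NoiseSpec(float(noise)).p


def _as_clamps(model: BooleanModel, clamps) -> dict[int, Clamp]:
    if not clamps:
        return {}
    out: dict[int, Clamp] = {}
    for name, clamp in clamps.items():
        if name not in model.index:
            raise KeyError(f"clamp on unknown node {name!r}")
        if not isinstance(clamp, Clamp):
            mode, level = clamp
            clamp = Clamp(mode, level)
        out[model.index[name]] = clamp
    return out


def compile_rules(model: BooleanModel) -> Callable[[State], State]:
    """Compile the whole synchronous rule map to one Python function.

    Inputs map to themselves (they are resampled separately).  The result
    is cached on the model.
    """
    if model._rules_fn is not None:
        return model._rules_fn
    names = model.names
    parts = []
    for node in model.nodes:
        expr = node.name if node.is_input else f"({node.rule.text})"
        parts.append(f"1 if {expr} else 0")
    src = (
        "def _step(_s):\n"
        f"    ({', '.join(names)},) = _s\n"
        f"    return ({', '.join(parts)},)\n"
    )
    ns: dict = {"__builtins__": {}}
    exec(src, ns)
    model._rules_fn = ns["_step"]
    return model._rules_fn


def compiled_step(
    model: BooleanModel,
    env: Mapping[str, float] | None = None,
    clamps: Mapping[str, Clamp] | None = None,
) -> Callable[[State], State]:
    """Deterministic synchronous step for binary env levels and clamps.

    Raises ``ValueError`` when any level is fractional — deterministic
    descent (attractor analysis) requires a well-defined map.
    """
    rules = compile_rules(model)
    overrides: list[tuple[int, int]] = []
    env = env or {}
    for name, level in env.items():
        if name not in model.index:
            raise KeyError(f"unknown input {name!r}")
        if level not in (0, 1, 0.0, 1.0):
            raise ValueError(f"deterministic step needs binary level for {name!r}, got {level}")
        overrides.append((model.index[name], int(level)))
    for idx, clamp in _as_clamps(model, clamps).items():
        if clamp.level == 0.0:
            continue
        if clamp.level != 1.0:
            raise ValueError("deterministic step needs clamp levels of 0 or 1")
        overrides.append((idx, clamp.value))
    if not overrides:
        return rules

    def step(state: State) -> State:
        out = list(rules(state))
        for i, v in overrides:
            out[i] = v
        return tuple(out)

    return step


def synchronous_step(
    model: BooleanModel,
    state: State,
    env: Mapping[str, float] | None = None,
    clamps: Mapping[str, Clamp] | None = None,
    noise: NoiseSpec | float | None = None,
    rng: np.random.Generator | None = None,
) -> State:
    """One synchronous update with the stochastic layers described above.

    ``env`` maps input names to levels in [0, 1]; inputs not listed hold
    their previous value.  A generator is required whenever any level,
    clamp or noise probability is fractional.
    """
    if len(state) != len(model):
        raise ValueError("state length does not match model")
    p = _as_noise(noise)
    clamp_map = _as_clamps(model, clamps)

    def draw() -> float:
        if rng is None:
            raise ValueError("rng required for stochastic levels/noise")
        return rng.random()

    out = list(compile_rules(model)(state))
    env = env or {}
    for name, level in env.items():
        if name not in model.index:
            raise KeyError(f"unknown input {name!r}")
        i = model.index[name]
        if level <= 0.0:
            out[i] = 0
        elif level >= 1.0:
            out[i] = 1
        else:
            out[i] = 1 if draw() < level else 0
    for i, clamp in clamp_map.items():
        if clamp.level >= 1.0 or (clamp.level > 0.0 and draw() < clamp.level):
            out[i] = clamp.value
    if p > 0.0:
        for i in model.free_indices:
            c = clamp_map.get(i)
            if c is not None and c.level > 0.0:  # a zero-level clamp is no clamp
                continue
            if draw() < p:
                out[i] = 1 - out[i]
    return tuple(out)


@dataclass(frozen=True)
class Window:
    """A simulation window: a fixed environment/clamp/noise regime."""

    steps: int
    env: Mapping[str, float] = field(default_factory=dict)
    clamps: Mapping[str, Clamp] = field(default_factory=dict)
    noise: float = 0.0

    def __post_init__(self):
        if self.steps <= 0:
            raise ValueError("window length must be positive")


@dataclass(frozen=True)
class Trajectory:
    """A time-ordered state sequence plus everything that produced it.

    ``states[0]`` is the initial condition; window ``k`` produced the
    states in ``window_slices()[k]``.
    """

    model: BooleanModel
    states: tuple[State, ...]
    windows: tuple[Window, ...]
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.states)

    def window_slices(self) -> list[slice]:
        slices, offset = [], 1
        for win in self.windows:
            stop = min(offset + win.steps, len(self.states))
            slices.append(slice(offset, stop))
            offset += win.steps
        return slices


def substream(seed: int, *key: int) -> np.random.Generator:
    """Counter-derived RNG substream: order-independent ensemble streams."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(key)))


def simulate_trajectory(
    model: BooleanModel,
    initial: State,
    schedule: Sequence[Window],
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> Trajectory:
    """Run an ordered sequence of windows from an initial state.

    Bit-exact reproducible for a fixed seed; with zero noise and binary
    levels the result is identical across seeds.
    """
    if rng is None:
        rng = substream(seed, 0) if seed is not None else None
    windows = tuple(schedule)
    states = [tuple(int(v) for v in initial)]
    state = states[0]
    for win in windows:
        for _ in range(win.steps):
            state = synchronous_step(model, state, win.env, win.clamps, win.noise, rng)
            states.append(state)
    return Trajectory(model, tuple(states), windows, seed)
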