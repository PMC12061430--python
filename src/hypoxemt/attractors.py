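"""Attractor detection and basin statistics.

Two complementary routes:

* :func:`enumerate_attractors` — exhaustive deterministic descent from
  every state of the free-node hypercube (exact basin weights; small
  networks, used as the oracle);
* :func:`sample_attractors` — the stochastic sampling procedure used on
  large networks: noisy time courses of length ``T`` with flip noise ``p``
  from ``N`` random initial conditions per environment, with every visited
  state descended deterministically to its attractor.  Basin weights are
  the fraction of visited states mapping to each attractor.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from io import StringIO
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .dynamics import Clamp, compiled_step, substream, synchronous_step
from .model_io import BooleanModel

__all__ = [
    "Attractor",
    "AttractorTable",
    "SamplingConfig",
    "canonical_cycle",
    "descend_to_attractor",
    "enumerate_attractors",
    "sample_attractors",
    "export_attractor_table",
    "read_attractor_table",
    "expected_visited_distribution",
]

State = tuple[int, ...]

DEFAULT_ENUMERATION_CAP = 22
DESCENT_STEP_CAP = 10**6


def canonical_cycle(states: Sequence[State]) -> tuple[State, ...]:
    """Canonical rotation of a cycle: start at the lexicographically
    smallest state, so the same cycle entered at any phase compares equal."""
    states = tuple(states)
    k = min(range(len(states)), key=lambda i: states[i])
    return states[k:] + states[:k]


@dataclass(frozen=True)
class Attractor:
    """A fixed point (length 1) or limit cycle in canonical form."""

    states: tuple[State, ...]
    environment: tuple[tuple[str, int], ...] = ()
    basin_weight: float | None = None

    @property
    def length(self) -> int:
        return len(self.states)

    @property
    def is_fixed_point(self) -> bool:
        return len(self.states) == 1

    def with_weight(self, weight: float) -> "Attractor":
        return Attractor(self.states, self.environment, weight)

    def __repr__(self) -> str:
        kind = "fixed point" if self.is_fixed_point else f"{self.length}-cycle"
        w = "" if self.basin_weight is None else f", basin={self.basin_weight:.3f}"
        return f"<Attractor {kind}{w}>"


def _env_key(env: Mapping[str, float] | None) -> tuple[tuple[str, int], ...]:
    return tuple(sorted((k, int(v)) for k, v in (env or {}).items()))


def descend_to_attractor(
    model: BooleanModel,
    state: State,
    env: Mapping[str, float] | None = None,
    clamps: Mapping[str, Clamp] | None = None,
    step_cap: int = DESCENT_STEP_CAP,
) -> tuple[Attractor, int]:
    """Noise-free descent to the attractor; returns it with the transient
    length (number of pre-cycle steps).  Environment and clamp levels must
    be binary so the descent is deterministic."""
    step = compiled_step(model, env, clamps)
    seen: dict[State, int] = {}
    path: list[State] = []
    s = tuple(int(v) for v in state)
    while s not in seen:
        if len(path) > step_cap:
            raise RuntimeError(
                f"descent exceeded {step_cap} steps; the state space of "
                f"{len(model)} nodes cannot require this many — likely a bug"
            )
        seen[s] = len(path)
        path.append(s)
        s = step(s)
    start = seen[s]
    cycle = canonical_cycle(path[start:])
    return Attractor(cycle, _env_key(env)), start


def _free_indices(model: BooleanModel, clamps: Mapping[str, Clamp] | None) -> list[int]:
    hard = set()
    for name, clamp in (clamps or {}).items():
        c = clamp if isinstance(clamp, Clamp) else Clamp(*clamp)
        if c.level >= 1.0:
            hard.add(model.index[name])
    return [i for i in model.free_indices if i not in hard]


def enumerate_attractors(
    model: BooleanModel,
    env: Mapping[str, float] | None = None,
    clamps: Mapping[str, Clamp] | None = None,
    cap: int = DEFAULT_ENUMERATION_CAP,
) -> list[Attractor]:
    """Exhaustive attractor inventory with exact basin weights.

    Descends from every state of the free-node hypercube (inputs held at
    the environment's binary values, hard-clamped nodes fixed); basin
    weight = basin size / 2**(free nodes).  Attractors are returned sorted
    by descending basin weight, ties broken by canonical state order.
    """
    free = _free_indices(model, clamps)
    if len(free) > cap:
        raise ValueError(
            f"{len(free)} free nodes exceeds the enumeration cap of {cap}; "
            "use sample_attractors for networks of this size"
        )
    step = compiled_step(model, env, clamps)
    base = list(step(tuple(0 for _ in model.nodes)))  # settles inputs/clamps
    for i in free:
        base[i] = 0

    assign: dict[State, int] = {}
    attractors: list[Attractor] = []
    counts: list[int] = []
    env_key = _env_key(env)
    for bits in itertools.product((0, 1), repeat=len(free)):
        s = list(base)
        for i, b in zip(free, bits):
            s[i] = b
        s = tuple(s)
        if s in assign:
            counts[assign[s]] += 1
            continue
        path: list[State] = []
        pos: dict[State, int] = {}
        cur = s
        while cur not in assign and cur not in pos:
            pos[cur] = len(path)
            path.append(cur)
            cur = step(cur)
        if cur in assign:
            aid = assign[cur]
        else:
            cycle = canonical_cycle(path[pos[cur]:])
            aid = len(attractors)
            attractors.append(Attractor(cycle, env_key))
            counts.append(0)
        for q in path:
            assign[q] = aid
        counts[aid] += 1
    total = 2 ** len(free)
    result = [a.with_weight(c / total) for a, c in zip(attractors, counts)]
    result.sort(key=lambda a: (-a.basin_weight, a.states))
    return result


@dataclass(frozen=True)
class SamplingConfig:
    """Parameters of the stochastic attractor-sampling protocol.

    Defaults follow the standard protocol: time courses of length T = 25
    with flip noise p = 0.02 from N = 100 random initial conditions per
    environment; environments default to every binary combination of the
    declared inputs.
    """

    T: int = 25
    p: float = 0.02
    N: int = 100
    environments: tuple[Mapping[str, int], ...] | None = None

    def __post_init__(self):
        if self.T <= 0 or self.N <= 0:
            raise ValueError("T and N must be positive")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("noise p must be in [0, 1]")

    def resolve_environments(self, model: BooleanModel) -> list[dict[str, int]]:
        if self.environments is not None:
            return [dict(e) for e in self.environments]
        combos = itertools.product((0, 1), repeat=len(model.input_names))
        return [dict(zip(model.input_names, bits)) for bits in combos]


@dataclass
class AttractorTable:
    """Attractors per environment, each carrying its basin weight."""

    model: BooleanModel
    entries: list[tuple[dict[str, int], list[Attractor]]] = field(default_factory=list)

    def environments(self) -> list[dict[str, int]]:
        return [dict(env) for env, _ in self.entries]

    def attractors_for(self, env: Mapping[str, int]) -> list[Attractor]:
        key = _env_key(env)
        for e, attrs in self.entries:
            if _env_key(e) == key:
                return attrs
        raise KeyError(f"no entry for environment {dict(env)!r}")

    def all_attractors(self) -> list[Attractor]:
        return [a for _, attrs in self.entries for a in attrs]


def sample_attractors(
    model: BooleanModel,
    config: SamplingConfig = SamplingConfig(),
    seed: int = 0,
) -> AttractorTable:
    """Stochastic attractor sampling across environments.

    For each environment, ``N`` noisy trajectories of length ``T`` are run
    from uniformly random free-node initial states (inputs fixed at the
    environment's binary values, flip noise only on free nodes); every
    visited state, initial state included, is descended noise-free to its
    attractor.  Attractors are deduplicated by canonical form; basin
    weight = fraction of visited states per environment.  Reproducible for
    a fixed seed, with per-trajectory substreams so ensemble order does not
    matter.
    """
    table = AttractorTable(model)
    free = list(model.free_indices)
    for e_idx, env in enumerate(config.resolve_environments(model)):
        step = compiled_step(model, env)
        basin: dict[State, int] = {}
        attractors: list[Attractor] = []
        counts: list[int] = []

        # memoized descent with path compression
        def descend(s0: State) -> int:
            path: list[State] = []
            pos: dict[State, int] = {}
            cur = s0
            while cur not in basin and cur not in pos:
                pos[cur] = len(path)
                path.append(cur)
                cur = step(cur)
            if cur in basin:
                aid = basin[cur]
            else:
                cycle = canonical_cycle(path[pos[cur]:])
                aid = len(attractors)
                attractors.append(Attractor(cycle, _env_key(env)))
                counts.append(0)
            for q in path:
                basin[q] = aid
            return aid

        base = step(tuple(0 for _ in model.nodes))
        for j in range(config.N):
            rng = substream(seed, e_idx, j)
            s = list(base)
            for i in free:
                s[i] = int(rng.integers(0, 2))
            state = tuple(s)
            counts[descend(state)] += 1
            for _ in range(config.T):
                state = synchronous_step(model, state, env, None, config.p, rng)
                counts[descend(state)] += 1
        total = config.N * (config.T + 1)
        found = [a.with_weight(c / total) for a, c in zip(attractors, counts)]
        found.sort(key=lambda a: (-a.basin_weight, a.states))
        table.entries.append((dict(env), found))
    return table


def export_attractor_table(table: AttractorTable) -> str:
    """Render as CSV: one row per (environment, attractor, cycle position).

    Columns: input levels, attractor id, cycle length, cycle position, one
    column per node, basin weight.  Ordering is bit-exact stable.
    """
    model = table.model
    if not table.entries:
        raise ValueError("empty attractor table")
    rows = []
    for e_idx, (env, attrs) in enumerate(table.entries):
        for a_idx, attr in enumerate(attrs):
            for pos, state in enumerate(attr.states):
                row = {name: env.get(name, "") for name in model.input_names}
                row["attractor_id"] = f"E{e_idx}_A{a_idx}"
                row["cycle_length"] = attr.length
                row["cycle_position"] = pos
                row.update(zip(model.names, state))
                row["basin_weight"] = attr.basin_weight
                rows.append(row)
    cols = (
        list(model.input_names)
        + ["attractor_id", "cycle_length", "cycle_position"]
        + list(model.names)
        + ["basin_weight"]
    )
    return pd.DataFrame(rows, columns=cols).to_csv(index=False)


def read_attractor_table(text: str, model: BooleanModel) -> AttractorTable:
    """Read back a CSV produced by :func:`export_attractor_table`."""
    df = pd.read_csv(StringIO(text))
    table = AttractorTable(model)
    # group by environment prefix of the attractor id, preserving file order
    df["_env"] = df["attractor_id"].str.extract(r"^(E\d+)_")[0]
    for _, env_group in df.groupby("_env", sort=False):
        env = {name: int(env_group.iloc[0][name]) for name in model.input_names
               if pd.notna(env_group.iloc[0][name])}
        attrs = []
        for _, cyc in env_group.groupby("attractor_id", sort=False):
            cyc = cyc.sort_values("cycle_position")
            states = tuple(
                tuple(int(r[name]) for name in model.names) for _, r in cyc.iterrows()
            )
            attrs.append(
                Attractor(canonical_cycle(states), _env_key(env),
                          float(cyc.iloc[0]["basin_weight"]))
            )
        table.entries.append((env, attrs))
    return table


def expected_visited_distribution(
    model: BooleanModel,
    env: Mapping[str, int],
    T: int = 25,
    p: float = 0.02,
    cap: int = 18,
) -> dict[tuple[State, ...], float]:
    """Exact expected basin weights under the sampling protocol.

    Propagates the full distribution over the free-node hypercube through
    T noisy synchronous steps from the uniform initial distribution and
    averages the visited-state distribution over steps 0..T, then sums it
    per deterministic basin.  Exact small-network oracle for the Monte
    Carlo estimates of :func:`sample_attractors`.
    """
    free = list(model.free_indices)
    m = len(free)
    if m > cap:
        raise ValueError(f"{m} free nodes exceeds the exact-propagation cap of {cap}")
    step = compiled_step(model, env)
    base = step(tuple(0 for _ in model.nodes))

    def to_state(code: int) -> State:
        s = list(base)
        for b, i in enumerate(free):
            s[i] = (code >> b) & 1
        return tuple(s)

    def to_code(state: State) -> int:
        return sum(state[i] << b for b, i in enumerate(free))

    size = 1 << m
    det_map = np.array([to_code(step(to_state(c))) for c in range(size)])

    dist = np.full(size, 1.0 / size)
    acc = dist.copy()
    for _ in range(T):
        nxt = np.zeros(size)
        np.add.at(nxt, det_map, dist)
        for b in range(m):
            flipped = nxt[np.arange(size) ^ (1 << b)]
            nxt = (1 - p) * nxt + p * flipped
        dist = nxt
        acc += dist
    acc /= T + 1

    # fold the visited-state distribution into deterministic basins
    basin_code: dict[int, tuple[State, ...]] = {}
    weights: dict[tuple[State, ...], float] = {}
    for c in range(size):
        cur, path = c, []
        while cur not in basin_code:
            path.append(cur)
            seen = set(path)
            nxt_c = int(det_map[cur])
            if nxt_c in seen:
                # found the cycle within this path
                k = path.index(nxt_c)
                cycle = canonical_cycle([to_state(x) for x in path[k:]])
                for q in path:
                    basin_code[q] = cycle
                break
            cur = nxt_c
        else:
            cycle = basin_code[cur]
            for q in path:
                basin_code[q] = cycle
        weights[basin_code[c]] = weights.get(basin_code[c], 0.0) + acc[c]
    return weights
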