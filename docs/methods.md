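# Methods

## Model class and update semantics

`hypoxemt` simulates Boolean regulatory networks: each node holds a binary
activity and is assigned either an update rule (a propositional formula
over node activities, with `and`/`or`/`not` and the constants
`True`/`False`) or the role of an environmental input. Updates are
synchronous — all rules are evaluated simultaneously on the previous
state — which makes the deterministic dynamics a map on the finite state
space with well-defined attractors (fixed points and limit cycles).
Asynchronous and multi-valued schemes are out of scope.

One stochastic step is composed of four layers, in a fixed order:

1. **Rules.** Every non-input node's rule is evaluated on the previous
   state.
2. **Inputs.** Each environmental input is resampled as
   Bernoulli(*level*), with its level in [0, 1]. Levels 0 and 1 are
   saturating environments; intermediate levels model non-saturating
   signals (e.g. 30% hypoxia). Unlisted inputs hold their previous value.
   Levels are resampled independently every step, with no dwell times —
   the simplest semantics for a stochastically tuned input; correlated
   on/off episodes are a possible extension.
3. **Clamps.** A clamped node is overridden to its forced value (ON or
   OFF) with per-step probability *q*. `q = 1` is a hard knockout or
   constitutive activation; fractional *q* models partial knockdown as
   intermittent loss, re-drawn every step (a 5% knockdown forces the node
   OFF on ~5% of steps). A clamp with `q = 0` is exactly no clamp.
4. **Flip noise.** Each non-input, non-clamped node is inverted with
   probability *p*, independently per node. Noise serves basin
   exploration; inputs define the environment being sampled and are never
   flipped.

With *p* = 0 and all levels binary, the step is deterministic, and
trajectories are identical across seeds. Randomness uses one master seed
with counter-derived substreams per trajectory (`SeedSequence` spawn
keys), so ensemble results do not depend on evaluation order.

## Attractors and basins

Two routes are implemented and tested against each other:

* **Exhaustive enumeration** descends deterministically from every state
  of the free-node hypercube (inputs fixed at the environment's binary
  values, hard-clamped nodes fixed). Basin weight is basin size divided
  by 2^(free nodes). The default cap is 22 free nodes.
* **Stochastic sampling** runs N noisy time courses of length T with flip
  noise p from uniformly random initial conditions, for each binary
  combination of the inputs (defaults T = 25, p = 0.02, N = 100). Every
  visited state — the initial state and the T subsequent states — is
  descended noise-free to its attractor; attractors are deduplicated by
  canonical form (the cycle rotation starting at the lexicographically
  smallest state) and weighted by the fraction of visited states in their
  basin.

The visited-state weighting is a deliberate convention: it weights an
attractor both by how often trajectories enter its basin and by how long
they linger there, so under noise it is biased toward noise-robust
attractors relative to the uniform basin-size weights of enumeration.
For this reason the statistical test of the sampler compares its Monte
Carlo weights against the *exact* expectation of the sampled process,
computed by propagating the full probability distribution over the
free-node hypercube through T noisy steps (deterministic image followed by
an independent bit-flip channel per node) and averaging over steps 0..T.
Recovery is checked against enumeration directly: every attractor with an
enumerated basin of at least 0.05 must be found.

## Phenotype signatures

Cell states are named by partial node-state patterns attached to
regulatory modules (e.g. on the EMT module: Epithelial = miR200 ON,
E-cadherin ON, SNAI1 OFF, ZEB1 OFF; Hybrid E/M = SNAI1 ON with the
ZEB1/miR-200 switch unflipped; Mesenchymal = ZEB1 ON, miR200 OFF,
E-cadherin OFF). Classification picks the highest-priority satisfied
signature per module; the shipped sets are mutually exclusive so
priorities act only as a safety net, and an equal-priority double match is
an error rather than a silent choice. Window statistics report, per
schedule window, the fraction of live ensemble steps matching each
phenotype (plus "unclassified", so fractions sum to 1 per module) and
each node's mean activity.

Under flip noise a multi-node signature is briefly violated whenever one
of its nodes is flipped, for the flip step plus the recovery step(s). At
the sampling noise p = 0.02 this interrupts the three-node mesenchymal
signature on roughly 14% of live steps even though the underlying
attractor is pure; at p = 0.005 the stationary mesenchymal fraction
exceeds 0.95. Stationary-state assertions are therefore made in the
small-noise regime (p = 0.005), while dose–response protocols keep the
standard p = 0.02.

## Experiment protocols

An experiment is an ordered list of windows (steps, environment, clamps,
noise) run over an ensemble of non-interacting cells from a shared
initial condition — an explicit state, or a named phenotype resolved
against the attractors of an initial environment (the resolution errors
out unless exactly one attractor matches). Death handling: when a cell's
state matches the death signature (apoptosis execution), the trajectory
ends at that state; the death state is not counted as live time. The
shipped death signature spans the execution context — executioner ON, no
Src survival signal, adherens junctions present — rather than the
executioner node alone, so a single flip-noise event cannot register as a
death (with a one-node signature, 2% flip noise would spuriously kill
most of a 150-cell ensemble over 60 steps even in protected
environments). In continuous mode, dead or schedule-complete cells are replaced by fresh
cells from the initial condition until a live-step budget is consumed
exactly. Phenotype fractions are always over live steps.

Dose series and 2-D grids sweep input levels or clamp levels, optionally
across mutation backgrounds (named clamp sets applied to all windows);
when no ladder is given, the log2-style ladder 0, 0.625, 1.25, 2.5, 5,
10, 20, 40, 80% is used. Division counting reports rising edges of a
designated mitotic-exit marker per window and the implied mean cycle
length.

The metastatic-cascade preset runs seven environment pulses — primary
epithelium (normoxia, stiff ECM, high density); hypoxic core; hypoxia
with density drop; invasion (normoxia, low density); intravasation (no
ECM, no neighbors); extravasation (soft ECM); secondary site (stiff ECM,
high density) — with saturating growth factor throughout. Default pulse
length is 20 steps, enough for every transient of the demonstration
network; ensembles of 10–50 cells suffice in the deterministic regime.
Anoikis-style protocols condition cells in their oxygen environment
*before* detachment: oxygen-dependent Src survival signaling takes one
update step to engage, so switching oxygen and attachment in the same
step would race the apoptosis rule in a way the modeled experiments do
not.

## The demonstration network

The bundled 21-node hypoxia–EMT network (6 inputs, 15 rules) is a
synthetic stand-in built to exhibit the canonical circuit logic at
demonstration scale, not a transcription of any published full-scale
model. It wires: oxygen sensing (PHD hydroxylation plus constitutive VHL
degrade HIF-1α; hypoxia or VHL loss stabilizes it); two HIF-1α regimes
(basal, supporting proliferative metabolism; high, repressing Myc and
Cyclin D); a mechanosensitive EMT switch (SNAI1 requires a stiff matrix
and freedom from contact inhibition; ZEB1 ⊣ miR-200 double-negative
feedback; E-cadherin as the epithelial reporter); an autocrine TGF-β loop
(ZEB1 → secretion → receptor → ZEB1) that locks the mesenchymal state in;
cell-cycle entry requiring Myc, Cyclin D, basal HIF-1α, a stiff attached
matrix and low density; and apoptosis of E-cadherin-positive cells
lacking Src survival signaling upon detachment (anoikis) or soft-matrix
TGF-β exposure. Deliberately omitted: migration machinery, ROS, NF-κB,
FIH, β-catenin/LEF1, and cell-cycle phase structure — the rule-file
loader accepts externally supplied full-scale models for those.

Because the network is compact, every qualitative claim about it
(hypoxia ⇒ EMT with arrest, robustness to TGFbR knockout and VHL
hyper-activation, contact inhibition, anoikis logic, the VHL/Myc/CyclinD
epistasis, the cascade sequence) is checked by deterministic descent —
no tolerance is involved. What passing these tests shows is that the
implemented semantics drive the intended circuit logic; it does not show
that any particular real cell line behaves this way, nor does it
exercise the combinatorial redundancy of a full-scale network.

## Validation statistics

The assay harness compares control and perturbed ensembles for each
curated observation. The per-cell readout is the mean activity of a node
(fraction of ON steps) or the fraction of window steps matching a
phenotype. The decision rule: a simulation matches a directional
observation when a two-sided unpaired t-test is significant at α = 0.05
*and* the change is at least 5% of the average of the two compared values
*and* the direction agrees; it matches a no-change observation when any
of those conditions fails. Welch's unequal-variance test is the default
(the choice is exposed in `MatchRule`; no multiple-testing correction is
applied). When both samples are constant — Boolean ensembles saturate —
significance falls back to exact equality of means. Assays group one or
more tests; an assay matches only if all its tests do, and failures
flagged as contradicting other sources are reported separately.

The bundled 16-row assay table encodes qualitative consequences of the
demonstration network's own rules (hypoxia raises ZEB1 and lowers
E-cadherin, VHL loss drives the mesenchymal program and arrests the
cycle, SNAI1 knockdown blocks hypoxic EMT, and so on). Two rows were
deliberately encoded as robust directional claims rather than strict
no-change claims, because fractional autocrine signaling under noise
shifts means by a few percent: the TGFbR-knockout row asserts that
hypoxia still raises ZEB1 under the knockout, and the Myc row asserts
that Myc hyper-activation leaves the hypoxic EMT program unchanged. The
table is a fixture for exercising the harness, not curated experimental
data.

## Numerical and engineering choices

* Rule expressions are parsed with Python's `ast` restricted to Boolean
  operators, names and Boolean constants; the whole synchronous rule map
  is compiled to a single generated function per model, cached on the
  model.
* The serialization dialect writes inputs once in an `inputs:` header, so
  models are normalized to inputs-first node order; `X *= X`
  self-assignments are also read as input declarations (the convention of
  published rule files).
* Link counting is syntactic: each distinct regulator appearing in a rule
  contributes one ordered (regulator, target) link, with no
  essential-variable reduction, and each input contributes its formal
  self-loop from the `X *= X` declaration convention.
* Descent is memoized with path compression; the descent step cap (10^6)
  exists only to surface implementation bugs, since n-node state spaces
  cannot need more than 2^n steps.
* Random networks draw k distinct regulators per free node and a uniform
  random *non-constant* truth table rendered in disjunctive normal form;
  constant tables are redrawn because they would silently drop regulators
  from the rule text.
* Problem sizes in the test suite: enumeration oracles up to 12 free
  nodes; 50 random networks in the sampler cross-check; ensembles of
  100–150 cells and 60–80 steps in stochastic protocols. These sizes give
  3-standard-error resolution of ~0.1 on a fraction, which is what the
  monotonicity and stationarity assertions require.

## Known limitations

* Attractor detection is enumeration- or sampling-based; no symbolic
  (SAT/BDD) methods, so completeness guarantees stop at the enumeration
  cap.
* Input resampling has no temporal correlation; slowly fluctuating
  environments are not represented.
* Basin weights from sampling estimate the visited-state measure, not
  the basin-size measure; the two agree only in the noise-free limit.
* Cells are independent: no cell–cell coupling, secretion fields, or
  tissue geometry.
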