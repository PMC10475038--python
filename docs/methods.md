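# Methods

## Model

Cellular energy metabolism is represented as a network of queues.  Each
metabolite pool *i* holds an integer number of concentration packets of size
Δ(C_i) (mmol/L); its concentration is `packets × Δ(C_i)`.  Each enzymatic
step is a reversible Michaelis-Menten reaction with at most two substrates
and two products and unit stoichiometry per slot:

    v = (Vf · S1·S2/(K_S1·K_S2) − Vr · P1·P2/(K_P1·K_P2))
        / ((1 + S1/K_S1 + P1/K_P1) · (1 + S2/K_S2 + P2/K_P2))

Absent slots contribute a factor 1 to the numerator product and drop out of
the denominator, which reproduces the textbook reversible uni-uni law and,
with Vr = 0 and P = 0, the classical irreversible form Vf·S/(K_S + S).
Inhibition constants are accepted in network files for provenance but the
rate law carries no inhibition term.

A velocity is converted into a per-step firing probability by normalizing
against the time step and the packet quantum, `mu = |v|·dt/Δ(C)`; positive
velocities act as arrival rates, negative ones as service rates.  The engine
advances on a constant global dt: every reaction and balancing flow fires as
an independent Bernoulli trial with probability mu, and a firing moves one
packet out of each substrate queue and into each product queue.  In the
required small-mu regime the firing counts of a constant-rate event are
binomial ≈ Poisson and inter-firing gaps are geometric ≈ exponential, which
is the queueing-theory reading of the scheme; both limits are property-
tested.  Balancing flows are zeroth-order (concentration-independent)
pseudo-reactions that stand in for everything outside the modelled pathways
— cofactor turnover, transport, biosynthetic drains — and are the natural
target of calibration.

### Stepping semantics and non-negativity

Rates are evaluated synchronously from the pre-step state.  Fired events are
applied in a uniformly random order; any firing that would drive a queue
negative is skipped and recorded, so counts are non-negative structurally,
never by clamping.  The implementation is batch-vectorized over an ensemble
axis (cells, or GA candidates with per-cell constants).  When the pre-step
counts cover the step's total demanded consumption — the overwhelmingly
common case — every application order yields the same state and the whole
step is applied as one matrix update; otherwise the affected cell is
replayed sequentially with the random-order/skip semantics.  The two paths
therefore agree exactly wherever order cannot matter.

The ensemble is driven by a single seeded generator rather than per-cell
derived seeds: cells remain i.i.d., identical seed + configuration
reproduces bit-identical trajectories, and the batch layout is what makes
full-length runs affordable (a 10,000 s run of the 68-reaction network at
dt = 0.01 s is ~10⁶ steps and takes on the order of a minute on one CPU).

### Time-step condition

`validate_timestep` evaluates mu for every (event, touched pool) pair at the
initial state and requires max mu ≤ `mu_threshold` (default 0.1); `simulate`
refuses to start otherwise.  dt defaults to 0.01 s.  The threshold 0.1
operationalizes "mu ≪ 1": it bounds the probability of demanding more than
one quantum per pool per step while keeping run times practical.

### Packet quanta

The default quantum is `initial_concentration / 1000` (floor 1e-6 mmol/L),
i.e. ~1000 packets per pool; pools starting at zero inherit the network's
median quantum.  Quanta may differ between the pools of one reaction; the
firing probability then uses the smallest touched quantum (the binding one
for the mu ≪ 1 condition).  With unequal quanta a single one-packet-per-pool
firing cannot realize the macroscopic flux for every pool simultaneously —
larger-quantum pools turn over proportionally faster.  This is an accepted
property of the quantized scheme (calibration absorbs it); every fixture
used for quantitative agreement with deterministic integration uses a
uniform quantum, where the mapping is exact.

### Noise

`perturb_constants` multiplies each kinetic constant by max(1e-6, 1 + cv·z),
z ~ N(0,1), optionally also the initial concentrations.  The same transform
is available per cell inside ensemble runs (`constant_noise_cv`,
`initial_noise_cv`).  Defaults are 0 (off).

## Bundled default network

The bundled network integrates glycolysis (10 reactions), the pentose
phosphate pathway (9 including PRPP synthesis), the TCA cycle (7 steps with
isocitrate + cis-aconitate and succinyl-CoA + succinate lumped into single
queues carrying the second member's kinetics), palmitate beta-oxidation
(entry, carnitine shuttle, seven 4-reaction spiral turns) and the
anaplerotic links (PDH, pyruvate carboxylase, malic enzyme, transaminases,
glutaminolysis, ATP-citrate lyase) — 68 reactions over 65 pools.  TCA queues
start at literature concentrations; glucose starts at 5.0 mmol/L (normal
blood glucose) and is deliberately not replenished, so glycolysis
extinguishes as glucose runs out and beta-oxidation becomes the dominant
acetyl-CoA source — the experiment the simulator is built to exhibit.
Redox/energy cofactors are folded out of the species slots; their turnover
lives in the balancing-flow abstraction.  The final thiolysis emits a single
acetyl-CoA packet because slots carry unit stoichiometry.

The exact kinetic constants of the integrated model are not published, so
the bundled table is an explicit approximation (`version =
"approximate-1"`): every Michaelis constant equals the species' starting
concentration (each reaction begins at half-saturation, maximally responsive
to deviations in either direction), every reverse velocity uses the Vf/100
default, and each forward velocity is calibrated at build time so the
reaction's initial firing probability hits a designed target in the 1-10%
band.  The per-step targets are routed so that at t = 0 every pool's packet
arrivals balance its services except glucose (the depleting substrate);
residual imbalances are carried by 12 tunable balancing flows (e.g. lactate
and alanine export, glutamine and palmitate supply, an acetyl-CoA
biosynthetic drain).  This makes the seeded network self-consistent before
any tuning, which is what lets scaled-down GA passes suffice in tests.

## Literature statistics

Reported concentrations are points or closed ranges.  For a Gaussian model
the maximum-likelihood estimates from points are the arithmetic mean and the
population SD (divisor n), floored at 1e-9 mmol/L.  When ranges participate,
one value per range is chosen jointly with (mean, SD) to maximize the
likelihood; with (mean, SD) profiled out in closed form this is exactly
variance minimization over the box of ranges, solved by a small GA whose
initial population always contains the range midpoints (so the result can
never fall below the midpoint baseline).  The published comparison table
prints estimates truncated to 4 decimals and derives Z-scores from those
printed values; `literature_report` reproduces that convention (truncation
before the Z-score), with full precision available via
`table_precision=None`.  Both fitting modes are exposed because the
published table is internally inconsistent about whether ranges entered each
row's estimate; the point-only mode reproduces the rows whose printed means
equal the point means.

## Genetic-algorithm calibration

A chromosome is a vector of multipliers on the seeded table: one gene per
reaction Vf, one per reaction Vr, one per tunable balancing flow (bounds
0.2-5.0).  Fitness is the sum of a literature term — squared relative
distances between per-second samples of the simulated concentrations and the
reference vector — and a stability term — the mean absolute difference
between the average of the last 100 recordings and the initial
concentrations.  The two are equally weighted; the weighting is an exposed
knob with no principled setting, and the composite is zero exactly at a
stable trajectory resting on the reference.

The trivial minimizer (zero every rate, nothing moves) is excluded by a
constraint: every reaction and flow must start with firing probability in
[1%, 10%].  Violating candidates score infinite fitness without simulation;
reproduction repairs violating genes by resampling (each event's initial
probability depends only on its own genes, so repair is one pass).
Selection is truncation to the 10 best of 100; children are uniform
gene-wise crossovers of random elite pairs; each gene mutates with
probability 0.10 by a normal perturbation of SD = amplitude × 10% of the
gene's bound width (amplitude default 1.0 — the amplitude's units are not
fixed by anything external, so bound-relative scaling keeps genes
commensurable).  Elites carry their evaluated fitness unchanged, so the best
fitness is non-increasing by construction.  The initial population contains
the incumbent all-ones chromosome, so calibration can only improve on the
seeded table.  Each generation is evaluated as one vectorized batch under a
generation-derived seed; the standalone `evaluate_chromosome` uses a
(seed, generation, index)-derived stream and is exactly reproducible.
Default evaluation length is 3600 s of simulated time per candidate.

Calibration protocol note: evaluation runs start from the reference
concentrations (the literature values), matching the experiment the loss is
written for.  Starting elsewhere makes the stability term (anchored at the
initial state) and the literature term (anchored at the reference) disagree
and visibly biases parameter recovery in the planted self-consistency
experiment.

## Sensitivity analysis

One metabolite's starting concentration is swept over multipliers of its
baseline (default 0.5-1.5, five points); each grid value is simulated with
independent replicates and every pool's final concentration is the endpoint.
Two scores are computed per measured pool: the first-order variance ratio
V(E[Y|start])/V(Y) with the conditional mean estimated per grid value (in
[0,1] up to estimator noise; the standard variance-based index), and the
endpoint ratio — mean endpoint at each non-baseline start over the baseline
mean (near 1 ⇔ robustness).  Published-style five-number summaries (min,
p5, median, p95, max, linear interpolation) are reported for both flavors;
the endpoint ratio is the one whose concatenated distribution can exceed 1
and is therefore the flavor behind robustness tables.  Both are always
emitted because the two readings answer different questions and the
historical reporting conflates them.

## Synthetic fixtures: what passing shows

The toy generators produce networks with known analytic behavior: an
irreversible chain (monotone terminal pool, Michaelis-Menten relaxation
checked against explicit-Euler integration at dt/100), a closed ring (exact
packet conservation), a branch competition over a 5-packet queue (underflow
skipping and order fairness), and a planted steady state (zero expected
drift by construction; the substrate of the GA self-consistency experiment).
They emulate the *mechanics* of the full model — quantization, stochastic
firing, competition, stationarity — under uniform quanta and known
constants.  They do not emulate real-data features: heterogeneous quanta
spanning three orders of magnitude, literature-grade constant uncertainty,
or unmodelled-pathway drift.  Passing therefore validates the engine's
probability calculus and the calibrator's behavior, not the biological
accuracy of any particular constant table.

## Problem sizes used by the shipped tests

Full-length experiments are kept, heavy optimizations are scaled:
the recorder/stability runs use the complete 10,000 s × dt 0.01 experiment
(single cell for the dispersion statistic — harder than the 50-cell average,
since averaging only shrinks dispersion); the default-network GA pass in the
stability check uses population 24, 3 generations, 40 s evaluations; the
robustness sweep uses 5 grid points × 10 replicates × 300 s; planted
recovery uses population 100, 40 generations, 300 s evaluations.  Paper-
scale settings (population 100, 3600 s evaluations, 50 cells, 10,000 s) are
the library and CLI defaults.

## Known limitations

* The 68-reaction constant table is a curated, self-consistent approximation,
  not a replica of any published table; all quantitative claims about it are
  the ones the tests compute.
* Electron transport / oxidative phosphorylation, glucose replenishment and
  protein catabolism are out of scope; their net effect is representable
  only through balancing flows.
* One firing moves one packet per touched pool, so with unequal quanta the
  realized flux differs per pool from the macroscopic velocity (see Packet
  quanta above).
* The dispersion statistic uses sliding-window SDs (window 100 measurements,
  ddof 1) over the overall mean; slow secular drift contributes little to
  it, by design (it measures local fluctuation, not trend).
* Exact-time stochastic simulation (Gillespie SSA, tau-leaping) and dynamic
  per-step time increments are intentionally not implemented; the constant
  global dt is the modelling choice the engine is built around.
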