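# Methods

## Model

trapopt treats a mosquito population as moving on a finite set of point
sites (households, villages, breeding habitats). Movement is Markovian with
a daily time step: the probability of being at site *j* tomorrow depends
only on the current site *i*, through a row-stochastic movement matrix
**τ** derived from a dispersal kernel applied to pairwise distances and,
optionally, a resource-type masking matrix.

Traps enter as absorbing states. Each trap *k* has an attractiveness kernel
giving a raw odds weight ν<sub>ik</sub> for a mosquito at site *i* to enter
trap *k* within a day. The augmented transition matrix is the block form

```
[[ Q, R ],
 [ 0, I ]]
```

where site row *i* is `[τ_i, ν_i] / (1 + Σ_k ν_ik)` and trap rows are
identity (a trapped mosquito stays trapped). The denominator implements an
odds interpretation: a trap of maximum attractiveness *A* co-located with a
site captures with daily probability *A*/(1+*A*) — the ratio of entering to
not entering is *A* : 1. Multiple traps share the denominator, so nearby
traps compete for the same mosquitoes; this competition is precisely the
trade-off the optimizer has to negotiate.

The score of a trap configuration is the expected number of days until
absorption. For transient block Q this is the row sum of the fundamental
matrix (I − Q)<sup>−1</sup>, obtained by solving the linear system
(I − Q) t = **1** directly (never by explicit inversion). The optimizer
minimizes either the mean of t over origin sites or its maximum (worst
origin).

### Assumptions

- All sites carry equal population weight; the mean objective weights
  origins uniformly.
- Movement and trapping probabilities are stationary in time — no trap
  saturation, no seasonality, no mortality (a death process would only
  shorten detection times for a live-capture objective; it is out of scope).
- One population per run; sex- or species-specific analyses are separate
  runs with their own kernels.

## Dispersal kernels

| family | form | parameters |
| --- | --- | --- |
| exponential | w(d) = e^(−d/m) | m = mean dispersal distance (coordinate units) |
| zero-inflated exponential | point mass z at the current site; off-diagonal ∝ e^(−d/m) scaled to 1 − z | z ∈ [0,1] staying probability, m conditional mean distance |
| long-tailed | w(d) = (1 + d/(m(b−1)))^(−b), a Lomax with mean m | b > 1 tail shape; → exponential as b → ∞ |
| custom | any callable of distance | — |

Diagonal handling differs by family: for the plain exponential and
long-tailed kernels the diagonal weight is w(0) and the whole row is
normalized, so the staying probability is an emergent quantity; for the
zero-inflated kernel the diagonal is pinned exactly to z and only the
off-diagonal mass is normalized (to 1 − z). A site with no positive
off-diagonal weight is isolated and keeps self-probability 1; a row that is
entirely zero (possible only with a zero mask row combination) is an error,
not a silent repair.

The long-tailed family needed a concrete functional form; the Lomax
(shifted power law) was chosen because it has an interpretable mean equal to
the stated mean dispersal distance, strictly heavier tails than the
exponential at every shape, and a clean exponential limit. Users wanting a
different heavy-tailed law can pass a custom kernel.

Masking multiplies weight (i, j) by mask[type(i), type(j)] — the row is the
mosquito's *current* resource context (e.g. a blood-fed female seeking
oviposition water) — and rows are renormalized afterwards, i.e. mask entries
are relative modifiers, not absolute probabilities.

Distances are Euclidean by default (planar/synthetic data); a haversine mode
(spherical Earth, radius 6,371,008.8 m) handles lon/lat inputs.

## Trap kernels

- exponential: A·e^(−d/radius), with "mean radius of attractiveness" radius.
- sigmoidal: A/(1 + e^(shape·(d − radius))), inflection at d = radius where
  the value is A/2. At d = 0 the value is below A; the maximum
  attractiveness is the supremum parameter, not the contact value.
- an optional per-resource-type multiplier vector lets a trap appeal
  differently by the origin site's resource type (ovitrap-style behaviour);
  default is no modulation.

## Expected time and its Monte-Carlo check

Unreachable origins (no path to any trap, or positive probability of
entering a trap-free closed region) receive a +inf sentinel rather than an
exception, so the GA can rank and discard such configurations — important in
continuous mode, where a chromosome can wander into dead space. Reachability
is decided exactly by a boolean fixed-point computation on the support of Q
before the solve; the restricted system is additionally guarded by a
condition-number estimate (threshold 10¹²).

`simulate_walkers` is an independent cross-check: it propagates per-site
occupancy counts with multinomial draws (cost scales with steps, not
walkers), lumping all traps into one absorbed state, and reports per-origin
empirical means with standard errors plus censoring counts. The test suite
requires agreement with the linear solve within 3 standard errors at 100,000
walkers per origin.

## Genetic algorithm

Chromosomes contain only movable traps — node indices in discrete mode,
(x, y) pairs in continuous mode — so immovable traps are preserved by
construction. One generation = tournament selection (size 3, minimizing,
ties to the lowest index), two-point crossover on the gene list (probability
0.7; a coordinate pair is one gene and is never split; children jointly
conserve the parental multiset), mutation (individual probability 0.3),
evaluation, and re-injection of the best-ever individual over the current
worst (size-1 elitism), which makes the best-fitness trace non-increasing.
Repetitions are independent seeded restarts (seeds spawned from the master
seed); every trace is retained and the reported optimum is the best across
repetitions. Infinite fitness compares as worst; duplicate genes
(co-located traps) are legal and simply share capture odds.

Mode-specific choices, made after profiling the suburb scenario and exposed
in `GAConfig`:

- Discrete mutation resamples each gene uniformly over nodes with
  probability 0.5.
- Continuous mutation perturbs each selected coordinate pair with an
  isotropic Gaussian whose step starts at 5% of the (5%-padded) site
  bounding-box diagonal and decays geometrically to 2% of that start by the
  final generation. A fixed large step cannot finish the job when trap
  radii (~16 m) are two orders of magnitude below the landscape extent
  (~1 km): late-stage refinements need moves comparable to the trap radius.
- Continuous per-gene mutation rate defaults to 0.1 (vs 0.5 discrete):
  perturbing half of 16 coordinate pairs at once almost never improves a
  good layout.
- Continuous populations initialize at node coordinates jittered by a
  quarter of the initial step, not uniformly in the box: only the
  neighbourhoods of sites carry fitness gradient, and a uniform scatter
  starts ~95% of traps in flat dead space.

With these settings the discrete and continuous modes reach mean-objective
optima within a few percent of each other on the suburb scenario, which is
the behaviour the block-matrix model predicts (the continuous optimum sits
on the nodes).

`brute_force_discrete` enumerates node placements exactly (multisets when
all movable kernels are identical, ordered tuples otherwise; refuses above
200,000 combinations) and is the oracle for GA correctness on small
instances.

## Synthetic data

The fixtures module generates every landscape used in tests: grids, uniform
scatters, clustered settlements, a well-separated two-cluster layout, and a
six-node hexagon with alternating blood-feeding/water resources. Two
scenarios bundle realistic parameter sets at desk scale:

- `suburb_small`: 60 household sites in 1 km × 1 km; zero-inflated
  exponential movement (z = 0.72, m = 54 m); 16 movable traps, half
  exponential (A = 0.5, radius 15.88 m), half sigmoidal (A = 0.5, inflection
  16 m, shape 0.25 per metre).
- `island_small`: 30 village sites in four clusters over 3 km × 5 km;
  exponential movement with m = 700 m (chosen so neighbouring villages
  exchange migrants daily while distant clusters are weakly coupled);
  exponential traps (A = 0.5, radius 24 m); two immovable traps pinned at
  the northernmost and southernmost sites, the rest movable.

Scenario sizes (60 and 30 sites) were picked so that brute-force and
Monte-Carlo oracles run in seconds while preserving the qualitative
structure — two competing trap profiles, household-scale attraction radii,
immovable sentinels, diminishing returns in trap count. What these fixtures
do **not** emulate: real building footprints and road networks, resistance-
landscape movement (elevation/land-use effects), unequal site populations,
temporal variation. Passing tests therefore demonstrate correctness of the
machinery and qualitative reproduction of the published patterns, not
quantitative predictions for any real site.

## Numerical choices

- Row-stochasticity is enforced to 1e-12 and checked in tests; the
  zero-inflated diagonal is exact by construction.
- (I − Q) t = 1 is solved with LAPACK via `scipy.linalg.solve`; the
  condition threshold 10¹² leaves a comfortable margin before double
  precision degrades the expected-time estimates.
- CSV round-trips use 17-significant-digit floats and round-trip float
  parsing, so fixture emission is byte-stable.
- Problem sizes in the shipped tests (100k walkers, population 64, up to 800
  generations, 3 repetitions) keep the whole suite in the minutes range on
  one core while leaving the statistical checks well-powered.

## Known limitations

- The continuous-mode GA is a local-refinement metaheuristic; on multimodal
  landscapes different seeds can settle in different basins (hence
  repetitions with retained traces).
- The odds-renormalization rule means adding traps strictly reduces
  movement probabilities everywhere, which is the intended competition
  semantics but implies a single site cannot exceed daily capture
  probability Σν/(1+Σν) < 1 for finite attractiveness.
- Masking applies to sites only; trap attractiveness is modulated by the
  origin site's type, not by trap-side resource states.
- No account of trap servicing, saturation, or detection lag downstream of
  capture.
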