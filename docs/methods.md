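# Methods

This note documents the models, default parameters and numerical choices in
`conflictplan`, and what the synthetic landscapes do and do not emulate.

## Conflict-risk model

Incidents are point events (planar km coordinates, year, fatality count).
Each incident exposes every planning unit whose centroid lies within a
30 km radius ("impact zone"); the geometry is point-in-disc on centroids
rather than polygon–buffer intersection, which at 10 km grid resolution is
equivalent in practice and keeps the brute-force test oracle trivial.

From the exposure tallies, a calibration window (default 2000–2008 in the
synthetic timeline) yields three per-unit predictors: number of exposing
incidents, summed fatalities, and years since last exposure. Units never
exposed in the window receive a censored years-since-last value of window
length + 1 (configurable); fatalities enter untransformed by default with an
optional log1p variant. A logistic regression of these predictors against
presence/absence of exposure in a disjoint, later validation window
(2009–2014) is fitted by maximum likelihood (statsmodels `Logit`,
convergence tolerance 1e-8, max 100 iterations). Fit quality is McFadden's
pseudo-R². Degenerate inputs raise explicit errors: constant response,
fewer than 4 observations, or single-covariate complete separation (the
offending covariate is named). Zero-variance covariates are dropped from
the design and reported with a zero coefficient, so the intercept-only
limit returns pseudo-R² = 0 rather than a singular-matrix failure.

Prediction applies the fitted coefficients to predictors built over a more
recent window (2005–2014), giving each unit a probability of at least one
incident over the coming five-year management horizon. The 95% interval is
normal on the linear-predictor scale using the coefficient covariance, then
inverse-logit transformed — this guarantees 0 ≤ ci_low ≤ p ≤ ci_high ≤ 1,
which interval construction on the probability scale would not.

## Strategy encodings

All four strategies are pure transformations of the selection problem.
Targets are always set as T × the feature's total raw extent (default
T = 0.30) before any exclusion, so an avoided feature still "owes" its full
target.

* *ignorant*: identity.
* *avoiding*: units with risk p > θ removed (locked-in units are always
  retained regardless of risk).
* *accounting*: effective amounts a·(1−p). This makes the expected
  surviving representation meet the target and biases selection towards
  safer units. A reliability loop then solves the problem, computes each
  feature's survival probability over the selected units (raw amounts
  against the T-fraction goal), and multiplies the working target of every
  feature below ρ by 1.1, iterating at most 20 times. ρ defaults to 0.95,
  the smallest conventional level consistent with the binomial worked
  example (five units at 25% risk give 89.65% < 95%; six give 96.24%).
* *sensitive*: exclusion at θ, then accounting.

Targets exceeding the total available effective amount are capped at it and
flagged rather than raising: such features are simply unattainable at the
requested fraction and the cap makes the planner buy whatever of them
remains available. Note a structural consequence measured on the reference
landscape: a feature whose entire range is high-risk gets a capped target
equal to "everything it has", which forces a large spend for little
evaluated benefit (see Limitations).

The heterogeneous survival probability (`meeting_probability_hetero`) is
exact for up to 20 units — an iterative doubling over survive/lose outcomes,
2ⁿ paths — and Monte Carlo above that (default 100,000 replicates, standard
error available). The equal-risk unit-amount case reduces exactly to the
binomial tail.

## Solver

The annealer minimises

  E(S) = Σ_{i∈S, not locked} cᵢ + λ Σ_f base_f · max(t_f − rep_f, 0)/t_f

where base_f is a cheapest-covering-cost estimate (t_f × the best $/amount
rate among units holding f), making the penalty scale λ dimensionless;
λ = 10 by default so repairing a shortfall is always cheaper than paying for
it. Moves are single-unit add/drop proposals with Metropolis acceptance and
geometric cooling (factor 0.9995/step). The initial temperature, unless
given, is the median |ΔE| of 200 probe moves from the start state. Each run
starts from a greedy fill under its own seed-shuffled tie-break; the trimmed
greedy incumbent is kept as a floor so a run never returns worse than its
construction heuristic. A final greedy repair plus a costliest-first drop
pass ensures feasibility when attainable and removes redundancy. Runs are
bit-for-bit reproducible under their seed; ensembles use seeds
seed+0…seed+n−1 and report per-unit selection frequencies and the
least-cost feasible run. Locked-in units contribute amounts but no
acquisition cost (configurable), so reported cost is new investment.

The exact solver enumerates all subsets (refusing > 20 free units), breaking
cost ties lexicographically on unit ids. On 50 random 12-unit instances the
annealer matches the exact optimum on ≥ 60% and never goes below it; LP
relaxation bounds on the 900-unit reference problems place the annealer
within 1.5–6% of optimal.

## Monte Carlo evaluation

Each selected unit is lost independently with its fine-scale point risk.
Default loss draw is continuous (u < p); a `paper_integer` mode draws r
uniformly from {1..100} and loses the unit iff r < 100p, reproducing the
integer semantics of the original analysis with its ≤ 1 percentage-point
downward bias in effective loss probability. Targets are judged on *raw*
surviving amounts against T × original extent, independent of the amounts
the planner used — losses are realised once, at evaluation, never twice.
Locked-in units are subject to loss like any others. Reports give the
per-replicate targets-met distribution, its median and 2.5/97.5 percentiles
(1,000 replicates by default), and ROI = median targets met / (cost/10⁹ USD).
`exact_expected_targets` provides the analytic cross-check
Σ_f P(target f survives) via the same exact/Monte-Carlo survival machinery.

## Synthetic landscapes

The generator produces what the analysis *assumes* about real data, not any
particular geography:

* cost: log-normal marginal (log-sd 0.5, ~1.6× multiplicative spread),
  spatially smoothed by a Gaussian kernel with 50 km range, normalised to a
  configurable mean (default 10⁶ USD per 10×10 km cell);
* species ranges: ~disc-shaped patches, mean radius 50 km with 30%
  between-species spread and 1.5 km boundary jitter — contiguous-ish compact
  ranges are what the target logic needs; biogeographic realism is not
  attempted;
* ecoregions and nations: Voronoi partitions of the grid (ecoregions
  tessellate exactly; nations are contiguous blocks so a national-scale risk
  layer — the within-nation mean of fine risk — is derivable);
* 5% of units are pre-protected ("locked in");
* conflict: 3 hotspots each emitting Poisson(5) incidents/year scattered
  with a 15 km Gaussian, retained year-to-year with probability 0.85 and
  otherwise relocated; placement (and relocation) weights cells by
  exp(coupling × standardised species richness), so positive coupling
  reproduces the empirical tendency of conflict to concentrate in biodiverse
  regions; fatalities are gamma-Poisson with mean 3 and overdispersion 1.

These conflict defaults were chosen so the *fitted* five-year risk map looks
like a conflict-affected region rather than a war zone: median risk ≈ 5%,
roughly a quarter of cells above 50% (a concentrated belt), and a realised
richness–risk rank correlation ≈ 0.5–0.6 at coupling 2. Earlier, hotter
settings saturated the landscape (median risk > 50%), which contradicts the
premise of risk-accounting — that safer alternatives exist.

The reference comparison (`reference_config`) uses a 30×30 grid, 40 species
+ 6 ecoregions, coupling 2, 25 solver runs of 15,000 annealing steps and
500 evaluation replicates — sizes chosen so a full sweep completes in well
under a minute on one CPU while leaving the solver near-optimal (see LP
bounds above). Production-style runs can raise these to the conventional
100 runs / 1,000 replicates via `SolverConfig` and `EvaluationConfig`.

## Pipeline conventions

* National-scale planning replaces each unit's risk with its nation's mean
  fine risk — the layer's defining property is zero within-nation variance,
  so exclusion and discounting act on whole nations at once.
* Sensitivity runs re-plan on the upper or lower 95% risk bound but always
  evaluate with the fine-scale point estimate: networks planned under
  different beliefs are judged against the same world.
* θ grids default to 0.05 steps over [0, 1]; threshold-free strategies are
  solved once per scale/bound and replicated across the grid.
* All stage seeds derive deterministically (CRC-based, process-independent)
  from one master seed; identical configuration implies identical output.

## Limitations

* The generator does not model refugee movement, cross-border spillover,
  cost–risk correlation, or map projections; event coordinates are clipped
  to the grid.
* Desk-scale geometry can produce species whose *entire* range lies inside
  the conflict belt (range radius and belt width are the same order). For
  such features the accounting strategy's capped target forces buying the
  whole range for near-zero survival probability, which depresses its
  measured ROI relative to risk-ignorance on some seeds. In
  continental-scale data, where every feature retains some low-risk range,
  this cost sink is absent; conclusions about the ROI *ordering* of
  strategies therefore do not transfer from these desk landscapes to real
  data without checking for fully-exposed features.
* The evaluation assumes total loss of an impacted unit (worst case) and
  independence of losses across units; spatially correlated conflict shocks
  would widen the targets-met distribution.
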