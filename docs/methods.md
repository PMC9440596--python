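# Methods

## The model

Each study group's joint distribution over 15 variables — six
anthropometric covariates (age, weight W, height H, BMI, waist WC, hip HC)
and nine DXA compartments (fat / lean / bone mineral content × trunk /
legs / arms; TF, TL, TB, LF, LL, LB, AF, AL, AB) — is modelled as a
Gaussian Bayesian network: a DAG in which every node is a linear function
of its parents plus independent Gaussian noise. Working on z-scores makes
the edge weights standardized regression coefficients. The assumptions
are the usual ones: approximate joint normality (checked per variable by a
Kolmogorov–Smirnov test, with natural-log transforms where it fails),
linearity of every parent–child relation, and homoscedastic residuals.

Prediction does not condition on evidence in the joint Gaussian; it follows
the plug-in hierarchical scheme: compartments whose parents are all
anthropometric are predicted first, and each downstream compartment uses
the *predicted* values of its compartment parents. Since every node model
is linear with no intercept, the whole predictor is a composition of
linear maps, which the test suite verifies against a closed-form matrix
evaluation.

## Robustness construction

Structure learning is notoriously sample-hungry at n ≈ 100 per training
group, hence the two-stage filter:

* **Consensus**: an adjacency must appear in ≥ 7 of 12 learners (4
  Markov-blanket/constraint-based variants × two α levels, two BIC-search
  variants, MMHC × two α levels). Counting is on the undirected adjacency
  (orientation instability should not discard a stable dependence;
  a strict directed mode is switchable); orientation is then re-decided by
  majority vote with BIC tie-breaks, and any directed cycle is broken at
  its lowest-support edge.
* **Bootstrap stability**: edges must recur in ≥ 70% of B bootstrap
  replicates of m rows drawn with replacement (m = 500 exceeds every
  group's n, so resampling must be with replacement). Both thresholds are
  closed: exactly 7/12 and exactly 0.70 survive.

By default every replicate reruns the full 12-learner ensemble; a fast
mode (one restart-free hill-climbing run per replicate) exists for tests
and desk-scale runs.

## Algorithmic choices

* **Fisher-z test**: partial correlations from the inverse covariance
  submatrix; z = √(n−|Z|−3)·atanh(ρ); two-sided normal p-value. Degenerate
  or singular tests count as independence, which is the conservative
  direction for edge discovery.
* **Blanket → skeleton**: candidate edges are blanket pairs confirmed from
  both sides (AND rule); pruning is level-wise over *current*
  neighbourhoods in the stable style of the PC algorithm, capping
  conditioning sets at size 3. Searching all blanket subsets instead was
  measured to inflate false separations through sheer test count.
* **Orientation**: collider detection from recorded separating sets, then
  Meek-style propagation, then greedy BIC orientation of leftovers with
  deterministic lexicographic tie-breaks. The blacklist is honoured at
  every step; edges forbidden in both directions are dropped.
* **Gaussian BIC**: per family, the linear-Gaussian log-likelihood minus
  ((|Pa|+2)/2)·ln n (coefficients, intercept, residual variance). Residual
  variances are floored at 1e−12 so near-deterministic fits keep a finite
  score.
* **Hill-climbing restarts**: the Gaussian BIC is score-equivalent, so
  single-edge orientations tie and a purely greedy search systematically
  picks the lexicographically first one, which can trap it. Hill-climbing
  therefore restarts 10 times from an 8-move random perturbation of the
  incumbent (seeded; the learner stays deterministic). On 4-node
  benchmarks this configuration matches exhaustive DAG enumeration in
  ≥ 96% of random instances.
* **Prior knowledge**: arcs from compartments into anthropometrics and all
  arcs into age are forbidden; covariate↔covariate arcs are allowed during
  learning but excluded from the final robust graph (only arcs into
  compartments are kept, matching the published arc counts' scope).

## The synthetic cohort

The study data are unavailable, so all analyses run on a generator
calibrated to the published summary tables.

* **Anthropometrics**: (age, W, H, WC, HC) are drawn from a Gaussian
  copula. Each margin is moment-matched to the published per-sex mean, SD
  and skewness — a shifted log-normal when |skew| ≥ 0.1 (mirrored for
  negative skew), else normal — and clipped to physiologic bounds (weight
  15–150 kg, height 100–210 cm, circumference bounds likewise; the age
  clip is deliberately loose because each group's 9–18.5 y window is
  enforced by truncating the age margin itself, which the copula then
  propagates into the size variables).
* **Covariate correlations are invented**: the publication reports none,
  so plausible adolescent values are used (age–height 0.8, weight–HC 0.9,
  WC–HC 0.85, …), repaired to the nearest positive-definite matrix and
  fully overridable. They matter: several recovery properties depend on
  the collinearity they induce.
* **BMI** is always computed as W/(H/100)², never sampled. Its published
  summary row is therefore only a validation reference (a mean of ratios
  is not a ratio of means); inside the SEM, BMI is standardized by its
  model-implied moments, computed once with a fixed seed, so that
  downstream compartment means stay calibrated.
* **Compartments**: generated in topological order in z-space as
  z_v = β_v·z_Pa(v) + ε_v, with the published standardized coefficients.
  The residual variance is σ_v² = Var̂(β_v·z_Pa(v))·(1−R²_v)/R²_v from the
  realized parent columns, *not* 1−R²_v: with correlated parents this is
  the unique choice for which an OLS refit recovers both the coefficients
  and the explained variance simultaneously. The recovery analysis
  (`analysis/03_validate_recovery.py`) confirms all 127 published
  quantities within ±0.008 at n = 5000 over 20 seeds.
* **Table repairs**: the published girls trunk-BMC SD (0.63 kg) is
  incompatible with its own quartiles (IQR 0.17); a validation pass
  replaces any SD further than three robust-SD units from IQR/1.349 by
  IQR/1.349 and logs the repair. The boys arm-BMC row's mean/quartile
  clash is logged but left as printed (only the SD enters the generator).
  Each group's AL (arm lean) model as printed lists AL itself as a parent
  — impossible in a DAG — and is remapped to AF, the only arm variable
  otherwise absent from those rows.

What the generator does **not** emulate: pubertal growth trajectories,
DXA measurement error, non-Gaussian residual structure in the
compartments, and any covariate dependence beyond the invented correlation
matrix. Passing tests therefore demonstrate internal consistency of the
method and faithful transcription of the published models — not that the
pipeline would recover the same networks from new field data.

## Preprocessing conventions

* Group boundaries are closed on the older side: a girl aged exactly 13.0
  (boy 14.0) belongs to the older group; this reproduces the published
  group sizes 147/88/136/105.
* The 80/20 split takes round(0.8·n) training rows (banker's rounding),
  uniformly at random, reproducibly by seed, unstratified.
* The KS normality test estimates its parameters from the sample (no
  Lilliefors correction), which is anti-conservative; α = 0.05 by default
  and configurable. Which variables get log-transformed is decided
  data-adaptively per group; transforms fitted on training rows are
  applied unchanged to validation rows, and predictions are
  back-transformed before any kg-scale metric.
* Standardization always uses training-set statistics; negative predicted
  masses are clamped to zero with a logged count.

## Error metrics

With residuals B[i,v] = predicted − observed (kg): |Bias| = Σ_v |mean_i
B[i,v]| (the per-compartment *mean* residual — this makes the criterion
sample-size-free and matches the magnitude of the published totals), SD =
Σ_v sd_i(B[i,v]) with n−1, and SEP = Σ_v √(bias_v² + sd_v²), so SEP_v
dominates both components and SEP_v² = bias_v² + sd_v² holds by
construction. R² between predictions and observations is the squared
Pearson correlation (switchable to 1−SSE/SST). MAPE excludes zero
observations with a logged count. Candidate selection minimizes
validation SEP with ties broken by fewer covariates, then fewer arcs,
then label order — exactly reproducing all four published selections from
the printed candidate table.

## Problem sizes

Desk-scale defaults used by the analysis scripts and tests: 25–50
bootstrap replicates in fast single-learner mode, groups of 100–2000
simulated rows, 20-seed averages for recovery checks. The library
defaults (B = 500, m = 500, full ensemble per replicate) implement the
published protocol and are the right choice when minutes-to-hours of
compute are acceptable.

## Known limitations

* At n = 2000 the consensus stage recovers about 73% of the generating
  response-side arcs (with essentially no spurious ones). Six of the 23
  boys-over-14 arcs carry standardized coefficients whose implied partial
  correlations fall below ~0.05 under some small conditioning set —
  partly through near-cancellation along parallel paths, partly because
  deterministic BMI makes H nearly redundant given (W, BMI) — so all ten
  test-based learners prune them and the ≥ 7-of-12 support rule cannot be
  met; only the BIC learners find them. This is a property of the
  published coefficient pattern combined with the invented covariate
  correlations, not of the implementation; detection would require
  roughly n ≥ 10⁴.
* Orientation within the lean-mass backbone is frequently statistically
  equivalent (score-equivalent BIC), so learned arc directions there
  should not be read causally.
* The generator's margins match three moments per variable; quartiles are
  not matched exactly for skewed variables.
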