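# Methods

This note records the statistical model behind `readzipf`, the
operational choices made where the construct is qualitative, and what the
synthetic data do and do not establish.

## Data model

A clinical code is 1–5 alphanumeric characters; depth equals length and
the first character's class determines the section (digit → process of
care, uppercase → diagnosis, lowercase → medication).  Case is never
folded — it carries the section semantics.  Trailing `.` filler
characters, emitted by some Read v2 export dialects (`G30..`), are
stripped before the depth is computed, so depth always means the semantic
level; an all-dots token is malformed.  Terminology files are optional
everywhere: corpus analyses run from observed codes alone, and only
"codes available" depth profiles need a terminology.  Depth ceilings per
section (4 for medication, 5 elsewhere in the official terminology) are
configuration, not hard-coded fact, because the official release is not
distributed with the package.

## The fitting sample

All power-law fitting operates on the frequency-of-frequencies sample:
one observation per distinct code, namely its usage count.  This matches
the `P(f) ∝ f^(−β)` formulation and the Pareto plots over frequency; the
token stream itself is never the fitting sample.  Exponents are carried
in all three equivalent conventions, `β = 1 + k = 1 + 1/α`, enforced to
1e-12 on every fit.

## Discrete power-law estimation

* **Likelihood.** For integer counts `x ≥ xmin` the model pmf is
  `x^(−β) / ζ(β, xmin)` with `ζ` the Hurwitz zeta function
  (`scipy.special.zeta`).  The discrete likelihood is used throughout;
  frequency data are small integers, where the continuous approximation
  is known to bias β.  `β̂` is found by bounded scalar minimisation of
  the negative log-likelihood on (1.001, 6]; the upper bound is
  configurable and exists to keep degenerate samples from diverging
  (realistic corpus exponents lie well inside it).  A tail whose
  observations all equal `xmin` has zero log-spread and no interior
  maximum; that raises a divergent-MLE error rather than returning the
  bound.
* **KS distance.** `D` is the exact maximum of `|S(x) − P(x)|` over
  integers `x` in `[xmin+1, max observed]`, where `S` and `P` are the
  empirical and model *inclusive* tail functions.  Both tails equal 1 at
  `xmin`, so that point carries no information and is excluded; for a
  sample concentrated entirely at `xmin` the comparison point is
  `xmin+1`, where `D` is the model mass strictly above the cutoff.
  Because `S` is piecewise constant and `P` strictly decreasing, the
  supremum is attained at observed values or the integers just above
  them, so the exact `D` needs only O(distinct values) zeta evaluations.
* **Cutoff scan.** Every distinct observed value is a candidate `xmin`
  provided it leaves at least `min_tail` (default 10) tail observations;
  each candidate is fitted by MLE and scored by `D`; smallest `D` wins,
  ties to the smaller cutoff.
* **Plausibility.** The bootstrap p-value draws replicates of the
  original sample size: below-cutoff observations are resampled from the
  empirical data, tail observations from the fitted discrete power law
  (sampled exactly by inverse-CDF bisection on the zeta tail — no
  continuous approximation).  Each replicate is refitted by the same
  scan; `p` is the fraction of replicate KS distances at least the
  observed one, and the power law is plausible when `p > 0.1` (a named
  constant).  Replicate `r` derives its generator from `(seed, r)`, so
  runs are bit-reproducible.  A replicate whose refit finds no
  admissible cutoff is scored `D = ∞`, counting toward plausibility
  (conservative).  Default `n_boot` is 200 in the library and must be at
  least 20, below which `p` cannot resolve the 0.1 threshold; rigorous
  p-value precision needs more replicates than desk-scale defaults.

Calibration behaviour (verified by the test suite at n = 2,000,
n_boot = 100): genuine discrete power-law samples are accepted
(`p > 0.1`) in ≥ 80% of seeds, while narrow shifted-Poisson ("indexical")
count samples are rejected in ≥ 90%.

## Core/peripheral segmentation

The two-regime structure seen on per-practice Pareto plots — a straight
power-law region of rare codes and a deviating region of common codes —
is operationalised as follows.  In the rank-frequency view the core is a
*flattening* of the head: the most common codes are more alike in
frequency than the Zipf line extrapolated from rare codes predicts.  On
the tail-CDF plot this appears as the empirical curve dropping below the
fitted line at high frequency.  The transition `f*` is the smallest
observed frequency above `xmin` at which the signed log-space deficit
`log10 P(x) − log10 S(x)` exceeds `ε` (default 0.05) *and keeps
exceeding it* out to the largest observed frequency, with the model tail
scaled by `n_tail/n_types` so the curves coincide at the cutoff.  Codes
with count ≥ `f*` form the core.

Two robustness choices matter and are exposed as configuration:

* the deficit is **signed**, not absolute — at the extreme upper order
  statistics `|log10 S − log10 P|` exceeds 0.05 with high probability
  under the model itself (the single maximum alone would qualify ~90% of
  the time), so an absolute test would split almost every corpus;
* a detected core must contain at least `min_core_size` (default 10)
  distinct codes — a "core" of one or two extreme order statistics is
  indistinguishable from noise.

With these rules, pure Zipfian corpora come out degenerate (no core) and
corpora with an injected high-frequency block are detected with the
block in the core.  Region mean depths are type-weighted by default (the
regions are sets of vocabulary items); token weighting is available.

## Synthetic corpora

The generator emulates the statistical structure the analysis assumes,
not clinical content:

* **Terminology.**  Random prefix-closed trees per section, roots using
  section-appropriate initial characters, children formed by appending
  one alphanumeric character, growth preferring deeper parents so a
  large share of codes reaches the section ceiling.  Medication uses
  ceiling 4, other sections 5.
* **Zipfian corpora.**  Tokens are i.i.d. draws with `p(r) ∝ r^(−α)`
  over `n_types` ranks; the rank-frequency parameterisation is primary
  because the pipeline ingests event streams, and the fitted frequency
  exponent recovers `β = 1 + 1/α` (verified end-to-end to ±0.1 at
  n_types = 5,000).  Defaults (`α = 1.5`, 5,000 types, 200,000 tokens)
  put `β` near 1.67 and TTR in the low percent range, inside the bands
  reported for real primary-care corpora (β ≈ 1.5–2.1, TTR ≈ 0.3–11%).
* **Depth–rank coupling.**  A rank is "monotone" with probability |ρ|
  (`depth_rank_correlation`); monotone ranks receive the selected codes
  in order of increasing depth (common codes shallower; reversed for
  ρ < 0), the rest at random, so ρ = 0 makes depth exactly independent
  of rank.  This empirical-quantile coupling is feasible for any depth
  marginal the terminology offers, unlike a parametric map from rank
  quantile to target depth, which breaks when the terminology cannot
  supply the targeted depths.
* **Injected core.**  `core_size > 0` replaces the head with a flat
  block: each of the top ranks gets `core_boost` (default 3) times the
  weight the Zipf line assigns to rank `core_size+1`.  The injected code
  texts are recorded in the ground truth so detection can be scored.
* **Indexical corpora.**  All codes at the section's depth ceiling with
  counts `1 + Poisson(mean 9)` — narrow, non-heavy-tailed usage with
  TTR an order of magnitude higher than the Zipfian sections, mirroring
  how medication data behave.
* **Panels.**  Per-practice configs concatenate into one corpus;
  stratification recovers each member exactly.  Sweeping α over
  [1.0, 1.8] spans fitted per-practice β from roughly 1.55 to 2.05.

Every corpus is emitted with a ground-truth sidecar (config, realised
per-code counts, depths, sections, injected block) that tests validate by
independent recount.  Identical seeds give byte-identical corpora.

What passing tests on these corpora do **not** show: real coding data
have temporal trends, patient-level correlation, clinically structured
co-occurrence and dirty records; the generator draws i.i.d. tokens from
a stationary law, so results here establish correctness of the
estimators and pipeline, not that any particular real corpus is Zipfian.

## Problem sizes and numerics

Statistical checks run at desk scale, chosen for test power: parameter
recovery uses 20 seeds × 5,000 observations per exponent (mean
|β̂ − β| ≤ 0.05); calibration uses 20 seeds × 2,000 observations with
100 bootstrap replicates; segmentation checks use 2,000-type,
100,000-token corpora.  Zeta-based quantities are exact to double
precision; the MLE optimiser tolerance is 1e-8, well inside the 1e-3
agreement demanded against the grid-search oracle.  Rank ties are broken
by code text so fixtures are deterministic; ties never affect the
frequency sample or the fit.

## Known limitations

* No comparison against alternative heavy-tailed models (lognormal,
  stretched exponential); plausibility is the only model check, matching
  the analysis the pipeline implements.
* The `ε`/persistence/minimum-size segmentation rule is one
  operationalisation of a visual construct; different rules move `f*`.
* Dates are parsed and retained but not used analytically (no
  windowing or trend analysis).
* TTR depends strongly on corpus length; cross-practice TTR comparisons
  are meaningful only at comparable token counts, which the panel
  generator provides but real extracts may not.
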