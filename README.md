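# readzipf

Zipf and power-law analysis of hierarchically coded clinical-event
corpora.

UK primary-care records are coded with 5-byte alphanumeric Read codes in
which each character encodes one level of a hierarchy (`G` → `G3` →
`G30` → `G301` → `G3011`, depth 1–5) and the first character's class
fixes the section: digits are processes of care, uppercase letters
diagnoses, lowercase letters medication.  Treating the stream of codes a
practice emits as a *corpus* and each code as a *word*, the machinery of
statistical linguistics applies: code usage in diagnosis and procedure
data is heavy-tailed and approximately Zipfian, while medication coding
behaves like an indexical reference system (every code recorded at the
deepest level the terminology offers, with narrow, non-heavy-tailed
usage counts).  Comparing these statistics across practices is a
candidate data-quality signal.  This package is for health-informatics
researchers who want to run that analysis on coded event extracts — and,
because real extracts usually cannot be shared, it ships a synthetic
corpus generator that reproduces the relevant statistical structure.

## The model

Three equivalent descriptions of Zipfian data are used interchangeably,
and every fit carries all three exponents:

* rank–frequency (Zipf): `f(r) ∝ r^(−α)`;
* frequency distribution: `P(f) ∝ f^(−β)` with `β = 1 + 1/α`;
* Pareto tail CDF: `P(X ≥ x) ∝ x^(−k)` with `k = β − 1 = 1/α`.

Fitting operates on the frequency-of-frequencies sample (one observation
per distinct code: its usage count) with the standard discrete power-law
recipe: maximum-likelihood `β̂` using the Hurwitz-zeta normaliser
`ζ(β, xmin)`, a scan over candidate lower cutoffs `xmin` keeping the one
with the smallest Kolmogorov–Smirnov distance, and a semiparametric
bootstrap p-value; the power law is regarded as a plausible model when
`p > 0.1`.  Around the fit the package computes type–token ratios
(TTR = 100 × types/tokens), empirical Pareto curves, depth-of-use
profiles, per-practice stratified fits, and a core/peripheral vocabulary
segmentation at the frequency where the empirical curve leaves the
fitted line.

## Worked example

Simulate a Zipfian diagnosis corpus (α = 1.5, so β = 1 + 1/α ≈ 1.67) and
run the full pipeline:

```sh
readzipf simulate --seed 42 --n-types 2000 --n-tokens 80000 \
    --alpha 1.5 --correlation 0.6 --out events.csv
readzipf analyze --input events.csv --sections diagnosis \
    --n-boot 100 --seed 7 --out-dir analysis
```

which prints

```
wrote 80000 events (1310 types) to events.csv
report written to analysis/report.json
diagnosis: beta=1.691 xmin=2 TTR=1.64% p=0.930 (plausible)
```

The fitted `β̂ = 1.691` recovers the generator's implied exponent 1.667
to within sampling error; `xmin = 2` says the power law holds essentially
from the smallest counts; TTR of 1.64% reflects heavy repetition (1,310
distinct codes over 80,000 events); and the bootstrap p-value of 0.93
(≫ 0.1) means the power law is a plausible model of these counts.
`analysis/` contains the JSON report, frequency/Pareto/depth tables as
TSV, and a log-log Pareto plot with the fitted line overlaid.  An
indexical corpus (`--generator indexical`) instead yields `p < 0.1` —
not plausibly a power law — with 100% of codes used at the depth
ceiling.

The same operations are available as a library
(`readzipf.fit_power_law`, `readzipf.goodness_of_fit`,
`readzipf.sample_zipf_corpus`, ...); see the module docstrings.

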