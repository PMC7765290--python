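# Methods

## Instrument model

The full instrument is modelled as the product set
joints × sites × features: 12 joints (MCP, PIP, DIP of digits 2–5),
2 sites per joint, 6 features, hence 144 items and a maximum total of
504. All six features are stored per joint site even though some are
clinically read per joint; this is the only item model consistent with
the 144-item count, and per-joint readings can be encoded by scoring one
site and zeroing the other. Site labels are abstract (`site_A`/`site_B`)
with anatomical aliases (proximal/dorsal → A, distal/palmar → B) because
the site pair in use depends on the feature. Anatomical ordering
(MCP < PIP < DIP, digit ascending) is the single serialization and
tie-breaking order throughout. A reduced instrument is the same type
restricted to a joint subset, so restriction composes and the maximum
total is additive over joints.

## Cohort data

Cohorts are long-format records keyed by (patient, timepoint ∈ {t0, t1},
rater, joint, site, feature). Validation is strict: unknown tokens,
out-of-range or fractional values, duplicate keys and follow-up-only
patients are all errors with row numbers. Missing items are an error by
default — silent zero-imputation would bias SRMs toward 0 — with an
explicit, loudly logged `missing="zero"` escape hatch. Multi-rater
cohorts are collapsed by one of three policies: `consensus_required`
(raters must agree; disagreements resolved only by an explicit
`consensus` rater, the appropriate policy for consensus-read clinical
data), `mean` (item-wise mean, rounded half away from zero to stay on
the ordinal grid; fractional means available behind a flag), or
`single:<rater>`. The SD of a single observation is NaN, not 0.

## Responsiveness (SRM)

Change is `Δ = score(t0) − score(t1)` per complete-case patient (scores
that rise under therapy give negative SRMs), and
`SRM = mean(Δ) / SD(Δ)` with the sample (n−1) SD; the denominator
convention is switchable via `ddof` since either appears in the
literature. Classification uses |SRM| — the strata are conventionally
written for positive values but responsiveness is directionless — at
0.2 / 0.5 / 0.8. Degenerate cases are explicit: a sub-score whose items
are zero throughout the cohort has no defined responsiveness (NaN,
"not available"); zero change variance with zero mean is SRM 0; zero
variance with non-zero mean is NaN with a warning.

## Selection and the simplified score

Joints are ranked by |overall sub-score SRM| descending, NaN last, ties
broken anatomically; the top k (default 3) are kept, and a magnitude tie
across the cut pulls in the whole tie block (flagged). Summation over
the selected joints' items is unweighted: selection itself is the only
weighting applied. Signed ranking is available behind a flag.

## Relative efficacy

`RE = (SRM_s / SRM_ref)²`; 0/0 is NaN, x/0 is +inf, both flagged.
Bootstrap bounds resample **patients** with replacement — the only
exchangeable unit in a paired pre/post design; resampling items or
timepoints would break pairing — with B = 5000 by default, and take
empirical 2.5/97.5 percentiles by the nearest-rank definition
(`sorted[⌈q·m⌉ − 1]`), so a fixed seed reproduces bounds bit-for-bit.
Replicates with NaN RE are excluded from the quantiles and counted;
infinite REs stay in the ranking. On cohorts whose reference SRM is
near zero the replicate distribution is extremely heavy-tailed (lower
bound 0, very large upper bound); the degenerate/infinite counters exist
to surface that rather than hide it. An exhaustive mode enumerates all
nⁿ ordered resamples for tiny cohorts, which the tests compare against
an independent brute-force enumeration.

## Agreement statistics

Pearson r comes with the t-based two-sided p (n−2 df) and a Fisher-z
95% CI (±1.96/√(n−3)); strength uses Cohen's strata on |r|
(0.1/0.3/0.5). Reliability is the two-way mixed ICC in the
**consistency** form — sICC = (MS_rows − MS_err)/(MS_rows + (k−1)·MS_err)
(single measure) and aICC = (MS_rows − MS_err)/MS_rows (average
measure), computed from the targets × raters ANOVA with patient ×
timepoint overall scores as targets — because the source description of
"two-way mixed" does not fix the agreement/consistency type; the
absolute-agreement form is behind `form="agreement"`. The two
consistency forms satisfy the Spearman–Brown identity
aICC = k·sICC/(1 + (k−1)·sICC), which the tests assert on random grids,
and both are cross-checked against an independent reference
implementation. Baseline-vs-follow-up comparisons use a two-sided
paired t-test on complete cases (the test behind such descriptive-table
p-values is not standardized; this choice is recorded in the output
metadata). Identical samples return t = 0, p = 1 as the continuous
limit; a non-zero constant difference raises instead of fabricating a p.

## Synthetic cohort generator

Each item carries a persistent latent severity
`S = μ_feature + frailty_patient + u`, u ~ N(0,1), frailty ~ N(0, 0.5).
Observed latents are `L_t = S + ε_t` with ε_t ~ N(0, σ_change/√2), plus
the (joint, feature) treatment shift at t1, so the latent change has SD
σ_change (default 1) and — crucially — both timepoints share the same
marginal distribution. (Generating t1 by adding independent noise to
the *realized* t0 latent would give t1 a larger variance, and the
nonlinear thresholding converts unequal variances into a spurious mean
score increase of about one SRM unit; the exchangeable-noise form keeps
the null honest, with |overall SRM| ≈ 0.005 at n = 500.) Scores are
`clip(floor(L), 0, max)` — equal-width thresholds at 1, 2, … on the
latent scale. An item is active with a feature-specific prevalence,
else 0 at both timepoints. Raters misread an active item by ±1 (within
range) with probability `rater_flip_prob` (default 0.1); inactive items
are never perturbed, so a zero-prevalence feature is zero everywhere.
Dropout is deterministic — the last patients by id lack t1 — keeping
fixtures stable across seeds.

Defaults emulate the study shape: 17 baseline patients, 13 with
follow-up, 2 raters. Prevalences (synovitis 0.75, tenosynovitis 0.55,
periarticular inflammation 0.80, edema 0.30, erosion 0.35,
proliferation 0.05) and severities encode "inflammatory features
frequent, osseous damage less so, proliferation rare", and were set once
to land baseline descriptives in the right magnitude regime (baseline
overall ≈ 53 of 504, per-feature ordering preserved). The study-shaped
`adam_like_config` adds small uniform latent drifts (+0.06 synovitis,
+0.05 periarticular inflammation and erosion, −0.04 tenosynovitis and
edema) whose *expected* overall SRM is in the trivial band
(≈ −0.11 measured at n = 500). Per-joint prevalence is uniform within a
feature (no finer detail is available to emulate).

What passing tests do and do not show: the generator reproduces
structure (ranges, keys, dropout, rater noise, prevalence regimes,
near-null responsiveness), not any real cohort's means or SDs; with 13
complete cases the sampling SD of an overall SRM is ≈ 1/√13 ≈ 0.28, so
single-seed SRM values at study size scatter well beyond the trivial
band, and which joints top the ranking under a near-null effect is
noise-driven. Conclusions about real data should lean on the
large-n calibration and recovery properties, not on any one small-n
draw.

## Numerical and design choices

- All computation is at full precision; 2-decimal rounding happens only
  at serialization, with full-precision companions written alongside
  (computing from rounded intermediates is exactly how a squared SRM
  ratio becomes irreproducible from its own displayed inputs).
- Determinism: every stochastic stage takes an explicit seed; identical
  run configs produce byte-identical report bundles, and the manifest
  records seed, versions and flags.
- Problem sizes used by the test suite and acceptance script — 100
  recovery replicates at n = 200 with latent shift 0.5, null calibration
  at n = 500, p-value uniformity at 10⁴ replicates of n = 15,
  B = 5000–20000 bootstraps — were chosen to make the stochastic
  assertions sharp (recovery ≥ 95%, |null SRM| < 0.1, KS p > 0.01)
  while remaining desk-scale.
- k (number of selected joints) defaults to 3 but is configurable;
  nothing in the method fixes it.

## Known limitations

- Timepoints are fixed to t0/t1; longer longitudinal designs are out of
  scope, as are wrist/foot joints and other scoring systems' features.
- The pipeline's ICC block operates on overall scores (item-level grids
  are accessible through the library).
- No BCa or studentized bootstrap variants; the percentile method is
  the point.
- The generator's latent model is one admissible choice among many that
  match the marginal facts being emulated; its effect sizes are latent
  standardized shifts, not directly observable score differences.
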