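# psamris

Analytics for the OMERACT PsAMRIS hand-MRI score: responsiveness
analysis, data-driven score simplification, bootstrap relative
efficacy, and rater-agreement validation — plus a synthetic cohort
generator so the whole pipeline is testable without patient data.

## The problem

PsAMRIS is a semi-quantitative MRI score for psoriatic arthritis of the
hand: six features — synovitis (0–3), flexor tenosynovitis (0–3),
periarticular inflammation (0/1), bone edema (0–3), bone erosion
(0–10), bone proliferation (0/1) — read at two sites in each of the 12
MCP/PIP/DIP joints of digits 2–5, i.e. 144 ordinal items summed into an
overall score. Scoring all 144 items is slow enough to limit clinical
use, which motivates a simplified instrument restricted to the joints
that actually carry the change signal under therapy.

This package implements that simplification pipeline for researchers in
clinimetrics and musculoskeletal imaging:

- **Responsiveness.** For every sub-score, the standardized response
  mean `SRM = mean(Δ) / SD(Δ)` with `Δ = score(t0) − score(t1)` per
  patient (sample SD), stratified as trivial/small/moderate/large at
  |SRM| = 0.2 / 0.5 / 0.8.
- **Selection.** Joints ranked by |overall-sub-score SRM| (ties broken
  anatomically, tie blocks across the cut included); the top *k*
  (default 3) define the simplified instrument, e.g. {MCP3, MCP4, PIP4}
  → 36 items instead of 144.
- **Relative efficacy.** `RE = (SRM_simplified / SRM_full)²` with
  percentile confidence bounds from B = 5000 bootstrap resamples of
  patients (nearest-rank 2.5/97.5 percentiles; degenerate replicates
  counted, infinite ones retained).
- **Agreement.** Pearson r with Fisher-z CI and Cohen strata; two-way
  mixed ICC (consistency form, single- and average-measure) from the
  targets × raters ANOVA; paired t-tests for baseline-vs-follow-up
  comparisons.
- **Synthetic cohorts.** A latent-Gaussian threshold model with
  per-feature prevalence and severity, patient frailty, latent
  treatment shifts, deterministic dropout and ordinal rater noise,
  emulating a 17-patient / 13-follow-up / two-rater study.

## Worked example

```python
from psamris import (adam_like_config, generate, resolve_raters, srm_grid,
                     rank_joints, select_joints, derive_simplified, bootstrap_re)

cohort = resolve_raters(generate(adam_like_config(seed=1)), "mean")
grid = srm_grid(cohort)
selection = select_joints(rank_joints(grid), k=3)
simplified = derive_simplified(cohort.schema, selection)
res = bootstrap_re(cohort, simplified, B=5000, seed=1)
```

Running `python examples/03_srm_and_selection.py` prints (seed 1):

```
complete cases: 13  excluded: 4
overall instrument SRM: 0.16 (trivial)
...
selected: ['PIP2', 'MCP4', 'DIP4'] (tie expanded: False)
simplified instrument: 36 items instead of 144
```

With only 13 complete cases and near-zero true change, the overall SRM
(0.16) sits in the trivial band, and which joints top the |SRM| ranking
is noise-driven — an instability the synthetic generator makes visible
(the recovery tests show that with a real concentrated effect and
n = 200 the correct joints are re-selected in >95% of replicates).
`examples/04_bootstrap_efficacy.py` shows the matching efficacy output:

```
RE = 0.10  [0.00, 333.87] (B = 5000)
degenerate replicates dropped: 4, infinite retained: 70
```

a heavy-tailed percentile interval, which is exactly what squaring a
ratio of two near-zero SRMs produces on a small cohort.

The other `examples/` scripts cover the instrument model, cohort
simulation and descriptives, agreement statistics, and the one-call
pipeline (`RunConfig` + `run`) that writes a deterministic report
bundle. A thin CLI mirrors the library:

```bash
psamris simulate --seed 1 --out cohort.csv
psamris srm --cohort cohort.csv --out grid.csv
psamris reduce --grid grid.csv --out selection.json --schema-out spsamris.json
psamris run --seed 1 --out bundle/
```

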