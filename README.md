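# vfsim

Monte-Carlo simulation of longitudinal visual-field (VF) testing for
glaucoma follow-up, built for clinicians and vision scientists asking a
resource-allocation question: **how long does it take, under a given testing
schedule, before a patient's intrinsic perimetric variability and
reliability can be considered known?**

Standard automated perimetry summarises each test by the mean deviation
(MD, in dB). Repeated tests fluctuate around the true trajectory
(test-retest *variability*, σ) and are sometimes discarded altogether
(*reliability*, the probability p that a test yields usable data). Both are
treated as immutable, subject-specific quantities. `vfsim` simulates
cohorts of subjects, applies the clinically observable estimation
procedure visit by visit, and reports the **critical time** at which the
estimates stabilize.

## Model

Each subject carries a ground-truth quadruple sampled independently:

| parameter | distribution | default |
|---|---|---|
| baseline MD, `md0` | Normal(μ, s) | μ = −4 dB, s = 2 dB |
| progression rate, `r` | skew-normal SN(ξ, ω, α) | ξ = −0.05, ω = 0.8 dB/yr, α = −2 |
| intrinsic variability, `σ` | lognormal (log-scale mean 0.5, sigma 0.4) | median e^0.5 ≈ 1.65 dB |
| intrinsic reliability, `p` | Beta(9, 1.5) rescaled onto [0.5, 0.99] | median ≈ 0.93 |

Every test result is `md0 + r·t + ε`, `ε ~ N(0, σ²)`, and is kept with
probability `p`. The core dataset holds 4 tests/visit on the finest grid
(3-monthly over 20 years, or daily over 28 days); the 12 testing conditions
(1–4 tests per visit × 1/2/4× review interval) are derived by subsetting.

Per visit `v` the observable estimates are cumulative: the reliability
estimate `p̂_v` is the fraction of kept tests among all administered so far;
the variability estimate `σ̂_v` is the sample SD of all kept values so far,
after removing the OLS-estimated progression slope under the long-term plan
(raw values under the short-term plan, where progression over days is
negligible). Two stopping rules are scanned over each estimate series:

* **TcV / TcR** — first 3 consecutive defined estimates whose range is
  within 5% of their mean (clinically observable criterion); the third
  visit's time is the critical time.
* **TgV / TgR** — first 3 consecutive estimates each within 5% of the
  ground-truth parameter (validation criterion).

Visits with no usable result are skipped without resetting the 3-visit
window; subjects whose rule never fires are censored.

The detection-probability calculator complements this: the chance that one
test detects a fixed difference `d` (e.g. 0.8 dB of progression) is
`Φ(d/σ)`, and with `n` tests per visit the chance of detection on ≥ 1 test
is `1 − (1 − Φ(d/σ))^n`.

## Worked example

The detection grid (rows: σ in dB; columns: tests per visit; cells:
probability of detecting a 0.8 dB difference on ≥ 1 test):

```text
$ vfsim detect
                  snr  1_tests_per_visit  2_tests_per_visit  3_tests_per_visit  4_tests_per_visit
variability_db
0.5            1.6000             0.9452             0.9970             0.9998             1.0000
1.0            0.8000             0.7881             0.9551             0.9905             0.9980
1.5            0.5333             0.7031             0.9118             0.9738             0.9922
2.0            0.4000             0.6554             0.8813             0.9591             0.9859
2.5            0.3200             0.6255             0.8598             0.9475             0.9803
```

A low-variability patient (0.5 dB) is well served by a single test per
visit (94.5% detection); at 2 dB of noise even four tests per visit reach
only 98.6% for the same signal, and a single test misses one time in three.

A full (reduced-size) experiment from Python:

```python
from vfsim import RunConfig, run_experiment

run_experiment(RunConfig(n_subjects=2000, seed=42, output_dir="demo"))
```

writes per-subject critical times and summary tables. Median (IQR) years to
a stable *reliability* estimate (TcR, long-term plan) by review interval
(rows, × 3 months) and tests per visit (columns):

```text
                    1_tests_per_visit   ...  4_tests_per_visit
1                      0.5 (0.5, 0.5)   ...      0.75 (0.5, 1)
2                            1 (1, 1)   ...         1.5 (1, 2)
4                            2 (2, 2)   ...           3 (2, 4)
```

Reliability is typically known by the third visit — half a year at
3-monthly review, two years at yearly review. Stable *variability*
estimates take far longer (median 12 days of daily single tests in the
short-term plan; several years on clinical schedules), which is why the
package's short-term intensive schedules exist at all.

The same run prints the sampled cohort summary
(`population_summary.csv`): median slope −0.57 dB/yr, median σ 1.61 dB,
median reliability 0.93 at n = 2000 — converging to the design values
(−0.57, 1.65, 0.93) at the full cohort size.

## Command line

```bash
vfsim simulate --seed 1 --n 100000 --family both --out run/   # cohort + critical times
vfsim analyze  --in run/                                      # summary tables from CSVs
vfsim detect   --signal 0.8 --variabilities 0.5,1,1.5,2,2.5   # detection grid
vfsim report   --seed 1 --n 100000 --out run/                 # full pipeline + manifest
```

Configuration can also be given as YAML/JSON (`--config`), including the
rolling-window tolerance (`tolerance: 0.10` for the documented 10%
variant). All outputs are deterministic in the seed.

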