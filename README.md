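# ivdquant

Quantitative MRI of lumbar intervertebral discs (IVDs): T2 relaxometry,
regional segmentation, morphometry, nucleus-to-annulus signal ratios,
and an association battery relating these disc-health markers to
lifetime physical-loading exposure.

The package is aimed at musculoskeletal imaging researchers who quantify
disc degeneration from sagittal spine MRI. It implements, as a tested
and reusable pipeline:

* **T2 relaxometry** — the disc signal decays mono-exponentially with
  echo time, `S(TE) = S0·exp(−TE/T2)`, so a straight-line fit of
  `ln S` on TE across the eight echoes (15.75 … 162.75 ms) gives
  `T2 = −1/slope`. Higher disc T2 indicates greater hydration.
* **Five anterior–posterior regions** — each traced disc is split into
  five equal-length bands along its anterior–posterior axis (anterior
  annulus, anterior nucleus, central nucleus, posterior nucleus,
  posterior annulus) for regional T2 values.
* **Morphometry** — disc height (mean endplate-to-endplate chord across
  the whole disc), width (anterior-to-posterior distance), slice area,
  volume (Σ slice areas × 4.5 mm effective slice spacing), and the
  dimensionless disc-height / vertebral-body-height ratio.
* **Nucleus-to-annulus ratio** — mean T2-weighted signal of the three
  central regions over the mean of the two outer regions, a hydration
  contrast marker.
* **Statistics** — per-level and average-spine simple and
  covariate-adjusted linear regressions of each disc outcome on the
  BPAQ (bone-specific physical activity questionnaire) total score,
  sex-stratified pooled-disc standardized models, regional-T2 models,
  pain/disability models, covariate screening, and Benjamini–Hochberg
  FDR sensitivity analysis.

No imaging data are required: a phantom module simulates multi-echo,
T2-weighted and vertebral stacks with known ground truth, and a cohort
generator plants exposure–outcome effects so every estimator can be
validated by parameter recovery. See `docs/methods.md` for the models,
conventions and limitations.

## Worked example

Simulate a noisy phantom (Gaussian σ = 5 on S0 = 1000), quantify it from
its boundary traces, and compare with the ground-truth ledger:

```python
import ivdquant as iq

spec = iq.default_phantom_spec(seed=42, noise_model="gaussian", noise_sigma=5.0)
geo = iq.make_disc_geometry(spec)
stack, truth = iq.simulate_multiecho(spec, geo)
t2w = iq.simulate_t2w(spec, geo)
vert, vtraces, _ = iq.simulate_vertebral(spec, geo)

summary = iq.quantify_participant(
    stack, t2w, vert, truth.disc_traces + vtraces,
    config=iq.PipelineConfig(log_level="WARNING"),
)
print(summary[["level", "t2_ms", "t2_r3", "height_mm",
               "volume_cm3", "height_ratio", "na_ratio"]].round(3))
```

This prints (seed 42):

```
  level   t2_ms   t2_r3  height_mm  volume_cm3  height_ratio  na_ratio
T11/T12  94.764 112.045      7.097       7.941         0.267     2.003
 T12/L1  95.836 113.889      7.540       8.680         0.284     2.000
  L1/L2  98.036 116.023      7.984       9.419         0.301     1.996
  L2/L3  99.074 117.962      8.428      10.281         0.318     1.997
  L3/L4 101.208 120.006      8.871      10.958         0.334     1.997
  L4/L5  99.353 118.972      9.758      12.250         0.368     1.998
  L5/S1  96.424 115.050      8.871      10.958         0.334     2.006
```

Reading the L5/S1 row against the truth ledger: the central-nucleus T2
(`t2_r3` = 115.05 ms) recovers the true 115 ms to within the noise; the
volume (10.958 cm³) matches the analytic truth of 10.954 cm³; and the
nucleus-to-annulus ratio (2.006) reflects the simulated 2:1 intensity
contrast. The whole-disc `t2_ms` (96.4 ms) sits a little above the mean
of the five region T2s (93.8 ms) because a single log-linear fit across
a heterogeneous disc weights the longer-T2 nucleus at late echoes — an
estimator property discussed in `docs/methods.md`.

The full pipeline (synthetic cohort with planted effects → per-
participant phantoms → quantification → association battery) runs from
the command line:

```bash
ivdquant simulate --out out/ --seed 7         # full pipeline, writes CSVs
ivdquant report out/results.csv               # human-readable tables
```

`out/results.csv` is a tidy table (family, stratum, level, region,
outcome, n, beta, ci_low, ci_high, p, q, adjusted, covariates), and
`out/report.txt` lays the models out per level, average spine, sex
stratum and region.

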