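# voxpower

Statistical-power, effect-size-inflation and replication-overlap simulation
for **mass-univariate voxelwise brain–behavior correlation studies**.

Small-sample neuroimaging studies that correlate a behavioral trait with
activity at every voxel face a harsh statistical regime: thousands of
simultaneous Pearson tests, stringent thresholds, and — plausibly — many
weak true effects rather than a few strong ones. `voxpower` makes that
regime tangible. It builds a simulated axial brain slice of 4,713 voxels,
designs per-voxel population correlations ρ_v under two named scenarios,
generates a large synthetic cohort, and then emulates thousands of small
studies by subsampling it, so you can watch what a given sample size and
threshold actually deliver.

The two scenarios:

* **Weak Diffuse (WD)** — 72% of the slice carries weak effects
  (|ρ| ∈ [0.05, 0.14]); the rest carries even smaller nonzero effects.
* **Strong Localized (SL)** — 3.8% of the slice carries strong effects
  (|ρ| ∈ [0.61, 0.80]) in four compact blobs (two positive, two negative);
  everything else is exactly null.

Each subsample of size *n* is scored per voxel with the Pearson test
(t = r√((n−2)/(1−r²)), two-sided p from t with n−2 df), thresholded
(uncorrected p < α or Benjamini–Hochberg FDR), and summarized by:

1. **average power** — fraction of true-effect voxels reaching significance;
2. **at-least-one power** — whether any true-effect voxel was detected;
3. **mean significant |r|** — the winner's-curse inflation: conditional on
   significance, |r| ≥ r*(α, n), the critical correlation, no matter how
   small the true effect;
4. **percent significant voxels** — apparent spatial extent;
5. **Dice overlap** 2|A∩B|/(|A|+|B|) between paired repetitions — how well
   a "replication study" reproduces the map.

Alongside the simulator sit the analytic calculators used for calibration:
exact power of the correlation test (quadrature of the exact sampling
density of r), its Fisher-z approximation, Fisher-z confidence intervals,
and a search for the uncorrected threshold that balances the expected
type II to type I **error counts** at a chosen ratio.

## Worked example

```python
import voxpower as vp

field = vp.make_effect_field(vp.ScenarioSpec.weak_diffuse(seed=0))
print(f"WD field: {field.mask.n_voxels} voxels, "
      f"{int(field.band_mask.sum())} in band |rho| 0.05-0.14")

cfg = vp.ExperimentConfig(
    scenario=vp.ScenarioSpec.weak_diffuse(seed=0),
    full_n=10_000, n_grid=(30, 150), n_reps=200, master_seed=1,
)
bundle = vp.run_experiment(cfg)
print(bundle.curves[bundle.curves.metric.isin(["avg_power", "mean_sig_abs_r"])]
      .to_string(index=False))
```

prints

```
WD field: 4713 voxels, 3393 in band |rho| 0.05-0.14
scenario  n_sub         metric     mean     lo95     hi95  n_defined
      WD     30      avg_power 0.017695 0.003602 0.040738        200
      WD     30 mean_sig_abs_r 0.510806 0.483294 0.543903        200
      WD    150      avg_power 0.066793 0.033461 0.100170        200
      WD    150 mean_sig_abs_r 0.244787 0.231877 0.259503        200
```

Read it as: a 30-subject study of the Weak Diffuse world detects under 2%
of the true effects at p < .01, and the voxels it does report carry a mean
|r| around 0.51 — more than three times the largest true effect (0.14).
Even at n = 150 average power stays below 7% while the reported effect
sizes remain inflated. The intervals are 2.5/97.5 percentiles over the 200
repetitions.

The analytic side is one call:

```python
>>> vp.power_correlation(0.3, 30, 0.001, method="exact")
0.0416...
```

i.e. a "medium" correlation of 0.3 tested in 30 subjects at the common
whole-brain threshold p < .001 is detected about 4% of the time.

The same functionality is exposed on the command line:

```bash
voxpower power --rho 0.3 --n 30 --alpha 0.001
voxpower scenario build --kind SL --out sl_field.nii.gz
voxpower experiment run --scenario WD --n-reps 200 --out results/wd
voxpower balance --scenario WD --n 30 --ratio 4
voxpower demo --rho 0.3
```

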