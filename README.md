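# dseqc

Quality control for 4D fMRI time series via a sum-of-squares ("DSE")
variance decomposition and a chi-squared test for squared DVARS.

The total variability of an I voxels × T timepoints dataset splits exactly
into a **fast** component D (mean square of half-differences of adjacent
scans — `DVARS_t² / 4`), a **slow** component S (mean square of
half-sums), and an **edge** component E (first and last scans), each
further split into global-signal and non-global parts.  The package

- computes all twelve diagnostic time series, their scan-level averages,
  and voxelwise A/D/S variance maps;
- builds the DSE summary table (RMS, % of total variability, and values
  relative to their expectation under IID noise), with analytic reference
  values under IID and time–space-separable noise models, and the
  `(S − D)/A · T/(T−1)` average lag-1 autocorrelation heuristic;
- tests each scan pair's squared DVARS against a chi-squared null whose
  mean and variance are estimated robustly (median of squared DVARS;
  IQR/half-IQR spread with an optional power transform), yielding
  p-values, Z-scores, standardized DVARS variants (%D-var, Δ%D-var,
  relative DVARS), and statistical (Bonferroni) plus practical
  (Δ%D-var > 5%) flags;
- simulates heteroscedastic Gaussian / AR(1) / variance-spiked data and
  runs the bias, calibration and power experiments that validate the test.

## CLI

```sh
# full QC report for a 4D NIfTI (or an I×T matrix in TSV/CSV/NPY form)
dseqc qc data.nii --mask mask.nii -o qc_out/

# synthetic data
dseqc simulate -I 5000 -T 600 --rho 0.4 --spike-rate 0.05 --seed 1 -o sim.tsv

# bias / calibration / power experiment grids from a YAML or JSON config
dseqc experiment config.yaml -o experiments/

# re-render the DSE table from a saved time-series TSV
dseqc table qc_out/dse_timeseries.tsv -I 5000
```

`qc` writes: tidy DSE time-series TSV, DSE table (TSV/JSON/text),
per-pair inference TSV, flagged-pair list, null-model JSON (μ₀, σ₀², ν,
ν/I), A/D/S NIfTI maps, a provenance record, and optionally a DSE plot
(`--plot`).

An experiment config holds a `seed` and lists of scenarios, e.g.

```yaml
seed: 7
bias:
  - {I: 10000, T: 200, sigma_min: 200, sigma_max: 500, replicates: 200}
validity:
  - {I: 10000, T: 600, sigma_min: 200, sigma_max: 500, replicates: 20,
     mu0_method: median_dvars2}
power:
  - {I: 10000, T: 600, rho: 0.2, spike_rate: 0.05, replicates: 100}
```

## Python API

```python
import numpy as np, dseqc

raw = dseqc.read_nifti_4d("data.nii", mask_path="mask.nii")
scaled = dseqc.scale_center(raw)                  # center, rescale to ~100
dse = dseqc.compute_dse_timeseries(scaled)        # 12 series + averages
table = dseqc.summarize(dse)                      # DSE table
result = dseqc.infer_dvars(dse)                   # chi-squared DVARS test
print(table.render())
print(result.flagged_pairs)
```

## Notes

- Sample quantiles use numpy's default linear interpolation throughout;
  IQR-based estimates depend on this choice, so it is fixed and documented.
- Scan-pair indices in outputs are 1-based: pair t covers scans (t, t+1).
- The estimated degrees of freedom ν behave as an effective number of
  spatial elements but are highly estimator-dependent; do not reuse them
  outside this test.
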