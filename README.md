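# mgcalab

Single-chamber Mg/Ca paleothermometry from pulse-resolved femtosecond
LA-ICP-MS signals.

The Mg/Ca molar ratio of planktic foraminifer shell calcite increases with
the temperature at which the calcite formed, which makes fossil tests an
archive of past surface-ocean temperature. Laser-ablation ICP-MS can resolve
that ratio chamber by chamber on a single test: a pulsed laser ablates a
~45 µm spot on one chamber wall, and the mass spectrometer records ²⁵Mg⁺ and
⁴⁴Ca²⁺ count rates as a train of ~0.9 s aerosol peaks at 1 Hz. `mgcalab`
implements the full data path for that kind of measurement, for analysts who
want a tested, scriptable alternative to spreadsheet reduction:

- **acquisition** — a synthetic signal generator (gas blank, rectangular
  pulse peaks, surface contamination, Mg banding, sensitivity drift, Poisson
  counting noise) with known ground truth, so every downstream stage can be
  verified end to end;
- **reduction** — pulse segmentation, gas-blank background subtraction, and
  a fixed rejection chain: early-ablation contamination trim (default 3 s),
  minimum count rates, then a 3×MAD outlier rule on the per-pulse
  ²⁵Mg⁺/⁴⁴Ca²⁺ ratio series;
- **quantification** — internal-standard calibration with a relative
  sensitivity factor (RSF) measured on bracketing MACS-3 reference-material
  spots:

  C_uncorr = C_IS · R_ik · (A_k/A_i) · (M_EL/M_IS),
  RSF = C_uncorr(standard) / C_true(standard),
  C_El = C_uncorr / RSF,

  plus the blank-based limit of detection (mean + 3σ), replicate precision
  (1 RSD), and a plausibility QC that rejects Mg/Ca > 20 mmol/mol;
- **calibration** — the exponential proxy relationship
  Mg/Ca = B·exp(A·T) with the *G. ruber* Dekens/Anand constants
  (B = 0.38 mmol/mol, A = 0.09 /°C) and an ln-linear least-squares fitter in
  the statsmodels model/results style;
- **stats** — the small-sample chamber-comparison battery (two-sided
  F-test, pooled/Welch t-test, Pearson r with t-based significance);
- **tables / reproduce** — readers and writers for the deposited
  tab-separated layouts, a packaged station/chamber-mean table, and a
  one-call reproduction of the station-table analyses.

## Worked example

Simulate a bracketed session with a contaminated sample spot, quantify it,
and fit a calibration to the packaged station table:

```python
import mgcalab as mg

sample = mg.SignalScenario(true_mgca=3.5, contamination_duration=3.0,
                           contamination_factor=10.0)
trains = mg.simulate_session(n_samples=1, bracket_every=28,
                             scenarios=[sample],
                             standard_scenario=mg.macs3_scenario(), seed=0)
results, rsf_model = mg.quantify_session(trains)
print(f"recovered Mg/Ca: {results[0].mgca_mmolmol:.6f} mmol/mol")

df = mg.load_table2()
fit = mg.MgCaCalibration.from_dataframe(
    df, temperature="sst_c", mgca="mgca_f1", label="F-1 vs SST").fit()
print(fit.summary())
```

prints

```
recovered Mg/Ca: 3.500000 mmol/mol
Exponential Mg/Ca calibration: F-1 vs SST
  Mg/Ca = B exp(A T), ln-linear least squares, n = 10
  A (exponent)        = 0.0938 ± 0.0354 /degC
  B (pre-exponential) = 0.523 ± 0.389 mmol/mol
  sensitivity         = 9.4 ± 3.5 % per degC
  r = 0.684, p = 0.02907
```

The first line is the closure property that anchors the whole pipeline: a
noise-free simulated spot, even with a 10× surface-contamination interval,
is recovered exactly after reduction and RSF quantification. The fit says
that the penultimate-chamber Mg/Ca of the packaged station means rises ~9%
per °C of sea-surface temperature, with r = 0.68 across the ten stations.
Back-calculating temperature from a chamber value uses the inverse map:
`mg.mgca_to_temperature(3.84)` → 25.70 °C with the default constants.

A `mgcalab` console script exposes the same pipeline
(`simulate`, `reduce`, `quantify`, `calibrate`, `stats`, `reproduce`);
`mgcalab reproduce --out report/` writes the station-table regression,
correlation and chamber-test report as TSVs and plots.

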