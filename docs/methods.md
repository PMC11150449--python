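# Methods

## Signal model

A laser spot is modelled as a gas-blank interval (default 20 s) followed by
an ablation interval (default 60 s) of rectangular aerosol peaks, one per
laser pulse at the pulse repetition rate (default 1 Hz), each lasting the
peak length (default 0.9 s) and separated by washout. Peaks are rectangular
because the only property the reduction relies on is that they are
separable (peak length ≤ pulse period); any separable peak shape would
reduce identically after peak-window averaging. The detector samples at
10 readings/s, with reading timestamps at interval midpoints so that each
0.9 s peak contains exactly nine readings.

Expected count rates are

- blank: `background_mg`, `background_ca` (cps);
- in peak: background + sensitivity × concentration, where the Mg and Ca
  concentrations of the ablated calcite follow from the scenario's true
  molar Mg/Ca and its Ca mass fraction (default 0.4004 g/g, stoichiometric
  CaCO₃).

Three disturbances modulate the in-peak expectation:

- **surface contamination** multiplies the Mg ablation signal (not the
  background, and not Ca — Ca is the matrix) by `contamination_factor` for
  the first `contamination_duration` seconds of ablation (0–3 s). This
  emulates adsorbed trace-element contamination on the outer test surface.
- **Mg banding**: one sinusoidal cycle of fractional amplitude β over the
  ablation (phase 0), emulating the alternating high/low-Mg bands laid down
  across a chamber wall. Real banding profiles are not strictly
  single-cycle sinusoids; the model only guarantees the envelope
  [(1−β), (1+β)] × plateau that the tests check.
- **drift**: both channels' sensitivities scale by 1 + rate·t/3600 with t
  the session clock, so the true ratio is drift-invariant but absolute
  sensitivities (and hence the RSF) move over a session.

Counting noise is Poisson on the expected counts per reading interval
(cps × Δt), drawn independently per reading and converted back to cps —
standard ICP-MS counting statistics. `noise="none"` returns the closed-form
expectation bit-exactly. All randomness flows through explicit seeds or a
caller-supplied generator; there is no global random state.

### Count-rate defaults

The source measurements publish no count-rate magnitudes, so the defaults
are a package choice made once: Mg sensitivity 0.1 and Ca sensitivity
1.5 cps per µg/g, backgrounds 10 and 500 cps. They were chosen so that pure
counting statistics put the replicate precision (1 RSD) of simulated MACS-3
analyses in the low-single-digit-percent range typical of carbonate
reference-material replicates (measured at ~0.5–1.6% over 10 replicates,
seed-dependent). A consequence of these deliberately scaled-down
sensitivities is that the Mg limit of detection, expressed in
concentration units, is orders of magnitude above the sub-µg/g LODs of a
real sector-field instrument; the LOD estimator itself (blank mean + 3×SD)
is the standard one, only its scale differs. The synthetic generator also
omits plasma physics, mass bias, detector dead time, spikes from
inclusions, and the ⁴⁴Ca²⁺ charge-state efficiency (absorbed into the RSF
by construction), so passing tests demonstrate the correctness of the
reduction arithmetic and its statistical behaviour under counting noise —
not robustness to every artefact of real ablation profiles.

## Reduction

Pulses are segmented by averaging readings inside each peak window; the
ablation onset comes from acquisition metadata when available, otherwise
from the first reading where Ca exceeds the provisional blank mean + 5×SD
(Ca is the matrix channel and always far above blank). The per-isotope
background is the mean over the blank window (default: the whole
pre-ablation interval; at least 3 readings), subtracted from every pulse;
blank SDs are retained for the LOD.

Rejection order is fixed and deliberate:

1. **contamination trim** — pulses starting within `contamination_trim`
   seconds of ablation onset (default 3 s, the conservative upper bound of
   the 1–3 s window in which surface contamination is observed) are
   dropped regardless of their values: deterministic and conservative,
   rather than adaptive detection;
2. **minimum count rates** — background-corrected Mg < 50 cps or
   Ca < 500 cps (defaults, configurable) drops a pulse;
3. **outliers** — on the surviving per-pulse ratios,
   |r − median| > k·1.4826·MAD (default k = 3; an SD-based rule is
   available). When the MAD is zero (more than half the pulses identical,
   essentially only in noise-free data) the rule degenerates to flagging
   any deviation beyond float round-off, which keeps the
   single-spike-among-identical-pulses case well defined.

Fewer than 5 retained pulses marks the spot failed; failed spots propagate
as `qc="failed"` results rather than silently averaging. Ratios are formed
per pulse (one integrated peak = one "scan").

## Quantification

The three-step internal-standard scheme: the apparent concentration is
C_IS · R_ik · (A_k/A_i) · (M_EL/M_IS) with CIAAW abundances (²⁵Mg 0.1000,
⁴⁴Ca 0.02086) and atomic masses (24.305, 40.078 g/mol); the RSF is the
apparent Mg of a MACS-3 spot (quantified with MACS-3's own Ca, 376,900
µg/g, as internal standard) divided by the certified 1756 µg/g; unknowns
divide by the RSF. Sample C_IS defaults to 400,400 µg/g Ca (stoichiometric
calcite, ~40% m/m), configurable. Two closures pin the arithmetic: the
calibrant quantified against its own RSF returns exactly 1756 µg/g (and
7.683 mmol/mol), and any common instrument bias in the simulated
sensitivities cancels exactly.

RSF over a session is linearly interpolated between bracketing standards
(clamped beyond the first/last standard), with a nearest-standard option.
Under a linear differential drift, a sample midway between brackets is
recovered without bias by linear interpolation — the property that
motivated the default.

Per-spot values: each retained pulse's ratio is converted to Mg/Ca
individually; the spot value is their mean and the reported 1σ ("Error")
their n−1 standard deviation. QC: Mg/Ca > 20 mmol/mol is rejected from all
downstream statistics; values outside the typical 1–6 mmol/mol range but
≤ 20 pass with a warning.

## Temperature calibration

Mg/Ca = B·exp(A·T), with the *G. ruber* defaults B = 0.38 mmol/mol and
A = 0.09 /°C. (The source text prints the two constants against swapped
letters; 0.38 must be the pre-exponential — the opposite assignment gives
>100 mmol/mol at 20 °C, far outside the observed 1–6 mmol/mol range.)
Fitting is OLS of ln(Mg/Ca) on T: the slope estimates A, exp(intercept)
estimates B (SE by the delta method), and the quoted sensitivity is
100 × slope % per °C — the small-slope approximation of
100×(e^slope − 1), matching how such sensitivities are conventionally
quoted alongside ln-scale regressions. Inverse-variance weighting by the
supplied 1σ (propagated to the log scale) is available but not the
default, since the provenance analyses state no weighting; temperature
uncertainty is not modelled (none is published). Because back-calculated
temperature is an affine function of ln(Mg/Ca), correlations of calculated
versus measured temperature equal the ln(Mg/Ca)–temperature correlations
exactly; the tests assert this invariance.

## Chamber statistics

SD uses n−1 everywhere; all p-values are two-sided; no multiple-testing
correction (none is applied in the provenance analyses). The F-test takes
larger variance over smaller with p = 2×(upper tail), capped at 1. The
t-test runs from raw data or from (mean, SD, n) summaries with identical
results; `mode="auto"` pools variances unless the F-test rejects equality
at α = 0.05, then switches to Welch–Satterthwaite. Pearson significance
uses t = r√((n−2)/(1−r²)) on n−2 df, with missing pairs dropped.
Implementation p-values route through scipy distributions; the test suite
checks them against direct numerical integration of hand-written t and F
densities to 1e-8.

## Station table and reproduction

The packaged station table holds the ten station/cast rows of chamber-mean
Mg/Ca ± 1σ with SST, mixed-layer and in-situ temperatures; the missing-value
tokens `n.a.`/`n.app.` parse to NaN, depth intervals accept hyphen or
en-dash (a single bongonet depth becomes a zero-width interval). The
reproduction run fits ln-linear regressions for the F-1 and F-2 chambers
against all three temperature measures (in-situ regressions use the 7
complete rows), back-calculates temperatures with the default constants,
correlates them with measured temperatures, and runs the chamber test
battery on the published per-specimen group summaries (F0: 2.71 ± 0.99,
n = 17; F-1: 3.74 ± 0.58, n = 16; F-2: 3.79 ± 1.00, n = 17), concluding
F-1 ≈ F-2 and both ≠ F0. The published per-specimen headline statistics
(the r = 0.83 F-1–SST correlation, the few-percent sensitivities) were
computed on per-specimen data not contained in the station means; the
station-mean regressions give r = 0.68 and ~9%/°C for F-1 vs SST, and the
report annotates every such row rather than pretending to reproduce the
per-specimen numbers.

## Problem sizes and numerical choices

Monte-Carlo checks use ensembles sized for stable assertions at modest
cost: 50–100 spots per condition for noise-robustness and SE-scaling
(3-point log-log slope over pulse counts 30/60/120 against the −1/2 law),
200 replicates × 50 pairs for calibration parameter recovery, 1000 random
cases for the statistics-oracle equivalence. Noise-free closures are
asserted to 1e-9 relative or tighter; forward/inverse temperature
round-trips to 1e-12. Degenerate inputs fail loudly: empty blank windows,
unidentifiable ablation onset, zero-variance temperature, n < 2 groups and
non-positive ratios all raise with the offending field named.

## Shape of the API

The one genuinely model-like component — the exponential calibration — is
exposed in the statsmodels idiom (`MgCaCalibration(...).fit()` →
`CalibrationFitResults` with estimates, SEs, diagnostics and `summary()`);
the signal-processing stages, which are deterministic transformations
rather than fitted models, keep a functional pipeline API with typed
configuration and result dataclasses.
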