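"""Internal-standard + relative-sensitivity-factor (RSF) quantification.

Converts background-corrected ²⁵Mg⁺/⁴⁴Ca²⁺ intensity ratios into Mg
concentrations and molar Mg/Ca via the standard three-step scheme used in
carbonate LA-ICP-MS:

  C_uncorr = C_IS · R_ik · (A_k / A_i) · (M_EL / M_IS)     (apparent conc.)
  RSF      = C_uncorr(standard) / C_true(standard)         (instrument bias)
  C_El     = C_uncorr / RSF                                (calibrated conc.)

where C_IS is the internal-standard (Ca) concentration of the unknown, A the
isotopic abundances, M the atomic masses, and the RSF is measured on
bracketing spots of the MACS-3 carbonate reference material. Also provides
the blank-based limit of detection (mean + 3 SD), replicate precision
(1 RSD), and the Mg/Ca plausibility QC filter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np

from .acquisition import PulseTrain
from .reduction import RatioSeries, ReductionConfig, reduce_spot

__all__ = [
    "QuantificationConstants",
    "ReferenceValues",
    "MACS3",
    "RSFModel",
    "SpotResult",
    "LODResult",
    "uncorrected_concentration",
    "compute_rsf",
    "correct_concentration",
    "mass_to_molar_ratio",
    "limit_of_detection",
    "replicate_precision",
    "qc_filter",
    "quantify_spot",
    "standard_rsf",
    "quantify_session",
    "QCWarning",
]


class QCWarning(UserWarning):
    """Raised (as a warning) for quantified values outside the typical range."""


@dataclass(frozen=True)
class QuantificationConstants:
    """Constants entering the internal-standard equation.

    Defaults: ²⁵Mg analyte (abundance 0.1000) against the ⁴⁴Ca internal
    standard (abundance 0.02086, measured as the doubly charged ion — the
    charge state affects acquisition only, its efficiency is absorbed into
    the RSF), CIAAW atomic masses, and a calcite internal-standard Ca
    concentration of 400,400 µg/g (stoichiometric CaCO₃, ~40% m/m).
    """

    abundance_i: float = 0.1000       # A_i, ²⁵Mg
    abundance_k: float = 0.02086      # A_k, ⁴⁴Ca
    mass_el: float = 24.305           # M_EL, Mg g/mol
    mass_is: float = 40.078           # M_IS, Ca g/mol
    c_is: float = 400_400.0           # C_IS, µg/g Ca in the unknown

    def __post_init__(self) -> None:
        if not (0 < self.abundance_i <= 1 and 0 < self.abundance_k <= 1):
            raise ValueError("isotopic abundances must be in (0, 1]")
        if self.mass_el <= 0 or self.mass_is <= 0:
            raise ValueError("atomic masses must be > 0")
        if self.c_is <= 0:
            raise ValueError("c_is must be > 0")


@dataclass(frozen=True)
class ReferenceValues:
    """Certified composition of the calibration reference material."""

    name: str = "MACS-3"
    c_mg_true: float = 1756.0         # µg/g
    c_ca_true: float = 376_900.0      # µg/g (37.69% m/m)

    def __post_init__(self) -> None:
        if self.c_mg_true <= 0 or self.c_ca_true <= 0:
            raise ValueError("reference concentrations must be > 0")


MACS3 = ReferenceValues()


def uncorrected_concentration(r_ik: float | np.ndarray,
                              constants: QuantificationConstants | None = None
                              ) -> float | np.ndarray:
    """Apparent analyte concentration (µg/g) from an intensity ratio."""
    constants = constants or QuantificationConstants()
    r = np.asarray(r_ik, dtype=float)
    if np.any(r < 0):
        raise ValueError("intensity ratio r_ik must be >= 0")
    out = (constants.c_is * r * (constants.abundance_k / constants.abundance_i)
           * (constants.mass_el / constants.mass_is))
    return float(out) if np.isscalar(r_ik) else out


def compute_rsf(c_uncorr_standard: float,
                reference: ReferenceValues = MACS3) -> float:
    """Relative sensitivity factor from a standard spot's apparent Mg."""
    if c_uncorr_standard <= 0:
        raise ValueError("uncorrected standard concentration must be > 0")
    return c_uncorr_standard / reference.c_mg_true


def correct_concentration(c_uncorr: float | np.ndarray,
                          rsf: float) -> float | np.ndarray:
    """Calibrated concentration: apparent concentration divided by the RSF."""
    if rsf <= 0:
        raise ValueError("rsf must be > 0")
    out = np.asarray(c_uncorr, dtype=float) / rsf
    return float(out) if np.isscalar(c_uncorr) else out


def mass_to_molar_ratio(c_mg: float | np.ndarray, c_ca: float | np.ndarray,
                        constants: QuantificationConstants | None = None
                        ) -> float | np.ndarray:
    """Mg/Ca molar ratio in mmol/mol from mass concentrations in µg/g."""
    constants = constants or QuantificationConstants()
    mg = np.asarray(c_mg, dtype=float)
    ca = np.asarray(c_ca, dtype=float)
    if np.any(mg <= 0) or np.any(ca <= 0):
        raise ValueError("concentrations must be > 0")
    out = 1000.0 * (mg / constants.mass_el) / (ca / constants.mass_is)
    scalar = np.isscalar(c_mg) and np.isscalar(c_ca)
    return float(out) if scalar else out


@dataclass(frozen=True)
class LODResult:
    """Blank-based limit of detection: blank mean + 3 × blank SD."""

    blank_mean: float
    blank_sd: float
    lod: float


def limit_of_detection(blank_readings: Sequence[float]) -> LODResult:
    """LOD from gas-blank readings (mean + 3 SD, SD with n−1)."""
    x = np.asarray(blank_readings, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 blank readings for an LOD")
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    return LODResult(blank_mean=mean, blank_sd=sd, lod=mean + 3.0 * sd)


def replicate_precision(values: Sequence[float]) -> float:
    """Replicate precision as 1 RSD in percent: 100 × SD / mean."""
    x = np.asarray(values, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 replicate values")
    mean = float(np.mean(x))
    if mean <= 0:
        raise ValueError("mean of replicates must be > 0")
    return 100.0 * float(np.std(x, ddof=1)) / mean


#: Mg/Ca above this (mmol/mol) is geochemically implausible for foram calcite.
QC_REJECT_MMOLMOL = 20.0
#: Typical Mg/Ca range for G. ruber chamber calcite.
QC_TYPICAL_RANGE = (1.0, 6.0)


def qc_filter(mgca_mmolmol: float) -> Literal["pass", "rejected_gt20"]:
    """Plausibility QC on a quantified Mg/Ca value.

    Values above 20 mmol/mol are rejected outright (excluded from downstream
    statistics); values outside the typical 1–6 mmol/mol range but ≤ 20 pass
    with a :class:`QCWarning`.
    """
    if mgca_mmolmol > QC_REJECT_MMOLMOL:
        return "rejected_gt20"
    lo, hi = QC_TYPICAL_RANGE
    if not (lo <= mgca_mmolmol <= hi):
        warnings.warn(
            f"Mg/Ca {mgca_mmolmol:.2f} mmol/mol outside the typical "
            f"{lo:g}-{hi:g} mmol/mol range", QCWarning, stacklevel=2)
    return "pass"


@dataclass(frozen=True)
class RSFModel:
    """RSF as a function of acquisition time, from bracketing standards.

    ``interpolation='linear'`` interpolates between bracketing standard
    spots (clamped to the nearest standard beyond the session edges);
    ``'nearest'`` uses the closest standard in time.
    """

    bracket_times: np.ndarray
    rsf_values: np.ndarray
    interpolation: Literal["linear", "nearest"] = "linear"

    def __post_init__(self) -> None:
        object.__setattr__(self, "bracket_times",
                           np.asarray(self.bracket_times, dtype=float))
        object.__setattr__(self, "rsf_values",
                           np.asarray(self.rsf_values, dtype=float))
        if len(self.bracket_times) != len(self.rsf_values):
            raise ValueError("bracket_times and rsf_values lengths differ")
        if len(self.bracket_times) == 0:
            raise ValueError("need at least one standard spot")
        if np.any(np.diff(self.bracket_times) <= 0):
            raise ValueError("bracket_times must be strictly increasing")
        if np.any(self.rsf_values <= 0):
            raise ValueError("rsf values must be > 0")
        if self.interpolation not in ("linear", "nearest"):
            raise ValueError("interpolation must be 'linear' or 'nearest'")

    def rsf_at(self, t: float) -> float:
        tt, vv = self.bracket_times, self.rsf_values
        if self.interpolation == "nearest":
            return float(vv[np.argmin(np.abs(tt - t))])
        return float(np.interp(t, tt, vv))


@dataclass
class SpotResult:
    """Calibrated per-spot product.

    ``sigma1`` is the standard deviation (n−1) of the retained per-pulse
    Mg/Ca values — the 'Error' column of the deposited per-spot tables.
    ``lod_mg`` is the Mg limit of detection expressed in µg/g via the spot's
    own sensitivity.
    """

    spot_id: str
    c_mg: float                   # µg/g
    mgca_mmolmol: float
    sigma1: float
    n_retained: int
    lod_mg: float
    qc: Literal["pass", "rejected_gt20", "failed"]
    rsf: float
    acquired_at_s: float = 0.0


def quantify_spot(series: RatioSeries, rsf: float,
                  constants: QuantificationConstants | None = None,
                  acquired_at_s: float = 0.0) -> SpotResult:
    """Quantify one reduced spot against an RSF.

    Per-pulse ratios are converted individually to Mg/Ca; the spot value is
    their mean and ``sigma1`` their SD, so the spot uncertainty reflects the
    per-pulse scatter.
    """
    constants = constants or QuantificationConstants()
    if series.failed:
        return SpotResult(spot_id=series.spot_id, c_mg=np.nan,
                          mgca_mmolmol=np.nan, sigma1=np.nan,
                          n_retained=series.n_retained, lod_mg=np.nan,
                          qc="failed", rsf=rsf, acquired_at_s=acquired_at_s)

    ratios = series.retained_ratios
    c_uncorr = uncorrected_concentration(ratios, constants)
    c_mg_pulses = correct_concentration(c_uncorr, rsf)
    mgca_pulses = mass_to_molar_ratio(c_mg_pulses, constants.c_is, constants)
    c_mg = float(np.mean(c_mg_pulses))
    mgca = float(np.mean(mgca_pulses))
    sigma1 = float(np.std(mgca_pulses, ddof=1)) if len(mgca_pulses) > 1 else 0.0

    # Mg LOD in concentration units: blank (mean + 3 SD, cps) scaled by the
    # spot's own µg/g-per-cps response (c_mg corresponds to the mean
    # background-corrected Mg intensity carried on the ratio series).
    bg = series.background
    lod_cps = bg.mg_mean + 3.0 * bg.mg_sd
    if np.isfinite(series.mean_mg_cps) and series.mean_mg_cps > 0:
        lod_mg = lod_cps * c_mg / series.mean_mg_cps
    else:
        lod_mg = np.nan

    qc = qc_filter(mgca)
    return SpotResult(spot_id=series.spot_id, c_mg=c_mg, mgca_mmolmol=mgca,
                      sigma1=sigma1, n_retained=series.n_retained,
                      lod_mg=lod_mg, qc=qc, rsf=rsf,
                      acquired_at_s=acquired_at_s)


def standard_rsf(series: RatioSeries,
                 reference: ReferenceValues = MACS3,
                 constants: QuantificationConstants | None = None) -> float:
    """RSF from a reduced standard spot (its own Ca as internal standard)."""
    constants = constants or QuantificationConstants()
    std_constants = QuantificationConstants(
        abundance_i=constants.abundance_i, abundance_k=constants.abundance_k,
        mass_el=constants.mass_el, mass_is=constants.mass_is,
        c_is=reference.c_ca_true)
    c_uncorr = uncorrected_concentration(series.mean_ratio, std_constants)
    return compute_rsf(c_uncorr, reference)


def quantify_session(trains: Sequence[PulseTrain],
                     reduction_config: ReductionConfig | None = None,
                     constants: QuantificationConstants | None = None,
                     reference: ReferenceValues = MACS3,
                     interpolation: Literal["linear", "nearest"] = "linear",
                     ) -> tuple[list[SpotResult], RSFModel]:
    """Reduce and quantify a whole session of spots.

    Standard spots (``target == 'standard'``) define the RSF-versus-time
    model; each sample spot is quantified against the RSF interpolated to its
    acquisition time. Returns the sample results (in acquisition order) and
    the fitted :class:`RSFModel`.
    """
    constants = constants or QuantificationConstants()
    reduction_config = reduction_config or ReductionConfig()

    reduced: list[tuple[PulseTrain, RatioSeries]] = []
    std_times: list[float] = []
    std_rsfs: list[float] = []
    for train in trains:
        series = reduce_spot(train, reduction_config)
        reduced.append((train, series))
        if train.target == "standard" and not series.failed:
            std_times.append(train.acquired_at_s)
            std_rsfs.append(standard_rsf(series, reference, constants))

    if not std_times:
        raise ValueError("session has no usable standard spots")
    rsf_model = RSFModel(bracket_times=np.array(std_times),
                         rsf_values=np.array(std_rsfs),
                         interpolation=interpolation)

    results: list[SpotResult] = []
    for train, series in reduced:
        if train.target != "sample":
            continue
        rsf = rsf_model.rsf_at(train.acquired_at_s)
        results.append(quantify_spot(series, rsf, constants,
                                     acquired_at_s=train.acquired_at_s))
    return results, rsf_model
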