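"""Exponential Mg/Ca–temperature calibration.

The proxy relationship is Mg/Ca = B·exp(A·T), with Mg/Ca in mmol/mol and T
in °C. For *G. ruber* the canonical Dekens/Anand constants are B = 0.38
mmol/mol and A = 0.09 /°C; the forward and inverse conversions and an
ln-linear least-squares fitter live here.

Fitting follows the statsmodels model/results idiom: build an
:class:`MgCaCalibration` model from (T, Mg/Ca) pairs, call :meth:`fit`, and
read estimates, standard errors and diagnostics off the returned
:class:`CalibrationFitResults` (or print ``summary()``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "CalibrationParams",
    "DEKENS_ANAND",
    "temperature_to_mgca",
    "mgca_to_temperature",
    "MgCaCalibration",
    "CalibrationFitResults",
    "fit_exponential_calibration",
    "calibration_registry",
]


@dataclass(frozen=True)
class CalibrationParams:
    """Constants of one exponential calibration Mg/Ca = B·exp(A·T)."""

    pre_exponential: float = 0.38   # B, mmol/mol
    exponent: float = 0.09          # A, per °C
    label: str = "Dekens et al. 2002 / Anand et al. 2003 (G. ruber)"

    def __post_init__(self) -> None:
        if self.pre_exponential <= 0:
            raise ValueError("pre_exponential must be > 0")
        if self.exponent <= 0:
            raise ValueError("exponent must be > 0")


DEKENS_ANAND = CalibrationParams()


def temperature_to_mgca(temperature_c: float | np.ndarray,
                        params: CalibrationParams = DEKENS_ANAND
                        ) -> float | np.ndarray:
    """Predicted Mg/Ca (mmol/mol) at a calcification temperature (°C)."""
    t = np.asarray(temperature_c, dtype=float)
    out = params.pre_exponential * np.exp(params.exponent * t)
    return float(out) if np.isscalar(temperature_c) else out


def mgca_to_temperature(mgca_mmolmol: float | np.ndarray,
                        params: CalibrationParams = DEKENS_ANAND
                        ) -> float | np.ndarray:
    """Back-calculated temperature (°C); exact inverse of the forward map."""
    m = np.asarray(mgca_mmolmol, dtype=float)
    if np.any(m <= 0):
        raise ValueError("mgca must be > 0")
    out = np.log(m / params.pre_exponential) / params.exponent
    return float(out) if np.isscalar(mgca_mmolmol) else out


class MgCaCalibration:
    """Exponential calibration model for (temperature, Mg/Ca) pairs.

    Fitting is ordinary least squares of ln(Mg/Ca) on T; with
    ``weighted=True`` the fit is inverse-variance weighted using the
    supplied 1σ uncertainties propagated onto the log scale (σ_ln ≈ σ/Mg/Ca).

    Parameters
    ----------
    temperature_c, mgca_mmolmol : array-like
        Paired observations; pairs with a missing entry are dropped.
    sigma : array-like, optional
        1σ uncertainties of the Mg/Ca values (mmol/mol).
    label : str
        Carried onto the fitted parameters.
    """

    def __init__(self, temperature_c: Sequence[float],
                 mgca_mmolmol: Sequence[float],
                 sigma: Optional[Sequence[float]] = None,
                 label: str = "fitted"):
        t = np.asarray(temperature_c, dtype=float)
        m = np.asarray(mgca_mmolmol, dtype=float)
        s = None if sigma is None else np.asarray(sigma, dtype=float)
        if len(t) != len(m):
            raise ValueError("temperature and mgca lengths differ")
        keep = np.isfinite(t) & np.isfinite(m)
        if s is not None:
            if len(s) != len(m):
                raise ValueError("sigma length differs from mgca")
            keep &= np.isfinite(s)
        t, m = t[keep], m[keep]
        s = None if s is None else s[keep]
        if len(t) < 3:
            raise ValueError("need at least 3 complete (T, Mg/Ca) pairs")
        if np.any(m <= 0):
            raise ValueError("mgca must be > 0")
        if np.ptp(t) == 0:
            raise ValueError("temperature has zero variance")
        self.temperature_c = t
        self.mgca_mmolmol = m
        self.sigma = s
        self.label = label

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, temperature: str, mgca: str,
                       sigma: Optional[str] = None,
                       label: str = "fitted") -> "MgCaCalibration":
        s = df[sigma].to_numpy() if sigma is not None else None
        return cls(df[temperature].to_numpy(), df[mgca].to_numpy(),
                   sigma=s, label=label)

    def fit(self, weighted: bool = False) -> "CalibrationFitResults":
        y = np.log(self.mgca_mmolmol)
        X = sm.add_constant(self.temperature_c)
        if weighted:
            if self.sigma is None:
                raise ValueError("weighted fit requires sigma")
            sigma_ln = self.sigma / self.mgca_mmolmol
            res = sm.WLS(y, X, weights=1.0 / sigma_ln**2).fit()
        else:
            res = sm.OLS(y, X).fit()
        return CalibrationFitResults(self, res)


class CalibrationFitResults:
    """Estimates and diagnostics of one fitted exponential calibration.

    Attributes
    ----------
    exponent, exponent_se : float
        Slope A of ln(Mg/Ca) vs T (per °C) and its standard error.
    pre_exponential, pre_exponential_se : float
        exp(intercept) in mmol/mol; SE by the delta method.
    sensitivity_pct_per_degc, sensitivity_se : float
        100 × slope (± 100 × slope SE): percent Mg/Ca change per 1 °C.
    r, p : float
        Pearson correlation of ln(Mg/Ca) with T and its two-sided p-value
        (identical to the slope's t-test p-value).
    n : int
        Pairs used.
    """

    def __init__(self, model: MgCaCalibration, sm_results):
        self.model = model
        self._sm = sm_results
        intercept, slope = sm_results.params
        intercept_se, slope_se = sm_results.bse
        self.exponent = float(slope)
        self.exponent_se = float(slope_se)
        self.pre_exponential = float(np.exp(intercept))
        self.pre_exponential_se = float(np.exp(intercept) * intercept_se)
        self.sensitivity_pct_per_degc = 100.0 * self.exponent
        self.sensitivity_se = 100.0 * self.exponent_se
        self.r = float(np.sign(slope) * np.sqrt(sm_results.rsquared))
        self.p = float(sm_results.pvalues[1])
        self.n = int(sm_results.nobs)
        self.resid = np.asarray(sm_results.resid)

    @property
    def params(self) -> CalibrationParams:
        """Fitted constants as reusable :class:`CalibrationParams`."""
        return CalibrationParams(pre_exponential=self.pre_exponential,
                                 exponent=self.exponent,
                                 label=self.model.label)

    def predict(self, temperature_c: float | np.ndarray) -> float | np.ndarray:
        return temperature_to_mgca(temperature_c, self.params)

    def summary(self) -> str:
        lines = [
            f"Exponential Mg/Ca calibration: {self.model.label}",
            f"  Mg/Ca = B exp(A T), ln-linear least squares, n = {self.n}",
            f"  A (exponent)        = {self.exponent:.4f} "
            f"± {self.exponent_se:.4f} /degC",
            f"  B (pre-exponential) = {self.pre_exponential:.3f} "
            f"± {self.pre_exponential_se:.3f} mmol/mol",
            f"  sensitivity         = {self.sensitivity_pct_per_degc:.1f} "
            f"± {self.sensitivity_se:.1f} % per degC",
            f"  r = {self.r:.3f}, p = {self.p:.4g}",
        ]
        return "\n".join(lines)


def fit_exponential_calibration(
        pairs: Sequence[tuple], label: str = "fitted",
        weighted: bool = False) -> CalibrationFitResults:
    """Fit from (T, Mg/Ca) or (T, Mg/Ca, 1σ) tuples (functional wrapper)."""
    pairs = list(pairs)
    t = [p[0] for p in pairs]
    m = [p[1] for p in pairs]
    s = [p[2] for p in pairs] if pairs and len(pairs[0]) > 2 else None
    return MgCaCalibration(t, m, sigma=s, label=label).fit(weighted=weighted)


def calibration_registry(entries: Sequence[CalibrationParams],
                         t_grid: Sequence[float]) -> pd.DataFrame:
    """Tabulate Mg/Ca(T) for several calibrations over a temperature grid.

    Ships only the Dekens/Anand defaults plus fits produced in-session;
    third-party calibration constants are supplied by the caller.
    """
    entries = list(entries)
    if not entries:
        raise ValueError("registry needs at least one calibration")
    t = np.asarray(list(t_grid), dtype=float)
    data = {"temperature_c": t}
    for e in entries:
        data[e.label] = temperature_to_mgca(t, e)
    return pd.DataFrame(data)
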