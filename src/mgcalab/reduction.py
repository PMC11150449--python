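"""Transient-signal reduction for pulse-resolved LA-ICP-MS spots.

Turns a raw :class:`~mgcalab.acquisition.PulseTrain` into a per-pulse,
background-corrected ²⁵Mg⁺/⁴⁴Ca²⁺ intensity-ratio series with contamination,
minimum-count-rate and outlier rejection. The rejection order is fixed:
early-ablation contamination trim, then minimum count rates, then ratio
outliers among the survivors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .acquisition import AcquisitionSettings, PulseTrain

__all__ = [
    "ReductionConfig",
    "BackgroundStats",
    "PulseSignals",
    "RatioSeries",
    "segment_pulses",
    "subtract_background",
    "apply_rejections",
    "reduce_spot",
]

#: 1/Φ⁻¹(3/4): scales the median absolute deviation to a Gaussian σ.
MAD_TO_SIGMA = 1.4826

#: A spot with fewer retained pulses than this is marked failed.
MIN_RETAINED = 5


@dataclass(frozen=True)
class ReductionConfig:
    """Knobs of the reduction routine.

    ``contamination_trim`` discards the first seconds of ablation where
    surface contamination inflates trace-element signals (1–3 s is typical;
    the default is the conservative upper bound). Minimum count rates drop
    pulses too weak to quantify. The outlier rule flags pulses whose ratio
    deviates from the series median (MAD rule) or mean (SD rule) by more than
    ``outlier_k`` robust/classic standard deviations.
    """

    blank_window: Optional[tuple[float, float]] = None  # default: full blank
    contamination_trim: float = 3.0     # seconds after ablation onset
    min_mg_cps: float = 50.0            # background-corrected threshold
    min_ca_cps: float = 500.0
    outlier_rule: str = "mad_k"         # 'mad_k' or 'sd_k'
    outlier_k: float = 3.0

    def __post_init__(self) -> None:
        if self.contamination_trim < 0:
            raise ValueError("contamination_trim must be >= 0")
        if self.outlier_k <= 0:
            raise ValueError("outlier_k must be > 0")
        if self.outlier_rule not in ("mad_k", "sd_k"):
            raise ValueError("outlier_rule must be 'mad_k' or 'sd_k'")
        if self.blank_window is not None:
            lo, hi = self.blank_window
            if not (0 <= lo < hi):
                raise ValueError("blank_window must satisfy 0 <= start < end")


@dataclass(frozen=True)
class BackgroundStats:
    """Gas-blank mean and SD per channel (inputs to background
    subtraction and the limit of detection)."""

    mg_mean: float
    mg_sd: float
    ca_mean: float
    ca_sd: float
    n_readings: int


@dataclass
class PulseSignals:
    """Per-pulse integrated (peak-averaged) intensities for one spot."""

    spot_id: str
    pulse_index: np.ndarray
    pulse_start_s: np.ndarray  # seconds after ablation onset
    mg_cps: np.ndarray
    ca_cps: np.ndarray
    ablation_start_s: float
    background: Optional[BackgroundStats] = None  # set after subtraction


@dataclass
class RatioSeries:
    """Reduced per-pulse ratio series with rejection flags.

    ``r_ik`` is the background-corrected ²⁵Mg⁺/⁴⁴Ca²⁺ intensity ratio per
    pulse (NaN where the Ca intensity is non-positive). ``rejected`` holds
    ``None`` for retained pulses or one of ``'contamination'``,
    ``'below_min'``, ``'outlier'``.
    """

    spot_id: str
    pulse_index: np.ndarray
    r_ik: np.ndarray
    rejected: list[Optional[str]]
    background_mg: float
    background_ca: float
    background: BackgroundStats
    failed: bool = False
    #: mean background-corrected Mg intensity over retained pulses (cps);
    #: used downstream to express the Mg LOD in concentration units
    mean_mg_cps: float = float("nan")

    @property
    def retained(self) -> np.ndarray:
        return np.array([r is None for r in self.rejected])

    @property
    def n_retained(self) -> int:
        return int(self.retained.sum())

    @property
    def retained_ratios(self) -> np.ndarray:
        return self.r_ik[self.retained]

    @property
    def mean_ratio(self) -> float:
        return float(np.mean(self.retained_ratios))

    @property
    def sd_ratio(self) -> float:
        r = self.retained_ratios
        return float(np.std(r, ddof=1)) if len(r) > 1 else 0.0


def _detect_onset(train: PulseTrain) -> float:
    """Ablation onset from metadata if present, else the first reading where
    Ca exceeds blank mean + 5×blank SD (Ca is the matrix channel)."""
    if train.settings is not None and train.truth is not None:
        return train.settings.blank_duration
    # provisional blank: first quarter of the record
    n0 = max(3, len(train.times) // 4)
    mu = float(np.mean(train.ca44_cps[:n0]))
    sd = float(np.std(train.ca44_cps[:n0], ddof=1))
    thresh = mu + 5.0 * max(sd, 1e-12)
    above = np.nonzero(train.ca44_cps > thresh)[0]
    if len(above) == 0:
        raise ValueError(f"no detectable ablation onset in {train.spot_id}")
    return float(train.times[above[0]])


def segment_pulses(train: PulseTrain,
                   settings: AcquisitionSettings | None = None) -> PulseSignals:
    """Integrate the raw series into one Mg and Ca intensity per laser pulse.

    Readings falling inside each peak window (pulse start to pulse start +
    peak length) are averaged; washout readings are discarded. The number of
    pulses is ``floor(ablation_duration × pulse_rate)``.
    """
    settings = settings or train.settings or AcquisitionSettings()
    onset = _detect_onset(train)
    n_pulses = settings.n_pulses
    period = 1.0 / settings.pulse_rate

    starts = onset + np.arange(n_pulses) * period
    mg = np.empty(n_pulses)
    ca = np.empty(n_pulses)
    for i, t0 in enumerate(starts):
        in_peak = (train.times >= t0) & (train.times < t0 + settings.peak_length)
        if not np.any(in_peak):
            raise ValueError(
                f"pulse {i} of {train.spot_id} has no readings in its peak")
        mg[i] = np.mean(train.mg25_cps[in_peak])
        ca[i] = np.mean(train.ca44_cps[in_peak])

    return PulseSignals(spot_id=train.spot_id,
                        pulse_index=np.arange(n_pulses),
                        pulse_start_s=starts - onset,
                        mg_cps=mg, ca_cps=ca, ablation_start_s=onset)


def subtract_background(pulses: PulseSignals, train: PulseTrain,
                        config: ReductionConfig | None = None) -> PulseSignals:
    """Subtract the gas-blank mean from each pulse's intensities.

    The blank is averaged over ``config.blank_window`` (seconds since spot
    start; defaults to the whole pre-ablation interval). The blank mean and
    SD per channel are kept on the result for the limit-of-detection
    estimate.
    """
    config = config or ReductionConfig()
    lo, hi = config.blank_window or (0.0, pulses.ablation_start_s)
    if hi > pulses.ablation_start_s + 1e-9:
        raise ValueError("blank_window extends into the ablation interval")
    sel = (train.times >= lo) & (train.times < hi)
    n = int(sel.sum())
    if n < 3:
        raise ValueError(f"blank window [{lo}, {hi}) holds {n} readings; "
                         "need at least 3")
    bg = BackgroundStats(
        mg_mean=float(np.mean(train.mg25_cps[sel])),
        mg_sd=float(np.std(train.mg25_cps[sel], ddof=1)),
        ca_mean=float(np.mean(train.ca44_cps[sel])),
        ca_sd=float(np.std(train.ca44_cps[sel], ddof=1)),
        n_readings=n,
    )
    return PulseSignals(spot_id=pulses.spot_id,
                        pulse_index=pulses.pulse_index,
                        pulse_start_s=pulses.pulse_start_s,
                        mg_cps=pulses.mg_cps - bg.mg_mean,
                        ca_cps=pulses.ca_cps - bg.ca_mean,
                        ablation_start_s=pulses.ablation_start_s,
                        background=bg)


def apply_rejections(pulses: PulseSignals,
                     config: ReductionConfig | None = None) -> RatioSeries:
    """Flag contamination/low-count/outlier pulses and form the ratio series.

    Requires background-corrected pulses (run :func:`subtract_background`
    first). Fewer than five retained pulses marks the spot failed rather than
    silently averaging it.
    """
    config = config or ReductionConfig()
    if pulses.background is None:
        raise ValueError("apply_rejections needs background-corrected pulses")

    n = len(pulses.pulse_index)
    rejected: list[Optional[str]] = [None] * n

    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(pulses.ca_cps > 0, pulses.mg_cps / pulses.ca_cps, np.nan)

    # 1) early-ablation contamination trim
    for i in range(n):
        if pulses.pulse_start_s[i] < config.contamination_trim - 1e-12:
            rejected[i] = "contamination"
    # 2) minimum background-corrected count rates
    for i in range(n):
        if rejected[i] is None and (pulses.mg_cps[i] < config.min_mg_cps or
                                    pulses.ca_cps[i] < config.min_ca_cps):
            rejected[i] = "below_min"
    # 3) ratio outliers among the survivors
    surv = np.array([rej is None for rej in rejected])
    rs = r[surv]
    if len(rs) >= 3:
        if config.outlier_rule == "mad_k":
            center = np.median(rs)
            scale = MAD_TO_SIGMA * np.median(np.abs(rs - center))
        else:
            center = np.mean(rs)
            scale = np.std(rs, ddof=1)
        # a zero scale (over half the pulses identical) degenerates the rule
        # to "any deviation from the center", up to float round-off
        floor = abs(center) * 1e-12
        bad = np.abs(r - center) > max(config.outlier_k * scale, floor)
        for i in range(n):
            if surv[i] and bad[i]:
                rejected[i] = "outlier"

    series = RatioSeries(spot_id=pulses.spot_id,
                         pulse_index=pulses.pulse_index.copy(),
                         r_ik=r, rejected=rejected,
                         background_mg=pulses.background.mg_mean,
                         background_ca=pulses.background.ca_mean,
                         background=pulses.background)
    series.failed = series.n_retained < MIN_RETAINED
    if series.n_retained > 0:
        series.mean_mg_cps = float(np.mean(pulses.mg_cps[series.retained]))
    return series


def reduce_spot(train: PulseTrain,
                config: ReductionConfig | None = None,
                settings: AcquisitionSettings | None = None) -> RatioSeries:
    """Full reduction chain: segment → background-subtract → reject."""
    config = config or ReductionConfig()
    pulses = segment_pulses(train, settings)
    corrected = subtract_background(pulses, train, config)
    return apply_rejections(corrected, config)
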