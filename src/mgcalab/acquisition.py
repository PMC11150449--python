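"""Synthetic pulse-resolved LA-ICP-MS acquisition.

Generates count-rate time series (²⁵Mg⁺ and ⁴⁴Ca²⁺ channels) for laser spots
on a reference material or a foraminifer chamber, with known ground truth so
the downstream reduction and quantification stages can be tested end to end.

The signal model is deliberately simple: a gas-blank baseline, then a train of
rectangular ablation peaks (one per laser pulse, separable because the peak is
shorter than the pulse period), with optional early-ablation surface
contamination on the Mg channel, sinusoidal within-wall Mg banding, slow
multiplicative sensitivity drift, and Poisson counting noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np

__all__ = [
    "AcquisitionSettings",
    "SignalScenario",
    "PulseTrain",
    "macs3_scenario",
    "simulate_spot",
    "simulate_session",
    "write_signal_csv",
    "read_signal_csv",
]

#: Molar masses used to convert a Mg/Ca molar ratio into mass concentrations.
MASS_MG = 24.305
MASS_CA = 40.078

#: MACS-3 pressed-powder carbonate reference material certified mass fractions.
MACS3_MG_UGG = 1756.0
MACS3_CA_UGG = 376_900.0


def _require(cond: bool, name: str, msg: str) -> None:
    if not cond:
        raise ValueError(f"invalid {name}: {msg}")


@dataclass(frozen=True)
class AcquisitionSettings:
    """Laser and data-acquisition parameters for one spot.

    Defaults follow a 45 µm spot ablated at 1 Hz and low fluence, ~0.9 s
    aerosol peaks with 1 s cell washout, a 20 s gas blank before ablation and
    10 readings per second.
    """

    pulse_rate: float = 1.0          # laser pulses per second
    peak_length: float = 0.9         # seconds of aerosol signal per pulse
    washout: float = 1.0             # seconds for the cell to clear
    spot_diameter: float = 45.0      # µm, metadata only
    fluence: float = 0.1             # J/cm², metadata only
    blank_duration: float = 20.0     # seconds of gas blank before ablation
    ablation_duration: float = 60.0  # seconds of ablation
    sampling_rate: float = 10.0      # detector readings per second

    def __post_init__(self) -> None:
        for name in ("pulse_rate", "peak_length", "washout", "spot_diameter",
                     "fluence", "blank_duration", "ablation_duration",
                     "sampling_rate"):
            _require(getattr(self, name) > 0, name, "must be > 0")
        _require(self.peak_length <= 1.0 / self.pulse_rate, "peak_length",
                 "peaks must not overlap (peak_length <= 1/pulse_rate)")

    @property
    def n_pulses(self) -> int:
        return math.floor(self.ablation_duration * self.pulse_rate)

    @property
    def total_duration(self) -> float:
        return self.blank_duration + self.ablation_duration

    def reading_times(self) -> np.ndarray:
        """Mid-interval reading timestamps over blank + ablation."""
        n = round(self.total_duration * self.sampling_rate)
        return (np.arange(n) + 0.5) / self.sampling_rate


@dataclass(frozen=True)
class SignalScenario:
    """Ground truth for one simulated spot.

    ``true_mgca`` is the molar Mg/Ca of the ablated calcite in mmol/mol;
    sensitivities convert µg/g concentrations into count rates; contamination
    multiplies the Mg ablation signal during the first seconds of ablation;
    banding modulates Mg sinusoidally across the wall; drift scales both
    channels' sensitivity with elapsed session time.
    """

    true_mgca: float                       # mmol/mol
    ca_mass_fraction: float = 0.4004       # g/g (stoichiometric calcite)
    mg_sensitivity: float = 0.1            # cps per µg/g
    ca_sensitivity: float = 1.5            # cps per µg/g
    background_mg: float = 10.0            # cps gas blank
    background_ca: float = 500.0           # cps gas blank
    contamination_duration: float = 0.0    # s after ablation start
    contamination_factor: float = 1.0      # multiplier on Mg signal (>= 1)
    banding_amplitude: float = 0.0         # fractional, in [0, 1)
    drift_rate: float = 0.0                # fractional sensitivity change / hour
    noise: Literal["none", "poisson"] = "none"
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        _require(self.true_mgca > 0, "true_mgca", "must be > 0")
        _require(0 < self.ca_mass_fraction <= 1, "ca_mass_fraction",
                 "must be in (0, 1]")
        _require(self.mg_sensitivity > 0, "mg_sensitivity", "must be > 0")
        _require(self.ca_sensitivity > 0, "ca_sensitivity", "must be > 0")
        _require(self.background_mg >= 0, "background_mg", "must be >= 0")
        _require(self.background_ca >= 0, "background_ca", "must be >= 0")
        _require(self.contamination_duration >= 0, "contamination_duration",
                 "must be >= 0")
        _require(self.contamination_factor >= 1, "contamination_factor",
                 "must be >= 1")
        _require(0 <= self.banding_amplitude < 1, "banding_amplitude",
                 "must be in [0, 1)")
        _require(self.noise in ("none", "poisson"), "noise",
                 "must be 'none' or 'poisson'")

    @property
    def c_ca(self) -> float:
        """True Ca concentration of the ablated material, µg/g."""
        return self.ca_mass_fraction * 1e6

    @property
    def c_mg(self) -> float:
        """True Mg concentration implied by ``true_mgca``, µg/g."""
        return self.true_mgca / 1000.0 * (MASS_MG / MASS_CA) * self.c_ca


def macs3_scenario(**overrides) -> SignalScenario:
    """Scenario whose ablated material matches MACS-3 certified values."""
    true_mgca = (MACS3_MG_UGG / MASS_MG) / (MACS3_CA_UGG / MASS_CA) * 1000.0
    params = dict(true_mgca=true_mgca, ca_mass_fraction=MACS3_CA_UGG / 1e6)
    params.update(overrides)
    return SignalScenario(**params)


@dataclass
class PulseTrain:
    """One spot's raw time series plus acquisition metadata."""

    spot_id: str
    target: Literal["standard", "sample", "blank"]
    times: np.ndarray         # seconds since spot start, strictly increasing
    mg25_cps: np.ndarray
    ca44_cps: np.ndarray
    settings: AcquisitionSettings = field(default_factory=AcquisitionSettings)
    truth: Optional[SignalScenario] = None
    acquired_at_s: float = 0.0  # seconds since session start

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.mg25_cps = np.asarray(self.mg25_cps, dtype=float)
        self.ca44_cps = np.asarray(self.ca44_cps, dtype=float)
        if not (len(self.times) == len(self.mg25_cps) == len(self.ca44_cps)):
            raise ValueError("invalid times/mg25_cps/ca44_cps: unequal lengths")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("invalid times: must be strictly increasing")
        if np.any(self.mg25_cps < 0) or np.any(self.ca44_cps < 0):
            raise ValueError("invalid count rates: must be >= 0")


def expected_cps(scenario: SignalScenario, settings: AcquisitionSettings,
                 times: np.ndarray, session_time_s: float = 0.0
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free expected count rates at the given reading times.

    Blank readings sit at the background levels; in-peak readings add
    sensitivity × concentration, with the contamination multiplier applied to
    Mg for ``t < contamination_duration`` after ablation onset, banding as one
    sinusoidal cycle over the ablation, and drift applied multiplicatively to
    both channels.
    """
    t = np.asarray(times, dtype=float)
    t_abl = t - settings.blank_duration
    in_ablation = (t_abl >= 0) & (t_abl < settings.ablation_duration)
    phase = np.mod(t_abl, 1.0 / settings.pulse_rate)
    in_peak = in_ablation & (phase < settings.peak_length)

    drift = 1.0 + scenario.drift_rate * (session_time_s + t) / 3600.0
    banding = 1.0 + scenario.banding_amplitude * np.sin(
        2.0 * np.pi * np.clip(t_abl, 0.0, None) / settings.ablation_duration)
    contam = np.where(in_peak & (t_abl < scenario.contamination_duration),
                      scenario.contamination_factor, 1.0)

    mg = scenario.background_mg + np.where(
        in_peak,
        scenario.mg_sensitivity * drift * scenario.c_mg * banding * contam,
        0.0)
    ca = scenario.background_ca + np.where(
        in_peak, scenario.ca_sensitivity * drift * scenario.c_ca, 0.0)
    return mg, ca


def simulate_spot(scenario: SignalScenario,
                  settings: AcquisitionSettings | None = None,
                  spot_id: str = "spot",
                  target: Literal["standard", "sample", "blank"] = "sample",
                  session_time_s: float = 0.0,
                  rng: Optional[np.random.Generator] = None) -> PulseTrain:
    """Simulate one laser spot.

    With ``noise='none'`` the closed-form expectation is returned exactly.
    With ``noise='poisson'`` each reading is an independent Poisson draw of
    the expected counts in one reading interval, converted back to cps; the
    draw is seeded from ``scenario.seed`` unless an explicit ``rng`` is given.
    """
    settings = settings or AcquisitionSettings()
    times = settings.reading_times()
    mg, ca = expected_cps(scenario, settings, times, session_time_s)

    if scenario.noise == "poisson":
        if rng is None:
            rng = np.random.default_rng(scenario.seed)
        dt = 1.0 / settings.sampling_rate
        mg = rng.poisson(mg * dt) / dt
        ca = rng.poisson(ca * dt) / dt

    return PulseTrain(spot_id=spot_id, target=target, times=times,
                      mg25_cps=mg, ca44_cps=ca, settings=settings,
                      truth=scenario, acquired_at_s=session_time_s)


# Idle time between consecutive spots (stage move, pre-ablation purge).
SPOT_SPACING_S = 20.0


def simulate_session(n_samples: int,
                     bracket_every: int,
                     scenarios: Sequence[SignalScenario],
                     standard_scenario: SignalScenario,
                     settings: AcquisitionSettings | None = None,
                     seed: Optional[int] = None) -> list[PulseTrain]:
    """Simulate a measurement session with bracketing standards.

    Standard spots are emitted at the session start and after every
    ``bracket_every`` sample spots (the paper-style bracketing is every 27–30
    samples, roughly two hours). Acquisition timestamps increase monotonically
    so sensitivity drift is expressible across the session.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if bracket_every < 1:
        raise ValueError("bracket_every must be >= 1")
    if len(scenarios) == 0:
        raise ValueError("scenarios must not be empty")
    if len(scenarios) == 1:
        scenarios = list(scenarios) * n_samples
    if len(scenarios) != n_samples:
        raise ValueError(
            f"need 1 or {n_samples} scenarios, got {len(scenarios)}")

    settings = settings or AcquisitionSettings()
    rng = np.random.default_rng(seed)
    period = settings.total_duration + SPOT_SPACING_S

    trains: list[PulseTrain] = []
    clock = 0.0
    n_std = 0

    def emit(scn: SignalScenario, target: str, label: str) -> None:
        nonlocal clock
        trains.append(simulate_spot(scn, settings, spot_id=label,
                                    target=target, session_time_s=clock,
                                    rng=rng))
        clock += period

    emit(standard_scenario, "standard", f"STD_{n_std:03d}")
    n_std += 1
    for i, scn in enumerate(scenarios):
        emit(scn, "sample", f"SMP_{i:03d}")
        if (i + 1) % bracket_every == 0:
            emit(standard_scenario, "standard", f"STD_{n_std:03d}")
            n_std += 1
    return trains


def write_signal_csv(train: PulseTrain, path: str | Path) -> None:
    """Write one spot as a raw-signal CSV with a commented metadata header."""
    path = Path(path)
    s = train.settings
    lines = [
        f"# spot_id={train.spot_id}, target={train.target}, "
        f"pulse_rate={s.pulse_rate}, peak_length={s.peak_length}, "
        f"washout={s.washout}, blank_duration={s.blank_duration}, "
        f"ablation_duration={s.ablation_duration}, "
        f"sampling_rate={s.sampling_rate}, spot_diameter={s.spot_diameter}, "
        f"fluence={s.fluence}, acquired_at_s={train.acquired_at_s}",
        "time_s,mg25_cps,ca44_cps",
    ]
    for t, mg, ca in zip(train.times, train.mg25_cps, train.ca44_cps):
        lines.append(f"{t:.6g},{mg:.10g},{ca:.10g}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")


def read_signal_csv(path: str | Path) -> PulseTrain:
    """Read a raw-signal CSV written by :func:`write_signal_csv`."""
    path = Path(path)
    meta: dict[str, str] = {}
    times, mg, ca = [], [], []
    with path.open(encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for item in line.lstrip("# ").split(","):
                    if "=" in item:
                        k, v = item.split("=", 1)
                        meta[k.strip()] = v.strip()
                continue
            if line.startswith("time_s"):
                continue
            a, b, c = line.split(",")
            times.append(float(a))
            mg.append(float(b))
            ca.append(float(c))
    settings = AcquisitionSettings(
        pulse_rate=float(meta.get("pulse_rate", 1.0)),
        peak_length=float(meta.get("peak_length", 0.9)),
        washout=float(meta.get("washout", 1.0)),
        blank_duration=float(meta.get("blank_duration", 20.0)),
        ablation_duration=float(meta.get("ablation_duration", 60.0)),
        sampling_rate=float(meta.get("sampling_rate", 10.0)),
        spot_diameter=float(meta.get("spot_diameter", 45.0)),
        fluence=float(meta.get("fluence", 0.1)),
    )
    return PulseTrain(spot_id=meta.get("spot_id", path.stem),
                      target=meta.get("target", "sample"),  # type: ignore[arg-type]
                      times=np.array(times), mg25_cps=np.array(mg),
                      ca44_cps=np.array(ca), settings=settings,
                      acquired_at_s=float(meta.get("acquired_at_s", 0.0)))
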