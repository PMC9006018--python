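"""Simulation and site configuration.

``SimConfig`` bundles everything the synthetic-data generator needs: the site
(coordinates, timezone), the season, the ambient-temperature forcing, the
nest thermal model (Newtonian cooling plus metabolic heat input), and the
whole-nest metabolic-rate night profile (arrival peak, torpor entry ramp,
maintenance plateau, pre-dawn arousal).

Defaults describe a mid-latitude colony breeding season with torpor depth
and timing set to the physiological magnitudes this package's detectors are
built around: a ~56% nocturnal metabolic reduction on torpor nights, entry
starting ~19 min after sunset, arousal completing ~45 min before sunrise,
and an occupied-nest warming of ~12 degC above ambient so that a 56% drop in
heat input pulls the nest-to-ambient difference below the 7 degC detection
criterion.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["SimConfig", "load_config", "save_config"]

#: iButton-style logger resolution (degC)
LOGGER_QUANTUM = 0.0625


@dataclass
class SimConfig:
    """Parameters of the coupled nest-temperature / gas-exchange simulator.

    Attributes
    ----------
    latitude, longitude : float
        Colony coordinates, decimal degrees.
    timezone_offset : float
        Civil UTC offset in hours (e.g. 2.0 for central-European summer time).
    season_start, season_end : datetime.date
        First and last night of the simulated season (nights keyed by sunset date).
    n_nests : int
        Number of simultaneously monitored nests.
    sample_interval : float
        Temperature-logger sampling interval, minutes.
    mr_sample_interval : float
        Gas-analyzer sampling interval, minutes (respirometers log much
        faster than nest loggers).
    ambient_mean, ambient_amplitude, ambient_noise_sd : float
        Diel ambient forcing: seasonal mean (degC), half peak-to-trough
        amplitude of the sinusoid (degC), and Gaussian sensor/weather noise SD.
    cold_day_prob, cold_day_shift : float
        Day-to-day mean shifts come from a two-component mixture: with
        probability ``cold_day_prob`` a day is "cold" and its mean is lowered
        by ``cold_day_shift`` degC (plus small everyday jitter).
    day_jitter_sd : float
        SD of the everyday day-mean jitter (degC).
    nest_warming_gamma : float
        Heat-input coefficient, degC per minute per unit of metabolic rate.
    cooling_lambda : float
        Newtonian cooling rate of the nest, per minute.
    sensor_noise_sd : float
        Nest-logger noise SD (degC); readings are also quantised to the
        0.0625 degC logger resolution.
    resting_mr : float
        Whole-group resting oxygen-consumption rate (ml O2 / min) with the
        full family at the nest.
    day_mr_factor : float
        Daytime metabolic input as a fraction of ``resting_mr``: the adults
        forage by day, so only the nestlings heat the nest until the
        arrival near sunset steps the input up to the full family level
        (which is why nest temperature rises in the early night).
    departure_offset : float
        Minutes after sunrise at which the adults leave and the metabolic
        input returns to the daytime level.
    torpid_fraction : float
        Fractional MR reduction depth on torpor nights, in [0, 1].
    nontorpor_fraction : float
        Optional shallow nocturnal reduction on non-torpor nights (default 0:
        non-torpor nights rest flat at ``resting_mr``).
    torpor_probability : float
        Per-nest-night torpor probability (marginal, when ``torpor_ta_slope`` is 0).
    torpor_ta_slope : float
        Logistic coupling of torpor odds to the day-mean ambient temperature
        (per degC below the seasonal mean; 0 disables the coupling).
    entry_delay : float
        Minutes after sunset at which the torpor entry ramp starts.
    entry_tau, arousal_tau : float
        Exponential ramp time constants (minutes) for entry and arousal.
    arousal_lead : float
        Minutes before sunrise by which arousal is complete.
    mr_noise_sd : float
        Additive Gaussian noise on the gas trace (same units as resting_mr).
    arrival_peak_height : float
        Arrival spike height as a multiple of resting_mr.
    arrival_offset : float
        Minutes of the adults' arrival (spike onset) relative to sunset;
        negative means before sunset. Adults return around dusk, so the
        default puts the feeding peak 20 min before sunset.
    arrival_decay_tau : float
        Decay time constant of the arrival spike (minutes); the spike is
        truncated to zero 30 min after arrival, back at the resting plateau.
    rer : float
        Respiratory exchange ratio used to derive the VCO2 channel.
    seed : int
        Root seed; every nest-night derives an independent substream from it.
    """

    latitude: float = 51.0411
    longitude: float = 7.8267
    timezone_offset: float = 2.0
    season_start: dt.date = dt.date(2017, 5, 1)
    season_end: dt.date = dt.date(2017, 7, 31)
    n_nests: int = 10
    sample_interval: float = 5.0
    mr_sample_interval: float = 1.0
    ambient_mean: float = 18.0
    ambient_amplitude: float = 3.5
    ambient_noise_sd: float = 0.3
    cold_day_prob: float = 0.2
    cold_day_shift: float = 5.0
    day_jitter_sd: float = 1.0
    nest_warming_gamma: float = 1.0 / 30.0
    cooling_lambda: float = 1.0 / 60.0
    sensor_noise_sd: float = 0.2
    resting_mr: float = 6.0
    day_mr_factor: float = 0.7
    departure_offset: float = 15.0
    torpid_fraction: float = 0.56
    nontorpor_fraction: float = 0.0
    torpor_probability: float = 0.03
    torpor_ta_slope: float = 0.0
    entry_delay: float = 19.0
    entry_tau: float = 25.0
    arousal_tau: float = 12.0
    arousal_lead: float = 45.0
    mr_noise_sd: float = 0.3
    arrival_peak_height: float = 2.0
    arrival_offset: float = -20.0
    arrival_decay_tau: float = 5.0
    rer: float = 0.85
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not 0.0 <= self.torpid_fraction <= 1.0:
            raise ValueError("torpid_fraction must be in [0, 1]")
        if not 0.0 <= self.nontorpor_fraction <= 1.0:
            raise ValueError("nontorpor_fraction must be in [0, 1]")
        if not 0.0 <= self.torpor_probability <= 1.0:
            raise ValueError("torpor_probability must be in [0, 1]")
        if self.sample_interval <= 0:
            raise ValueError("sample_interval must be > 0")
        if self.cooling_lambda <= 0:
            raise ValueError("cooling_lambda must be > 0")
        if self.nest_warming_gamma < 0:
            raise ValueError("nest_warming_gamma must be >= 0")
        for name in ("entry_tau", "arousal_tau", "arrival_decay_tau"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("ambient_noise_sd", "sensor_noise_sd", "mr_noise_sd", "day_jitter_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.resting_mr <= 0:
            raise ValueError("resting_mr must be > 0")
        if self.season_end < self.season_start:
            raise ValueError("season_end must not precede season_start")

    @property
    def tzinfo(self) -> dt.tzinfo:
        return dt.timezone(dt.timedelta(hours=self.timezone_offset))

    def replace(self, **kwargs) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["season_start"] = self.season_start.isoformat()
        d["season_end"] = self.season_end.isoformat()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        for key in ("season_start", "season_end"):
            if isinstance(d.get(key), str):
                d[key] = dt.date.fromisoformat(d[key])
        return cls(**d)


def load_config(path: str | Path) -> SimConfig:
    """Load a SimConfig from a YAML file."""
    with open(path) as fh:
        return SimConfig.from_dict(yaml.safe_load(fh) or {})


def save_config(config: SimConfig, path: str | Path) -> None:
    """Write a SimConfig to YAML."""
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
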