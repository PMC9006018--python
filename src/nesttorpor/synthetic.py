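"""Coupled nest-temperature / gas-exchange simulator with known ground truth.

The generator emulates the two signals the detection pipeline consumes:

* an **ambient** series at the colony — a diel temperature curve (minimum
  near dawn, maximum mid-afternoon) with day-to-day mean shifts drawn from
  a two-component mixture ("cold" vs ordinary days) plus sensor noise;
* a whole-nest **metabolic rate** (VO2) night profile — a steep arrival
  spike near sunset decaying to the resting plateau within 30 min, then on
  torpor nights an exponential entry ramp toward a reduced maintenance
  plateau and an exponential arousal ramp completing before sunrise;
* a **nest temperature** obtained by integrating a heat balance: Newtonian
  cooling toward ambient plus a heat input proportional to metabolic rate,

      T[k+1] = T[k] + dt * ( -lambda * (T[k] - Ta[k]) + gamma * MR[k] ),

  whose equilibrium under constant forcing is Ta + gamma*MR/lambda. The
  logger reading adds Gaussian sensor noise and quantises to the 0.0625 degC
  instrument resolution.

Torpor is simulated at the whole-nest level — one pooled MR signal per nest
family — matching how it is measured; no per-individual attribution is made.

All randomness flows from one root seed. Each consumer derives an
independent substream via ``numpy.random.SeedSequence`` spawn keys
(documented in :func:`substream`), so a single nest-night is reproducible in
isolation and two runs with the same config are byte-identical on disk.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import LOGGER_QUANTUM, SimConfig, save_config
from .io import GasTrace, TemperatureTrace, write_gas_csv, write_records, write_temperature_csv
from .solar import SunTimes, sun_times

__all__ = [
    "GroundTruth",
    "SeasonDataset",
    "substream",
    "simulate_ambient",
    "simulate_mr_night",
    "simulate_tnest_night",
    "simulate_season",
]

# spawn-key channels (first element of the spawn key)
_CH_AMBIENT_DAYS = 0
_CH_AMBIENT_NOISE = 1
_CH_NEST = 2  # (CH_NEST, nest_idx, night_idx, sub) — sub 0: torpor draw, 1: MR noise
_CH_SENSOR = 3  # (CH_SENSOR, nest_idx) — nest-logger noise
_CH_OCCUPANTS = 4

#: the arrival spike has returned to the resting plateau this many minutes
#: after arrival (hard truncation, so the plateau is exact beyond it)
SPIKE_SUPPORT_MIN = 30.0


def substream(seed: int, *key: int) -> np.random.Generator:
    """Independent generator for one simulation channel.

    ``key`` is a spawn key ``(channel, ...indices)``; identical (seed, key)
    pairs always yield the same stream, so any nest-night can be regenerated
    without simulating the rest of the season.
    """
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


@dataclass
class GroundTruth:
    """Generative truth for one nest-night.

    ``true_reduction_pct`` is the reduction the measurement definition would
    yield on the noise-free trace: 100*(ref - min)/ref with ref the
    noise-free VO2 30 min after the arrival peak and min the noise-free
    nocturnal minimum. ``true_drop_magnitude`` is the noise-free nest-
    temperature fall from torpor entry to the nocturnal minimum (absent for
    nights simulated without a temperature channel).
    """

    nest_id: str
    night_date: dt.date
    torpor: bool
    true_reduction_pct: float
    true_entry_time: dt.datetime | None = None
    true_arousal_onset: dt.datetime | None = None
    true_peak_time: dt.datetime | None = None
    occupants_present: int = 0
    true_drop_magnitude: float | None = None
    day_mean_ta: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.true_reduction_pct <= 100.0:
            raise ValueError("true_reduction_pct must be in [0, 100]")
        if self.torpor and self.true_reduction_pct <= 0.0:
            raise ValueError("torpor implies true_reduction_pct > 0")


# ---------------------------------------------------------------------------
# ambient forcing


def _diel_shape(hour: np.ndarray) -> np.ndarray:
    """Unit diel curve: -1 at 05:00 (near dawn), +1 at 15:00 (mid-afternoon)."""
    h = np.asarray(hour, dtype=float) % 24.0
    h = np.where(h < 5.0, h + 24.0, h)  # map to [5, 29)
    rising = h < 15.0
    out = np.empty_like(h)
    out[rising] = -np.cos(np.pi * (h[rising] - 5.0) / 10.0)
    out[~rising] = np.cos(np.pi * (h[~rising] - 15.0) / 14.0)
    return out


def day_mean_offsets(config: SimConfig, n_days: int, seed: int) -> np.ndarray:
    """Day-to-day shifts of the ambient mean (two-component cold/warm mixture)."""
    rng = substream(seed, _CH_AMBIENT_DAYS)
    cold = rng.random(n_days) < config.cold_day_prob
    jitter = rng.normal(0.0, config.day_jitter_sd, n_days)
    return jitter - np.where(cold, config.cold_day_shift, 0.0)


def simulate_ambient(
    config: SimConfig,
    n_days: int,
    seed: int | None = None,
    start_date: dt.date | None = None,
) -> TemperatureTrace:
    """Simulate the colony ambient-temperature logger for ``n_days`` days.

    The series runs from local midnight of ``start_date`` (default: the
    configured season start) at ``sample_interval`` spacing: a diel curve
    with minimum near dawn and maximum mid-afternoon, a per-day mean shift
    (cold/warm mixture), and Gaussian noise. Deterministic given the seed.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    if seed is None:
        seed = config.seed
    if start_date is None:
        start_date = config.season_start
    per_day = int(round(24 * 60 / config.sample_interval))
    n = per_day * n_days
    start = dt.datetime.combine(start_date, dt.time(0), tzinfo=config.tzinfo)
    index = pd.date_range(start, periods=n, freq=pd.Timedelta(minutes=config.sample_interval))
    minutes = np.arange(n) * config.sample_interval
    hours = (minutes / 60.0) % 24.0
    offsets = day_mean_offsets(config, n_days, seed)
    # day means anchor at local noon and interpolate linearly in between, so
    # the ambient mean drifts smoothly instead of stepping at midnight
    anchors = (np.arange(n_days) + 0.5) * 24 * 60
    smooth_offset = np.interp(minutes, anchors, offsets)
    base = config.ambient_mean + smooth_offset + config.ambient_amplitude * _diel_shape(hours)
    noise = substream(seed, _CH_AMBIENT_NOISE).normal(0.0, 1.0, n) * config.ambient_noise_sd
    series = pd.Series(base + noise, index=index)
    return TemperatureTrace(series, source_id="ambient", role="ambient")


# ---------------------------------------------------------------------------
# metabolic-rate night profile


def _night_profile(
    minutes_rel_sunset: np.ndarray, night_minutes: float, config: SimConfig, depth: float
) -> tuple[np.ndarray, float | None, float | None]:
    """Noise-free whole-nest VO2 at the given minutes relative to sunset.

    Returns (values, entry_min, arousal_onset_min); the phase times are in
    minutes relative to sunset, or None when depth == 0.
    """
    m = np.asarray(minutes_rel_sunset, dtype=float)
    r = config.resting_mr
    level = np.full_like(m, r)
    entry_min: float | None = None
    arousal_onset_min: float | None = None
    if depth > 0.0:
        floor = r * (1.0 - depth)
        entry_min = config.entry_delay
        complete = night_minutes - config.arousal_lead
        arousal_onset_min = complete - 5.0 * config.arousal_tau
        if arousal_onset_min <= entry_min:
            raise ValueError("night too short for the configured torpor phases")
        in_entry = (m >= entry_min) & (m < arousal_onset_min)
        if config.entry_tau > 0:
            level[in_entry] = floor + (r - floor) * np.exp(
                -(m[in_entry] - entry_min) / config.entry_tau
            )
            start_level = floor + (r - floor) * np.exp(
                -(arousal_onset_min - entry_min) / config.entry_tau
            )
        else:
            level[in_entry] = floor
            start_level = floor
        in_arousal = m >= arousal_onset_min
        if config.arousal_tau > 0:
            level[in_arousal] = r - (r - start_level) * np.exp(
                -(m[in_arousal] - arousal_onset_min) / config.arousal_tau
            )
        # arousal_tau == 0: instant return to resting (level already r)
    # arrival spike, truncated to its 30-min support
    rel = m - config.arrival_offset
    in_spike = (rel >= 0.0) & (rel < SPIKE_SUPPORT_MIN)
    if config.arrival_peak_height > 1.0 and in_spike.any():
        amp = (config.arrival_peak_height - 1.0) * r
        if config.arrival_decay_tau > 0:
            level[in_spike] += amp * np.exp(-rel[in_spike] / config.arrival_decay_tau)
        else:
            level[in_spike] += np.where(rel[in_spike] == 0.0, amp, 0.0)
    # adults forage by day: before arrival and after the morning departure
    # only the nestlings heat the nest
    day_level = config.day_mr_factor * r
    level[m < config.arrival_offset] = day_level
    level[m >= night_minutes + config.departure_offset] = day_level
    return level, entry_min, arousal_onset_min


def _noise_free_reduction(
    times_min: np.ndarray, values: np.ndarray, config: SimConfig, night_minutes: float
) -> float:
    """Reduction % the measurement definition yields on a noise-free profile."""
    ref_min = config.arrival_offset + 30.0
    i_ref = int(np.argmin(np.abs(times_min - ref_min)))
    ref = values[i_ref]
    in_night = (times_min > ref_min) & (times_min <= night_minutes)
    if not in_night.any() or ref <= 0:
        return 0.0
    low = float(values[in_night].min())
    return max(0.0, (ref - low) * 100.0 / ref)


def simulate_mr_night(
    config: SimConfig,
    torpor: bool,
    sun: SunTimes,
    seed: int | None = None,
    nest_id: str = "sim",
    occupants: int = 4,
    depth: float | None = None,
) -> tuple[GasTrace, GroundTruth]:
    """Simulate one nest-box night of gas exchange.

    The trace runs from 3 h before sunset to 1 h after the next sunrise at
    the configured sampling interval. On torpor nights the noise-free
    reduction depth is ``config.torpid_fraction`` (override with ``depth``);
    on other nights ``config.nontorpor_fraction`` (default 0: a flat resting
    plateau). VCO2 is derived from VO2 at the configured respiratory
    exchange ratio.
    """
    if sun.next_sunrise <= sun.sunset:
        raise ValueError("invalid sun times: sunrise must follow sunset")
    if seed is None:
        seed = config.seed
    if depth is None:
        depth = config.torpid_fraction if torpor else config.nontorpor_fraction
    if torpor and depth <= 0.0:
        raise ValueError("torpor night requires a positive reduction depth")

    step = pd.Timedelta(minutes=config.mr_sample_interval)
    start = sun.sunset - pd.Timedelta(minutes=180)
    end = sun.next_sunrise + pd.Timedelta(minutes=60)
    index = pd.date_range(start, end, freq=step)
    m = (index - sun.sunset).total_seconds().to_numpy() / 60.0
    night_minutes = (sun.next_sunrise - sun.sunset).total_seconds() / 60.0

    clean, entry_min, arousal_min = _night_profile(m, night_minutes, config, depth)
    rng = substream(seed, _CH_NEST, 0, 0, 1)
    vo2 = np.clip(clean + rng.normal(0.0, config.mr_noise_sd, clean.size), 0.0, None)
    frame = pd.DataFrame({"vo2": vo2, "vco2": config.rer * vo2}, index=index)
    trace = GasTrace(frame, nest_id=nest_id, session_date=sun.date)

    truth = GroundTruth(
        nest_id=nest_id,
        night_date=sun.date,
        torpor=torpor,
        true_reduction_pct=_noise_free_reduction(m, clean, config, night_minutes),
        true_entry_time=(
            sun.sunset + pd.Timedelta(minutes=entry_min) if entry_min is not None else None
        ),
        true_arousal_onset=(
            sun.sunset + pd.Timedelta(minutes=arousal_min) if arousal_min is not None else None
        ),
        true_peak_time=sun.sunset + pd.Timedelta(minutes=config.arrival_offset),
        occupants_present=occupants,
    )
    return trace, truth


# ---------------------------------------------------------------------------
# nest-temperature heat balance


def _integrate_heat_balance(
    ta: np.ndarray, mr: np.ndarray, t0: float, dt_min: float, lam: float, gamma: float
) -> np.ndarray:
    """Forward-Euler integration of the nest heat balance (returns T at each sample)."""
    t = np.empty_like(ta)
    t[0] = t0
    for k in range(len(ta) - 1):
        t[k + 1] = t[k] + dt_min * (-lam * (t[k] - ta[k]) + gamma * mr[k])
    return t


def simulate_tnest_night(
    config: SimConfig,
    mr_trace: GasTrace,
    ambient: TemperatureTrace,
    t0: float,
    seed: int | None = None,
    nest_id: str | None = None,
) -> TemperatureTrace:
    """Integrate the nest heat balance over one night and read it like a logger.

    ``mr_trace`` and ``ambient`` must share the same time base. The physical
    temperature follows the Euler recurrence documented in the module
    docstring; the returned trace adds sensor noise and quantises to the
    0.0625 degC logger resolution. Set ``config.sensor_noise_sd`` to 0 for
    the noise-free physical series (still quantised by the logger model —
    pass through :func:`physical_tnest` to avoid quantisation entirely).
    """
    if len(mr_trace.frame) != len(ambient.series) or not mr_trace.frame.index.equals(
        ambient.series.index
    ):
        raise ValueError("mr_trace and ambient must share the same time base")
    if seed is None:
        seed = config.seed
    t = _integrate_heat_balance(
        ambient.series.to_numpy(),
        mr_trace.vo2.to_numpy(),
        t0,
        config.sample_interval,
        config.cooling_lambda,
        config.nest_warming_gamma,
    )
    rng = substream(seed, _CH_SENSOR, 0)
    noisy = t + rng.normal(0.0, config.sensor_noise_sd, t.size)
    quantised = np.round(noisy / LOGGER_QUANTUM) * LOGGER_QUANTUM
    series = pd.Series(quantised, index=ambient.series.index)
    return TemperatureTrace(series, source_id=nest_id or mr_trace.nest_id, role="nest")


def physical_tnest(
    config: SimConfig, mr: np.ndarray, ta: np.ndarray, t0: float
) -> np.ndarray:
    """Noise-free, unquantised heat-balance temperature (same recurrence)."""
    return _integrate_heat_balance(
        np.asarray(ta, float),
        np.asarray(mr, float),
        t0,
        config.sample_interval,
        config.cooling_lambda,
        config.nest_warming_gamma,
    )


# ---------------------------------------------------------------------------
# whole-season generation


@dataclass
class SeasonDataset:
    """Everything one simulated season produces.

    ``nests`` maps nest id to the full-season logger trace; ``gas`` maps
    (nest_id, night_date) to that night's gas trace; ``truth`` holds one
    GroundTruth row per nest-night; ``sun`` maps night date to its sun times.
    """

    config: SimConfig
    ambient: TemperatureTrace
    nests: dict[str, TemperatureTrace]
    gas: dict[tuple[str, dt.date], GasTrace]
    truth: list[GroundTruth]
    sun: dict[dt.date, SunTimes]

    @property
    def nights(self) -> list[dt.date]:
        return sorted(self.sun)

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(g) for g in self.truth])

    def write(self, outdir: str | Path) -> None:
        """Write the dataset: CSV traces, a TSV ground-truth manifest, YAML config."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        save_config(self.config, outdir / "config.yaml")
        write_temperature_csv(self.ambient, outdir / "ambient.csv")
        for nest_id in sorted(self.nests):
            write_temperature_csv(self.nests[nest_id], outdir / f"nest_{nest_id}.csv")
        for nest_id, date in sorted(self.gas):
            write_gas_csv(
                self.gas[(nest_id, date)], outdir / f"gas_{nest_id}_{date.isoformat()}.csv"
            )
        write_records(self.truth, outdir / "ground_truth.tsv", cls=GroundTruth)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_season(config: SimConfig) -> SeasonDataset:
    """Simulate a full monitoring season for ``config.n_nests`` nests.

    Every night between ``season_start`` and ``season_end`` (inclusive, keyed
    by sunset date) draws torpor independently per nest with
    ``torpor_probability``; when ``torpor_ta_slope`` > 0, colder days carry
    higher odds through a logistic link centred on the marginal probability.
    Nest temperature is one continuous integration over the whole season
    (daytime metabolic input stays at the resting level), so thermal history
    carries across nights exactly as a real logger would record it.
    """
    if config.n_nests <= 0:
        raise ValueError("n_nests must be >= 1")
    nights = [
        config.season_start + dt.timedelta(days=k)
        for k in range((config.season_end - config.season_start).days + 1)
    ]
    n_days = len(nights) + 2  # cover past the last sunrise
    ambient = simulate_ambient(config, n_days)
    amb = ambient.series
    index = amb.index
    offsets = day_mean_offsets(config, n_days, config.seed)
    day_means = config.ambient_mean + offsets

    sun = {d: sun_times(config.latitude, config.longitude, d, config.timezone_offset) for d in nights}

    occ_rng = substream(config.seed, _CH_OCCUPANTS)
    occupants = {k: 2 + int(occ_rng.integers(1, 5)) for k in range(config.n_nests)}

    # torpor probability per night (shared ambient day effect, logistic coupling)
    p0 = np.clip(config.torpor_probability, 1e-9, 1 - 1e-9)
    logit0 = np.log(p0 / (1 - p0))
    night_p = {
        d: float(
            _sigmoid(logit0 + config.torpor_ta_slope * (config.ambient_mean - day_means[i]))
        )
        for i, d in enumerate(nights)
    }

    nests: dict[str, TemperatureTrace] = {}
    gas: dict[tuple[str, dt.date], GasTrace] = {}
    truth: list[GroundTruth] = []
    ta = amb.to_numpy()

    for nest_idx in range(config.n_nests):
        nest_id = f"N{nest_idx + 1:03d}"
        mr = np.full(len(index), config.day_mr_factor * config.resting_mr)
        night_meta = []
        for night_idx, d in enumerate(nights):
            s = sun[d]
            draw_rng = substream(config.seed, _CH_NEST, nest_idx, night_idx, 0)
            torpor = bool(draw_rng.random() < night_p[d])
            depth = config.torpid_fraction if torpor else config.nontorpor_fraction
            start = s.sunset - pd.Timedelta(minutes=180)
            end = s.next_sunrise + pd.Timedelta(minutes=60)
            mask = (index >= start) & (index <= end)
            m_rel = (index[mask] - s.sunset).total_seconds().to_numpy() / 60.0
            night_minutes = (s.next_sunrise - s.sunset).total_seconds() / 60.0
            clean, entry_min, arousal_min = _night_profile(m_rel, night_minutes, config, depth)
            mr[mask] = clean
            night_meta.append((night_idx, d, s, torpor, depth, mask, clean, entry_min, arousal_min))

        t_phys = physical_tnest(
            config,
            mr,
            ta,
            float(
                ta[0]
                + config.nest_warming_gamma
                * config.day_mr_factor
                * config.resting_mr
                / config.cooling_lambda
            ),
        )
        sensor = substream(config.seed, _CH_SENSOR, nest_idx).normal(
            0.0, config.sensor_noise_sd, len(index)
        )
        logged = np.round((t_phys + sensor) / LOGGER_QUANTUM) * LOGGER_QUANTUM
        nests[nest_id] = TemperatureTrace(
            pd.Series(logged, index=index), source_id=nest_id, role="nest"
        )

        for night_idx, d, s, torpor, depth, mask, clean, entry_min, arousal_min in night_meta:
            # gas traces live on the analyzer's own (finer) grid
            g_index = pd.date_range(
                s.sunset - pd.Timedelta(minutes=180),
                s.next_sunrise + pd.Timedelta(minutes=60),
                freq=pd.Timedelta(minutes=config.mr_sample_interval),
            )
            g_rel = (g_index - s.sunset).total_seconds().to_numpy() / 60.0
            night_minutes = (s.next_sunrise - s.sunset).total_seconds() / 60.0
            g_clean, _, _ = _night_profile(g_rel, night_minutes, config, depth)
            noise = substream(config.seed, _CH_NEST, nest_idx, night_idx, 1).normal(
                0.0, config.mr_noise_sd, g_clean.size
            )
            vo2 = np.clip(g_clean + noise, 0.0, None)
            frame = pd.DataFrame({"vo2": vo2, "vco2": config.rer * vo2}, index=g_index)
            gas[(nest_id, d)] = GasTrace(frame, nest_id=nest_id, session_date=d)

            m_rel = (index[mask] - s.sunset).total_seconds().to_numpy() / 60.0
            red = _noise_free_reduction(g_rel, g_clean, config, night_minutes)
            drop_mag = None
            if depth > 0 and entry_min is not None:
                seg = t_phys[mask]
                after_entry = m_rel >= entry_min
                if after_entry.any():
                    i0 = int(np.argmax(after_entry))
                    drop_mag = float(seg[i0] - seg[after_entry].min())
            truth.append(
                GroundTruth(
                    nest_id=nest_id,
                    night_date=d,
                    torpor=torpor,
                    true_reduction_pct=red,
                    true_entry_time=(
                        s.sunset + pd.Timedelta(minutes=entry_min)
                        if entry_min is not None
                        else None
                    ),
                    true_arousal_onset=(
                        s.sunset + pd.Timedelta(minutes=arousal_min)
                        if arousal_min is not None
                        else None
                    ),
                    true_peak_time=s.sunset + pd.Timedelta(minutes=config.arrival_offset),
                    occupants_present=occupants[nest_idx],
                    true_drop_magnitude=drop_mag,
                    day_mean_ta=float(day_means[night_idx]),
                )
            )

    return SeasonDataset(
        config=config, ambient=ambient, nests=nests, gas=gas, truth=truth, sun=sun
    )
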