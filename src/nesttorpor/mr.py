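"""Night-by-night scoring of whole-nest gas-exchange traces.

Each instrumented nest-box night is reduced to a :class:`NightScore`:

* the arrival peak — the adults' return near sunset shows as a steep VO2
  spike; its time anchors everything else;
* ``mr_ref`` — the (smoothed) VO2 exactly 30 min after the peak, when the
  family has settled into resting;
* ``mr_min`` — the lowest (smoothed) nocturnal VO2 between then and sunrise;
* the relative reduction, (MR_ref - MR_min) * 100 / MR_ref;
* bout timing: onset of sustained decline vs sunset, arousal completion vs
  sunrise, bout duration.

Torpor classification follows a conservative guideline: a reduction of at
least ~50%, corroborated by a substantial nest-temperature drop for the
same nest-night when temperature data exist. All quantities describe the
pooled nest family — no per-individual attribution is attempted.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .io import GasTrace
from .solar import SunTimes
from .tnest import DropEvent

__all__ = [
    "NightScore",
    "MRParams",
    "detect_arrival_peak",
    "score_night",
    "classify_torpor",
    "link_tnest",
    "respiratory_quotient",
    "reduction_pct",
    "TORPOR_THRESHOLD_DEFAULT",
    "TORPOR_THRESHOLD_REPLICATION",
]

#: conservative torpor guideline: reduction of about half the resting rate
TORPOR_THRESHOLD_DEFAULT = 50.0
#: replication preset admitting the boundary nights just under 50%
TORPOR_THRESHOLD_REPLICATION = 48.0


def reduction_pct(mr_ref: float, mr_min: float) -> float:
    """Relative metabolic reduction, (MR_ref - MR_min) * 100 / MR_ref."""
    if mr_ref <= 0:
        raise ValueError("mr_ref must be > 0")
    return (mr_ref - mr_min) * 100.0 / mr_ref


@dataclass
class NightScore:
    """One night's metabolic analysis for one nest-box."""

    nest_id: str
    night_date: dt.date
    peak_time: dt.datetime | None
    mr_ref: float
    mr_min: float
    mr_min_time: dt.datetime | None
    reduction_pct: float
    torpor: bool = False
    onset_time: dt.datetime | None = None
    onset_vs_sunset: float | None = None  # minutes, positive = after sunset
    arousal_end_time: dt.datetime | None = None
    end_vs_sunrise: float | None = None  # minutes, positive = before sunrise
    bout_duration: float | None = None  # hours
    tnest_drop: float | None = None  # degC, from the linked DropEvent
    tnest_lag: float | None = None  # minutes, T_nest decline start - onset_time
    rer_mean: float | None = None
    no_arrival: bool = False
    arousal_open: bool = False  # no recovery before trace end
    mr_only: bool = False  # classified without a temperature channel

    def __post_init__(self) -> None:
        if self.mr_min <= self.mr_ref and not 0.0 <= self.reduction_pct <= 100.0:
            raise ValueError("reduction_pct must be in [0, 100] when mr_min <= mr_ref")
        if self.bout_duration is not None and self.bout_duration < 0:
            raise ValueError("bout_duration must be >= 0")


@dataclass
class MRParams:
    """Tunables of the night-scoring stage.

    ``mr_ref`` is read off a smoothed trace (default 15-min window): the
    reference is nominally a point value, but point noise would corrupt
    every downstream percentage. Onset and arousal use a sustained-decline
    convention — VO2 below ``onset_factor`` x mr_ref for at least
    ``persistence`` minutes, tracked back to the decline's local start —
    because bout endpoints need an explicit rule to be comparable across
    nights.
    """

    smooth_window: float = 15.0  # minutes, for mr_ref and onset tracking
    min_smooth_window: float = 45.0  # minutes, for the nocturnal-minimum search
    peak_smooth_window: float = 5.0  # minutes, for arrival-peak detection
    search_window: float = 90.0  # minutes around sunset
    peak_factor: float = 1.3  # peak must top the pre-window median by this
    fallback_after_sunset: float = 30.0  # minutes, when no arrival is found
    onset_factor: float = 0.9  # of mr_ref
    persistence: float = 30.0  # minutes
    ref_offset: float = 30.0  # minutes after the peak
    vo2_floor: float = 1e-9  # below this, samples are excluded from RER


def _smooth(series: pd.Series, window_min: float) -> pd.Series:
    if window_min <= 0:
        return series.astype(float)
    return series.rolling(
        pd.Timedelta(minutes=window_min), center=True, min_periods=1
    ).mean()


class CoverageError(ValueError):
    """The trace does not cover the required analysis window."""


def detect_arrival_peak(
    trace: GasTrace, sun: SunTimes, params: MRParams | None = None
) -> tuple[dt.datetime | None, bool]:
    """Locate the arrival spike near sunset.

    Returns ``(peak_time, no_arrival)``. The peak is the maximum of the
    5-min moving-average VO2 within +/-90 min of sunset, accepted only if it
    tops the pre-window median by the configured factor (default 1.3x);
    otherwise ``(None, True)`` and scoring falls back to a fixed reference
    time (sunset + 30 min). Ties go to the earlier sample.
    """
    p = params or MRParams()
    lo = sun.sunset - pd.Timedelta(minutes=p.search_window)
    hi = sun.sunset + pd.Timedelta(minutes=p.search_window)
    idx = trace.frame.index
    if idx[0] > lo or idx[-1] < hi:
        raise CoverageError(
            f"trace {trace.nest_id}/{trace.session_date} does not cover the "
            f"arrival search window [{lo}, {hi}]"
        )
    smooth = _smooth(trace.vo2, p.peak_smooth_window)
    window = smooth[(idx >= lo) & (idx <= hi)]
    pre = smooth[idx < lo]
    baseline = float(pre.median()) if len(pre) else float(smooth.median())
    peak_val = float(window.max())
    if baseline > 0 and peak_val < p.peak_factor * baseline:
        return None, True
    peak_time = window.idxmax()  # idxmax returns the first (earliest) maximum
    return peak_time.to_pydatetime(), False


def score_night(
    trace: GasTrace,
    sun: SunTimes,
    peak_time: dt.datetime | None = None,
    no_arrival: bool = False,
    params: MRParams | None = None,
) -> NightScore:
    """Score one nest-box night from its gas trace.

    ``mr_ref`` is the smoothed VO2 at peak + 30 min; ``mr_min`` the smoothed
    minimum in (peak + 30 min, sunrise); the reduction follows
    (MR_ref - MR_min) * 100 / MR_ref. Onset is the first sustained decline
    (below 0.9 x mr_ref for >= 30 min) tracked back to its local start;
    arousal ends at the first recovery above 0.9 x mr_ref after the minimum
    (or the trace end, flagged ``arousal_open``).
    """
    p = params or MRParams()
    if peak_time is None and not no_arrival:
        peak_time, no_arrival = detect_arrival_peak(trace, sun, p)
    if peak_time is None:
        peak_time = (
            pd.Timestamp(sun.sunset) + pd.Timedelta(minutes=p.fallback_after_sunset)
        ).to_pydatetime()

    idx = trace.frame.index
    ref_time = pd.Timestamp(peak_time) + pd.Timedelta(minutes=p.ref_offset)
    if idx[-1] < ref_time or idx[-1] < sun.next_sunrise - pd.Timedelta(minutes=p.smooth_window):
        raise CoverageError(
            f"trace {trace.nest_id}/{trace.session_date} must span peak + "
            f"{p.ref_offset:.0f} min through sunrise"
        )
    smooth = _smooth(trace.vo2, p.smooth_window)
    i_ref = int(np.argmin(np.abs(idx.asi8 - ref_time.value)))
    mr_ref = float(smooth.iloc[i_ref])
    if mr_ref <= 0:
        raise ValueError(f"non-positive mr_ref in {trace.nest_id}/{trace.session_date}")

    # the nocturnal minimum is read off a wider smoothing window: the raw
    # minimum of a noisy trace is biased low, and the maintenance plateau
    # lasts hours, so heavier averaging costs nothing. Smoothing is applied
    # to the night-truncated trace so windows near sunrise cannot mix in the
    # post-departure morning decline.
    night_trace = trace.vo2[idx <= sun.next_sunrise]
    min_smooth = _smooth(night_trace, p.min_smooth_window)
    night = min_smooth[min_smooth.index > ref_time]
    if night.empty:
        raise CoverageError("no samples between reference time and sunrise")
    mr_min = float(night.min())
    mr_min_time = night.idxmin()
    red = reduction_pct(mr_ref, mr_min)
    red = float(np.clip(red, 0.0, 100.0))

    # onset: first sustained excursion below onset_factor * mr_ref,
    # tracked back to the local start of the decline
    sm = smooth.to_numpy()
    below = (
        (sm < p.onset_factor * mr_ref)
        & np.asarray(idx > ref_time)
        & np.asarray(idx <= sun.next_sunrise)
    )
    need = max(1, int(round(p.persistence / max(trace.interval, 1e-9))))
    onset_idx: int | None = None
    run = 0
    for k, flag in enumerate(below):
        run = run + 1 if flag else 0
        if run >= need:
            onset_idx = k - need + 1
            break
    onset_time = None
    onset_vs_sunset = None
    if onset_idx is not None:
        j = onset_idx
        tol = 0.02 * mr_ref
        while j > 0 and idx[j - 1] > ref_time and sm[j - 1] >= sm[j] - tol and sm[j - 1] < mr_ref:
            j -= 1
        onset_time = idx[j].to_pydatetime()
        onset_vs_sunset = (idx[j] - pd.Timestamp(sun.sunset)).total_seconds() / 60.0

    # arousal completion: first recovery above onset_factor * mr_ref after the minimum
    arousal_end_time = None
    end_vs_sunrise = None
    arousal_open = False
    if onset_time is not None:
        # on shallow nights noise can place the smoothed minimum before the
        # first sustained decline; recovery is only meaningful after both
        t0 = max(pd.Timestamp(mr_min_time), pd.Timestamp(onset_time))
        recovered = (sm >= p.onset_factor * mr_ref) & np.asarray(idx > t0)
        if recovered.any():
            k = int(np.argmax(recovered))
            arousal_end_time = idx[k].to_pydatetime()
        else:
            arousal_end_time = idx[-1].to_pydatetime()
            arousal_open = True
        end_vs_sunrise = (
            pd.Timestamp(sun.next_sunrise) - pd.Timestamp(arousal_end_time)
        ).total_seconds() / 60.0

    bout = None
    if onset_time is not None and arousal_end_time is not None:
        bout = (pd.Timestamp(arousal_end_time) - pd.Timestamp(onset_time)).total_seconds() / 3600.0

    rer = None
    if trace.has_vco2:
        rer = respiratory_quotient(trace, (idx[0], idx[-1]), params=p)

    return NightScore(
        nest_id=trace.nest_id,
        night_date=sun.date,
        peak_time=None if no_arrival else peak_time,
        mr_ref=mr_ref,
        mr_min=mr_min,
        mr_min_time=mr_min_time.to_pydatetime(),
        reduction_pct=red,
        onset_time=onset_time,
        onset_vs_sunset=onset_vs_sunset,
        arousal_end_time=arousal_end_time,
        end_vs_sunrise=end_vs_sunrise,
        bout_duration=bout,
        rer_mean=rer,
        no_arrival=no_arrival,
        arousal_open=arousal_open,
    )


def classify_torpor(
    score: NightScore,
    threshold: float = TORPOR_THRESHOLD_DEFAULT,
    has_tnest: bool = True,
) -> bool:
    """Apply the conservative torpor guideline to a scored night.

    Torpor requires a reduction of at least ``threshold`` percent (>= rule
    at the boundary) and, when nest-temperature data exist for the night, a
    linked substantial drop. Without a temperature channel the call is
    MR-only and the score is flagged accordingly.
    """
    meets = score.reduction_pct >= threshold
    if has_tnest:
        return bool(meets and score.tnest_drop is not None)
    return bool(meets)


def link_tnest(score: NightScore, events: list[DropEvent]) -> NightScore:
    """Attach the same-night nest-temperature drop, if any, to a night score.

    The lag is the drop's decline start minus the metabolic onset, in
    minutes (positive: the nest cools after the metabolic decline begins —
    thermal inertia). Multiple same-night events indicate a deduplication
    failure upstream and raise.
    """
    matches = [
        ev
        for ev in events
        if ev.nest_id == score.nest_id and ev.night_date == score.night_date
    ]
    if len(matches) > 1:
        raise ValueError(
            f"{len(matches)} drop events for {score.nest_id}/{score.night_date}; "
            "expected nightly-deduplicated input"
        )
    if not matches:
        return replace(score, mr_only=True)
    ev = matches[0]
    lag = None
    if score.onset_time is not None:
        lag = (pd.Timestamp(ev.start_time) - pd.Timestamp(score.onset_time)).total_seconds() / 60.0
    return replace(score, tnest_drop=ev.magnitude, tnest_lag=lag, mr_only=False)


def respiratory_quotient(
    trace: GasTrace,
    window: tuple[dt.datetime, dt.datetime] | None = None,
    params: MRParams | None = None,
) -> float:
    """Mean respiratory exchange ratio VCO2/VO2 over a window.

    Samples with VO2 at or below the floor are excluded (their ratio is
    undefined); the excluded count is logged at debug level.
    """
    p = params or MRParams()
    if not trace.has_vco2:
        raise ValueError("vco2 channel absent; respiratory quotient unavailable")
    frame = trace.frame
    if window is not None:
        frame = frame[(frame.index >= window[0]) & (frame.index <= window[1])]
    vo2 = frame["vo2"].to_numpy(float)
    vco2 = frame["vco2"].to_numpy(float)
    ok = vo2 > p.vo2_floor
    if not ok.any():
        raise ValueError("no samples with VO2 above the floor")
    import logging

    logging.getLogger("nesttorpor.mr").debug(
        "RER: %d/%d samples excluded (VO2 at floor)", int((~ok).sum()), ok.size
    )
    return float(np.mean(vco2[ok] / vo2[ok]))
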