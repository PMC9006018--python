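"""Detection of substantial nest-temperature drops — the torpor indicator.

A nest warmed by resting birds sits well above ambient; when the family
lowers its metabolic rate the nest cools toward ambient. A *substantial
drop* is a run of samples whose nest-to-ambient difference falls to or below
a criterion (default 7 degC), extended backwards to the onset of continuous
decline (where the drop magnitude is measured) and forwards to recovery.
Candidate events are then screened with a shape score against the canonical
torpor cycle — monotone entry, stable cold plateau, active rewarming — to
reject artefacts such as abrupt departure cooling, which crosses the
criterion but never rewarms.

Occupancy is inferred from nocturnal nest warming: an empty nest tracks
ambient, an occupied one is elevated by the birds' heat input. Only nests
continuously occupied for a minimum run of nights (default 30) enter the
season denominators.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import AlignedPair, TemperatureTrace, align
from .solar import SunTimes, night_window

__all__ = [
    "DropEvent",
    "OccupancyRecord",
    "DetectionParams",
    "detect_drops",
    "shape_score",
    "infer_occupancy",
    "select_monitored_nests",
    "night_date_of",
]


@dataclass
class DropEvent:
    """One detected substantial nest-temperature drop.

    ``start_time`` is the onset of continuous decline (where the magnitude
    is measured), ``criterion_time`` the first sample at or below the
    criterion, ``end_time`` the recovery completion. ``magnitude`` is nest
    temperature at start minus the in-event minimum; ``min_diff`` the lowest
    nest-to-ambient difference reached.
    """

    nest_id: str
    night_date: dt.date
    start_time: dt.datetime
    criterion_time: dt.datetime
    end_time: dt.datetime
    magnitude: float  # degC
    duration: float  # hours, start -> end
    min_tnest: float  # degC
    min_diff: float  # degC
    shape_score: float = float("nan")
    gapped: bool = False

    def __post_init__(self) -> None:
        if self.magnitude <= 0:
            raise ValueError("magnitude must be > 0")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if not self.start_time <= self.criterion_time < self.end_time:
            raise ValueError("need start_time <= criterion_time < end_time")


@dataclass
class OccupancyRecord:
    """Nightly occupancy verdict for one nest.

    ``occupied`` is None when the night had under 50% sample coverage
    (unknown — excluded from denominators). ``evidence`` is the mean
    nocturnal nest-to-ambient difference.
    """

    nest_id: str
    night_date: dt.date
    occupied: bool | None
    evidence: float = float("nan")


@dataclass
class DetectionParams:
    """Tunables of the drop detector, with the conventions they encode.

    The criterion is a pointwise inequality on (T_nest - T_a); a minimum
    persistence below it (default 30 min) suppresses single-sample noise from
    the +/-0.5 degC logger accuracy. "Decreased continuously" is evaluated on
    a median-smoothed trace with a per-step tolerance, because the 0.0625
    degC quantisation breaks strict monotonicity. Event end is recovery to
    within ``recovery_margin`` of the start value — the end of a drop needs
    an explicit convention for durations to be well defined.
    """

    criterion: float = 7.0  # degC, on T_nest - T_a
    min_persistence: float = 30.0  # minutes at/below criterion
    smooth_window: float = 15.0  # minutes, median smoothing
    decline_tol: float = 0.25  # degC allowed uphill per step during "continuous" decline
    slope_window: float = 30.0  # minutes over which the decline rate is measured
    min_decline_rate: float = 0.02  # degC/min marking an actual drop (vs diel drift)
    thermal_tau: float = 60.0  # minutes; assumed nest thermal time constant
    bridge_window: float = 90.0  # minutes the walk-back may bridge a level plateau
    recovery_margin: float = 2.0  # degC below start value counting as recovered
    merge_window: float = 30.0  # minutes between events that merge
    max_gap: float = 30.0  # minutes; larger in-event gaps flag the event
    shape_threshold: float = 0.5
    occupancy_threshold: float = 3.0  # degC mean nocturnal elevation
    min_coverage: float = 0.5  # fraction of expected nocturnal samples


def night_date_of(when: dt.datetime, tz_offset_hours: float) -> dt.date:
    """Attribute a timestamp to the night of its (local) sunset date.

    Nights are keyed by the calendar date of their sunset: local times after
    noon belong to that date, times before noon to the previous date.
    """
    local = when.astimezone(dt.timezone(dt.timedelta(hours=tz_offset_hours)))
    return (local - dt.timedelta(hours=12)).date()


def _median_smooth(values: np.ndarray, interval_min: float, window_min: float) -> np.ndarray:
    w = max(1, int(round(window_min / interval_min)))
    if w % 2 == 0:
        w += 1
    if w == 1:
        return values.astype(float)
    return (
        pd.Series(values).rolling(w, center=True, min_periods=1).median().to_numpy()
    )


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal [start, stop) runs of True."""
    out = []
    n = len(mask)
    i = 0
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            out.append((i, j))
            i = j
        else:
            i += 1
    return out


def _lagged_ambient(ta: np.ndarray, interval_min: float, tau_min: float) -> np.ndarray:
    """Ambient passed through the nest's first-order thermal filter.

    A passively coupled nest follows ambient through a low-pass with the
    nest time constant, so T_nest minus this filtered ambient isolates the
    birds' heat input: ambient swings — however fast — cancel instead of
    masquerading as (or masking) a metabolic decline.
    """
    a = 1.0 - np.exp(-interval_min / tau_min)
    out = np.empty_like(ta, dtype=float)
    acc = ta[0]
    for k, x in enumerate(ta):
        acc += a * (x - acc)
        out[k] = acc
    return out


def _walk_back_to_decline_start(
    smooth_t: np.ndarray,
    smooth_detrended: np.ndarray,
    run_start: int,
    interval_min: float,
    p: DetectionParams,
) -> int:
    """Index where the continuous decline into a below-criterion run began.

    "Continuous decline" is evaluated on the smoothed *detrended* signal
    (nest temperature minus thermally-lagged ambient): an occupied nest
    passively tracks the evening ambient decline, so raw nest temperature
    drifts down every evening, while the detrended signal only falls when
    the birds' heat input does. Declining means a trailing slope of at
    least ``min_decline_rate`` over ``slope_window`` minutes; the walk-back
    follows that mask from the below-criterion run to where the real drop
    began, then refines the start to the latest sample within
    ``decline_tol`` of the local nest-temperature maximum just before
    (which is where the drop magnitude is read).
    """
    w = max(1, int(round(p.slope_window / interval_min)))
    n = len(smooth_detrended)
    lo = np.maximum(np.arange(n) - w, 0)
    slope = (smooth_detrended - smooth_detrended[lo]) / (
        (np.arange(n) - lo).clip(min=1) * interval_min
    )
    declining = slope <= -p.min_decline_rate
    # tolerate brief threshold flicker: fill false gaps shorter than half the
    # slope window when flanked by declining samples on both sides
    max_gap = max(1, w // 2)
    for c, d in _runs(~declining):
        if 0 < c and d < n and d - c <= max_gap:
            declining[c:d] = True

    # the criterion may only be crossed once the cooling has already levelled
    # off into the maintenance plateau (and noise can break the mask
    # mid-decline): whenever the walk-back stalls, bridge backwards — up to
    # bridge_window minutes, with no substantial rebound — to the nearest
    # earlier declining stretch and continue from there
    bridge = max(1, int(round(p.bridge_window / interval_min)))
    i = run_start
    while True:
        while i > 0 and declining[i - 1]:
            i -= 1
        bridged = False
        for k in range(i - 1, max(-1, i - bridge - 1), -1):
            if smooth_detrended[k] > smooth_detrended[i] + 1.0:
                break  # rebounded: the earlier decline is a different excursion
            if declining[k]:
                i = k
                bridged = True
                break
        if not bridged:
            break
    j0 = max(0, i - w)
    window = smooth_t[j0 : i + 1]
    top = window.max()
    near_top = np.nonzero(window >= top - p.decline_tol)[0]
    return j0 + int(near_top[-1])


def detect_drops(
    nest: TemperatureTrace,
    ambient: TemperatureTrace,
    criterion: float = 7.0,
    params: DetectionParams | None = None,
    tz_offset_hours: float = 0.0,
    nightly_dedup: bool = True,
) -> list[DropEvent]:
    """Detect substantial nest-temperature drops in one nest's season.

    Steps: (1) find maximal runs with (T_nest - T_a) <= criterion lasting at
    least the minimum persistence; (2) extend each run's start backwards to
    the onset of continuous (tolerance-smoothed) decline; (3) extend its end
    forwards to recovery (first sample back within ``recovery_margin`` of the
    start value, or trace end); (4) merge events separated by less than the
    merge window, then keep at most one event per night (largest magnitude);
    (5) measure magnitude, duration and minima. Events containing a gap
    longer than ``max_gap`` are flagged ``gapped`` (excluded from duration
    statistics downstream).
    """
    if criterion <= 0:
        raise ValueError("criterion must be > 0")
    p = params or DetectionParams()
    p = DetectionParams(**{**p.__dict__, "criterion": criterion})

    pair = align(nest, ambient)
    frame = pair.frame
    times = frame.index
    t_nest = frame["t_nest"].to_numpy()
    diff = pair.diff.to_numpy()
    interval = nest.interval
    smooth = _median_smooth(t_nest, interval, p.smooth_window)
    detrended = t_nest - _lagged_ambient(frame["t_a"].to_numpy(), interval, p.thermal_tau)
    smooth_det = _median_smooth(detrended, interval, p.smooth_window)

    min_run = max(1, int(round(p.min_persistence / interval)))
    runs = [(a, b) for a, b in _runs(diff <= p.criterion) if b - a >= min_run]

    # raw segments [start, crit_idx, end)
    tz = dt.timezone(dt.timedelta(hours=tz_offset_hours))
    segments: list[tuple[int, int, int]] = []
    for a, b in runs:
        start = _walk_back_to_decline_start(smooth, smooth_det, a, interval, p)
        start_value = t_nest[start]
        # recovery search is capped at the next local noon: these are
        # nocturnal (daily) torpor bouts, and letting an unrecovered event
        # run on would fuse it with the following night's drop
        night = night_date_of(times[start].to_pydatetime(), tz_offset_hours)
        cap = dt.datetime.combine(night + dt.timedelta(days=1), dt.time(12), tzinfo=tz)
        end = b - 1
        while (
            end + 1 < len(t_nest)
            and t_nest[end] < start_value - p.recovery_margin
            and times[end + 1] <= cap
        ):
            end += 1
        segments.append((start, a, end + 1))

    # merge segments separated by < merge_window
    merged: list[tuple[int, int, int]] = []
    for seg in segments:
        if merged and (times[seg[0]] - times[merged[-1][2] - 1]).total_seconds() / 60.0 < p.merge_window:
            prev = merged[-1]
            merged[-1] = (prev[0], prev[1], max(prev[2], seg[2]))
        else:
            merged.append(seg)

    gap_min = np.diff(times.asi8) / 60e9
    events: list[DropEvent] = []
    for start, crit, stop in merged:
        seg_t = t_nest[start:stop]
        seg_d = diff[start:stop]
        magnitude = float(seg_t[0] - seg_t.min())
        if magnitude <= 0:
            continue
        duration = (times[stop - 1] - times[start]).total_seconds() / 3600.0
        if duration <= 0:
            continue
        gapped = bool((gap_min[start : stop - 1] > p.max_gap).any()) if stop - 1 > start else False
        events.append(
            DropEvent(
                nest_id=nest.source_id,
                night_date=night_date_of(times[start].to_pydatetime(), tz_offset_hours),
                start_time=times[start].to_pydatetime(),
                criterion_time=times[crit].to_pydatetime(),
                end_time=times[stop - 1].to_pydatetime(),
                magnitude=magnitude,
                duration=duration,
                min_tnest=float(seg_t.min()),
                min_diff=float(seg_d.min()),
                gapped=gapped,
            )
        )

    # nightly dedup: the merge window normally leaves one event per night;
    # keep the largest if several remain
    if nightly_dedup:
        by_night: dict[dt.date, DropEvent] = {}
        for ev in events:
            cur = by_night.get(ev.night_date)
            if cur is None or ev.magnitude > cur.magnitude:
                by_night[ev.night_date] = ev
        deduped = sorted(by_night.values(), key=lambda e: e.start_time)
    else:
        deduped = events

    for ev in deduped:
        seg = nest.series[(nest.series.index >= ev.start_time) & (nest.series.index <= ev.end_time)]
        ev.shape_score = shape_score(ev, seg, criterion=p.criterion, ambient=ambient)
    return deduped


def shape_score(
    event: DropEvent,
    segment: pd.Series,
    criterion: float = 7.0,
    ambient: TemperatureTrace | None = None,
    min_samples: int = 12,
) -> float:
    """Score how much a drop resembles a torpor cycle, in [0, 1].

    The composite averages three sub-scores, each capturing one phase of a
    torpor cycle:

    * entry — the fraction of clear (beyond-noise) declining 30-min steps
      between event start and the criterion crossing, weighted by how long
      that decline lasts (a real entry-plus-cooling takes an hour or more;
      brief noise excursions do not);
    * plateau — a real maintenance plateau holds the nest-to-ambient
      difference clearly below the criterion (median depth ~1 degC or
      more) for hours, where noise rattles shallowly just under it for
      minutes; the sub-score is the product of a depth and a duration
      factor on the smoothed difference;
    * rewarming — the mean rewarming slope relative to half the cooling
      slope, with sustained recovery required (>= 30 min); abrupt recovery
      is the noise signature, absent recovery the departure signature, both
      score 0.

    Segments shorter than ``min_samples`` score 0 ("short").
    """
    values = segment.to_numpy(float)
    if len(values) < min_samples:
        return 0.0
    interval = np.median(np.diff(segment.index.asi8)) / 60e9
    smooth = _median_smooth(values, interval, 15.0)
    i_min = int(np.argmin(smooth))
    w30 = max(1, int(round(30.0 / interval)))

    # robust per-step noise scale of the smoothed trace
    sigma = (
        float(np.median(np.abs(np.diff(smooth)))) / 0.6745 if len(smooth) > 1 else 0.0
    )

    # 1. sustained monotone decline during entry — the phase from event
    # start to the criterion crossing: every trailing 30-min change should
    # be a clear fall (beyond the noise scale), and a real entry plus
    # passive cooling takes an hour or more
    n_entry = int(np.searchsorted(segment.index.asi8, pd.Timestamp(event.criterion_time).value))
    n_entry = min(max(n_entry, 0), len(smooth) - 1)
    if n_entry >= 1:
        k = np.arange(1, n_entry + 1)
        disp = smooth[k] - smooth[np.maximum(k - w30, 0)]
        entry_frac = float(np.mean(disp <= -sigma)) * min(1.0, n_entry * interval / 60.0)
    else:
        entry_frac = 0.0

    # 2. plateau: judged on the nest-to-ambient difference, which is flat
    # during maintenance regardless of ambient drift — it must be stable
    # (close to its own minimum) and sit clearly below the criterion
    if ambient is not None:
        pair = align(
            TemperatureTrace(segment, source_id=event.nest_id, role="nest"), ambient
        )
        diff = _median_smooth(pair.diff.to_numpy(), interval, 15.0)
    else:
        # constant-ambient approximation when no ambient series is at hand
        diff = _median_smooth(values - (event.min_tnest - event.min_diff), interval, 15.0)
    below = diff <= criterion
    if below.any():
        d_below = diff[below]
        # depth is judged against the segment's own noise level (robust
        # sigma from first differences): a plateau must sit below the
        # criterion by clearly more than the trace wiggles
        sigma = float(np.median(np.abs(np.diff(diff)))) / 0.6745 if len(diff) > 1 else 0.0
        depth_scale = max(0.75, 4.0 * sigma)
        depth_factor = float(np.clip(np.median(criterion - d_below) / depth_scale, 0.0, 1.0))
        duration_factor = float(np.clip(below.sum() * interval / 120.0, 0.0, 1.0))
        plateau_frac = depth_factor * duration_factor
    else:
        plateau_frac = 0.0

    # 3. rewarming vs cooling rate; a real arousal is *sustained* and
    # monotone — recovery spanning under 30 min is the noise signature,
    # absent recovery the abrupt-departure signature, both score 0
    cool = smooth[0] - smooth[i_min]
    cool_minutes = max(interval, i_min * interval)
    cool_rate = cool / cool_minutes
    rewarm_minutes = (len(smooth) - 1 - i_min) * interval
    if i_min < len(smooth) - 1 and rewarm_minutes >= 30.0:
        # steepest sustained (1-h) rise in the recovery tail: events capped
        # before full recovery still show the arousal rewarming clearly
        w60 = max(1, int(round(60.0 / interval)))
        k = np.arange(i_min + 1, len(smooth))
        back = np.maximum(k - w60, i_min)
        spans = k - back
        sustained = spans >= w30  # a "rise" must span at least 30 min
        if sustained.any():
            rises = (smooth[k[sustained]] - smooth[back[sustained]]) / (
                spans[sustained] * interval
            )
            rewarm_rate = float(rises.max())
        else:
            rewarm_rate = 0.0
        # monotonicity judged over the arousal itself (first 90 min after
        # the minimum), weighted by how much of that window the tail covers
        k90 = k[k <= i_min + max(1, int(round(90.0 / interval)))]
        rise30 = smooth[k90] - smooth[np.maximum(k90 - w30, i_min)]
        rewarm_mono = float(np.mean(rise30 >= 0.0)) * min(1.0, rewarm_minutes / 90.0)
    else:
        rewarm_rate = 0.0
        rewarm_mono = 0.0
    if cool_rate <= 0:
        rewarm_score = 0.0
    else:
        rewarm_score = float(np.clip(rewarm_rate / (0.5 * cool_rate), 0.0, 1.0)) * rewarm_mono

    return float(np.mean([entry_frac, plateau_frac, rewarm_score]))


def infer_occupancy(
    nest: TemperatureTrace,
    ambient: TemperatureTrace,
    nights: dict[dt.date, SunTimes],
    events: list[DropEvent] | None = None,
    params: DetectionParams | None = None,
) -> list[OccupancyRecord]:
    """Nightly occupancy from nocturnal nest warming.

    A night counts as occupied when the mean nocturnal (T_nest - T_a)
    exceeds the occupancy threshold (default 3 degC), or when a detected
    drop event — which implies prior warming — spans it. Nights with under
    50% nocturnal sample coverage are unknown (``occupied=None``) and stay
    out of every denominator.
    """
    p = params or DetectionParams()
    pair = align(nest, ambient)
    diff = pair.diff
    event_nights = {ev.night_date for ev in events or []}
    out: list[OccupancyRecord] = []
    for date in sorted(nights):
        lo, hi = night_window(nights[date])
        seg = diff[(diff.index >= lo) & (diff.index < hi)]
        expected = (hi - lo).total_seconds() / 60.0 / nest.interval
        if len(seg) < p.min_coverage * expected:
            out.append(OccupancyRecord(nest.source_id, date, None))
            continue
        evidence = float(seg.mean())
        occupied = evidence > p.occupancy_threshold or date in event_nights
        out.append(OccupancyRecord(nest.source_id, date, occupied, evidence))
    return out


def _longest_true_run(flags: list[bool]) -> int:
    best = cur = 0
    for f in flags:
        cur = cur + 1 if f else 0
        best = max(best, cur)
    return best


def select_monitored_nests(
    occupancy: list[OccupancyRecord], min_nights: int = 30
) -> tuple[list[str], dict[str, int]]:
    """Nests continuously occupied for at least ``min_nights`` consecutive nights.

    Returns the selected nest ids and, for each, its occupied-night count —
    the nest's contribution to the season's observation total (observations
    = sum of occupied nights over selected nests). Unknown nights break runs
    conservatively (they are not evidence of occupancy).
    """
    by_nest: dict[str, list[OccupancyRecord]] = {}
    for rec in occupancy:
        by_nest.setdefault(rec.nest_id, []).append(rec)
    selected: list[str] = []
    counts: dict[str, int] = {}
    for nest_id, recs in by_nest.items():
        recs = sorted(recs, key=lambda r: r.night_date)
        flags = [bool(r.occupied) for r in recs]
        if _longest_true_run(flags) >= min_nights:
            selected.append(nest_id)
            counts[nest_id] = sum(flags)
    return sorted(selected), counts
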