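"""Season aggregation, descriptive statistics and group contrasts.

Turns per-event and per-night records into the season-level tables a field
study reports: how many nests were monitored, how many nest-nights were
observed, how often substantial nest-temperature drops occurred (counts and
percentages), the magnitude/duration statistics of those drops, Pearson
correlations between bout-timing quantities, and a mixed-model contrast of
daily ambient temperature between days preceding torpor nights and days
preceding ordinary nights (random intercepts for year and nest).

Rounding follows the printed-table conventions: percentages of nights and
event statistics to one decimal, nest percentages to the nearest integer,
both half-up.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
import scipy.stats

from .tnest import DropEvent, OccupancyRecord, select_monitored_nests

__all__ = [
    "SeasonSummary",
    "PooledSummary",
    "EventStats",
    "GroupContrast",
    "round_half_up",
    "summarize_season",
    "pool_seasons",
    "describe_events",
    "pearson",
    "contrast_ambient",
]


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal half-up rounding (the convention printed tables use)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class SeasonSummary:
    """One season's roll-up of monitored nests and detected drops."""

    year: int
    n_nests_observed: int
    n_observations: int  # sum of occupied nights over monitored nests
    n_nests_with_drops: int
    n_nights_with_drops: int
    pct_nests_with_drop: float | None = None  # integer rounding
    pct_nights_with_drops: float | None = None  # 1-decimal rounding

    def __post_init__(self) -> None:
        if self.n_nights_with_drops > self.n_observations:
            raise ValueError("nights with drops cannot exceed observations")
        if self.n_nests_with_drops > self.n_nests_observed:
            raise ValueError("nests with drops cannot exceed nests observed")
        if self.pct_nests_with_drop is None and self.n_nests_observed > 0:
            self.pct_nests_with_drop = round_half_up(
                100.0 * self.n_nests_with_drops / self.n_nests_observed, 0
            )
        if self.pct_nights_with_drops is None and self.n_observations > 0:
            self.pct_nights_with_drops = round_half_up(
                100.0 * self.n_nights_with_drops / self.n_observations, 1
            )
        self._check_consistency()

    def _check_consistency(self) -> None:
        # self-check: printed percentages must recompute from their own counts
        if self.pct_nests_with_drop is not None and self.n_nests_observed > 0:
            expect = round_half_up(100.0 * self.n_nests_with_drops / self.n_nests_observed, 0)
            if abs(self.pct_nests_with_drop - expect) > 1e-9:
                raise ValueError("pct_nests_with_drop inconsistent with counts")
        if self.pct_nights_with_drops is not None and self.n_observations > 0:
            expect = round_half_up(100.0 * self.n_nights_with_drops / self.n_observations, 1)
            if abs(self.pct_nights_with_drops - expect) > 1e-9:
                raise ValueError("pct_nights_with_drops inconsistent with counts")


def summarize_season(
    events: list[DropEvent],
    occupancy: list[OccupancyRecord],
    year: int,
    min_nights: int = 30,
) -> SeasonSummary:
    """Build the season summary from deduplicated events and nightly occupancy.

    Only nests continuously occupied for at least ``min_nights`` nights are
    counted; observations are their occupied-night totals. Events are
    expected deduplicated to one per nest-night (the detector guarantees
    this).
    """
    selected, counts = select_monitored_nests(occupancy, min_nights=min_nights)
    chosen = set(selected)
    kept = [ev for ev in events if ev.nest_id in chosen]
    seen = {(ev.nest_id, ev.night_date) for ev in kept}
    if len(seen) != len(kept):
        raise ValueError("events must be deduplicated to one per nest-night")
    return SeasonSummary(
        year=year,
        n_nests_observed=len(selected),
        n_observations=sum(counts.values()),
        n_nests_with_drops=len({ev.nest_id for ev in kept}),
        n_nights_with_drops=len(kept),
    )


@dataclass
class PooledSummary:
    """Across-season pooled totals and spread of the per-season nest percentage."""

    total_observations: int
    total_drop_nights: int
    total_nests_observed: int
    pct_nests_mean: float | None
    pct_nests_sd: float | None  # sample SD (n-1); None for a single season
    pct_nests_range: tuple[float, float] | None


def pool_seasons(summaries: list[SeasonSummary]) -> PooledSummary:
    """Pool seasons: totals are exact sums; spread uses the per-season
    (rounded, as printed) nest percentages with the sample SD."""
    if not summaries:
        raise ValueError("need at least one season summary")
    pcts = [s.pct_nests_with_drop for s in summaries if s.pct_nests_with_drop is not None]
    mean = float(np.mean(pcts)) if pcts else None
    sd = float(np.std(pcts, ddof=1)) if len(pcts) > 1 else None
    rng = (float(min(pcts)), float(max(pcts))) if pcts else None
    return PooledSummary(
        total_observations=sum(s.n_observations for s in summaries),
        total_drop_nights=sum(s.n_nights_with_drops for s in summaries),
        total_nests_observed=sum(s.n_nests_observed for s in summaries),
        pct_nests_mean=mean,
        pct_nests_sd=sd,
        pct_nests_range=rng,
    )


@dataclass
class EventStats:
    """Mean +/- SD and range of drop magnitude (degC) and duration (h)."""

    n: int
    magnitude_mean: float | None = None
    magnitude_sd: float | None = None
    magnitude_range: tuple[float, float] | None = None
    n_durations: int = 0
    duration_mean: float | None = None
    duration_sd: float | None = None
    duration_range: tuple[float, float] | None = None


def describe_events(events: list[DropEvent], ndigits: int = 1) -> EventStats:
    """Descriptive statistics of drop magnitudes and durations.

    Gapped events keep their magnitude but are excluded from duration
    statistics (their true extent is unknown). Empty input yields an empty
    result, not an error; single events report no SD.
    """
    if not events:
        return EventStats(n=0)
    mags = np.array([ev.magnitude for ev in events], float)
    durs = np.array([ev.duration for ev in events if not ev.gapped], float)

    def r(x: float) -> float:
        return round_half_up(float(x), ndigits)

    out = EventStats(
        n=len(events),
        magnitude_mean=r(mags.mean()),
        magnitude_sd=r(mags.std(ddof=1)) if len(mags) > 1 else None,
        magnitude_range=(r(mags.min()), r(mags.max())),
        n_durations=len(durs),
    )
    if len(durs):
        out.duration_mean = r(durs.mean())
        out.duration_sd = r(durs.std(ddof=1)) if len(durs) > 1 else None
        out.duration_range = (r(durs.min()), r(durs.max()))
    return out


def pearson(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation with the two-sided t-transform p.

    Requires equal-length finite inputs of at least 3 points and non-zero
    variance in both.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need equal-length 1-d inputs with n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    r, p = scipy.stats.pearsonr(x, y)
    return float(r), float(p)


@dataclass
class GroupContrast:
    """Mixed-model contrast of one response between torpor and ordinary days."""

    response: str
    mean_torpor: float
    ci_torpor: tuple[float, float]
    mean_nontorpor: float
    ci_nontorpor: tuple[float, float]
    n: int
    r2_marginal: float
    p_value: float
    degenerate: bool = False  # random variances collapsed; equals the OLS fit

    def __post_init__(self) -> None:
        if not self.ci_torpor[0] <= self.mean_torpor <= self.ci_torpor[1]:
            raise ValueError("torpor CI must bracket its mean")
        if not self.ci_nontorpor[0] <= self.mean_nontorpor <= self.ci_nontorpor[1]:
            raise ValueError("non-torpor CI must bracket its mean")
        if self.n <= 0:
            raise ValueError("n must be > 0")


def _ols_contrast(df: pd.DataFrame, response: str) -> tuple[dict, float, float]:
    import statsmodels.formula.api as smf

    cell = smf.ols(f"{response} ~ 0 + C(torpor)", data=df).fit()
    diff = smf.ols(f"{response} ~ C(torpor)", data=df).fit()
    ci = cell.conf_int()
    params = {}
    for level in (False, True):
        name = f"C(torpor)[{level}]"
        params[level] = (float(cell.params[name]), (float(ci.loc[name, 0]), float(ci.loc[name, 1])))
    p = float(diff.pvalues.iloc[1])
    r2 = float(diff.rsquared)
    return params, p, r2


def contrast_ambient(
    day_records: pd.DataFrame,
    responses: tuple[str, ...] = ("mean_ta", "min_ta", "max_ta"),
) -> list[GroupContrast]:
    """Contrast daily ambient temperature between torpor and ordinary days.

    ``day_records`` needs one row per day with columns ``torpor`` (whether
    the FOLLOWING night was torpid), ``year``, ``nest`` and the response
    columns. The model is response ~ group with random intercepts for year
    and nest (variance components); 95% Wald CIs on the group means, a Wald
    test for the group difference, and the marginal R-squared (variance of
    the fixed-effect predictions over total variance). When the random
    variances collapse to zero the fit degenerates, by construction, to the
    ordinary two-group linear model, and is reported from it exactly.
    """
    import statsmodels.formula.api as smf

    df = day_records.copy()
    for col in ("torpor", "year", "nest"):
        if col not in df.columns:
            raise ValueError(f"day_records must have a {col!r} column")
    df["torpor"] = df["torpor"].astype(bool)
    out: list[GroupContrast] = []
    for response in responses:
        if response not in df.columns:
            continue
        sub = df.dropna(subset=[response])
        n_by_group = sub.groupby("torpor")[response].size()
        if len(n_by_group) < 2 or (n_by_group == 0).any():
            raise ValueError(f"{response}: both groups must be non-empty")
        n = int(len(sub))
        sub = sub.assign(_one=1)
        vc = {"year": "0 + C(year)", "nest": "0 + C(nest)"}
        degenerate = False
        try:
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cell = smf.mixedlm(
                    f"{response} ~ 0 + C(torpor)", data=sub, groups="_one", vc_formula=vc
                ).fit(reml=True)
                diff = smf.mixedlm(
                    f"{response} ~ C(torpor)", data=sub, groups="_one", vc_formula=vc
                ).fit(reml=True)
            vcs = np.array([float(v) for v in cell.vcomp]) if len(cell.vcomp) else np.array([0.0])
            degenerate = bool(np.all(vcs < 1e-8 * float(cell.scale)))
        except Exception:
            degenerate = True

        if degenerate:
            params, p, r2 = _ols_contrast(sub, response)
        else:
            ci = cell.conf_int()
            params = {}
            for level in (False, True):
                name = f"C(torpor)[{level}]"
                params[level] = (
                    float(cell.params[name]),
                    (float(ci.loc[name, 0]), float(ci.loc[name, 1])),
                )
            p = float(diff.pvalues["C(torpor)[T.True]"])
            fixed = diff.model.exog @ diff.fe_params
            var_fixed = float(np.var(fixed))
            var_random = float(np.sum(diff.vcomp)) if len(diff.vcomp) else 0.0
            var_resid = float(diff.scale)
            r2 = var_fixed / (var_fixed + var_random + var_resid)

        out.append(
            GroupContrast(
                response=response,
                mean_torpor=params[True][0],
                ci_torpor=params[True][1],
                mean_nontorpor=params[False][0],
                ci_nontorpor=params[False][1],
                n=n,
                r2_marginal=r2,
                p_value=p,
                degenerate=degenerate,
            )
        )
    return out
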