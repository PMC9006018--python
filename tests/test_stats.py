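"""Season aggregation, descriptive statistics, correlation, mixed models."""

import math
import shutil
import subprocess
import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nesttorpor import (
    contrast_ambient,
    describe_events,
    pearson,
    pool_seasons,
    summarize_season,
)
from nesttorpor.stats import SeasonSummary, round_half_up
from nesttorpor.tnest import DropEvent, OccupancyRecord

# the study's printed per-season monitoring counts, used as inputs:
# (year, nests observed, observations, nests with drops, nights with drops)
SEASON_COUNTS = [
    (2010, 24, 1507, 11, 24),
    (2011, 34, 2181, 20, 25),
    (2012, 43, 3078, 38, 82),
    (2013, 43, 3149, 43, 187),
    (2014, 50, 3393, 32, 61),
    (2015, 48, 3365, 29, 44),
    (2017, 48, 3131, 29, 46),
    (2018, 41, 2553, 11, 16),
]


def summaries(rows=SEASON_COUNTS):
    return [SeasonSummary(*r) for r in rows]


class TestSeasonSummary:
    def test_2013_row_percentages(self):
        s = SeasonSummary(2013, 43, 3149, 43, 187)
        assert s.pct_nests_with_drop == 100
        assert s.pct_nights_with_drops == 5.9

    @pytest.mark.parametrize(
        "row, pct_nests, pct_nights",
        [
            ((2010, 24, 1507, 11, 24), 46, 1.6),
            ((2011, 34, 2181, 20, 25), 59, 1.1),
            ((2012, 43, 3078, 38, 82), 88, 2.7),
            ((2014, 50, 3393, 32, 61), 64, 1.8),
            ((2015, 48, 3365, 29, 44), 60, 1.3),
            ((2017, 48, 3131, 29, 46), 60, 1.5),
            ((2018, 41, 2553, 11, 16), 27, 0.6),
        ],
    )
    def test_all_season_rows_round_as_printed(self, row, pct_nests, pct_nights):
        s = SeasonSummary(*row)
        assert s.pct_nests_with_drop == pct_nests
        assert s.pct_nights_with_drops == pct_nights

    def test_inconsistent_percentages_rejected(self):
        with pytest.raises(ValueError):
            SeasonSummary(2013, 43, 3149, 43, 187, pct_nests_with_drop=90.0)

    def test_count_bounds_enforced(self):
        with pytest.raises(ValueError):
            SeasonSummary(2020, 10, 100, 11, 5)

    def test_zero_observations_reported_absent(self):
        s = SeasonSummary(2020, 0, 0, 0, 0)
        assert s.pct_nests_with_drop is None
        assert s.pct_nights_with_drops is None


class TestPoolSeasons:
    def test_first_period_totals(self):
        p = pool_seasons(summaries(SEASON_COUNTS[:6]))
        assert p.total_observations == 16673
        assert p.total_drop_nights == 423

    def test_across_season_nest_percentage_mean_sd(self):
        p = pool_seasons(summaries(SEASON_COUNTS[:6]))
        assert round_half_up(p.pct_nests_mean) == 70
        assert round_half_up(p.pct_nests_sd) == 20
        assert p.pct_nests_range == (46, 100)

    def test_second_period_totals(self):
        p = pool_seasons(summaries(SEASON_COUNTS[6:]))
        assert p.total_observations == 5684
        assert p.total_drop_nights == 62

    def test_single_season_has_no_sd(self):
        p = pool_seasons(summaries(SEASON_COUNTS[:1]))
        assert p.pct_nests_mean == 46
        assert p.pct_nests_sd is None


class TestSummarizeSeason:
    def make_occupancy(self, nest_ids, n_nights=40, start=dt.date(2017, 5, 1)):
        return [
            OccupancyRecord(nid, start + dt.timedelta(days=i), True)
            for nid in nest_ids
            for i in range(n_nights)
        ]

    def make_event(self, nid, date):
        t0 = dt.datetime(date.year, date.month, date.day, 20, tzinfo=dt.timezone.utc)
        return DropEvent(
            nest_id=nid,
            night_date=date,
            start_time=t0,
            criterion_time=t0 + dt.timedelta(hours=1),
            end_time=t0 + dt.timedelta(hours=8),
            magnitude=8.0,
            duration=8.0,
            min_tnest=22.0,
            min_diff=5.0,
        )

    def test_counts_and_percentages(self):
        occ = self.make_occupancy(["a", "b", "c"])
        events = [
            self.make_event("a", dt.date(2017, 5, 3)),
            self.make_event("a", dt.date(2017, 5, 9)),
            self.make_event("b", dt.date(2017, 5, 4)),
        ]
        s = summarize_season(events, occ, year=2017)
        assert s.n_nests_observed == 3
        assert s.n_observations == 120
        assert s.n_nests_with_drops == 2
        assert s.n_nights_with_drops == 3
        assert s.pct_nights_with_drops == 2.5
        assert s.pct_nests_with_drop == 67

    def test_under_threshold_nests_excluded_entirely(self):
        occ = self.make_occupancy(["a"], n_nights=40) + self.make_occupancy(
            ["b"], n_nights=10
        )
        events = [self.make_event("b", dt.date(2017, 5, 4))]
        s = summarize_season(events, occ, year=2017)
        assert s.n_nests_observed == 1
        assert s.n_nights_with_drops == 0

    def test_duplicate_nest_night_events_rejected(self):
        occ = self.make_occupancy(["a"])
        events = [
            self.make_event("a", dt.date(2017, 5, 3)),
            self.make_event("a", dt.date(2017, 5, 3)),
        ]
        with pytest.raises(ValueError):
            summarize_season(events, occ, year=2017)

    def test_zero_events(self):
        s = summarize_season([], self.make_occupancy(["a", "b"]), year=2017)
        assert s.n_nights_with_drops == 0
        assert s.pct_nights_with_drops == 0.0


class TestDescribeEvents:
    def ev(self, magnitude, duration, gapped=False):
        t0 = dt.datetime(2017, 6, 1, 20, tzinfo=dt.timezone.utc)
        return DropEvent(
            nest_id="n",
            night_date=t0.date(),
            start_time=t0,
            criterion_time=t0 + dt.timedelta(hours=1),
            end_time=t0 + dt.timedelta(hours=duration),
            magnitude=magnitude,
            duration=duration,
            min_tnest=22.0,
            min_diff=5.0,
            gapped=gapped,
        )

    def test_single_event_no_sd(self):
        s = describe_events([self.ev(8.6, 10.0)])
        assert s.magnitude_mean == 8.6
        assert s.magnitude_sd is None

    def test_range_endpoints(self):
        s = describe_events([self.ev(3.0, 4.0), self.ev(18.0, 22.0), self.ev(8.6, 10.8)])
        assert s.magnitude_range == (3.0, 18.0)
        assert s.duration_range == (4.0, 22.0)

    def test_matches_direct_recomputation(self):
        rng = np.random.default_rng(8)
        mags = rng.uniform(3, 18, 40)
        durs = rng.uniform(4, 22, 40)
        events = [self.ev(m, d) for m, d in zip(mags, durs)]
        s = describe_events(events)
        assert s.magnitude_mean == round_half_up(mags.mean(), 1)
        assert s.magnitude_sd == round_half_up(mags.std(ddof=1), 1)
        assert s.duration_mean == round_half_up(durs.mean(), 1)

    def test_gapped_events_excluded_from_durations_only(self):
        s = describe_events([self.ev(8.0, 10.0), self.ev(9.0, 12.0, gapped=True)])
        assert s.n == 2
        assert s.n_durations == 1
        assert s.duration_mean == 10.0

    def test_empty_input_is_empty_result(self):
        s = describe_events([])
        assert s.n == 0 and s.magnitude_mean is None


class TestPearson:
    def test_perfect_positive_line(self):
        x = np.arange(6.0)
        r, p = pearson(x, 2 * x + 1)
        assert r == pytest.approx(1.0)

    def test_perfect_negative_line(self):
        x = np.arange(6.0)
        r, _ = pearson(x, -x)
        assert r == pytest.approx(-1.0)

    def test_matches_textbook_formula_to_1e12(self):
        x = np.array([1.3, 2.1, 0.4, 3.3, 2.8, 1.9])
        y = np.array([0.7, 1.9, 0.2, 2.5, 3.1, 1.1])
        r, p = pearson(x, y)
        xm, ym = x - x.mean(), y - y.mean()
        r_direct = (xm * ym).sum() / math.sqrt((xm**2).sum() * (ym**2).sum())
        n = len(x)
        t = r_direct * math.sqrt((n - 2) / (1 - r_direct**2))
        from scipy.stats import t as tdist

        p_direct = 2 * tdist.sf(abs(t), n - 2)
        assert abs(r - r_direct) < 1e-12
        assert abs(p - p_direct) < 1e-12

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        data=st.lists(
            st.tuples(st.floats(-100, 100), st.floats(-100, 100)), min_size=4, max_size=30
        ),
        a=st.floats(0.1, 10),
        b=st.floats(-50, 50),
    )
    def test_symmetry_and_positive_affine_invariance(self, data, a, b):
        x = np.array([u for u, v in data])
        y = np.array([v for u, v in data])
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return
        r1, _ = pearson(x, y)
        r2, _ = pearson(y, x)
        r3, _ = pearson(a * x + b, y)
        assert r1 == pytest.approx(r2, abs=1e-12)
        assert r1 == pytest.approx(r3, abs=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def synth_days(rng, mu_t=17.3, mu_nt=20.8, n_t=6, n_nt=54, sd=2.0, year_sd=0.0, nest_sd=0.5):
    years, nests = [2017, 2018], ["a", "b", "c", "d", "e"]
    yeff = {y: rng.normal(0, year_sd) for y in years}
    neff = {n: rng.normal(0, nest_sd) for n in nests}
    rows = []
    for i in range(n_t + n_nt):
        t = i < n_t
        y, n = years[i % 2], nests[i % 5]
        mu = (mu_t if t else mu_nt) + yeff[y] + neff[n]
        rows.append(dict(torpor=t, year=y, nest=n, mean_ta=rng.normal(mu, sd)))
    return pd.DataFrame(rows)


class TestContrastAmbient:
    def test_recovers_generative_means_within_ci(self):
        rng = np.random.default_rng(1)
        res = contrast_ambient(synth_days(rng), responses=("mean_ta",))[0]
        assert res.ci_torpor[0] <= 17.3 <= res.ci_torpor[1]
        assert res.ci_nontorpor[0] <= 20.8 <= res.ci_nontorpor[1]
        assert res.n == 60

    def test_identical_groups_null_result(self):
        rng = np.random.default_rng(2)
        df = synth_days(rng, mu_t=20.0, mu_nt=20.0, n_t=30, n_nt=30, nest_sd=0.0)
        res = contrast_ambient(df, responses=("mean_ta",))[0]
        assert res.p_value > 0.5
        assert res.r2_marginal < 0.05

    def test_zero_variance_degenerate_equals_ols(self):
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(3)
        rows = [
            dict(
                torpor=i < 30,
                year=2017,
                nest=f"n{i}",
                mean_ta=rng.normal(17.3 if i < 30 else 20.8, 2.0),
            )
            for i in range(60)
        ]
        df = pd.DataFrame(rows)
        res = contrast_ambient(df, responses=("mean_ta",))[0]
        ols = smf.ols("mean_ta ~ 0 + C(torpor)", data=df).fit()
        assert abs(res.mean_torpor - ols.params["C(torpor)[True]"]) < 1e-6
        assert abs(res.mean_nontorpor - ols.params["C(torpor)[False]"]) < 1e-6

    def test_empty_group_rejected(self):
        df = pd.DataFrame(
            dict(torpor=[False] * 10, year=2017, nest="a", mean_ta=np.arange(10.0))
        )
        with pytest.raises(ValueError):
            contrast_ambient(df, responses=("mean_ta",))

    def test_mean_recovery_low_bias(self):
        # parameter recovery across replicates: bias under 0.2 degC
        rng = np.random.default_rng(4)
        err_t, err_nt = [], []
        for _ in range(40):
            res = contrast_ambient(synth_days(rng), responses=("mean_ta",))[0]
            err_t.append(res.mean_torpor - 17.3)
            err_nt.append(res.mean_nontorpor - 20.8)
        assert abs(np.mean(err_nt)) < 0.2
        assert abs(np.mean(err_t)) < 0.5  # n=6 in the torpor group


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript not available")
def test_group_means_cross_checked_against_lme4(tmp_path):
    """Fixed-effect group means agree with an lme4 fit of the same model."""
    rng = np.random.default_rng(9)
    df = synth_days(rng, nest_sd=1.0)
    csv = tmp_path / "days.csv"
    df.to_csv(csv, index=False)
    script = tmp_path / "fit.R"
    script.write_text(
        "suppressMessages(library(lme4))\n"
        f"d <- read.csv('{csv}')\n"
        "d$torpor <- factor(d$torpor, levels=c('False','True'))\n"
        "m <- lmer(mean_ta ~ 0 + torpor + (1|year) + (1|nest), data=d, REML=TRUE)\n"
        "cat(fixef(m)['torporFalse'], fixef(m)['torporTrue'], sep=',')\n"
    )
    out = subprocess.run(
        ["Rscript", str(script)], capture_output=True, text=True, timeout=120
    )
    assert out.returncode == 0, out.stderr
    mean_false, mean_true = map(float, out.stdout.strip().split(","))
    res = contrast_ambient(df, responses=("mean_ta",))[0]
    assert res.mean_nontorpor == pytest.approx(mean_false, abs=0.05)
    assert res.mean_torpor == pytest.approx(mean_true, abs=0.05)
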