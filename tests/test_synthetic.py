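"""Generator contracts: forcing, night profiles, heat balance, seasons."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nesttorpor import (
    SimConfig,
    simulate_ambient,
    simulate_mr_night,
    simulate_season,
    simulate_tnest_night,
)
from nesttorpor.config import LOGGER_QUANTUM
from nesttorpor.mr import score_night
from nesttorpor.synthetic import GroundTruth, physical_tnest


class TestAmbient:
    def test_degenerate_forcing_is_constant(self, quiet_config):
        cfg = quiet_config.replace(ambient_amplitude=0.0)
        trace = simulate_ambient(cfg, 3, seed=1)
        assert np.allclose(trace.series.to_numpy(), cfg.ambient_mean)

    def test_determinism_same_seed(self, default_config):
        a = simulate_ambient(default_config, 5, seed=9)
        b = simulate_ambient(default_config, 5, seed=9)
        assert (a.series == b.series).all()

    def test_noise_sd_recovered_from_residuals(self, default_config):
        cfg = default_config.replace(ambient_noise_sd=1.0)
        n_days = 35  # 10 080 five-minute samples
        noisy = simulate_ambient(cfg, n_days, seed=4)
        clean = simulate_ambient(cfg.replace(ambient_noise_sd=0.0), n_days, seed=4)
        resid = noisy.series.to_numpy() - clean.series.to_numpy()
        assert abs(resid.std(ddof=1) - 1.0) < 0.05

    def test_diel_extremes_near_dawn_and_afternoon(self, quiet_config):
        trace = simulate_ambient(quiet_config, 1, seed=0)
        hours = trace.series.index.tz_convert(quiet_config.tzinfo).hour
        tmin_h = hours[int(np.argmin(trace.series.to_numpy()))]
        tmax_h = hours[int(np.argmax(trace.series.to_numpy()))]
        assert 3 <= tmin_h <= 7
        assert 13 <= tmax_h <= 17

    def test_nonpositive_days_rejected(self, default_config):
        with pytest.raises(ValueError):
            simulate_ambient(default_config, 0, seed=1)


class TestMRNight:
    def test_no_torpor_plateau_at_resting(self, quiet_config, site_sun):
        gas, truth = simulate_mr_night(quiet_config, False, site_sun, seed=1)
        assert truth.true_reduction_pct == 0.0
        plateau = gas.vo2[
            (gas.frame.index >= site_sun.sunset + pd.Timedelta(minutes=30))
            & (gas.frame.index <= site_sun.next_sunrise)
        ]
        assert np.isclose(plateau.min(), quiet_config.resting_mr)

    def test_default_depth_measures_as_56_percent(self, quiet_config, site_sun):
        gas, truth = simulate_mr_night(quiet_config, True, site_sun, seed=1)
        assert abs(truth.true_reduction_pct - 56.0) < 1.0
        score = score_night(gas, site_sun)
        assert abs(score.reduction_pct - 56.0) < 1.0

    def test_square_wave_limit_exact_ratio(self, quiet_config, site_sun):
        cfg = quiet_config.replace(entry_tau=0.0, arousal_tau=0.0, torpid_fraction=0.5)
        gas, _ = simulate_mr_night(cfg, True, site_sun, seed=1)
        ref_time = site_sun.sunset + pd.Timedelta(minutes=cfg.arrival_offset + 30)
        i_ref = int(np.argmin(np.abs(gas.frame.index.asi8 - pd.Timestamp(ref_time).value)))
        ref = gas.vo2.iloc[i_ref]
        night = gas.vo2[
            (gas.frame.index > ref_time) & (gas.frame.index <= site_sun.next_sunrise)
        ]
        assert night.min() / ref == pytest.approx(0.5, abs=1e-12)

    def test_arrival_spike_height_and_decay(self, quiet_config, site_sun):
        gas, truth = simulate_mr_night(quiet_config, False, site_sun, seed=1)
        assert np.isclose(
            gas.vo2.max(), quiet_config.arrival_peak_height * quiet_config.resting_mr
        )
        after = gas.vo2[
            gas.frame.index >= truth.true_peak_time + pd.Timedelta(minutes=30)
        ]
        assert after.max() <= quiet_config.resting_mr + 1e-9

    def test_invalid_sun_times_rejected(self, quiet_config, site_sun):
        import dataclasses

        bad = dataclasses.replace  # constructing inverted SunTimes raises itself
        with pytest.raises(ValueError):
            bad(site_sun, sunset=site_sun.next_sunrise, next_sunrise=site_sun.sunset)

    def test_ground_truth_invariants(self):
        with pytest.raises(ValueError):
            GroundTruth("n", dt.date(2017, 6, 1), torpor=True, true_reduction_pct=0.0)
        with pytest.raises(ValueError):
            GroundTruth("n", dt.date(2017, 6, 1), torpor=False, true_reduction_pct=120.0)


class TestHeatBalance:
    def grid(self, cfg, hours=12.0):
        n = int(hours * 60 / cfg.sample_interval) + 1
        return pd.date_range("2017-06-01", periods=n, freq="5min", tz="UTC")

    def make_traces(self, cfg, ta_value, mr_value, hours=12.0):
        from nesttorpor.io import GasTrace, TemperatureTrace

        idx = self.grid(cfg, hours)
        amb = TemperatureTrace(pd.Series(np.full(len(idx), ta_value), index=idx), "a", "ambient")
        gas = GasTrace(
            pd.DataFrame({"vo2": np.full(len(idx), mr_value)}, index=idx),
            "n",
            dt.date(2017, 6, 1),
        )
        return amb, gas

    def test_zero_mr_converges_to_ambient_exponentially(self, quiet_config):
        cfg = quiet_config
        amb, gas = self.make_traces(cfg, 18.0, 0.0)
        trace = simulate_tnest_night(cfg, gas, amb, t0=30.0)
        t = trace.series.to_numpy()
        # discrete Newtonian cooling: T_k - Ta = (T0 - Ta) * (1 - lam*dt)^k
        k = np.arange(len(t))
        expected = 18.0 + 12.0 * (1 - cfg.cooling_lambda * cfg.sample_interval) ** k
        assert np.max(np.abs(t - np.round(expected / LOGGER_QUANTUM) * LOGGER_QUANTUM)) < 1e-9

    def test_steady_state_equals_closed_form(self, quiet_config):
        cfg = quiet_config
        amb, gas = self.make_traces(cfg, 18.0, cfg.resting_mr, hours=24.0)
        t = physical_tnest(
            cfg,
            gas.vo2.to_numpy(),
            amb.series.to_numpy(),
            t0=18.0,
        )
        eq = 18.0 + cfg.nest_warming_gamma * cfg.resting_mr / cfg.cooling_lambda
        # by ~24/lambda minutes the fixed point is reached to 1e-6
        assert abs(t[-1] - eq) < 1e-6
        # and convergence is monotone toward the fixed point
        gaps = np.abs(t - eq)
        assert (np.diff(gaps) <= 1e-12).all()

    def test_step_drop_matches_fine_step_integrator(self, quiet_config):
        cfg = quiet_config
        idx = self.grid(cfg, hours=12.0)
        n = len(idx)
        mr = np.full(n, cfg.resting_mr)
        mr[n // 3 :] *= 1 - 0.56
        ta = np.full(n, 18.0)
        eq = 18.0 + cfg.nest_warming_gamma * cfg.resting_mr / cfg.cooling_lambda
        coarse = physical_tnest(cfg, mr, ta, t0=eq)

        # 1-second brute-force integration of the same recurrence
        sec = 1.0 / 60.0
        n_fine = int((n - 1) * cfg.sample_interval * 60) + 1
        t_fine = np.empty(n_fine)
        t_fine[0] = eq
        for k in range(n_fine - 1):
            idx_coarse = int(k * sec / cfg.sample_interval)
            dtdt = -cfg.cooling_lambda * (t_fine[k] - 18.0) + cfg.nest_warming_gamma * mr[
                idx_coarse
            ]
            t_fine[k + 1] = t_fine[k] + sec * dtdt

        def crossing(times_min, temps):
            below = temps - 18.0 < 7.0
            return times_min[int(np.argmax(below))] if below.any() else None

        tc = crossing(np.arange(n) * cfg.sample_interval, coarse)
        tf = crossing(np.arange(n_fine) * sec, t_fine)
        assert tc is not None and tf is not None
        assert abs(tc - tf) <= cfg.sample_interval  # within one sample

    def test_mismatched_time_bases_rejected(self, quiet_config):
        amb, gas = self.make_traces(quiet_config, 18.0, 6.0)
        amb_short = type(amb)(amb.series.iloc[:-5], "a", "ambient")
        with pytest.raises(ValueError):
            simulate_tnest_night(quiet_config, gas, amb_short, t0=20.0)


class TestSeason:
    def test_zero_probability_means_zero_torpor_nights(self, quiet_config):
        cfg = quiet_config.replace(
            n_nests=2,
            season_start=dt.date(2017, 6, 1),
            season_end=dt.date(2017, 6, 8),
            torpor_probability=0.0,
        )
        ds = simulate_season(cfg)
        assert not any(g.torpor for g in ds.truth)

    def test_torpor_count_within_binomial_99_interval(self):
        cfg = SimConfig(
            n_nests=40,
            season_start=dt.date(2017, 5, 1),
            season_end=dt.date(2017, 6, 29),
            torpor_probability=0.03,
            seed=13,
        )
        ds = simulate_season(cfg)
        count = sum(g.torpor for g in ds.truth)
        n = 40 * 60
        lo, hi = stats.binom.ppf([0.005, 0.995], n, 0.03)
        assert lo <= count <= hi

    def test_same_seed_byte_identical_output(self, tmp_path, quiet_config):
        cfg = quiet_config.replace(
            n_nests=2, season_start=dt.date(2017, 6, 1), season_end=dt.date(2017, 6, 4),
            torpor_probability=0.5,
        )
        d1, d2 = tmp_path / "a", tmp_path / "b"
        simulate_season(cfg).write(d1)
        simulate_season(cfg).write(d2)
        files1 = sorted(p.name for p in d1.iterdir())
        assert files1 == sorted(p.name for p in d2.iterdir())
        for name in files1:
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_thermal_sanity_floor(self, tiny_season):
        amb_min = tiny_season.ambient.series.min()
        for trace in tiny_season.nests.values():
            assert trace.series.min() >= amb_min - 3 * tiny_season.config.sensor_noise_sd

    def test_zero_nests_rejected(self, quiet_config):
        with pytest.raises(ValueError):
            simulate_season(quiet_config.replace(n_nests=0))

    def test_single_night_reproducible_in_isolation(self, tiny_season):
        # regenerating one nest-night's gas noise from the root seed matches
        from nesttorpor.synthetic import substream, _CH_NEST

        cfg = tiny_season.config
        key = sorted(tiny_season.gas)[4]
        nest_idx = int(key[0][1:]) - 1
        night_idx = (key[1] - cfg.season_start).days
        stored = tiny_season.gas[key]
        noise = substream(cfg.seed, _CH_NEST, nest_idx, night_idx, 1).normal(
            0.0, cfg.mr_noise_sd, len(stored)
        )
        # subtracting the regenerated noise recovers the noise-free profile
        # of an independent noise-free rerun (same root seed, same draws)
        clean_ds = simulate_season(cfg.replace(mr_noise_sd=0.0))
        clean = clean_ds.gas[key].vo2.to_numpy()
        recon = stored.vo2.to_numpy() - noise
        ok = stored.vo2.to_numpy() > 0  # clipping only bites at exactly 0
        assert np.allclose(recon[ok], clean[ok], atol=1e-9)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"torpid_fraction": 1.2},
            {"torpor_probability": -0.1},
            {"sample_interval": 0.0},
            {"cooling_lambda": 0.0},
            {"nest_warming_gamma": -1.0},
            {"mr_noise_sd": -0.5},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimConfig(**kwargs)

    def test_yaml_roundtrip(self, tmp_path):
        from nesttorpor import load_config, save_config

        cfg = SimConfig(seed=42, torpid_fraction=0.6)
        save_config(cfg, tmp_path / "c.yaml")
        assert load_config(tmp_path / "c.yaml") == cfg
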