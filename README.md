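# nesttorpor

Detection of nocturnal daily torpor in nest-resting bird families from two
non-invasive signals: nest-temperature loggers and whole-nest respirometry.

## The problem

Some birds that rest overnight in their nests — swift families in a colony
are the motivating case — can lower their metabolic rate (MR) during cold
nights to save energy (*daily torpor*). Measuring torpor in free-living
birds without handling them relies on two proxies recorded at the nest:

* **Nest temperature (T_nest).** A logger embedded in the nest wall sits
  well above ambient (T_a) while warm birds rest in it. A *substantial
  drop* — the nest-to-ambient difference falling to **T_nest − T_a ≤ 7 °C**
  with the shape of a torpor cycle (gradual entry, cold maintenance
  plateau, active rewarming before dawn) — indicates torpor.
* **Whole-nest oxygen consumption (V̇O2).** From an indirect-calorimetry
  trace the reference resting rate is the value half an hour after the
  arrival peak (the adults' return near sunset), MR_ref; the lowest
  nocturnal value is MR_min, and the relative reduction is

      reduction % = (MR_ref − MR_min) × 100 / MR_ref.

  A reduction of roughly **≥ 50 %**, corroborated by a substantial T_nest
  drop the same night, classifies a torpor night.

The package implements the full pipeline — logger/respirometer file
ingestion, sunset/sunrise computation (NOAA solar algorithm), drop
detection with torpor-cycle shape screening, nightly MR scoring, bout
timing relative to sun times, season-level aggregation, Pearson
correlations, and a linear-mixed-model contrast of ambient temperature
between days preceding torpor vs ordinary nights — plus a coupled
simulator (Newtonian nest cooling driven by a metabolic night profile)
that generates both signals with known ground truth for validation.

## Worked example

```python
import datetime as dt
from nesttorpor import (SimConfig, simulate_season, detect_drops,
                        score_night, link_tnest)

cfg = SimConfig(n_nests=2, season_start=dt.date(2017, 6, 1),
                season_end=dt.date(2017, 6, 10), torpor_probability=0.4,
                seed=3)
season = simulate_season(cfg)

nest = season.nests["N001"]
events = detect_drops(nest, season.ambient, tz_offset_hours=2.0)
for ev in events[:3]:
    print(f"{ev.night_date}  drop {ev.magnitude:.1f} degC over "
          f"{ev.duration:.1f} h  shape {ev.shape_score:.2f}")

night = events[0].night_date
score = score_night(season.gas[("N001", night)], season.sun[night])
score = link_tnest(score, events)
print(f"reduction {score.reduction_pct:.1f}%  onset "
      f"{score.onset_vs_sunset:+.0f} min vs sunset  lag {score.tnest_lag:+.0f} min")
```

prints

```
2017-06-01  drop 9.6 degC over 13.9 h  shape 1.00
2017-06-06  drop 9.9 degC over 13.8 h  shape 0.99
2017-06-09  drop 9.3 degC over 13.7 h  shape 0.99
reduction 57.1%  onset +15 min vs sunset  lag +16 min
```

Each detected event is one night's nest-temperature drop: ~9–10 °C deep,
lasting into the next morning, with a shape score near 1 (a clean torpor
cycle). The scored night shows the whole-nest metabolic rate reduced by
57.1 % relative to the post-arrival resting reference — past the ~50 %
torpor guideline — starting 15 min after sunset, with the nest beginning to
cool 16 min after the metabolic onset (thermal inertia of the nest wall).

A CLI wraps the same steps: `nesttorpor simulate | detect-tnest |
analyze-mr | summarize | contrast | suntimes` (see `nesttorpor --help`).

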