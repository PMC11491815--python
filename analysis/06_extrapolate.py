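#!/usr/bin/env python
"""Ecological extrapolations from the measured flight metrics.

Turns the campaign's per-bird flight proportions and bout durations into
daily flight time and distance, foraging radii around the nest, the
flying-to-total activity ratio and the between-sex airborne-time
difference, under the explicit assumptions of a 17 h foraging day and a
9.74 m/s flight speed.  Writes results/extrapolations.json.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from accelflight.extrapolate import (
    DEFAULT_ASSUMPTIONS,
    daily_flight_distance,
    daily_flight_time,
    flight_radius,
    flight_ratio,
    sex_time_difference,
)

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.parse_args()

    birds = pd.read_csv(ROOT / "results" / "bird_summaries.csv")
    segs = pd.read_csv(ROOT / "scratch" / "sim" / "flight_segments.csv")

    r_mean = float(birds["r_flight"].mean())
    t_mean = float(birds["t_flight_s"].mean())
    per_bird_km = birds["r_flight"].map(daily_flight_distance)
    r_m = float(birds.loc[birds.sex == "male", "r_flight"].mean())
    r_f = float(birds.loc[birds.sex == "female", "r_flight"].mean())
    q99 = float(np.quantile(segs["duration_s"], 0.99))

    out = {
        "assumptions": {
            "foraging_hours_per_day": DEFAULT_ASSUMPTIONS.foraging_hours_per_day,
            "flight_speed_m_s": DEFAULT_ASSUMPTIONS.flight_speed,
        },
        "daily_flight_time_min": daily_flight_time(r_mean),
        "daily_flight_distance_km_mean": float(per_bird_km.mean()),
        "daily_flight_distance_km_sd": float(per_bird_km.std(ddof=1)),
        "mean_flight_radius_m": flight_radius(t_mean),
        "radius_99pct_flights_m": flight_radius(q99),
        "flight_to_total_ratio": flight_ratio(r_mean),
        "sex_time_difference_s_per_h": sex_time_difference(r_m, r_f),
    }
    (ROOT / "results" / "extrapolations.json").write_text(json.dumps(out, indent=2) + "\n")

    minutes = out["daily_flight_time_min"]
    print(f"daily flight time: {minutes:.0f} min "
          f"({int(minutes // 60)} h {round(minutes % 60)} min of a 17 h foraging day)")
    print(f"daily flight distance: {out['daily_flight_distance_km_mean']:.0f} "
          f"+/- {out['daily_flight_distance_km_sd']:.0f} km")
    print(f"mean foraging radius: {out['mean_flight_radius_m']:.0f} m; "
          f"99% of flights within {out['radius_99pct_flights_m']:.0f} m")
    print(f"flying:total activity ratio 1:{out['flight_to_total_ratio']:.1f}")
    print(f"males fly {out['sex_time_difference_s_per_h']:+.0f} s per hour vs females")


if __name__ == "__main__":
    main()
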