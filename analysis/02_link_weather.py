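"""Link plants to stations and build weekly exposure categories.

Reads the CSV bundle from results/data/, assigns each plant its closest
1-3 stations within 100 miles, pools daily observations into plant-week
weather, computes the heat index where the week is warm enough, and
assigns every plant-week to baseline, an HI category, or a
minimum-temperature category.  Writes results/data/plant_week_exposure.csv
and reports the linkage losses.
"""

import os
import sys

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

import pandas as pd

from transitloss.geoweather import Plant, Station, weekly_weather_table
from transitloss.heat_exposure import classify_week

DATA = os.path.join(os.path.dirname(__file__), "..", "results", "data")


def main() -> None:
    plants_df = pd.read_csv(os.path.join(DATA, "plants.csv"))
    stations_df = pd.read_csv(os.path.join(DATA, "stations.csv"))
    daily = pd.read_csv(os.path.join(DATA, "daily_weather.csv"))
    slaughter = pd.read_csv(os.path.join(DATA, "slaughter.csv"))

    plants = [Plant(r.plant_id, r.lat, r.lon, r.volume_category)
              for r in plants_df.itertuples(index=False)]
    stations = [Station(r.station_id, r.lat, r.lon)
                for r in stations_df.itertuples(index=False)]
    weather, excluded = weekly_weather_table(plants, stations, daily)

    lost_head = slaughter.loc[
        slaughter["plant_id"].isin(excluded), "total"
    ].sum()
    total_head = slaughter["total"].sum()
    print(f"plants without a station within 100 mi: {len(excluded)} "
          f"({lost_head:,} head, {100 * lost_head / total_head:.2f}% of slaughter)")

    labels, reasons = [], []
    for r in weather.itertuples(index=False):
        cat, reason = classify_week(r.t_avg_week, r.t_min_week, r.rh_week)
        labels.append(cat.label if cat else None)
        reasons.append(reason)
    weather["category"] = labels
    weather["exclusion_reason"] = reasons
    out = os.path.join(DATA, "plant_week_exposure.csv")
    weather.to_csv(out, index=False)
    print("plant-week exposure categories:")
    print(weather["category"].value_counts(dropna=False).to_string())
    print(f"wrote {os.path.abspath(out)}")


if __name__ == "__main__":
    main()
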