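"""Generate the synthetic surveillance bundle the rest of the analysis uses.

Writes the five input streams (plants, stations, daily weather, weekly
slaughter records, monthly prices) as CSV under results/data/ and prints
the fleet composition and zero-count structure.  The generating regime uses
the published per-cell condemnation rates as ground truth, so the later
model fits can be judged against known values.
"""

import os
import sys

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from transitloss.synthetic_data import GeneratorConfig, generate, write_bundle

SEED = 20170511
OUTDIR = os.path.join(os.path.dirname(__file__), "..", "results", "data")


def main() -> None:
    cfg = GeneratorConfig(seed=SEED)
    bundle = generate(cfg)
    paths = write_bundle(bundle, OUTDIR)

    sl = bundle.slaughter
    print(f"plants: {len(bundle.plants)}  stations: {len(bundle.stations)}")
    print(bundle.plants["volume_category"].value_counts().to_string())
    print(f"weekly records: {len(sl)}  total head: {sl['total'].sum():,}")
    byweek = sl.groupby(["plant_id", "week"])["condemned"].sum()
    print(f"plant-weeks with zero condemnations: {(byweek == 0).mean():.1%}")
    cats = bundle.truth["true_categories"]["true_category"].value_counts()
    print("true exposure categories (plant-weeks):")
    print(cats.to_string())
    print(f"orphan plants (no station in radius): {bundle.truth['orphan_plant_ids']}")
    print(f"wrote {len(paths)} files to {os.path.abspath(OUTDIR)}")


if __name__ == "__main__":
    main()
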