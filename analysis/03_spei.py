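"""Compute site SPEI series at accumulation scales 6-72 months.

Thornthwaite PET and the climatic water balance are derived from each
site's monthly climate; the standardized index and its water-year means
are written per scale.
"""

import argparse
from pathlib import Path

import pandas as pd

from alderhydro.climate_spei import SPEI_SCALES, water_year_mean
from alderhydro.pipeline import spei_suite
from alderhydro.ringwidth_io import read_monthly_csv
from alderhydro.synthetic_data import SyntheticConfig


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--datadir", type=Path, default=Path("results/data"))
    parser.add_argument("--outdir", type=Path, default=Path("results"))
    parser.add_argument("--latitude", type=float, default=SyntheticConfig.latitude_deg)
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)
    for csv in sorted(args.datadir.glob("site*_climate.csv")):
        site_id = csv.stem.replace("_climate", "")
        climate = read_monthly_csv(csv, "climate", site_id=site_id)
        suite = spei_suite(climate, args.latitude, scales=SPEI_SCALES)
        monthly = {f"spei_{k}": s.values() for k, s in suite.items()}
        frame = pd.DataFrame(monthly)
        frame.insert(0, "year", frame.index.year)
        frame.insert(1, "month", frame.index.month)
        frame.to_csv(args.outdir / f"{site_id}_spei_monthly.csv", index=False)
        wy = pd.DataFrame(
            {f"spei_{k}": water_year_mean(s).values() for k, s in suite.items()}
        )
        wy.index.name = "water_year"
        wy.to_csv(args.outdir / f"{site_id}_spei_wateryear.csv")
        ac = {k: round(float(s.values().dropna().autocorr()), 2) for k, s in suite.items()}
        print(f"{site_id}: SPEI lag-1 autocorrelation by scale {ac}")
    print("persistence grows with the accumulation scale, as expected for an index")
    print("integrating progressively slower hydrological sub-systems")


if __name__ == "__main__":
    main()
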