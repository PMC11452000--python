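#!/usr/bin/env python
"""Optional country-grid replication against Natural Earth boundaries.

Downloads (once, with --download) the Natural Earth 1:10m admin-0
map-unit boundaries, extracts the countries used in the published
tabulations (England, Ireland, Northern Ireland, India, the contiguous
United States) to data/boundaries/<name>.geojson, and reproduces the
per-country grid point counts and effective-bandwidth tables.

Requires network access for --download and pyproj for the map
projections; both are optional dependencies, and the script exits with a
clear message when they are unavailable.

Usage:
    python scripts/replicate_countries.py --download
    python scripts/replicate_countries.py --country ireland --increments 25 10
"""

from __future__ import annotations

import argparse
import json
import sys
import urllib.request
import zipfile
from pathlib import Path

BOUNDARY_DIR = Path(__file__).resolve().parent.parent / "data" / "boundaries"
NE_URL = (
    "https://naciscdn.org/naturalearth/10m/cultural/ne_10m_admin_0_map_units.zip"
)

#: Natural Earth attribute filters per tabulated region
REGIONS = {
    "england": ("NAME", "England"),
    "ireland": ("NAME", "Ireland"),
    "northern-ireland": ("NAME", "N. Ireland"),
    "india": ("NAME", "India"),
    "united-states": ("NAME", "United States of America"),
}


def download(dest: Path) -> None:
    try:
        import geopandas
    except ImportError:
        sys.exit(
            "extracting shapefile attributes requires geopandas, which is not "
            "installed — skipping download"
        )
    dest.mkdir(parents=True, exist_ok=True)
    archive = dest / "ne_10m_admin_0_map_units.zip"
    if not archive.exists():
        print(f"downloading {NE_URL} ...")
        urllib.request.urlretrieve(NE_URL, archive)
    with zipfile.ZipFile(archive) as zf:
        zf.extractall(dest / "ne_raw")
    shp = next((dest / "ne_raw").glob("*.shp"))
    frame = geopandas.read_file(shp)
    for name, (col, value) in REGIONS.items():
        sel = frame[frame[col] == value]
        if sel.empty:
            print(f"warning: no feature matched {col} == {value!r} for {name}")
            continue
        geom = sel.geometry.union_all()
        (dest / f"{name}.geojson").write_text(
            json.dumps(geopandas.GeoSeries([geom]).__geo_interface__["features"][0])
        )
        print(f"wrote {dest / f'{name}.geojson'}")


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--download", action="store_true")
    parser.add_argument("--country", choices=sorted(REGIONS))
    parser.add_argument("--increments", type=float, nargs="+", default=[25.0])
    parser.add_argument("--dfs", type=int, nargs="+", default=[5, 10, 25])
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()

    if args.download:
        download(BOUNDARY_DIR)
        return
    if not args.country:
        parser.error("--country is required unless --download is given")

    from spatscale.exceptions import MissingDependencyError
    from spatscale.replicate import COUNTRY_PROJECTIONS, replicate_country_table

    boundary = BOUNDARY_DIR / f"{args.country}.geojson"
    if not boundary.exists():
        sys.exit(f"{boundary} not found; run with --download first")
    try:
        table = replicate_country_table(
            boundary,
            COUNTRY_PROJECTIONS[args.country],
            increments=args.increments,
            dfs=args.dfs,
            seed=args.seed,
        )
    except MissingDependencyError as exc:
        sys.exit(str(exc))
    print(table.to_string(index=False))


if __name__ == "__main__":
    main()
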