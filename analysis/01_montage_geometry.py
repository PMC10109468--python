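#!/usr/bin/env python
"""Acquisition geometry and imaging budget of the reference survey.

Computes, from the acquisition parameters alone (60x60 tiles of
6144x4090 px, 120-um field of view, 12.5% overlap, 8 s dwell, seven
montages), the tile footprint and pixel pitch, the per-montage extent
and unique area, and the dataset totals, and writes them to
results/01_geometry.json.
"""

import json
from pathlib import Path

from palynoscope.config import default_config
from palynoscope.geometry import dataset_totals, montage_extent, tile_footprint

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    grids = default_config().montage.grids()
    fp = tile_footprint(grids[0])
    ext = montage_extent(grids[0])
    tot = dataset_totals(grids)

    print(f"tile footprint : {fp.width_um:.1f} x {fp.height_um:.1f} um "
          f"({fp.pixel_pitch_nm:.2f} nm/px, ~{round(fp.pixel_pitch_nm)} nm)")
    print(f"montage extent : {ext.width_mm} x {ext.height_mm} mm -> {ext.area_cm2} cm2 "
          f"(exact {ext.area_cm2_exact:.4f} cm2)")
    print(f"dataset        : {tot.n_images} images over {len(grids)} montages, "
          f"{tot.total_area_cm2} cm2 unique area")
    print(f"imaging time   : {tot.acquisition_hours[0]:.1f} h per montage at "
          f"{grids[0].dwell_s_per_image:.0f} s dwell")

    OUT.mkdir(exist_ok=True)
    (OUT / "01_geometry.json").write_text(
        json.dumps(
            {
                "tile_width_um": fp.width_um,
                "tile_height_um": fp.height_um,
                "pixel_pitch_nm": fp.pixel_pitch_nm,
                "montage_width_mm": ext.width_mm,
                "montage_height_mm": ext.height_mm,
                "montage_area_cm2": ext.area_cm2,
                "montage_area_cm2_exact": ext.area_cm2_exact,
                "n_images": tot.n_images,
                "total_area_cm2": tot.total_area_cm2,
                "acquisition_hours_per_montage": tot.acquisition_hours[0],
            },
            indent=2,
        )
        + "\n"
    )
    print(f"wrote {OUT / '01_geometry.json'}")


if __name__ == "__main__":
    main()
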