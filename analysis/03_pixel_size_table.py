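#!/usr/bin/env python
"""Tabulate cropped-image and resized pixel sizes per modality.

Renders the default synthetic fields, measures the 10%-threshold crop box,
and reports the physical pixel size after resizing to each square input
resolution (truncated at one decimal, the package's reporting convention).
Writes results/03_pixel_sizes.csv.
"""

from pathlib import Path

import pandas as pd

from doseqa.plans import SimConfig, generate_plan, render_dose
from doseqa.preprocess import VALID_SIDES, field_bounding_box, report_pixel_pitch

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    rows = []
    for name, factory in [("VMAT_like", SimConfig.vmat_like), ("SBRT_like", SimConfig.sbrt_like)]:
        cfg = factory(rng_seed=3)
        dose = render_dose(generate_plan(cfg), cfg, arc_index=0)
        r0, r1, c0, c1 = field_bounding_box(dose, 0.10)
        n_rows, n_cols = r1 - r0, c1 - c0
        for side in VALID_SIDES:
            rows.append(
                {
                    "modality": name,
                    "crop_rows_px": n_rows,
                    "crop_cols_px": n_cols,
                    "target_side": side,
                    "pixel_size_y_mm": report_pixel_pitch(n_rows, cfg.pixel_pitch_mm[0], side),
                    "pixel_size_x_mm": report_pixel_pitch(n_cols, cfg.pixel_pitch_mm[1], side),
                }
            )
    df = pd.DataFrame(rows)
    RESULTS.mkdir(exist_ok=True)
    df.to_csv(RESULTS / "03_pixel_sizes.csv", index=False)
    print(df.to_string(index=False))
    print(
        "\nResizing the larger VMAT-like crop to 32x32 coarsens pixels to "
        "~3 mm, while the small SBRT-like field keeps sub-2 mm pixels; at "
        "128x128 both are at or below the native 0.8 mm pitch."
    )


if __name__ == "__main__":
    main()
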