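#!/usr/bin/env python
"""Compute all twelve dose-comparison image variants for example errors.

Injects one representative error of each of the five types into a single
arc, compares each perturbed dose against the error-free reference with
every comparison method, and tabulates the dynamic range of each map.
Writes results/02_comparison_summary.csv and example multi-channel TIFFs
under scratch/comparisons/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from doseqa.compare import Method, compare
from doseqa.errors import ErrorSpec, ErrorType, apply_error
from doseqa.io import write_comparison_tiff
from doseqa.plans import SimConfig, generate_plan, render_dose

ROOT = Path(__file__).resolve().parents[1]
EXAMPLE_ERRORS = {
    ErrorType.COLLIMATOR: 2.0,       # degrees
    ErrorType.MLC_SYSTEMATIC: 2.0,   # mm
    ErrorType.MLC_RANDOM: 1.0,       # mm (target of per-leaf draws)
    ErrorType.MU_SYSTEMATIC: 10.0,   # percent
    ErrorType.MU_RANDOM: 5.0,        # percent (target of per-segment draws)
}


def main() -> None:
    cfg = SimConfig.vmat_like(rng_seed=7)
    plan = generate_plan(cfg)
    ref = render_dose(plan, cfg, arc_index=0)
    rng = np.random.default_rng(7)

    scratch = ROOT / "scratch" / "comparisons"
    scratch.mkdir(parents=True, exist_ok=True)
    rows = []
    for etype, magnitude in EXAMPLE_ERRORS.items():
        applied = apply_error(plan, ErrorSpec(etype, magnitude), rng)
        ev = render_dose(applied.plan, cfg, arc_index=0)
        for method in Method:
            comp = compare(ref, ev, method)
            write_comparison_tiff(comp, scratch / f"{etype.value}_{method.value}.tif")
            for ch, name in zip(comp.channels, comp.channel_names):
                rows.append(
                    {
                        "error_type": etype.value,
                        "label_magnitude": applied.spec.magnitude,
                        "method": method.value,
                        "channel": name,
                        "min": ch.min(),
                        "max": ch.max(),
                        "mean_abs": np.abs(ch).mean(),
                    }
                )
    df = pd.DataFrame(rows)
    (ROOT / "results").mkdir(exist_ok=True)
    df.to_csv(ROOT / "results" / "02_comparison_summary.csv", index=False)

    print(df.round(4).to_string(index=False))
    print(
        "\nEach error type leaves a distinct signature: collimator rotation "
        "concentrates signal at the rotated field border, MLC errors along "
        "leaf edges, MU errors scale the whole field (smooth for systematic, "
        "textured for random). TIFFs in scratch/comparisons/."
    )


if __name__ == "__main__":
    main()
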