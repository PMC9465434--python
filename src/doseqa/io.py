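"""File formats: float TIFF images, plan text records, HDF5 datasets.

Dose and comparison images travel as 32-bit float TIFF with a JSON metadata
record in the TIFF image description (pixel pitch, SDD, method, channel
names).  Plans are serialized as a line-oriented text document, one record
per segment.  Preprocessed datasets live in an HDF5 container holding the
image tensor, both label sets, the split assignment, the normalization
statistics and the full study configuration as JSON provenance.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import tifffile

from .compare import ComparisonImage, Method
from .plans import DoseImage, Modality, Segment, TreatmentPlan
from .preprocess import DatasetStats

__all__ = [
    "write_dose_tiff",
    "read_dose_tiff",
    "write_comparison_tiff",
    "read_comparison_tiff",
    "write_plan_text",
    "read_plan_text",
    "save_dataset_h5",
    "load_dataset_h5",
]


def write_dose_tiff(img: DoseImage, path: str | Path, modality: str | None = None) -> None:
    meta = {
        "pixel_pitch_mm": list(img.pixel_pitch_mm),
        "sdd_cm": img.sdd_cm,
        "modality": modality,
    }
    tifffile.imwrite(
        str(path), img.pixels.astype(np.float32), description=json.dumps(meta)
    )


def read_dose_tiff(path: str | Path) -> tuple[DoseImage, dict]:
    with tifffile.TiffFile(str(path)) as tif:
        pixels = tif.asarray().astype(float)
        desc = tif.pages[0].tags.get("ImageDescription")
        meta = json.loads(desc.value) if desc is not None else {}
    img = DoseImage(
        pixels,
        tuple(meta.get("pixel_pitch_mm", (0.8, 0.8))),
        meta.get("sdd_cm", 100.0),
    )
    return img, meta


def write_comparison_tiff(comp: ComparisonImage, path: str | Path) -> None:
    meta = {
        "method": comp.method.value,
        "channel_names": comp.channel_names,
        "pixel_pitch_mm": list(comp.pixel_pitch_mm),
        "meta": {k: v for k, v in comp.meta.items() if _json_safe(v)},
    }
    tifffile.imwrite(
        str(path),
        comp.channels.astype(np.float32),
        photometric="minisblack",
        description=json.dumps(meta),
    )


def _json_safe(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False


def read_comparison_tiff(path: str | Path) -> ComparisonImage:
    with tifffile.TiffFile(str(path)) as tif:
        channels = tif.asarray().astype(float)
        desc = tif.pages[0].tags.get("ImageDescription")
        meta = json.loads(desc.value) if desc is not None else {}
    if channels.ndim == 2:
        channels = channels[None]
    return ComparisonImage(
        channels,
        Method(meta["method"]),
        list(meta["channel_names"]),
        tuple(meta.get("pixel_pitch_mm", (0.8, 0.8))),
        meta=meta.get("meta", {}),
    )


# ---------------------------------------------------------------------------
# plan text format
# ---------------------------------------------------------------------------

_PLAN_HEADER = "# doseqa plan v1"


def write_plan_text(plan: TreatmentPlan, path: str | Path) -> None:
    """One record per segment: MU, collimator angle, then both leaf banks."""
    lines = [_PLAN_HEADER, f"modality {plan.modality.value}"]
    for ai, arc in enumerate(plan.arcs):
        lines.append(f"arc {ai}")
        for seg in arc:
            lines.append(f"segment mu={float(seg.mu)!r} collimator_deg={float(seg.collimator_angle)!r}")
            lines.append("bank_a " + " ".join(repr(float(v)) for v in seg.leaf_positions_bank_a))
            lines.append("bank_b " + " ".join(repr(float(v)) for v in seg.leaf_positions_bank_b))
    Path(path).write_text("\n".join(lines) + "\n")


def read_plan_text(path: str | Path) -> TreatmentPlan:
    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not lines or lines[0] != _PLAN_HEADER:
        raise ValueError(f"not a doseqa plan file: {path}")
    modality = Modality(lines[1].split(maxsplit=1)[1])
    arcs: list[list[Segment]] = []
    i = 2
    pending: dict | None = None

    def flush():
        nonlocal pending
        if pending is not None:
            arcs[-1].append(
                Segment(pending["a"], pending["b"], pending["collimator"], pending["mu"])
            )
            pending = None

    while i < len(lines):
        line = lines[i]
        if line.startswith("arc "):
            flush()
            arcs.append([])
        elif line.startswith("segment "):
            flush()
            fields = dict(kv.split("=") for kv in line.split()[1:])
            pending = {
                "mu": float(fields["mu"]),
                "collimator": float(fields["collimator_deg"]),
                "a": None,
                "b": None,
            }
        elif line.startswith("bank_a "):
            pending["a"] = np.array([float(v) for v in line.split()[1:]])
        elif line.startswith("bank_b "):
            pending["b"] = np.array([float(v) for v in line.split()[1:]])
        else:
            raise ValueError(f"unrecognized plan line: {line!r}")
        i += 1
    flush()
    return TreatmentPlan(modality, arcs)


# ---------------------------------------------------------------------------
# HDF5 dataset container
# ---------------------------------------------------------------------------

def save_dataset_h5(
    path: str | Path,
    images: np.ndarray,
    level1: np.ndarray,
    level2: np.ndarray,
    split: np.ndarray,
    stats: DatasetStats | None = None,
    config: dict | None = None,
) -> None:
    """Preprocessed dataset: (N, c, s, s) images, labels, split, provenance."""
    images = np.asarray(images)
    with h5py.File(str(path), "w") as f:
        f.create_dataset("images", data=images.astype(np.float32), compression="gzip")
        f.create_dataset("level1", data=np.asarray(level1, dtype=np.int64))
        f.create_dataset("level2", data=np.asarray(level2, dtype=np.int64))
        f.create_dataset(
            "split", data=np.array([s.encode() for s in np.asarray(split, dtype=str)])
        )
        if stats is not None:
            g = f.create_group("stats")
            g.create_dataset("mean", data=stats.mean)
            g.create_dataset("stdev", data=stats.stdev)
        f.attrs["config"] = json.dumps(config or {})


def load_dataset_h5(path: str | Path) -> dict:
    with h5py.File(str(path), "r") as f:
        out = {
            "images": f["images"][...].astype(float),
            "level1": f["level1"][...],
            "level2": f["level2"][...],
            "split": np.array([s.decode() for s in f["split"][...]]),
            "config": json.loads(f.attrs["config"]),
        }
        if "stats" in f:
            out["stats"] = DatasetStats(f["stats/mean"][...], f["stats/stdev"][...])
    return out
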