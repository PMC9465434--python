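"""Synthetic arc plans and surrogate time-integrated portal-dose rendering.

This module stands in for a clinical plan cohort and a machine-specific
portal-dose prediction engine.  It generates VMAT-like and SBRT-like arc
plans — ordered segments, each with per-leaf MLC positions, a collimator
angle and monitor units (MU) — and renders each arc to a 2D time-integrated
dose image on a fixed-pitch detector grid.

Geometry conventions (used throughout the package)
--------------------------------------------------
* Arrays are indexed ``[row, col]`` with the origin at the top-left;
  ``row`` is the image y axis, ``col`` the x axis.
* Leaf travel is along x; the leaf index runs along y.
* Physical coordinates are millimetres at the detector plane, origin at
  the grid centre, +x with increasing column, +y with increasing row.
* ``leaf_positions_bank_a`` is the left (−x) field edge of each leaf pair,
  ``leaf_positions_bank_b`` the right (+x) edge; ``a <= b`` always.
* Collimator angles are degrees, positive = counter-clockwise rotation of
  the aperture in array coordinates.

Dose surrogate
--------------
Each segment contributes ``MU × aperture`` blurred by an isotropic Gaussian
penumbra of ``penumbra_sigma_mm``.  The aperture is a union of per-leaf-pair
rectangles, so the 2D blur is evaluated in closed form as products of
error-function edge profiles, then rotated by the collimator angle with a
bilinear image rotation about the grid centre.  Because the Gaussian is
isotropic, blurring before rotating equals rotating the blurred aperture, so
a rendered rectangular segment has exact analytic erf edge profiles at any
collimator angle that maps the pixel grid onto itself.  Dose is linear in
MU by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.special import erf

__all__ = [
    "Modality",
    "Segment",
    "TreatmentPlan",
    "DoseImage",
    "SimConfig",
    "ConfigurationError",
    "GeometryError",
    "generate_plan",
    "render_dose",
    "arcs_as_plans",
]


class ConfigurationError(ValueError):
    """Raised for an invalid simulation configuration."""


class GeometryError(ValueError):
    """Raised when an aperture does not fit on the dose grid."""


class Modality(str, Enum):
    VMAT_LIKE = "VMAT_like"
    SBRT_LIKE = "SBRT_like"


@dataclass
class Segment:
    """One control point: an MLC aperture plus its monitor units.

    ``leaf_positions_bank_a``/``_b`` hold the field-edge x positions (mm)
    of each leaf pair; bank A is the left bank so ``a <= b`` per pair.
    A closed pair has ``a == b``.
    """

    leaf_positions_bank_a: np.ndarray
    leaf_positions_bank_b: np.ndarray
    collimator_angle: float
    mu: float

    def __post_init__(self) -> None:
        self.leaf_positions_bank_a = np.asarray(self.leaf_positions_bank_a, dtype=float)
        self.leaf_positions_bank_b = np.asarray(self.leaf_positions_bank_b, dtype=float)
        if self.leaf_positions_bank_a.shape != self.leaf_positions_bank_b.shape:
            raise ValueError("leaf banks must have the same number of leaves")
        if np.any(self.leaf_positions_bank_a > self.leaf_positions_bank_b + 1e-9):
            raise ValueError("bank A position must not exceed bank B (overlapping aperture)")
        if self.mu < 0:
            raise ValueError("segment MU must be non-negative")

    @property
    def n_leaf_pairs(self) -> int:
        return int(self.leaf_positions_bank_a.size)

    def copy(self) -> "Segment":
        return Segment(
            self.leaf_positions_bank_a.copy(),
            self.leaf_positions_bank_b.copy(),
            float(self.collimator_angle),
            float(self.mu),
        )


@dataclass
class TreatmentPlan:
    """An ordered list of arcs, each an ordered list of segments."""

    modality: Modality
    arcs: list[list[Segment]]

    def __post_init__(self) -> None:
        if len(self.arcs) < 1:
            raise ValueError("plan must contain at least one arc")
        if any(len(arc) < 1 for arc in self.arcs):
            raise ValueError("every arc must contain at least one segment")
        if self.total_mu() <= 0:
            raise ValueError("plan total MU must be positive")

    def total_mu(self) -> float:
        return float(sum(seg.mu for arc in self.arcs for seg in arc))

    def arc_mu(self, arc_index: int) -> float:
        return float(sum(seg.mu for seg in self.arcs[arc_index]))

    @property
    def n_arcs(self) -> int:
        return len(self.arcs)

    def copy(self) -> "TreatmentPlan":
        return TreatmentPlan(self.modality, [[s.copy() for s in arc] for arc in self.arcs])


@dataclass
class DoseImage:
    """A 2D scalar dose distribution on a fixed-pitch detector grid."""

    pixels: np.ndarray
    pixel_pitch_mm: tuple[float, float] = (0.8, 0.8)
    sdd_cm: float = 100.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("dose image must be 2D")
        if np.any(self.pixels < 0):
            raise ValueError("dose values must be non-negative")
        if min(self.pixel_pitch_mm) <= 0:
            raise ValueError("pixel pitch must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def max(self) -> float:
        return float(self.pixels.max())


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    MU statistics are mean/sd of the per-arc monitor units; field sizes are
    the (x, y) extents of the union aperture in mm.  Defaults follow the two
    plan families via :meth:`vmat_like` and :meth:`sbrt_like`.
    """

    modality: Modality = Modality.VMAT_LIKE
    n_arcs: int = 2
    n_segments_per_arc: int = 20
    mu_mean: float = 333.0
    mu_sd: float = 85.0
    target_field_size_mm: tuple[float, float] = (95.0, 87.0)
    penumbra_sigma_mm: float = 2.0
    leaf_width_mm: float = 5.0
    grid_shape: tuple[int, int] = (160, 160)
    pixel_pitch_mm: tuple[float, float] = (0.8, 0.8)
    sdd_cm: float = 100.0
    base_collimator_deg: float = 0.0
    # Per-segment inward leaf jitter, as a fraction of the field x-extent;
    # 0 gives a static rectangular aperture.
    modulation_frac: float = 0.25
    mu_floor: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_arcs < 1 or self.n_segments_per_arc < 1:
            raise ConfigurationError("arc and segment counts must be positive")
        if min(self.grid_shape) < 8:
            raise ConfigurationError("grid too small")
        if self.mu_mean <= 0 or self.mu_sd < 0 or self.penumbra_sigma_mm <= 0:
            raise ConfigurationError("MU statistics and penumbra sigma must be positive")
        if min(self.target_field_size_mm) <= 0 or self.leaf_width_mm <= 0:
            raise ConfigurationError("field size and leaf width must be positive")
        if not (0.0 <= self.modulation_frac < 1.0):
            raise ConfigurationError("modulation_frac must be in [0, 1)")
        half_x = self.grid_shape[1] * self.pixel_pitch_mm[1] / 2.0
        half_y = self.grid_shape[0] * self.pixel_pitch_mm[0] / 2.0
        margin = 4.0 * self.penumbra_sigma_mm
        if self.target_field_size_mm[0] / 2.0 + margin > half_x or (
            self.target_field_size_mm[1] / 2.0 + margin > half_y
        ):
            raise ConfigurationError("grid does not contain the target field plus margin")

    @classmethod
    def vmat_like(cls, rng_seed: int = 0, **overrides) -> "SimConfig":
        return cls(rng_seed=rng_seed, **overrides)

    @classmethod
    def sbrt_like(cls, rng_seed: int = 0, **overrides) -> "SimConfig":
        defaults = dict(
            modality=Modality.SBRT_LIKE,
            mu_mean=1746.0,
            mu_sd=251.0,
            target_field_size_mm=(49.0, 47.0),
            grid_shape=(112, 112),
        )
        defaults.update(overrides)
        return cls(rng_seed=rng_seed, **defaults)

    @property
    def n_leaf_pairs(self) -> int:
        return int(math.ceil(self.target_field_size_mm[1] / self.leaf_width_mm))


def _grid_coords(config: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Physical (y, x) pixel-centre coordinates in mm, origin at grid centre."""
    n_rows, n_cols = config.grid_shape
    py, px = config.pixel_pitch_mm
    y = (np.arange(n_rows) - (n_rows - 1) / 2.0) * py
    x = (np.arange(n_cols) - (n_cols - 1) / 2.0) * px
    return y, x


def generate_plan(config: SimConfig) -> TreatmentPlan:
    """Generate one synthetic arc plan under the configured study conditions.

    Per-arc MU is drawn from N(mu_mean, mu_sd) clipped below at ``mu_floor``
    and split across segments with symmetric-Dirichlet weights.  Leaf pairs
    covering the target field open to the target edges with independent
    inward jitter per segment (uniform on ``[0, modulation_frac × width]``),
    so the union aperture over segments approximates the target field size.
    Deterministic given ``rng_seed``.
    """
    rng = np.random.default_rng(config.rng_seed)
    half_w = config.target_field_size_mm[0] / 2.0
    n_pairs = config.n_leaf_pairs
    jitter_scale = config.modulation_frac * config.target_field_size_mm[0] / 2.0

    arcs: list[list[Segment]] = []
    for _ in range(config.n_arcs):
        arc_mu = max(config.mu_floor, rng.normal(config.mu_mean, config.mu_sd))
        weights = rng.dirichlet(np.full(config.n_segments_per_arc, 5.0))
        segments = []
        for k in range(config.n_segments_per_arc):
            a = -half_w + rng.uniform(0.0, jitter_scale, size=n_pairs) if jitter_scale else np.full(n_pairs, -half_w)
            b = half_w - rng.uniform(0.0, jitter_scale, size=n_pairs) if jitter_scale else np.full(n_pairs, half_w)
            segments.append(
                Segment(a, b, config.base_collimator_deg, float(arc_mu * weights[k]))
            )
        arcs.append(segments)
    return TreatmentPlan(config.modality, arcs)


def _segment_fluence(seg: Segment, config: SimConfig) -> np.ndarray:
    """Isotropic-Gaussian-blurred aperture of one segment, in closed form.

    The aperture is a disjoint union of per-leaf-pair rectangles, so its 2D
    Gaussian blur separates into an erf profile along x (the leaf edges)
    times an erf profile along y (the leaf-width strip edges), summed over
    pairs — the exact continuous penumbra sampled at pixel centres.
    """
    y, x = _grid_coords(config)
    s = config.penumbra_sigma_mm * math.sqrt(2.0)
    a = seg.leaf_positions_bank_a[:, None]
    b = seg.leaf_positions_bank_b[:, None]
    h = 0.5 * (erf((x[None, :] - a) / s) - erf((x[None, :] - b) / s))
    n_pairs = seg.n_leaf_pairs
    stack_half = n_pairs * config.leaf_width_mm / 2.0
    y_lo = (-stack_half + np.arange(n_pairs) * config.leaf_width_mm)[:, None]
    y_hi = y_lo + config.leaf_width_mm
    v = 0.5 * (erf((y[None, :] - y_lo) / s) - erf((y[None, :] - y_hi) / s))
    return np.einsum("ir,ic->rc", v, h, optimize=True)


def _check_geometry(seg: Segment, config: SimConfig) -> None:
    _, x = _grid_coords(config)
    margin = 2.0 * config.penumbra_sigma_mm
    open_pair = seg.leaf_positions_bank_b - seg.leaf_positions_bank_a > 1e-9
    if not np.any(open_pair):
        return
    lo = seg.leaf_positions_bank_a[open_pair].min()
    hi = seg.leaf_positions_bank_b[open_pair].max()
    if lo < x[0] + margin or hi > x[-1] - margin:
        raise GeometryError(
            f"aperture [{lo:.1f}, {hi:.1f}] mm exceeds dose grid "
            f"[{x[0]:.1f}, {x[-1]:.1f}] mm (with {margin:.1f} mm penumbra margin)"
        )
    stack_half = config.n_leaf_pairs * config.leaf_width_mm / 2.0
    y, _ = _grid_coords(config)
    if stack_half > -y[0] - margin:
        raise GeometryError("leaf stack exceeds dose grid in y")


def render_dose(
    plan: TreatmentPlan,
    config: SimConfig,
    arc_index: int | None = None,
) -> DoseImage:
    """Render the time-integrated 2D dose of one arc (or the whole plan).

    Each segment's aperture is penumbra-blurred (closed-form isotropic
    Gaussian, ``penumbra_sigma_mm``), rotated by its collimator angle about
    the grid centre, scaled by its MU and summed.  Segments sharing a
    collimator angle are accumulated before the rotation, which is exact
    because rotation is linear.
    """
    arcs = plan.arcs if arc_index is None else [plan.arcs[arc_index]]

    by_angle: dict[float, np.ndarray] = {}
    for arc in arcs:
        for seg in arc:
            if seg.mu == 0.0:
                continue
            _check_geometry(seg, config)
            f = _segment_fluence(seg, config) * seg.mu
            key = float(seg.collimator_angle) % 360.0
            if key in by_angle:
                by_angle[key] += f
            else:
                by_angle[key] = f

    total = np.zeros(config.grid_shape, dtype=float)
    for angle, f in by_angle.items():
        if angle != 0.0:
            f = ndimage.rotate(f, angle, reshape=False, order=1, mode="constant")
        total += f
    # bilinear rotation can produce tiny negative overshoots at edges
    np.clip(total, 0.0, None, out=total)
    return DoseImage(total, config.pixel_pitch_mm, config.sdd_cm)


def arcs_as_plans(plan: TreatmentPlan) -> list[TreatmentPlan]:
    """Split a multi-arc plan into independent single-arc delivery units.

    Errors are delivered and verified per arc, so the dataset unit of the
    study is the arc; this helper flattens a cohort accordingly.
    """
    return [TreatmentPlan(plan.modality, [[s.copy() for s in arc]]) for arc in plan.arcs]
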