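"""Twelve 2D dose-comparison image variants.

Given a reference (error-free) and an evaluated (with-error) dose image on
the same grid, this module computes the comparison images used as
classifier input: five gamma maps with different global dose-difference /
distance-to-agreement criteria, the dose ratio, absolute and relative dose
difference (DD), signed distance-to-agreement (DTA) in x and y, a stacked
DD+DTA image, a sliding-window structural-similarity (SSIM) map, and the
Sobel gradient magnitude/direction of the relative DD map.

Gamma and DD maps are *signed*: the magnitude is multiplied by the sign of
the local dose difference (evaluated − reference), so over- and under-dosage
remain distinguishable for the classifier.

All dose-difference normalizations are global, i.e. relative to the maximum
of the reference distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import ndimage

from .plans import DoseImage

__all__ = [
    "Method",
    "GammaCriteria",
    "SsimParams",
    "ComparisonImage",
    "GAMMA_CRITERIA",
    "gamma_map",
    "ratio_map",
    "dd_map",
    "dta_map",
    "ssim_map",
    "gradient_map",
    "compare",
]


class Method(str, Enum):
    """The twelve comparison-image variants (7 methods, 5 gamma criteria)."""

    GAMMA11 = "gamma11"
    GAMMA22 = "gamma22"
    GAMMA33 = "gamma33"
    GAMMA31 = "gamma31"
    GAMMA13 = "gamma13"
    RATIO = "ratio"
    ABS_DD = "abs_dd"
    REL_DD = "rel_dd"
    DTA = "dta"
    DD_DTA = "dd_dta"
    SSIM = "ssim"
    GRADIENT = "gradient"


#: (dose-difference %, distance-to-agreement mm) per gamma variant.
GAMMA_CRITERIA: dict[Method, tuple[float, float]] = {
    Method.GAMMA11: (1.0, 1.0),
    Method.GAMMA22: (2.0, 2.0),
    Method.GAMMA33: (3.0, 3.0),
    Method.GAMMA31: (3.0, 1.0),
    Method.GAMMA13: (1.0, 3.0),
}

#: Channel count per method; all others are single-channel.
_N_CHANNELS = {Method.DTA: 2, Method.DD_DTA: 3, Method.GRADIENT: 2}


@dataclass
class GammaCriteria:
    """Global gamma criteria: DD as % of max reference dose, DTA in mm.

    ``search_radius_mm`` bounds the spatial search (default 3 × dta_mm);
    ``subsample_factor`` places candidate positions every
    ``pitch / subsample_factor`` with bilinear dose interpolation
    (1 = integer pixel offsets only, the exhaustive-oracle mode).
    """

    dd_percent: float
    dta_mm: float
    search_radius_mm: float | None = None
    subsample_factor: int = 4

    def __post_init__(self) -> None:
        if self.dd_percent <= 0 or self.dta_mm <= 0:
            raise ValueError("gamma criteria must be positive")
        if self.search_radius_mm is None:
            self.search_radius_mm = 3.0 * self.dta_mm
        if self.search_radius_mm < self.dta_mm:
            raise ValueError("search radius must cover at least one DTA")
        if self.subsample_factor < 1:
            raise ValueError("subsample factor must be >= 1")


@dataclass
class SsimParams:
    window_side_px: int = 11
    k1: float = 0.01
    k2: float = 0.03
    dynamic_range: float | None = None  # default: max reference dose

    def __post_init__(self) -> None:
        if self.window_side_px < 3 or self.window_side_px % 2 == 0:
            raise ValueError("SSIM window must be an odd integer >= 3")
        if self.k1 <= 0 or self.k2 <= 0:
            raise ValueError("k1 and k2 must be positive")


@dataclass
class ComparisonImage:
    """A 1–3 channel float comparison image with channel names."""

    channels: np.ndarray  # (n_channels, rows, cols)
    method: Method
    channel_names: list[str]
    pixel_pitch_mm: tuple[float, float] = (0.8, 0.8)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=float)
        if self.channels.ndim == 2:
            self.channels = self.channels[None]
        if self.channels.ndim != 3:
            raise ValueError("channels must be a (c, rows, cols) array")
        if not 1 <= self.channels.shape[0] <= 3:
            raise ValueError("comparison images have 1-3 channels")
        if len(self.channel_names) != self.channels.shape[0]:
            raise ValueError("one name per channel required")
        if not np.all(np.isfinite(self.channels)):
            raise ValueError("comparison image must be finite")

    @property
    def n_channels(self) -> int:
        return self.channels.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.channels.shape[1:]


def _as_pixels(img: DoseImage | np.ndarray) -> np.ndarray:
    return img.pixels if isinstance(img, DoseImage) else np.asarray(img, dtype=float)


def _pitch(img: DoseImage | np.ndarray, default=(0.8, 0.8)) -> tuple[float, float]:
    return tuple(img.pixel_pitch_mm) if isinstance(img, DoseImage) else default


def _check_shapes(ref: np.ndarray, ev: np.ndarray) -> None:
    if ref.shape != ev.shape:
        raise ValueError(f"shape mismatch: ref {ref.shape} vs eval {ev.shape}")


def _candidate_offsets(
    criteria: GammaCriteria, pitch: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Candidate offsets as integer subsample steps (ky, kx), sorted by
    distance with (0, 0) first; the third array is distance² in mm²."""
    py, px = pitch
    f = criteria.subsample_factor
    r = criteria.search_radius_mm
    ny = int(math.floor(r / (py / f)))
    nx = int(math.floor(r / (px / f)))
    KY, KX = np.meshgrid(np.arange(-ny, ny + 1), np.arange(-nx, nx + 1), indexing="ij")
    d2 = (KY * (py / f)) ** 2 + (KX * (px / f)) ** 2
    keep = d2 <= r**2 + 1e-12
    ky, kx, d2 = KY[keep], KX[keep], d2[keep]
    order = np.argsort(d2, kind="stable")
    return ky[order], kx[order], d2[order]


def gamma_map(
    ref: DoseImage,
    ev: DoseImage,
    criteria: GammaCriteria,
) -> ComparisonImage:
    """Signed global gamma index map.

    For each reference pixel r the gamma value is the minimum over candidate
    evaluated positions e within the search radius of

        sqrt( |e − r|² / dta²  +  (D_eval(e) − D_ref(r))² / ΔD² ),

    with ΔD = dd_percent/100 × max(ref), evaluated dose interpolated
    bilinearly at fractional offsets; candidate positions outside the image
    are excluded.  The result is signed by the local dose difference
    D_eval(r) − D_ref(r).  Candidates are visited in order of increasing
    distance with early termination once the pure-distance term exceeds the
    current worst pixel, which leaves the minimum unchanged.
    """
    R, E = _as_pixels(ref), _as_pixels(ev)
    _check_shapes(R, E)
    ref_max = R.max()
    if ref_max <= 0:
        raise ValueError("gamma requires a positive maximum reference dose")
    pitch = _pitch(ref)
    py, px = pitch
    dd_abs = criteria.dd_percent / 100.0 * ref_max
    dta2 = criteria.dta_mm**2

    n_rows, n_cols = R.shape
    rows = np.arange(n_rows)[:, None] * np.ones((1, n_cols))
    cols = np.ones((n_rows, 1)) * np.arange(n_cols)[None, :]

    f = criteria.subsample_factor
    g2 = np.full(R.shape, np.inf)
    all_ky, all_kx, all_d2 = _candidate_offsets(criteria, pitch)
    for ky, kx, d2 in zip(all_ky, all_kx, all_d2):
        dist_term = d2 / dta2
        if dist_term >= g2.max():
            break  # farther candidates cannot improve any pixel
        if ky % f == 0 and kx % f == 0:
            iy, ix = int(ky) // f, int(kx) // f
            if abs(iy) >= n_rows or abs(ix) >= n_cols:
                continue  # offset larger than the image
            ys = slice(max(0, iy), min(n_rows, n_rows + iy))
            xs = slice(max(0, ix), min(n_cols, n_cols + ix))
            ys0 = slice(max(0, -iy), min(n_rows, n_rows - iy))
            xs0 = slice(max(0, -ix), min(n_cols, n_cols - ix))
            dterm = (E[ys, xs] - R[ys0, xs0]) ** 2 / dd_abs**2
            np.minimum(g2[ys0, xs0], dist_term + dterm, out=g2[ys0, xs0])
        else:
            yy = rows + ky / f
            xx = cols + kx / f
            valid = (yy >= 0) & (yy <= n_rows - 1) & (xx >= 0) & (xx <= n_cols - 1)
            if not valid.any():
                continue
            sampled = ndimage.map_coordinates(
                E, [yy[valid], xx[valid]], order=1, mode="nearest"
            )
            dterm = (sampled - R[valid]) ** 2 / dd_abs**2
            cand = dist_term + dterm
            g2v = g2[valid]
            g2[valid] = np.minimum(g2v, cand)
    gamma = np.sqrt(g2) * np.sign(E - R)
    return ComparisonImage(
        gamma[None],
        _gamma_method(criteria),
        ["gamma"],
        pitch,
        meta={"dd_percent": criteria.dd_percent, "dta_mm": criteria.dta_mm},
    )


def _gamma_method(criteria: GammaCriteria) -> Method:
    for method, (dd, dta) in GAMMA_CRITERIA.items():
        if (dd, dta) == (criteria.dd_percent, criteria.dta_mm):
            return method
    return Method.GAMMA33


def gamma_map_bruteforce(ref: DoseImage, ev: DoseImage, criteria: GammaCriteria) -> np.ndarray:
    """Reference gamma by exhaustive per-pixel search over integer offsets.

    Independent of :func:`gamma_map`'s vectorized path; used to validate it.
    Only supports ``subsample_factor == 1``.
    """
    if criteria.subsample_factor != 1:
        raise ValueError("brute-force oracle is defined for integer pixel offsets")
    R, E = _as_pixels(ref), _as_pixels(ev)
    py, px = _pitch(ref)
    dd_abs = criteria.dd_percent / 100.0 * R.max()
    out = np.empty_like(R)
    n_rows, n_cols = R.shape
    my = int(criteria.search_radius_mm // py)
    mx = int(criteria.search_radius_mm // px)
    for i in range(n_rows):
        for j in range(n_cols):
            best = math.inf
            for di in range(-my, my + 1):
                for dj in range(-mx, mx + 1):
                    d2 = (di * py) ** 2 + (dj * px) ** 2
                    if d2 > criteria.search_radius_mm**2 + 1e-12:
                        continue
                    ii, jj = i + di, j + dj
                    if not (0 <= ii < n_rows and 0 <= jj < n_cols):
                        continue
                    val = d2 / criteria.dta_mm**2 + (E[ii, jj] - R[i, j]) ** 2 / dd_abs**2
                    best = min(best, val)
            sign = np.sign(E[i, j] - R[i, j])
            out[i, j] = math.sqrt(best) * sign
    return out


def ratio_map(ref: DoseImage, ev: DoseImage, eps: float = 1e-3) -> ComparisonImage:
    """Evaluated dose divided by reference dose, 1 where the reference is ~0."""
    R, E = _as_pixels(ref), _as_pixels(ev)
    _check_shapes(R, E)
    out = np.ones_like(R)
    mask = R >= eps * R.max()
    out[mask] = E[mask] / R[mask]
    return ComparisonImage(out[None], Method.RATIO, ["ratio"], _pitch(ref))


def dd_map(ref: DoseImage, ev: DoseImage, relative: bool = False) -> ComparisonImage:
    """Dose-difference map, absolute (Gy-like units) or relative to max(ref)."""
    R, E = _as_pixels(ref), _as_pixels(ev)
    _check_shapes(R, E)
    diff = E - R
    if relative:
        ref_max = R.max()
        if ref_max <= 0:
            raise ValueError("relative DD requires a positive maximum reference dose")
        diff = diff / ref_max
        return ComparisonImage(diff[None], Method.REL_DD, ["rel_dd"], _pitch(ref))
    return ComparisonImage(diff[None], Method.ABS_DD, ["abs_dd"], _pitch(ref))


def _dta_axis(R: np.ndarray, E: np.ndarray, pitch: float, chunk: int = 16) -> np.ndarray:
    """Signed DTA along the last axis, vectorized over leading rows.

    For each target pixel, the signed distance (mm) to the nearest point
    where the linearly interpolated evaluated profile crosses the
    reference value; saturates at ±W (half the axis extent) when no
    crossing lies within W, signed towards the profile's closest dose
    approach.  Rows are processed in chunks to keep the (rows, targets,
    positions) working set cache-resident.
    """
    n_rows, n = R.shape
    x = np.arange(n) * pitch
    W = n * pitch / 2.0
    # float32 is ample for mm-scale distances and halves the memory traffic
    R32 = R.astype(np.float32)
    E32 = E.astype(np.float32)
    x32 = x.astype(np.float32)
    out = np.empty((n_rows, n), dtype=float)
    for start in range(0, n_rows, chunk):
        sl = slice(start, min(start + chunk, n_rows))
        out[sl] = _dta_axis_block(R32[sl], E32[sl], x32, np.float32(pitch), np.float32(W))
    return out


def _dta_axis_block(R: np.ndarray, E: np.ndarray, x: np.ndarray, pitch: float, W: float) -> np.ndarray:
    # d[r, i, j] = E[r, j] - R[r, i]; crossings along j for each target i
    d = E[:, None, :] - R[:, :, None]
    d0 = d[:, :, :-1]
    d1 = d[:, :, 1:]
    denom = d0 - d1
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(denom != 0.0, d0 / denom, 0.0)
    crossing = (d0 * d1 <= 0.0) & ~((d0 == 0.0) & (d1 == 0.0))
    xc = x[None, None, :-1] + frac * pitch
    dist = xc - x[None, :, None]
    # flat-equal runs: both endpoints zero -> crossing at the left sample
    flat = (d0 == 0.0) & (d1 == 0.0)
    dist = np.where(flat, x[None, None, :-1] - x[None, :, None], dist)
    crossing = crossing | flat
    # the last sample can be an exact hit not covered by any interval
    last_hit = d[:, :, -1] == 0.0
    abs_dist = np.where(crossing & (np.abs(dist) <= W), np.abs(dist), np.inf)

    best = np.argmin(abs_dist, axis=2)
    best_dist = np.take_along_axis(dist, best[:, :, None], axis=2)[:, :, 0]
    found = np.take_along_axis(abs_dist, best[:, :, None], axis=2)[:, :, 0] < np.inf

    # candidate exact hit at the final sample
    last_dist = x[-1] - x[None, :]
    use_last = last_hit & (np.abs(last_dist) <= W) & (
        ~found | (np.abs(last_dist) < np.abs(best_dist))
    )
    best_dist = np.where(use_last, np.broadcast_to(last_dist, best_dist.shape), best_dist)
    found = found | use_last

    # saturation: sign of the side of the closest dose approach
    approach = np.argmin(np.abs(d), axis=2)  # (rows, targets)
    sign = np.sign(x[approach] - x[None, :])
    sign = np.where(sign == 0.0, 1.0, sign)
    return np.where(found, best_dist, sign * W)


def dta_map(ref: DoseImage, ev: DoseImage) -> ComparisonImage:
    """Signed distance-to-agreement in x (along rows) and y (along columns).

    x is the horizontal/column-index direction, y the vertical/row-index
    direction; positive DTA points towards increasing x (right) or
    increasing y (down).
    """
    R, E = _as_pixels(ref), _as_pixels(ev)
    _check_shapes(R, E)
    py, px = _pitch(ref)
    dta_x = _dta_axis(R, E, px)
    dta_y = _dta_axis(R.T, E.T, py).T
    return ComparisonImage(
        np.stack([dta_x, dta_y]), Method.DTA, ["dta_x", "dta_y"], (py, px)
    )


def ssim_map(
    ref: DoseImage,
    ev: DoseImage,
    params: SsimParams | None = None,
) -> ComparisonImage:
    """Sliding-window structural similarity map.

    Per window: ``((2 μx μy + C1)(2 σxy + C2)) / ((μx² + μy² + C1)(σx² + σy² + C2))``
    with C1 = (k1 L)², C2 = (k2 L)², L the dynamic range (max reference dose
    by default).  Uniform window, population moments, symmetric padding,
    one value per pixel.
    """
    params = params or SsimParams()
    R, E = _as_pixels(ref), _as_pixels(ev)
    _check_shapes(R, E)
    win = params.window_side_px
    if win > min(R.shape):
        raise ValueError("SSIM window larger than image")
    L = params.dynamic_range if params.dynamic_range is not None else R.max()
    if L <= 0:
        raise ValueError("SSIM dynamic range must be positive")
    c1 = (params.k1 * L) ** 2
    c2 = (params.k2 * L) ** 2

    def mean(a):
        return ndimage.uniform_filter(a, size=win, mode="reflect")

    mx, my = mean(R), mean(E)
    vx = np.maximum(mean(R * R) - mx * mx, 0.0)
    vy = np.maximum(mean(E * E) - my * my, 0.0)
    cxy = mean(R * E) - mx * my
    ssim = ((2 * mx * my + c1) * (2 * cxy + c2)) / ((mx**2 + my**2 + c1) * (vx + vy + c2))
    return ComparisonImage(ssim[None], Method.SSIM, ["ssim"], _pitch(ref))


_SOBEL_X = np.array([[-1.0, 0.0, 1.0], [-2.0, 0.0, 2.0], [-1.0, 0.0, 1.0]])
_SOBEL_Y = _SOBEL_X.T


def gradient_map(ref: DoseImage, ev: DoseImage) -> ComparisonImage:
    """Sobel gradient magnitude and direction of the relative DD map.

    Direction is atan2(Gy, Gx) in radians with the image-coordinate
    convention (+x right, +y down); zero gradient maps to direction 0.
    """
    rel = dd_map(ref, ev, relative=True).channels[0]
    gx = ndimage.correlate(rel, _SOBEL_X, mode="reflect")
    gy = ndimage.correlate(rel, _SOBEL_Y, mode="reflect")
    mag = np.hypot(gx, gy)
    direction = np.arctan2(gy, gx)
    return ComparisonImage(
        np.stack([mag, direction]), Method.GRADIENT, ["grad_mag", "grad_dir"], _pitch(ref)
    )


def compare(
    ref: DoseImage,
    ev: DoseImage,
    method: Method | str,
    *,
    subsample_factor: int = 4,
    ssim_params: SsimParams | None = None,
) -> ComparisonImage:
    """Compute one of the twelve comparison-image variants."""
    method = Method(method)
    if method in GAMMA_CRITERIA:
        dd, dta = GAMMA_CRITERIA[method]
        return gamma_map(ref, ev, GammaCriteria(dd, dta, subsample_factor=subsample_factor))
    if method is Method.RATIO:
        return ratio_map(ref, ev)
    if method is Method.ABS_DD:
        return dd_map(ref, ev, relative=False)
    if method is Method.REL_DD:
        return dd_map(ref, ev, relative=True)
    if method is Method.DTA:
        return dta_map(ref, ev)
    if method is Method.DD_DTA:
        rel = dd_map(ref, ev, relative=True)
        dta = dta_map(ref, ev)
        return ComparisonImage(
            np.concatenate([rel.channels, dta.channels]),
            Method.DD_DTA,
            ["rel_dd", "dta_x", "dta_y"],
            rel.pixel_pitch_mm,
        )
    if method is Method.SSIM:
        return ssim_map(ref, ev, ssim_params)
    if method is Method.GRADIENT:
        return gradient_map(ref, ev)
    raise ValueError(f"unknown comparison method {method!r}")  # pragma: no cover


def n_channels(method: Method | str) -> int:
    """Channel count a method produces."""
    return _N_CHANNELS.get(Method(method), 1)
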