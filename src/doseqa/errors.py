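"""Mechanical delivery-error injection and two-level labelling.

Five error types are simulated by perturbing plan parameters:

====================  ==========================  =================
type                  magnitude grid (no zero)    relevance threshold
====================  ==========================  =================
collimator rotation   −2 … +2° in 0.2° steps      1°
MLC systematic        −2 … +2 mm in 0.2 mm steps  1 mm
MLC random            −2 … +2 mm in 0.2 mm steps  0.5 mm
MU systematic         −10 … +10% in 1% steps      5%
MU random             −10 … +10% in 1% steps      3%
====================  ==========================  =================

Systematic errors apply one magnitude to every segment of an arc; random
errors draw an independent value per segment (MU) or per leaf (MLC) and
record the signed average of the draws as the label magnitude.  Level-1
labels classify the error type (5 classes); Level-2 labels classify the
magnitude as relevant/irrelevant against the per-type threshold, inclusive
at the boundary (|m| >= threshold is relevant).  The stricter thresholds
for random errors reflect that per-segment errors can average out in a
time-integrated dose image while remaining clinically consequential.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import NamedTuple

import numpy as np

from .plans import Segment, TreatmentPlan

__all__ = [
    "ErrorType",
    "Bank",
    "Relevance",
    "ErrorSpec",
    "LabelPair",
    "ErrorApplication",
    "MAGNITUDE_LIMITS",
    "LEVEL2_THRESHOLDS",
    "RANDOM_DRAW_SPREAD",
    "magnitude_grid",
    "level2_label",
    "label_pair",
    "apply_error",
]

logger = logging.getLogger(__name__)


class ErrorType(str, Enum):
    COLLIMATOR = "collimator"
    MLC_SYSTEMATIC = "mlc_systematic"
    MLC_RANDOM = "mlc_random"
    MU_SYSTEMATIC = "mu_systematic"
    MU_RANDOM = "mu_random"


class Bank(str, Enum):
    A = "A"
    B = "B"
    BOTH = "BOTH"


class Relevance(str, Enum):
    RELEVANT = "relevant"
    IRRELEVANT = "irrelevant"


#: (half-range, step) of the signed magnitude grid per error type.
MAGNITUDE_LIMITS: dict[ErrorType, tuple[float, float]] = {
    ErrorType.COLLIMATOR: (2.0, 0.2),
    ErrorType.MLC_SYSTEMATIC: (2.0, 0.2),
    ErrorType.MLC_RANDOM: (2.0, 0.2),
    ErrorType.MU_SYSTEMATIC: (10.0, 1.0),
    ErrorType.MU_RANDOM: (10.0, 1.0),
}

#: Absolute magnitude at and above which an error is labelled relevant.
LEVEL2_THRESHOLDS: dict[ErrorType, float] = {
    ErrorType.COLLIMATOR: 1.0,
    ErrorType.MLC_SYSTEMATIC: 1.0,
    ErrorType.MLC_RANDOM: 0.5,
    ErrorType.MU_SYSTEMATIC: 5.0,
    ErrorType.MU_RANDOM: 3.0,
}

#: Half-width of the uniform per-unit draw around the target magnitude
#: for the two random error types (mm for MLC, % for MU).
RANDOM_DRAW_SPREAD: dict[ErrorType, float] = {
    ErrorType.MLC_RANDOM: 0.5,
    ErrorType.MU_RANDOM: 2.0,
}

_RANDOM_TYPES = frozenset({ErrorType.MLC_RANDOM, ErrorType.MU_RANDOM})


def magnitude_grid(error_type: ErrorType, step_multiplier: int = 1) -> np.ndarray:
    """Signed magnitude grid for an error type, zero excluded, symmetric.

    ``step_multiplier`` coarsens the grid (2 doubles the step) for
    reduced-size studies while keeping the range endpoints.
    """
    limit, step = MAGNITUDE_LIMITS[ErrorType(error_type)]
    step = step * step_multiplier
    n = int(round(limit / step))
    positives = np.round(np.arange(1, n + 1) * step, 10)
    return np.concatenate([-positives[::-1], positives])


@dataclass
class ErrorSpec:
    """One concrete error to inject.

    For random types, ``per_unit_draws`` (one value per segment for MU,
    one per leaf and segment for MLC) may be pre-drawn; once drawn, the
    recorded ``magnitude`` equals their signed mean — that realized mean,
    not the target grid value, is the label magnitude.
    """

    error_type: ErrorType
    magnitude: float
    per_unit_draws: np.ndarray | None = None
    banks_affected: Bank = Bank.BOTH

    def __post_init__(self) -> None:
        self.error_type = ErrorType(self.error_type)
        self.banks_affected = Bank(self.banks_affected)
        if self.magnitude == 0.0:
            raise ValueError("error magnitude must be nonzero")
        limit, _ = MAGNITUDE_LIMITS[self.error_type]
        slack = RANDOM_DRAW_SPREAD.get(self.error_type, 0.0)
        if abs(self.magnitude) > limit + slack + 1e-9:
            raise ValueError(
                f"magnitude {self.magnitude} outside the {self.error_type.value} "
                f"range ±{limit}"
            )
        if self.per_unit_draws is not None:
            self.per_unit_draws = np.asarray(self.per_unit_draws, dtype=float)
            if not np.isclose(self.magnitude, self.per_unit_draws.mean(), atol=1e-12):
                raise ValueError("recorded magnitude must equal the mean of per-unit draws")

    @property
    def is_random(self) -> bool:
        return self.error_type in _RANDOM_TYPES


@dataclass(frozen=True)
class LabelPair:
    """Level-1 (error type) and Level-2 (magnitude relevance) labels."""

    level1: ErrorType
    level2: Relevance


class ErrorApplication(NamedTuple):
    """A perturbed plan together with the concrete spec that produced it.

    For random error types the returned spec carries the realized per-unit
    draws and their signed mean as the label magnitude.
    """

    plan: TreatmentPlan
    spec: ErrorSpec

    @property
    def labels(self) -> LabelPair:
        return label_pair(self.spec)


def level2_label(error_type: ErrorType, magnitude: float) -> Relevance:
    """Classify a magnitude as relevant/irrelevant (inclusive threshold)."""
    if magnitude == 0.0:
        raise ValueError("magnitude must be nonzero")
    threshold = LEVEL2_THRESHOLDS[ErrorType(error_type)]
    return Relevance.RELEVANT if abs(magnitude) >= threshold else Relevance.IRRELEVANT


def label_pair(spec: ErrorSpec) -> LabelPair:
    return LabelPair(spec.error_type, level2_label(spec.error_type, spec.magnitude))


def _clamp_banks(a: np.ndarray, b: np.ndarray) -> int:
    """Close any crossed leaf pairs at their midpoint; return the count."""
    crossed = a > b
    n = int(crossed.sum())
    if n:
        mid = 0.5 * (a[crossed] + b[crossed])
        a[crossed] = mid
        b[crossed] = mid
    return n


def apply_error(
    plan: TreatmentPlan,
    spec: ErrorSpec,
    rng: np.random.Generator | None = None,
) -> ErrorApplication:
    """Apply a mechanical error to a copy of ``plan``.

    Systematic types apply ``spec.magnitude`` uniformly: collimator errors
    add it to every segment angle, MLC-systematic errors shift the selected
    bank(s) as a whole (BOTH translates the aperture along +x; a single
    bank moves in its field-opening direction for positive magnitude), and
    MU-systematic errors scale every segment MU by ``1 + magnitude/100``.

    Random types draw one value per segment (MU) or per leaf and segment
    (MLC) uniform on ``magnitude ± spread`` and record the realized signed
    mean in the returned spec.  Leaf shifts that would cross the opposing
    bank are clamped to zero gap.  The input plan is never modified.
    """
    spec = ErrorSpec(spec.error_type, spec.magnitude, spec.per_unit_draws, spec.banks_affected)
    perturbed = plan.copy()
    segments = [seg for arc in perturbed.arcs for seg in arc]
    m = spec.magnitude
    n_clamped = 0

    if spec.error_type is ErrorType.COLLIMATOR:
        for seg in segments:
            seg.collimator_angle += m

    elif spec.error_type is ErrorType.MLC_SYSTEMATIC:
        for seg in segments:
            a, b = seg.leaf_positions_bank_a, seg.leaf_positions_bank_b
            if spec.banks_affected is Bank.BOTH:
                a += m
                b += m
            elif spec.banks_affected is Bank.A:
                a -= m  # positive magnitude opens the left edge outward
            else:
                b += m
            n_clamped += _clamp_banks(a, b)

    elif spec.error_type is ErrorType.MU_SYSTEMATIC:
        for seg in segments:
            seg.mu *= 1.0 + m / 100.0

    elif spec.error_type is ErrorType.MLC_RANDOM:
        spread = RANDOM_DRAW_SPREAD[spec.error_type]
        draws = spec.per_unit_draws
        if draws is None:
            if rng is None:
                raise ValueError("random error types need an rng when draws are not given")
            n_units = sum(2 * seg.n_leaf_pairs for seg in segments)
            draws = rng.uniform(m - spread, m + spread, size=n_units)
        draws = np.asarray(draws, dtype=float)
        pos = 0
        for seg in segments:
            k = seg.n_leaf_pairs
            seg.leaf_positions_bank_a += draws[pos : pos + k]
            seg.leaf_positions_bank_b += draws[pos + k : pos + 2 * k]
            n_clamped += _clamp_banks(seg.leaf_positions_bank_a, seg.leaf_positions_bank_b)
            pos += 2 * k
        spec = ErrorSpec(spec.error_type, float(draws.mean()), draws, spec.banks_affected)

    elif spec.error_type is ErrorType.MU_RANDOM:
        spread = RANDOM_DRAW_SPREAD[spec.error_type]
        draws = spec.per_unit_draws
        if draws is None:
            if rng is None:
                raise ValueError("random error types need an rng when draws are not given")
            draws = rng.uniform(m - spread, m + spread, size=len(segments))
        draws = np.asarray(draws, dtype=float)
        for seg, p in zip(segments, draws):
            seg.mu *= 1.0 + p / 100.0
        spec = ErrorSpec(spec.error_type, float(draws.mean()), draws, spec.banks_affected)

    else:  # pragma: no cover - exhaustive enum
        raise ValueError(f"unknown error type {spec.error_type!r}")

    if n_clamped:
        logger.warning(
            "%s magnitude %+g: clamped %d crossed leaf pair(s) to zero gap",
            spec.error_type.value, m, n_clamped,
        )
    return ErrorApplication(perturbed, spec)
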