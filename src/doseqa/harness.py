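"""Factorial study orchestration.

Enumerates the full cross-product of classification level × dose-comparison
method × normalization × resolution (2 × 12 × 2 × 3 = 144 cells), runs the
simulate → inject → compare → preprocess → split → train → evaluate pipeline
for each cell on a shared synthetic image bank, and aggregates per-factor
accuracy summaries (median/quartiles) plus rank-sum comparisons between
factor groups.

All cells of one study see byte-identical raw comparison images: the plan
cohort, injected errors and cropped comparison images are generated once
per master seed and cached per method, so factor effects are never
confounded with sampling noise.  Every result row carries the seeds and
configuration needed to regenerate it.
"""

from __future__ import annotations

import itertools
import time
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import errors as err
from .classifier import (
    ArchitectureSpec,
    HpoConfig,
    SplitData,
    TrainConfig,
    evaluate_accuracy,
    split_dataset,
    train_model,
    tune_hyperparameters,
)
from .compare import ComparisonImage, Method, compare, n_channels
from .errors import Bank, ErrorSpec, ErrorType, Relevance, apply_error, magnitude_grid
from .plans import DoseImage, Modality, SimConfig, generate_plan, render_dose
from .preprocess import (
    Normalization,
    compute_dataset_stats,
    crop_to_field,
    normalize,
    resize_square,
)

__all__ = [
    "FactorialCell",
    "ExperimentResult",
    "StudyConfig",
    "ImageBank",
    "enumerate_cells",
    "build_image_bank",
    "run_study",
    "run_cell",
    "summarize",
    "compare_factors",
    "results_to_frame",
]

ALL_LEVELS = (1, 2)
ALL_METHODS = tuple(Method)
ALL_NORMS = (Normalization.MINMAX, Normalization.MEANSTD)
ALL_RESOLUTIONS = (32, 64, 128)

_LEVEL1_INDEX = {t: i for i, t in enumerate(ErrorType)}


@dataclass(frozen=True)
class FactorialCell:
    level: int
    method: Method
    normalization: Normalization
    resolution: int

    def __post_init__(self) -> None:
        if self.level not in ALL_LEVELS:
            raise ValueError("level must be 1 or 2")
        object.__setattr__(self, "method", Method(self.method))
        object.__setattr__(self, "normalization", Normalization(self.normalization))
        if self.resolution not in ALL_RESOLUTIONS:
            raise ValueError(f"resolution must be one of {ALL_RESOLUTIONS}")


@dataclass
class ExperimentResult:
    cell: FactorialCell
    test_accuracy_percent: float
    n_train: int
    n_val: int
    n_test: int
    seed: int
    runtime_s: float
    error: str | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.error is None and not 0.0 <= self.test_accuracy_percent <= 100.0:
            raise ValueError("accuracy must be a percentage in [0, 100]")


def enumerate_cells(
    levels: Sequence[int] = ALL_LEVELS,
    methods: Sequence[Method] = ALL_METHODS,
    norms: Sequence[Normalization] = ALL_NORMS,
    resolutions: Sequence[int] = ALL_RESOLUTIONS,
) -> list[FactorialCell]:
    """Full factorial cross-product in stable (level, method, norm, res) order."""
    if not (levels and methods and norms and resolutions):
        raise ValueError("every factor needs at least one value")
    return [
        FactorialCell(lv, Method(m), Normalization(n), r)
        for lv, m, n, r in itertools.product(levels, methods, norms, resolutions)
    ]


@dataclass
class StudyConfig:
    """Desk-scale study conditions.

    The defaults define the synthetic counterpart of the clinical study:
    VMAT-like single-arc delivery units, all five error types with the
    reduced (double-step) magnitude grid, errors cycled over the grid so
    Level-1 classes are exactly balanced, and a fixed small CNN
    (hyperparameter search optional via ``hpo_trials``).
    """

    sim: SimConfig = field(default_factory=SimConfig)
    n_units: int = 25
    samples_per_type: int = 5
    step_multiplier: int = 2
    level2_classes: int = 2  # 2 = relevant/irrelevant, 10 = joint type x relevance
    train: TrainConfig = field(default_factory=TrainConfig)
    hpo_trials: int = 0
    hpo_sampler: str = "random"
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_units < 1 or self.samples_per_type < 1:
            raise ValueError("study size must be positive")
        if self.level2_classes not in (2, 10):
            raise ValueError("level2_classes must be 2 (binary) or 10 (joint)")


@dataclass
class ImageBank:
    """Shared upstream artifacts of one study: doses, errors, comparisons.

    ``unit_index[i]`` maps error sample i to its reference arc;
    comparison images are computed lazily per method and cached, as are
    their field crops, so factorial cells reuse identical inputs.
    """

    ref_doses: list[DoseImage]
    err_doses: list[DoseImage]
    unit_index: np.ndarray
    specs: list[ErrorSpec]
    level1: np.ndarray  # class index 0-4 (error type order)
    level2: np.ndarray  # 0/1 binary or 0-9 joint
    relevance: np.ndarray  # 0/1 regardless of level2 encoding
    config: StudyConfig
    _raw_cache: dict = field(default_factory=dict)
    _crop_cache: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.err_doses)

    def comparison_images(self, method: Method) -> list[ComparisonImage]:
        method = Method(method)
        if method not in self._raw_cache:
            self._raw_cache[method] = [
                compare(self.ref_doses[u], ev, method)
                for u, ev in zip(self.unit_index, self.err_doses)
            ]
        return self._raw_cache[method]

    def cropped_images(self, method: Method, threshold: float = 0.10) -> list[ComparisonImage]:
        method = Method(method)
        key = (method, threshold)
        if key not in self._crop_cache:
            self._crop_cache[key] = [
                crop_to_field(c, self.ref_doses[u], threshold)
                for u, c in zip(self.unit_index, self.comparison_images(method))
            ]
        return self._crop_cache[key]

    def labels_for_level(self, level: int) -> np.ndarray:
        if level == 1:
            return self.level1
        return self.level2

    def manifest(self) -> pd.DataFrame:
        rows = []
        for i, spec in enumerate(self.specs):
            rows.append(
                {
                    "sample": i,
                    "unit": int(self.unit_index[i]),
                    "error_type": spec.error_type.value,
                    "magnitude": spec.magnitude,
                    "bank": spec.banks_affected.value,
                    "level1": int(self.level1[i]),
                    "level2": int(self.level2[i]),
                    "relevant": int(self.relevance[i]),
                    "seed": self.config.master_seed,
                }
            )
        return pd.DataFrame(rows)


def build_image_bank(config: StudyConfig) -> ImageBank:
    """Generate the shared raw inputs of a study from the master seed.

    ``n_units`` single-arc plans are generated and rendered error-free;
    then for each unit and error type, ``samples_per_type`` errors with
    magnitudes cycled over the (reduced) grid are injected and rendered.
    """
    ss = np.random.SeedSequence(config.master_seed)
    plan_seeds, error_seed = ss.spawn(2)
    plan_children = plan_seeds.spawn(config.n_units)
    err_rng = np.random.default_rng(error_seed)

    sim = replace(config.sim, n_arcs=1)
    ref_doses: list[DoseImage] = []
    plans = []
    for i in range(config.n_units):
        cfg_i = replace(sim, rng_seed=int(plan_children[i].generate_state(1)[0] % 2**31))
        plan = generate_plan(cfg_i)
        plans.append((plan, cfg_i))
        ref_doses.append(render_dose(plan, cfg_i, arc_index=0))

    err_doses: list[DoseImage] = []
    unit_index: list[int] = []
    specs: list[ErrorSpec] = []
    level1: list[int] = []
    level2: list[int] = []
    relevance: list[int] = []

    for type_idx, etype in enumerate(ErrorType):
        grid = magnitude_grid(etype, config.step_multiplier)
        counter = 0
        for u, (plan, cfg_u) in enumerate(plans):
            for _ in range(config.samples_per_type):
                magnitude = float(grid[counter % len(grid)])
                counter += 1
                bank = Bank.BOTH
                if etype is ErrorType.MLC_SYSTEMATIC:
                    bank = (Bank.A, Bank.B, Bank.BOTH)[err_rng.integers(3)]
                applied = apply_error(
                    plan, ErrorSpec(etype, magnitude, banks_affected=bank), err_rng
                )
                err_doses.append(render_dose(applied.plan, cfg_u, arc_index=0))
                unit_index.append(u)
                specs.append(applied.spec)
                rel = int(applied.labels.level2 is Relevance.RELEVANT)
                level1.append(type_idx)
                relevance.append(rel)
                level2.append(type_idx * 2 + rel if config.level2_classes == 10 else rel)

    return ImageBank(
        ref_doses=ref_doses,
        err_doses=err_doses,
        unit_index=np.array(unit_index),
        specs=specs,
        level1=np.array(level1),
        level2=np.array(level2),
        relevance=np.array(relevance),
        config=config,
    )


def _default_arch(cell: FactorialCell, n_ch: int, n_classes: int) -> ArchitectureSpec:
    return ArchitectureSpec(
        n_blocks=2,
        filters_per_block=(8, 16),
        kernel_side=3,
        n_dense=1,
        dense_units=(64,),
        n_input_channels=n_ch,
        n_classes=n_classes,
        input_side=cell.resolution,
    )


def prepare_cell_data(
    bank: ImageBank, cell: FactorialCell, split: np.ndarray
) -> SplitData:
    """Crop/normalize/resize the bank for one factorial cell.

    Normalization statistics are pooled over the training split only and
    reused unchanged for validation and test images.
    """
    cropped = bank.cropped_images(cell.method)
    train_idx = np.flatnonzero(split == "train")
    stats = compute_dataset_stats([cropped[i] for i in train_idx])
    x = np.stack(
        [resize_square(normalize(c, stats, cell.normalization), cell.resolution) for c in cropped]
    )
    y = bank.labels_for_level(cell.level)
    tr = split == "train"
    va = split == "val"
    te = split == "test"
    return SplitData(x[tr], y[tr], x[va], y[va], x[te], y[te])


def run_cell(
    bank: ImageBank,
    cell: FactorialCell,
    split: np.ndarray,
    train_cfg: TrainConfig,
    hpo_trials: int = 0,
    hpo_sampler: str = "random",
) -> ExperimentResult:
    t0 = time.perf_counter()
    data = prepare_cell_data(bank, cell, split)
    n_classes = int(bank.labels_for_level(cell.level).max()) + 1
    n_ch = n_channels(cell.method)
    if hpo_trials > 0:
        tuning = tune_hyperparameters(
            data,
            HpoConfig(n_trials=hpo_trials, sampler=hpo_sampler, seed=train_cfg.seed),
            base_cfg=train_cfg,
        )
        arch, cfg = tuning.arch, tuning.train_config
    else:
        arch, cfg = _default_arch(cell, n_ch, n_classes), train_cfg
    trained = train_model(data, arch, cfg)
    acc = evaluate_accuracy(trained.model, data.x_test, data.y_test)
    return ExperimentResult(
        cell=cell,
        test_accuracy_percent=acc,
        n_train=len(data.y_train),
        n_val=len(data.y_val),
        n_test=len(data.y_test),
        seed=cfg.seed,
        runtime_s=time.perf_counter() - t0,
        provenance={
            "master_seed": bank.config.master_seed,
            "n_units": bank.config.n_units,
            "samples_per_type": bank.config.samples_per_type,
            "step_multiplier": bank.config.step_multiplier,
            "modality": bank.config.sim.modality.value,
            "arch": {
                "n_blocks": arch.n_blocks,
                "filters_per_block": list(arch.filters_per_block),
                "dense_units": list(arch.dense_units),
            },
            "learning_rate": cfg.learning_rate,
            "batch_size": cfg.batch_size,
            "max_epochs": cfg.max_epochs,
            "epochs_run": trained.n_epochs,
            "hpo_trials": hpo_trials,
        },
    )


def run_study(
    cells: Sequence[FactorialCell],
    config: StudyConfig,
    bank: ImageBank | None = None,
) -> list[ExperimentResult]:
    """Run the factorial study over the given cells.

    One image bank and one stratified split are shared by every cell; a
    failing cell is recorded with its error message and the study
    continues.
    """
    bank = bank if bank is not None else build_image_bank(config)
    split_seed = int(np.random.SeedSequence((config.master_seed, 17)).generate_state(1)[0] % 2**31)
    split = split_dataset(bank.level1, config.train.split_fractions, split_seed)
    train_cfg = replace(config.train, seed=config.master_seed % 2**31)
    results = []
    for cell in cells:
        try:
            results.append(
                run_cell(bank, cell, split, train_cfg, config.hpo_trials, config.hpo_sampler)
            )
        except Exception as exc:  # noqa: BLE001 - per-cell failures must not kill the study
            results.append(
                ExperimentResult(
                    cell=cell,
                    test_accuracy_percent=0.0,
                    n_train=0,
                    n_val=0,
                    n_test=0,
                    seed=train_cfg.seed,
                    runtime_s=0.0,
                    error=f"{type(exc).__name__}: {exc}",
                )
            )
    return results


def results_to_frame(results: Iterable[ExperimentResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "level": r.cell.level,
                "method": r.cell.method.value,
                "normalization": r.cell.normalization.value,
                "resolution": r.cell.resolution,
                "accuracy": r.test_accuracy_percent,
                "n_train": r.n_train,
                "n_val": r.n_val,
                "n_test": r.n_test,
                "seed": r.seed,
                "runtime_s": r.runtime_s,
                "error": r.error,
            }
        )
    return pd.DataFrame(rows)


def summarize(results: Iterable[ExperimentResult] | pd.DataFrame, by: str = "method") -> pd.DataFrame:
    """Median/quartile/min/max accuracy grouped by one factor, per level."""
    df = results if isinstance(results, pd.DataFrame) else results_to_frame(results)
    df = df[df["error"].isna()] if "error" in df else df
    if df.empty:
        raise ValueError("no successful results to summarize")
    if by not in ("method", "normalization", "resolution", "level"):
        raise ValueError(f"cannot summarize by {by!r}")
    keys = ["level", by] if by != "level" else ["level"]
    g = df.groupby(keys)["accuracy"]
    out = g.agg(
        median="median",
        q1=lambda s: s.quantile(0.25),
        q3=lambda s: s.quantile(0.75),
        min="min",
        max="max",
        n="count",
    ).reset_index()
    return out


def compare_factors(
    results: Iterable[ExperimentResult] | pd.DataFrame,
    factor: str,
    value_a,
    value_b,
) -> dict:
    """Wilcoxon rank-sum between the accuracy distributions of two factor levels.

    A pragmatic replacement for a formal multiple-comparison procedure:
    reports the statistic and two-sided p-value for one pairwise contrast.
    """
    from scipy.stats import ranksums

    df = results if isinstance(results, pd.DataFrame) else results_to_frame(results)
    a = df.loc[df[factor] == value_a, "accuracy"].to_numpy()
    b = df.loc[df[factor] == value_b, "accuracy"].to_numpy()
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both factor groups need at least one result")
    stat, p = ranksums(a, b)
    return {
        "factor": factor,
        "a": value_a,
        "b": value_b,
        "median_a": float(np.median(a)),
        "median_b": float(np.median(b)),
        "statistic": float(stat),
        "p_value": float(p),
    }
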