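"""Training, tuning and evaluation of the error-identification CNN.

Responsibilities: stratified 70/10/20 train/validation/test splitting,
cross-entropy training with early stopping on the validation loss (best
weights restored), seeded hyperparameter search (random sampling or a
Gaussian-process expected-improvement sampler, with median pruning of
unpromising trials), and test-set accuracy.

The test split is consumed exclusively by :func:`evaluate_accuracy`;
dataset statistics, early stopping and tuning see only train/validation
data.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Callable, NamedTuple

import numpy as np
import pandas as pd

from .nn import Adam, ArchitectureSpec, SmallCNN, TrainingDiverged

__all__ = [
    "TrainConfig",
    "HpoConfig",
    "Sampler",
    "TrainedModel",
    "TuningResult",
    "ArchitectureSpec",
    "split_dataset",
    "train_model",
    "tune_hyperparameters",
    "evaluate_accuracy",
]

TRAIN, VAL, TEST = "train", "val", "test"


@dataclass
class TrainConfig:
    split_fractions: tuple[float, float, float] = (0.70, 0.10, 0.20)
    early_stop_patience: int = 5
    max_epochs: int = 30
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if not np.isclose(sum(self.split_fractions), 1.0):
            raise ValueError("split fractions must sum to 1")
        if self.early_stop_patience < 0 or self.max_epochs < 1:
            raise ValueError("invalid stopping configuration")
        if self.batch_size < 1 or self.learning_rate <= 0:
            raise ValueError("invalid optimizer configuration")


class Sampler(str, Enum):
    RANDOM = "random"
    BAYESIAN = "bayesian"


#: Default desk-scale search space for the hyperparameter search.
DEFAULT_SEARCH_SPACE: dict = {
    "n_blocks": [1, 2],
    "base_filters": [8, 16],
    "dense_units": [32, 64],
    "log10_lr": (-3.5, -2.0),
    "batch_size": [32, 64],
}


@dataclass
class HpoConfig:
    n_trials: int = 5
    sampler: Sampler = Sampler.RANDOM
    pruning: bool = True
    space: dict = field(default_factory=lambda: dict(DEFAULT_SEARCH_SPACE))
    pruning_warmup_epochs: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("need at least one trial")
        self.sampler = Sampler(self.sampler)


class SplitData(NamedTuple):
    """Preprocessed images/labels carved into the three splits."""

    x_train: np.ndarray
    y_train: np.ndarray
    x_val: np.ndarray
    y_val: np.ndarray
    x_test: np.ndarray
    y_test: np.ndarray


@dataclass
class TrainedModel:
    model: SmallCNN
    history: pd.DataFrame
    best_val_loss: float
    n_epochs: int
    stopped_early: bool


@dataclass
class TuningResult:
    arch: ArchitectureSpec
    train_config: TrainConfig
    trials: pd.DataFrame
    best_val_loss: float


def split_dataset(
    labels: np.ndarray,
    fractions: tuple[float, float, float] = (0.70, 0.10, 0.20),
    seed: int = 0,
) -> np.ndarray:
    """Stratified train/val/test assignment, one of {"train","val","test"} per item.

    Stratification is by the given (Level-1) labels: within each class the
    shuffled items are allocated by largest-remainder rounding of the split
    fractions, so per-class proportions match the global fractions to within
    one item, the partition is exhaustive and disjoint, and the assignment
    is deterministic per seed.
    """
    labels = np.asarray(labels)
    if not np.isclose(sum(fractions), 1.0):
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    out = np.empty(labels.shape[0], dtype=object)
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if idx.size < 3:
            raise ValueError(f"class {cls!r} has fewer than 3 items; cannot split")
        rng.shuffle(idx)
        ideal = np.array(fractions) * idx.size
        counts = np.floor(ideal).astype(int)
        for k in np.argsort(-(ideal - counts)):
            if counts.sum() == idx.size:
                break
            counts[k] += 1
        b1, b2 = counts[0], counts[0] + counts[1]
        out[idx[:b1]] = TRAIN
        out[idx[b1:b2]] = VAL
        out[idx[b2:]] = TEST
    return out.astype(str)


def train_model(
    data: SplitData,
    arch: ArchitectureSpec,
    cfg: TrainConfig,
    epoch_callback: Callable[[int, float], bool] | None = None,
) -> TrainedModel:
    """Train a :class:`SmallCNN` with early stopping on validation loss.

    Stops once the validation loss has failed to improve for more than
    ``early_stop_patience`` epochs (patience 0 stops at the first
    non-improvement) and restores the best-validation-loss weights.
    ``epoch_callback(epoch, val_loss)`` returning True aborts the trial
    early (used for pruning); the partial model is still returned.
    Deterministic for a fixed seed.
    """
    x_train = np.ascontiguousarray(data.x_train, dtype=float)
    y_train = np.asarray(data.y_train, dtype=int)
    if not np.all(np.isfinite(x_train)):
        raise ValueError("training images must be finite")
    rng = np.random.default_rng(cfg.seed)
    model = SmallCNN(arch, np.random.default_rng(rng.integers(2**31)))
    opt = Adam(model, lr=cfg.learning_rate)

    best_val = np.inf
    best_weights = model.get_weights()
    wait = 0
    rows = []
    stopped = False
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(x_train))
        epoch_loss = 0.0
        for start in range(0, len(order), cfg.batch_size):
            sel = order[start : start + cfg.batch_size]
            loss = model.loss_and_grads(x_train[sel], y_train[sel])
            if not np.isfinite(loss):
                raise TrainingDiverged(
                    f"non-finite training loss at epoch {epoch} "
                    f"(lr={cfg.learning_rate}); lower the learning rate"
                )
            opt.step()
            epoch_loss += loss * len(sel)
        val_loss = model.loss(data.x_val, np.asarray(data.y_val, dtype=int))
        rows.append(
            {"epoch": epoch, "train_loss": epoch_loss / len(order), "val_loss": val_loss}
        )
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_weights = model.get_weights()
            wait = 0
        else:
            wait += 1
            if wait > cfg.early_stop_patience:
                stopped = True
                break
        if epoch_callback is not None and epoch_callback(epoch, val_loss):
            stopped = True
            break
    model.set_weights(best_weights)
    return TrainedModel(model, pd.DataFrame(rows), float(best_val), len(rows), stopped)


def evaluate_accuracy(model: SmallCNN, x_test: np.ndarray, y_test: np.ndarray) -> float:
    """Test accuracy as a percentage: 100 × correct / total."""
    y_test = np.asarray(y_test, dtype=int)
    if len(y_test) == 0:
        raise ValueError("empty test set")
    pred = model.predict(np.asarray(x_test, dtype=float))
    return 100.0 * float(np.mean(pred == y_test))


# ---------------------------------------------------------------------------
# hyperparameter search
# ---------------------------------------------------------------------------

def _sample_params(space: dict, rng: np.random.Generator) -> dict:
    lo, hi = space["log10_lr"]
    return {
        "n_blocks": int(rng.choice(space["n_blocks"])),
        "base_filters": int(rng.choice(space["base_filters"])),
        "dense_units": int(rng.choice(space["dense_units"])),
        "log10_lr": float(rng.uniform(lo, hi)),
        "batch_size": int(rng.choice(space["batch_size"])),
    }


def _encode(params: dict) -> np.ndarray:
    return np.array(
        [
            params["n_blocks"],
            np.log2(params["base_filters"]),
            np.log2(params["dense_units"]),
            params["log10_lr"],
            np.log2(params["batch_size"]),
        ]
    )


def _params_to_configs(
    params: dict, base_cfg: TrainConfig, input_side: int, n_channels: int, n_classes: int,
    seed: int,
) -> tuple[ArchitectureSpec, TrainConfig]:
    nb = params["n_blocks"]
    filters = tuple(params["base_filters"] * (2**i) for i in range(nb))
    arch = ArchitectureSpec(
        n_blocks=nb,
        filters_per_block=filters,
        kernel_side=3,
        n_dense=1,
        dense_units=(params["dense_units"],),
        n_input_channels=n_channels,
        n_classes=n_classes,
        input_side=input_side,
    )
    cfg = replace(
        base_cfg,
        learning_rate=10.0 ** params["log10_lr"],
        batch_size=params["batch_size"],
        seed=seed,
    )
    return arch, cfg


def _propose_bayesian(
    space: dict,
    observed: list[tuple[dict, float]],
    rng: np.random.Generator,
    n_candidates: int = 64,
) -> dict:
    """Expected-improvement proposal from a GP surrogate over encoded params."""
    from sklearn.gaussian_process import GaussianProcessRegressor
    from sklearn.gaussian_process.kernels import Matern
    from scipy.stats import norm

    X = np.array([_encode(p) for p, _ in observed])
    y = np.array([v for _, v in observed])
    gp = GaussianProcessRegressor(
        kernel=Matern(nu=2.5, length_scale=np.ones(X.shape[1])),
        normalize_y=True,
        alpha=1e-6,
        random_state=int(rng.integers(2**31)),
    )
    gp.fit(X, y)
    candidates = [_sample_params(space, rng) for _ in range(n_candidates)]
    Xc = np.array([_encode(p) for p in candidates])
    mu, sd = gp.predict(Xc, return_std=True)
    best = y.min()
    sd = np.maximum(sd, 1e-12)
    z = (best - mu) / sd
    ei = (best - mu) * norm.cdf(z) + sd * norm.pdf(z)
    return candidates[int(np.argmax(ei))]


def tune_hyperparameters(
    data: SplitData,
    hpo: HpoConfig,
    base_cfg: TrainConfig | None = None,
) -> TuningResult:
    """Seeded hyperparameter search minimizing validation loss.

    RANDOM draws ``n_trials`` configurations from the search space;
    BAYESIAN seeds the first three trials randomly and then proposes by
    expected improvement under a Gaussian-process surrogate.  With pruning
    enabled, a trial whose validation loss exceeds the median of previous
    trials' losses at the same epoch (after a warmup) is aborted early;
    pruned trials keep their best partial loss, so a best configuration is
    returned even if every trial was pruned.
    """
    base_cfg = base_cfg or TrainConfig()
    rng = np.random.default_rng(hpo.seed)
    input_side = data.x_train.shape[-1]
    n_channels = data.x_train.shape[1]
    n_classes = int(np.max(data.y_train)) + 1

    epoch_losses: list[list[float]] = []  # per completed/pruned trial
    observed: list[tuple[dict, float]] = []
    rows = []
    best: tuple[float, ArchitectureSpec, TrainConfig] | None = None

    for trial in range(hpo.n_trials):
        if hpo.sampler is Sampler.BAYESIAN and len(observed) >= 3:
            params = _propose_bayesian(hpo.space, observed, rng)
        else:
            params = _sample_params(hpo.space, rng)
        trial_seed = int(rng.integers(2**31))
        arch, cfg = _params_to_configs(
            params, base_cfg, input_side, n_channels, n_classes, trial_seed
        )

        losses_this: list[float] = []
        pruned = {"flag": False}

        def callback(epoch: int, val_loss: float) -> bool:
            losses_this.append(val_loss)
            if not hpo.pruning or epoch < hpo.pruning_warmup_epochs:
                return False
            peers = [h[epoch] for h in epoch_losses if len(h) > epoch]
            if len(peers) >= 2 and val_loss > float(np.median(peers)):
                pruned["flag"] = True
                return True
            return False

        result = train_model(data, arch, cfg, epoch_callback=callback)
        epoch_losses.append(losses_this)
        observed.append((params, result.best_val_loss))
        rows.append(
            {
                "trial": trial,
                **params,
                "val_loss": result.best_val_loss,
                "epochs": result.n_epochs,
                "pruned": pruned["flag"],
                "seed": trial_seed,
            }
        )
        if best is None or result.best_val_loss < best[0]:
            best = (result.best_val_loss, arch, cfg)

    assert best is not None
    return TuningResult(best[1], best[2], pd.DataFrame(rows), best[0])
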