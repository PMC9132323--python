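"""Training and four-condition evaluation of image classifiers.

The protocol: minimise cross-entropy with Adam (mini-batch 32), reduce the
learning rate by a factor of 10 when the training loss plateaus, and stop
once the loss has converged (improvement below a small threshold for a run
of consecutive epochs).  Results are averaged over several seed
initialisations and scored per test condition with the shared scoring rule
(shape category for Both/Conflict/Shape, non-shape category for Non-shape).

The default desk-scale preset is a compact convolutional network trained
from scratch on 64x64 rasters; pretrained weights for any architecture can
be supplied as an .npz file (they are never downloaded), and
``freeze_backbone`` restricts learning to the final linear layer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .. import evaluation
from ..evaluation import ConditionReport, mean_ci
from ..stimuli import (
    DatasetManifest,
    N_CATEGORIES,
    RenderConfig,
    StimulusError,
    generate_dataset,
    render,
)
from . import nn

ARCHITECTURES = ("compact", "compact_deep", "linear")


class TrainError(RuntimeError):
    """Training diverged or was misconfigured."""


@dataclass(frozen=True)
class TrainConfig:
    """Hyper-parameters of one training run.

    ``learning_rate=None`` resolves to 1e-5 when fine-tuning user-supplied
    weights and 1e-3 when training from scratch.  ``input_size`` must be a
    multiple of 8 (two stride-2 convolutions plus one 2x2 pool).
    """

    architecture: str = "compact"
    weights_init: str | Path = "scratch"   # "scratch" or a .npz weights file
    freeze_backbone: bool = False
    learning_rate: float | None = None
    batch_size: int = 32
    plateau_factor: float = 10.0
    plateau_patience: int = 3
    convergence_threshold: float = 1e-4
    convergence_patience: int = 5
    max_epochs: int = 80
    n_seeds: int = 10
    input_size: int = 224

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise TrainError(f"unknown architecture {self.architecture!r}")
        if self.batch_size < 1:
            raise TrainError("batch size must be >= 1")
        if self.plateau_factor <= 1:
            raise TrainError("plateau decay factor must be > 1")
        if self.input_size % 8:
            raise TrainError("input size must be a multiple of 8")

    @property
    def lr(self) -> float:
        if self.learning_rate is not None:
            return self.learning_rate
        return 1e-3 if self.weights_init == "scratch" else 1e-5

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TrainConfig":
        """Load a config from a YAML mapping (e.g. a pretrained-weights
        path under ``weights_init``); unknown keys are rejected."""
        import yaml

        payload = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(payload) - known
        if unknown:
            raise TrainError(f"unknown config keys {sorted(unknown)}")
        return cls(**payload)


def desk_config(**overrides) -> TrainConfig:
    """Desk-scale preset: compact net from scratch at 64x64."""
    base = TrainConfig(architecture="compact", input_size=64)
    return replace(base, **overrides)


# --------------------------------------------------------------------------
# model construction
# --------------------------------------------------------------------------


def build_classifier(config: TrainConfig, n_classes: int = N_CATEGORIES,
                     seed: int = 0) -> nn.Sequential:
    """Instantiate a classifier with ``n_classes`` outputs.

    With ``freeze_backbone`` every parameter except the final linear layer
    is frozen.  ``weights_init`` other than "scratch" names an .npz file of
    parameter arrays (saved with :func:`save_weights`) loaded before any
    freezing is applied.
    """
    rng = np.random.default_rng(seed)
    s = config.input_size
    if config.architecture == "linear":
        model = nn.Sequential([
            nn.Flatten(),
            nn.Linear(3 * s * s, n_classes, rng),
        ])
    elif config.architecture == "compact_deep":
        model = nn.Sequential([
            nn.Conv2d(3, 16, 3, 2, 1, rng), nn.ReLU(),
            nn.Conv2d(16, 32, 3, 1, 1, rng), nn.ReLU(),
            nn.Conv2d(32, 32, 3, 2, 1, rng), nn.ReLU(),
            nn.MaxPool2(),
            nn.Flatten(),
            nn.Linear(32 * (s // 8) ** 2, 64, rng), nn.ReLU(),
            nn.Linear(64, n_classes, rng),
        ])
    else:
        model = nn.Sequential([
            nn.Conv2d(3, 16, 3, 2, 1, rng), nn.ReLU(),
            nn.Conv2d(16, 32, 3, 2, 1, rng), nn.ReLU(),
            nn.MaxPool2(),
            nn.Flatten(),
            nn.Linear(32 * (s // 8) ** 2, 64, rng), nn.ReLU(),
            nn.Linear(64, n_classes, rng),
        ])
    if config.weights_init != "scratch":
        load_weights(model, config.weights_init)
    if config.freeze_backbone:
        head = final_layer(model)
        for p in model.parameters():
            p.frozen = True
        for p in head.parameters():
            p.frozen = False
    return model


def final_layer(model: nn.Sequential) -> nn.Linear:
    for layer in reversed(model.layers):
        if isinstance(layer, nn.Linear):
            return layer
    raise TrainError("model has no linear layer")


def trainable_parameter_count(model: nn.Sequential) -> int:
    return sum(p.value.size for p in model.parameters() if not p.frozen)


def save_weights(model: nn.Sequential, path: str | Path) -> None:
    np.savez(path, *[p.value for p in model.parameters()])


def load_weights(model: nn.Sequential, path: str | Path) -> None:
    path = Path(path)
    if not path.exists():
        raise TrainError(f"weights file {path} not found")
    with np.load(path) as data:
        arrays = [data[k] for k in data.files]
    params = model.parameters()
    if len(arrays) != len(params):
        raise TrainError("weights file does not match the architecture")
    for p, a in zip(params, arrays):
        if p.value.shape != a.shape:
            raise TrainError(f"shape mismatch for {p.name}: "
                             f"{p.value.shape} vs {a.shape}")
        p.value[...] = a


# --------------------------------------------------------------------------
# data preparation
# --------------------------------------------------------------------------


def _rasterise(specs, palette, templates, render_config: RenderConfig,
               input_size: int) -> np.ndarray:
    from PIL import Image

    out = np.empty((len(specs), 3, input_size, input_size), dtype=np.float32)
    for i, spec in enumerate(specs):
        raster = render(spec, palette, templates, render_config).raster
        img = Image.fromarray(raster).resize((input_size, input_size),
                                             Image.BOX)
        out[i] = np.asarray(img, dtype=np.float32).transpose(2, 0, 1) / 255.0
    return out - 0.5


def prepare_arrays(manifest: DatasetManifest, input_size: int,
                   render_config: RenderConfig | None = None) -> dict:
    """Render a manifest into CNN-ready arrays.

    Returns ``{"train": (X, y)} | {condition: (X, y_scored)}`` with X of
    shape (n, 3, s, s) in [-0.5, 0.5] and 0-based integer targets (training
    targets are the category labels; test targets follow the scoring rule).
    """
    render_config = RenderConfig() if render_config is None else render_config
    out = {}
    train = manifest.train_rows
    if train:
        X = _rasterise(train, manifest.palette, manifest.templates,
                       render_config, input_size)
        y = np.array([s.label - 1 for s in train], dtype=np.int64)
        out["train"] = (X, y)
    for cond in ("both", "conflict", "shape", "nonshape"):
        specs = manifest.subset(cond)
        if not specs:
            continue
        X = _rasterise(specs, manifest.palette, manifest.templates,
                       render_config, input_size)
        y = np.array([evaluation.scored_label(s) - 1 for s in specs],
                     dtype=np.int64)
        out[cond] = (X, y)
    return out


# --------------------------------------------------------------------------
# training loop
# --------------------------------------------------------------------------


def accuracy(model: nn.Sequential, X: np.ndarray, y: np.ndarray,
             batch_size: int = 256) -> float:
    hits = 0
    for i in range(0, len(X), batch_size):
        logits = model.forward(X[i:i + batch_size])
        hits += int((logits.argmax(axis=1) == y[i:i + batch_size]).sum())
    return hits / len(X)


def train(model: nn.Sequential, X: np.ndarray, y: np.ndarray,
          config: TrainConfig, seed: int = 0) -> pd.DataFrame:
    """Train to convergence; returns the per-epoch history
    (epoch, loss, train_accuracy, lr).

    Stops when the epoch loss has improved by less than
    ``convergence_threshold`` for ``convergence_patience`` consecutive
    epochs, or at ``max_epochs``.  The learning rate drops by
    ``plateau_factor`` after ``plateau_patience`` epochs without
    improvement.  Deterministic given (model init, seed).
    """
    rng = np.random.default_rng(seed)
    optim = nn.Adam(model.parameters(), lr=config.lr)
    history = []
    best_loss = np.inf
    stall_sched = 0
    stall_conv = 0
    n = len(X)
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        losses = []
        hits = 0
        for i in range(0, n, config.batch_size):
            idx = order[i:i + config.batch_size]
            logits = model.forward(X[idx])
            loss, grad = nn.softmax_cross_entropy(logits, y[idx])
            if not np.isfinite(loss):
                raise TrainError(
                    f"non-finite loss at epoch {epoch}, batch {i // config.batch_size}"
                    f" (lr={optim.lr:g}); reduce the learning rate")
            model.backward(grad)
            optim.step()
            losses.append(loss)
            hits += int((logits.argmax(axis=1) == y[idx]).sum())
        epoch_loss = float(np.mean(losses))
        history.append({"epoch": epoch, "loss": epoch_loss,
                        "train_accuracy": hits / n, "lr": optim.lr})
        improvement = best_loss - epoch_loss
        if improvement < config.convergence_threshold:
            stall_conv += 1
            stall_sched += 1
        else:
            stall_conv = 0
            stall_sched = 0
        best_loss = min(best_loss, epoch_loss)
        if stall_conv >= config.convergence_patience:
            break
        if stall_sched >= config.plateau_patience:
            optim.lr /= config.plateau_factor
            stall_sched = 0
    return pd.DataFrame(history)


def evaluate(model: nn.Sequential, arrays: dict) -> dict[str, float]:
    """Accuracy per test condition (scored labels baked into ``arrays``)."""
    out = {}
    for cond in ("both", "conflict", "shape", "nonshape"):
        if cond not in arrays:
            continue
        X, y = arrays[cond]
        out[cond] = accuracy(model, X, y)
    if not out:
        raise StimulusError("no test conditions to evaluate")
    return out


# --------------------------------------------------------------------------
# multi-seed experiment driver
# --------------------------------------------------------------------------


@dataclass
class EvalReport:
    """Per-seed, per-condition accuracies plus training diagnostics."""

    experiment_id: str
    variant: str
    config: TrainConfig
    reports: list[ConditionReport] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)
    histories: list[pd.DataFrame] = field(default_factory=list)

    def aggregate(self) -> dict[str, dict[str, float]]:
        """Mean accuracy and 95% CI half-width per condition over seeds."""
        out = {}
        conds = sorted({c for r in self.reports for c in r.metrics})
        for cond in conds:
            vals = [r.metrics[cond] for r in self.reports if cond in r.metrics]
            mean, ci = mean_ci(vals)
            out[cond] = {"mean": mean, "ci95": ci, "n_seeds": len(vals)}
        return out

    def to_json(self, path: str | Path) -> None:
        payload = {
            "experiment": self.experiment_id,
            "variant": self.variant,
            "architecture": self.config.architecture,
            "input_size": self.config.input_size,
            "train_accuracy": self.train_accuracy,
            "per_seed": [{"learner": r.learner_id, **r.metrics}
                         for r in self.reports],
            "aggregate": self.aggregate(),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def run_experiment(
    experiment_id: str,
    variant: str,
    config: TrainConfig | None = None,
    n_seeds: int | None = None,
    n_train: int = 2000,
    n_test_per_condition: int = 500,
    dataset_seed: int = 0,
    render_config: RenderConfig | None = None,
) -> EvalReport:
    """Generate a dataset, train ``n_seeds`` classifiers and evaluate each
    on every test condition the experiment defines."""
    config = desk_config() if config is None else config
    n_seeds = config.n_seeds if n_seeds is None else n_seeds
    manifest = generate_dataset(experiment_id, variant, n_train=n_train,
                                n_test_per_condition=n_test_per_condition,
                                seed=dataset_seed, symbolic_only=True)
    arrays = prepare_arrays(manifest, config.input_size, render_config)
    X, y = arrays["train"]
    report = EvalReport(experiment_id, variant, config)
    for seed in range(n_seeds):
        model = build_classifier(config, seed=seed)
        history = train(model, X, y, config, seed=seed)
        metrics = evaluate(model, arrays)
        report.histories.append(history)
        report.train_accuracy.append(accuracy(model, X, y))
        report.reports.append(ConditionReport(
            learner_id=f"{experiment_id}_{variant}_seed{seed}",
            experiment_id=experiment_id,
            variant=variant,
            metrics=metrics,
            n_per_condition={c: len(arrays[c][1]) for c in metrics},
        ))
    return report
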