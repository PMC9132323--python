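"""Scoring rules, condition-pattern classification and report plumbing.

Shared by the ideal observer and the CNN harness.  Accuracy on Both,
Conflict and Shape trials is scored against the category predicted by the
shape feature; accuracy on Non-shape trials against the category predicted
by the non-shape feature.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .stimuli import TEST_CONDITIONS, StimulusError, StimulusSpec

CHANCE = 0.2  # 1-in-5 categories

_PATTERN_NAMES = {
    ("high", "high", "high", "low"): "shape-reliant",
    ("high", "low", "low", "high"): "nonshape-reliant",
}


def scored_label(spec: StimulusSpec) -> int:
    """Category against which a test trial is scored.

    Both/Conflict/Shape: the shape category; Non-shape: the non-shape
    category.  Training specs have no scored label.
    """
    if spec.condition not in TEST_CONDITIONS:
        raise StimulusError(f"no scoring rule for condition {spec.condition!r}")
    if spec.condition == "nonshape":
        assert spec.nonshape_category is not None
        return spec.nonshape_category
    assert spec.shape_id is not None
    return spec.shape_id


@dataclass
class ConditionReport:
    """Per-condition metric for one learner (one model run or seed)."""

    learner_id: str
    experiment_id: str
    variant: str
    metrics: dict[str, float]                 # condition -> accuracy
    posterior: dict[str, float] | None = None  # ideal observer only
    n_per_condition: dict[str, int] = field(default_factory=dict)
    checkpoint: int | None = None

    def __post_init__(self) -> None:
        unknown = set(self.metrics) - set(TEST_CONDITIONS)
        if unknown:
            raise StimulusError(f"unknown conditions {sorted(unknown)}")
        for cond, v in self.metrics.items():
            if not 0.0 <= v <= 1.0:
                raise StimulusError(f"metric for {cond!r} outside [0, 1]")


@dataclass(frozen=True)
class PatternCall:
    """Qualitative level per condition plus the inferred reliance pattern."""

    levels: tuple[str, str, str, str]  # both, conflict, shape, nonshape
    label: str


def classify_pattern(report: ConditionReport, chance: float = CHANCE,
                     high_threshold: float = 0.5, low_threshold: float = 0.3
                     ) -> PatternCall:
    """Map the four condition metrics to a reliance pattern.

    Levels: high (>= high_threshold), low (<= low_threshold), else medium.
    high-high-high-low => shape-reliant; high-low-low-high =>
    nonshape-reliant; high Both with medium-or-better Conflict and high
    Shape and Non-shape => both-features; all low => unlearned; anything
    else => mixed.  The thresholds are conventions, exposed as arguments.
    """
    missing = [c for c in TEST_CONDITIONS if c not in report.metrics]
    if missing:
        raise StimulusError(f"missing conditions {missing}")

    def level(v: float) -> str:
        if v >= high_threshold:
            return "high"
        if v <= low_threshold:
            return "low"
        return "medium"

    levels = tuple(level(report.metrics[c]) for c in TEST_CONDITIONS)
    if levels in _PATTERN_NAMES:
        label = _PATTERN_NAMES[levels]
    elif all(lv == "low" for lv in levels):
        label = "unlearned"
    elif (levels[0] == "high" and levels[1] in ("medium", "high")
          and levels[2] == "high" and levels[3] == "high"):
        label = "both-features"
    else:
        label = "mixed"
    return PatternCall(levels, label)


def split_groups(reports: list[ConditionReport]
                 ) -> tuple[list[ConditionReport], list[ConditionReport]]:
    """Split learners into shape-reliant vs non-shape-reliant groups.

    A learner goes to the non-shape group when its Non-shape metric exceeds
    its Shape metric; ties go to the shape group.  The split partitions the
    input (disjoint and exhaustive).
    """
    if not reports:
        raise StimulusError("no reports to split")
    shape_group, nonshape_group = [], []
    for rep in reports:
        try:
            s, ns = rep.metrics["shape"], rep.metrics["nonshape"]
        except KeyError as exc:
            raise StimulusError(f"report {rep.learner_id} lacks {exc}") from exc
        (nonshape_group if ns > s else shape_group).append(rep)
    return shape_group, nonshape_group


def group_mean_metrics(group: list[ConditionReport]) -> dict[str, float]:
    conds = sorted({c for rep in group for c in rep.metrics})
    return {c: float(np.mean([rep.metrics[c] for rep in group if c in rep.metrics]))
            for c in conds}


def mean_ci(values, confidence: float = 0.95) -> tuple[float, float]:
    """Mean and normal-approximation confidence half-width over learners."""
    from scipy import stats

    values = np.asarray(values, dtype=float)
    if values.size <= 1:
        return float(values.mean()) if values.size else float("nan"), 0.0
    z = stats.norm.ppf(0.5 + confidence / 2)
    return float(values.mean()), float(z * values.std(ddof=1) / np.sqrt(values.size))


def reports_to_frame(reports: list[ConditionReport]) -> pd.DataFrame:
    """Tidy frame: one row per (learner, condition)."""
    records = []
    for rep in reports:
        for cond, v in rep.metrics.items():
            records.append({
                "learner": rep.learner_id,
                "experiment": rep.experiment_id,
                "variant": rep.variant,
                "checkpoint": rep.checkpoint,
                "condition": cond,
                "accuracy": v,
                "mean_posterior": (None if rep.posterior is None
                                   else rep.posterior.get(cond)),
                "n": rep.n_per_condition.get(cond),
            })
    return pd.DataFrame.from_records(records)


def make_report(reports: list[ConditionReport],
                out_dir: str | Path,
                curves: pd.DataFrame | None = None,
                plots: bool = False) -> dict[str, Path]:
    """Write tidy CSVs plus a JSON summary (and optional bar/curve figures).

    Returns the paths written, keyed by artefact name.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    frame = reports_to_frame(reports)
    paths["conditions_csv"] = out / "conditions.csv"
    frame.to_csv(paths["conditions_csv"], index=False)

    summary = {}
    for (exp, var), sub in frame.groupby(["experiment", "variant"]):
        conds = {}
        for cond, cc in sub.groupby("condition"):
            mean, ci = mean_ci(cc["accuracy"].to_numpy())
            conds[cond] = {"mean_accuracy": mean, "ci95": ci,
                           "n_learners": int(cc["learner"].nunique())}
        summary[f"{exp}_{var}"] = conds
    paths["summary_json"] = out / "summary.json"
    paths["summary_json"].write_text(json.dumps(summary, indent=1, sort_keys=True))

    if curves is not None:
        paths["curves_csv"] = out / "curves.csv"
        curves.to_csv(paths["curves_csv"], index=False)

    if plots:
        _plot_report(frame, curves, out, paths)
    return paths


def _plot_report(frame: pd.DataFrame, curves: pd.DataFrame | None,
                 out: Path, paths: dict[str, Path]) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    groups = list(frame.groupby(["experiment", "variant"]))
    fig, axes = plt.subplots(1, max(len(groups), 1),
                             figsize=(3 * max(len(groups), 1), 3), squeeze=False)
    for ax, ((exp, var), sub) in zip(axes[0], groups):
        means = sub.groupby("condition")["accuracy"].mean()
        order = [c for c in TEST_CONDITIONS if c in means.index]
        ax.bar(range(len(order)), [means[c] for c in order])
        ax.axhline(CHANCE, ls="--", c="k", lw=1)
        ax.set_xticks(range(len(order)), order, rotation=45)
        ax.set_ylim(0, 1)
        ax.set_title(f"{exp} {var}")
    fig.tight_layout()
    paths["bars_png"] = out / "bars.png"
    fig.savefig(paths["bars_png"], dpi=120)
    plt.close(fig)

    if curves is not None and not curves.empty:
        fig, ax = plt.subplots(figsize=(4, 3))
        acc = curves[curves["metric"] == "accuracy"] if "metric" in curves else curves
        for cond, sub in acc.groupby("condition"):
            ax.plot(sub["checkpoint"], sub["value"], marker="o", label=cond)
        ax.axhline(CHANCE, ls="--", c="k", lw=1)
        ax.set_xlabel("training trials")
        ax.set_ylabel("accuracy")
        ax.legend(fontsize=7)
        fig.tight_layout()
        paths["curves_png"] = out / "curves.png"
        fig.savefig(paths["curves_png"], dpi=120)
        plt.close(fig)
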