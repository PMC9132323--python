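"""Sequential Bayesian ideal observer over categorical stimulus features.

The model is a naive-Bayes categoriser with Dirichlet-multinomial
class-conditionals.  For a test vector x and class c,

    p(Y=c | x, D)  ∝  p(Y=c) · Π_f p(X^f = x^f | Y=c, D)

and each class-conditional is the posterior predictive of a categorical
variable under a Dirichlet prior (α = 1 everywhere: Laplace smoothing),

    p(X^f = k | Y=c, D) = (N_k + α_k) / Σ_v (N_v + α_v),

where N_k counts how often channel f took value k in the class-c training
trials.  Updating is just counting, so the model is exchangeable: any
permutation of a training batch yields the same posterior.

Segment-colour experiments (exp2-family) carry their non-shape cue as the
colours of the five segments.  These are modelled as one multinomial block:
five draws from a single 20-colour categorical distribution with a
Dir(α=1) prior, whose posterior predictive for a count vector n is the
Dirichlet-multinomial compound.  Treating the twenty counts as independent
categoricals instead would double-count the evidence (each observed colour
would also be scored as an "absence" on nineteen other channels) and makes
the colour cue crush the shape cue on Conflict trials; the block model is
what puts the two cues in exact balance there (likelihood factor
(N+1)/(N·/K+..) for shape against the same factor for colour), matching the
near-0.50 Conflict split this design produces when both cues are fully
predictive.  The per-location channels of the exp1 family, by contrast,
really are separate observations — an empty diagnostic location is a visible
background patch — which is why the patch cue dominates shape there.

Posteriors are accumulated in log space, so the 26-channel exp1/exp2
products cannot underflow.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from . import evaluation
from .features import FeatureSchema, FeatureVector, extract, schema_for
from .stimuli import N_CATEGORIES, StimulusError, StimulusSpec, generate_dataset

NORMALISATION_TOL = 1e-12


@dataclass
class PosteriorDistribution:
    """Probabilities over the five categories (non-negative, sum to one)."""

    probabilities: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if p.shape != (N_CATEGORIES,) or np.any(p < 0):
            raise StimulusError("posterior must be 5 non-negative probabilities")
        if abs(p.sum() - 1.0) > 1e-9:
            raise StimulusError("posterior must sum to 1")
        self.probabilities = p

    def __getitem__(self, label: int) -> float:
        return float(self.probabilities[label - 1])

    def argmax_label(self) -> int:
        # ties break toward the lowest class index (np.argmax is first-max)
        return int(np.argmax(self.probabilities)) + 1


@dataclass
class DirichletCountsModel:
    """Per-class observation counts plus Dirichlet hyper-parameters.

    ``cat_counts[j]`` is a (5, K_j) table for the j-th categorical channel;
    ``block_counts`` is a (5, 20) table of segment-colour draws for the
    exp2-family multinomial block (``None`` otherwise).  θ is integrated out
    analytically and never stored.
    """

    schema: FeatureSchema
    alpha: float = 1.0
    class_prior: np.ndarray = field(
        default_factory=lambda: np.full(N_CATEGORIES, 1.0 / N_CATEGORIES))
    cat_counts: list[np.ndarray] = field(default_factory=list)
    block_counts: np.ndarray | None = None
    n_per_class: np.ndarray = field(
        default_factory=lambda: np.zeros(N_CATEGORIES, dtype=np.int64))

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise StimulusError("alpha must be positive")
        self.class_prior = np.asarray(self.class_prior, dtype=float)
        if self.class_prior.shape != (N_CATEGORIES,) or np.any(self.class_prior < 0):
            raise StimulusError("class prior must be 5 non-negative weights")
        self.class_prior = self.class_prior / self.class_prior.sum()
        if not self.cat_counts:
            self.cat_counts = [
                np.zeros((N_CATEGORIES, self.schema.channels[j].cardinality),
                         dtype=np.int64)
                for j in self.schema.categorical_indices()
            ]
        if self.schema.count_block is not None and self.block_counts is None:
            lo, hi = self.schema.count_block
            self.block_counts = np.zeros((N_CATEGORIES, hi - lo), dtype=np.int64)

    # -- bookkeeping -------------------------------------------------------

    def _cat_value_index(self, j_cat: int, value: int) -> int:
        ch = self.schema.channels[self.schema.categorical_indices()[j_cat]]
        if not ch.contains(value):
            raise StimulusError(f"value {value} outside channel {ch.name!r}")
        return value - ch.lo


def init_model(schema: FeatureSchema, alpha: float = 1.0,
               class_prior=None) -> DirichletCountsModel:
    """Fresh model with all counts zero (flat Dirichlet prior everywhere)."""
    kwargs = {} if class_prior is None else {"class_prior": class_prior}
    return DirichletCountsModel(schema=schema, alpha=alpha, **kwargs)


def update(model: DirichletCountsModel, fv: FeatureVector, label: int
           ) -> DirichletCountsModel:
    """Record one labelled training trial (in place; returns the model).

    Counting is order-independent: replaying a batch in any permutation
    produces an identical model.
    """
    if fv.schema.experiment_id != model.schema.experiment_id:
        raise StimulusError("feature vector does not match the model schema")
    if not 1 <= label <= N_CATEGORIES:
        raise StimulusError(f"label {label} outside 1..{N_CATEGORIES}")
    c = label - 1
    for j_cat, j in enumerate(model.schema.categorical_indices()):
        k = model._cat_value_index(j_cat, fv.values[j])
        model.cat_counts[j_cat][c, k] += 1
    if model.schema.count_block is not None:
        lo, hi = model.schema.count_block
        counts = np.asarray(fv.values[lo:hi], dtype=np.int64)
        if counts.sum() != model.schema.count_total:
            raise StimulusError("count channels must sum to the segment total")
        model.block_counts[c] += counts
    model.n_per_class[c] += 1
    return model


def fit(model: DirichletCountsModel, specs, labels=None) -> DirichletCountsModel:
    """Sequentially update on a list of specs (labels default to spec.label)."""
    for i, spec in enumerate(specs):
        label = spec.label if labels is None else labels[i]
        update(model, extract(spec, model.schema), label)
    return model


def class_conditional(model: DirichletCountsModel, channel: int | str,
                      value: int, label: int) -> float:
    """Posterior-predictive probability that the channel takes ``value``
    under class ``label``.

    For categorical channels this is (N_k + α)/(Σ_v N_v + α); for a
    segment-count channel it is the beta-binomial marginal of the
    multinomial block.  Either way the values sum to one over the channel
    domain for fixed (channel, class).
    """
    if isinstance(channel, str):
        names = [ch.name for ch in model.schema.channels]
        if channel not in names:
            raise StimulusError(f"unknown channel {channel!r}")
        channel = names.index(channel)
    if not 0 <= channel < model.schema.n_channels:
        raise StimulusError(f"channel index {channel} out of range")
    ch = model.schema.channels[channel]
    if not ch.contains(value):
        raise StimulusError(f"value {value} outside channel {ch.name!r}")
    c = label - 1
    cat_idx = model.schema.categorical_indices()
    if channel in cat_idx:
        j_cat = cat_idx.index(channel)
        counts = model.cat_counts[j_cat][c]
        return float((counts[value - ch.lo] + model.alpha)
                     / (counts.sum() + ch.cardinality * model.alpha))
    # beta-binomial marginal of the Dirichlet-multinomial block
    lo, _ = model.schema.count_block
    a = model.block_counts[c].astype(float) + model.alpha
    a_v = a[channel - lo]
    a_rest = a.sum() - a_v
    n = model.schema.count_total
    k = value
    log_p = (gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
             + gammaln(k + a_v) + gammaln(n - k + a_rest) + gammaln(a_v + a_rest)
             - gammaln(a_v) - gammaln(a_rest) - gammaln(n + a_v + a_rest))
    return float(np.exp(log_p))


def log_likelihood(model: DirichletCountsModel, fv: FeatureVector) -> np.ndarray:
    """log p(x | Y=c, D) for every class c (length-5 array)."""
    out = np.zeros(N_CATEGORIES)
    alpha = model.alpha
    for j_cat, j in enumerate(model.schema.categorical_indices()):
        ch = model.schema.channels[j]
        k = fv.values[j] - ch.lo
        counts = model.cat_counts[j_cat]
        out += np.log(counts[:, k] + alpha)
        out -= np.log(counts.sum(axis=1) + ch.cardinality * alpha)
    if model.schema.count_block is not None:
        lo, hi = model.schema.count_block
        x = np.asarray(fv.values[lo:hi], dtype=float)
        n = model.schema.count_total
        a = model.block_counts.astype(float) + alpha       # (5, K)
        a_tot = a.sum(axis=1)
        out += gammaln(n + 1) - gammaln(x + 1).sum()
        out += gammaln(a_tot) - gammaln(a_tot + n)
        out += (gammaln(a + x[None, :]) - gammaln(a)).sum(axis=1)
    return out


def posterior(model: DirichletCountsModel, fv: FeatureVector
              ) -> PosteriorDistribution:
    """Posterior over the five categories for a test feature vector,
    computed in log space and normalised to machine precision."""
    with np.errstate(divide="ignore"):
        log_post = log_likelihood(model, fv) + np.log(model.class_prior)
    log_post -= logsumexp(log_post)
    p = np.exp(log_post)
    p /= p.sum()
    assert abs(p.sum() - 1.0) < NORMALISATION_TOL
    return PosteriorDistribution(p)


def predict(model: DirichletCountsModel, fv: FeatureVector) -> int:
    """Argmax class label; ties break toward the lowest class index."""
    return posterior(model, fv).argmax_label()


def evaluate_condition(model: DirichletCountsModel, specs) -> tuple[float, float]:
    """(mean labelled-class posterior, accuracy) over one test condition.

    The labelled class follows the scoring rule: the shape category for
    Both/Conflict/Shape trials, the non-shape category for Non-shape trials.
    """
    specs = list(specs)
    if not specs:
        raise StimulusError("empty test set")
    conditions = {s.condition for s in specs}
    if len(conditions) != 1:
        raise StimulusError(f"mixed conditions {sorted(conditions)}")
    masses, hits = [], []
    for spec in specs:
        target = evaluation.scored_label(spec)
        post = posterior(model, extract(spec, model.schema))
        masses.append(post[target])
        hits.append(post.argmax_label() == target)
    return float(np.mean(masses)), float(np.mean(hits))


def learning_curve(
    experiment_id: str,
    variant: str,
    checkpoints,
    seed: int = 0,
    n_train: int = 2000,
    n_test_per_condition: int = 500,
    alpha: float = 1.0,
) -> pd.DataFrame:
    """Per-condition metrics of the ideal observer at increasing amounts of
    training, reusing counts between checkpoints (no retraining).

    Returns a tidy frame with columns (checkpoint, condition, metric, value);
    metrics are ``mean_posterior`` and ``accuracy``.
    """
    checkpoints = sorted(int(c) for c in checkpoints)
    if checkpoints and checkpoints[-1] > n_train:
        raise StimulusError("checkpoint exceeds the training set size")
    manifest = generate_dataset(experiment_id, variant, n_train=n_train,
                                n_test_per_condition=n_test_per_condition,
                                seed=seed, symbolic_only=True)
    schema = schema_for(experiment_id)
    model = init_model(schema, alpha=alpha)
    by_condition = {
        cond: specs for cond in ("both", "conflict", "shape", "nonshape")
        if (specs := manifest.subset(cond))
    }
    train_rows = manifest.train_rows
    records = []
    done = 0
    for ckpt in checkpoints:
        for spec in train_rows[done:ckpt]:
            update(model, extract(spec, schema), spec.label)
        done = ckpt
        for cond, specs in by_condition.items():
            mass, acc = evaluate_condition(model, specs)
            records.append((ckpt, cond, "mean_posterior", mass))
            records.append((ckpt, cond, "accuracy", acc))
    return pd.DataFrame(records,
                        columns=["checkpoint", "condition", "metric", "value"])


# --------------------------------------------------------------------------
# checkpoint serialisation
# --------------------------------------------------------------------------


def to_json(model: DirichletCountsModel, path: str | Path | None = None) -> str:
    payload = {
        "schema": model.schema.experiment_id,
        "alpha": model.alpha,
        "class_prior": model.class_prior.tolist(),
        "cat_counts": [c.tolist() for c in model.cat_counts],
        "block_counts": (None if model.block_counts is None
                         else model.block_counts.tolist()),
        "n_per_class": model.n_per_class.tolist(),
    }
    text = json.dumps(payload)
    if path is not None:
        Path(path).write_text(text)
    return text


def from_json(source: str | Path) -> DirichletCountsModel:
    """Load a model checkpoint from a JSON string or a file path."""
    if isinstance(source, Path) or not str(source).lstrip().startswith("{"):
        text = Path(source).read_text()
    else:
        text = str(source)
    payload = json.loads(text)
    schema = schema_for(payload["schema"])
    model = DirichletCountsModel(
        schema=schema,
        alpha=payload["alpha"],
        class_prior=np.asarray(payload["class_prior"]),
        cat_counts=[np.asarray(c, dtype=np.int64) for c in payload["cat_counts"]],
        block_counts=(None if payload["block_counts"] is None
                      else np.asarray(payload["block_counts"], dtype=np.int64)),
        n_per_class=np.asarray(payload["n_per_class"], dtype=np.int64),
    )
    return model
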