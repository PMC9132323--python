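"""Per-experiment categorical feature schemas and symbolic feature extraction.

The ideal observer operates on feature vectors, not pixels, so extraction is
a pure function of a stimulus spec (and its seed-derived symbolic draws).

Channel domains
---------------
* shape channel: 1..5 are the five category shapes; ``SCRAMBLED`` (6)
  encodes images whose segments are placed at random (no coherent shape) —
  used by the 20% no-shape training trials of the b-variants, by the
  Non-shape test condition, and by the exp5_* datasets.
* exp1-family location channels: one per diagnostic canvas location, value
  = colour index (1..20) of the patch present there, or ``BACKGROUND`` (0)
  when the location is empty.  The 21-value domain makes the absence of a
  diagnostic patch an observable event, which is what lets the patch cue
  dominate shape on exp1 Conflict trials.
* exp2-family count channels: one per palette colour, value = number of
  segments of that colour (0..5).  The twenty counts always sum to the five
  segments; probabilistically they form a single multinomial block (five
  draws from one 20-colour distribution) rather than twenty independent
  categoricals — see :mod:`shapebias.ideal_observer`.
* exp3 size channel: diagnostic levels 1..5 plus the larger level 6 used by
  Shape-condition test images.
* exp4 global-colour channel: colour index 1..20.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stimuli import (
    FEATURE_KIND,
    N_CATEGORIES,
    N_COLOURS,
    N_SEGMENTS,
    StimulusSpec,
    StimulusError,
    realise_symbolic,
)

SCRAMBLED = N_CATEGORIES + 1  # sixth shape-channel value: no coherent shape
BACKGROUND = 0                # location-channel value: no patch present


@dataclass(frozen=True)
class Channel:
    """One categorical channel: name, cardinality, inclusive value range."""

    name: str
    cardinality: int
    lo: int
    hi: int

    def contains(self, value: int) -> bool:
        return self.lo <= value <= self.hi


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered channels of one experiment's feature vector.

    ``count_block`` marks the contiguous channel range (start, stop) whose
    values are segment counts drawn jointly (summing to ``count_total``);
    ``None`` for experiments whose channels are all single categorical draws.
    """

    experiment_id: str
    channels: tuple[Channel, ...]
    count_block: tuple[int, int] | None = None
    count_total: int = N_SEGMENTS

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def categorical_indices(self) -> list[int]:
        if self.count_block is None:
            return list(range(self.n_channels))
        lo, hi = self.count_block
        return [i for i in range(self.n_channels) if not lo <= i < hi]


@dataclass(frozen=True)
class FeatureVector:
    """One categorical value per channel of a schema."""

    schema: FeatureSchema
    values: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.values) != self.schema.n_channels:
            raise StimulusError("feature vector length does not match schema")
        for ch, v in zip(self.schema.channels, self.values):
            if not ch.contains(v):
                raise StimulusError(
                    f"value {v} outside domain of channel {ch.name!r}")


_SHAPE_CHANNEL = Channel("shape", N_CATEGORIES + 1, 1, SCRAMBLED)


def schema_for(experiment_id: str) -> FeatureSchema:
    """Feature schema of an experiment.

    exp1-family: shape + 5 location channels (21 values each);
    exp2-family: shape + 20 colour-count channels (counts 0..5, one joint
    multinomial block); exp3-family: shape + size level (6 values);
    exp4-family: shape + global colour (20 values).
    """
    try:
        kind = FEATURE_KIND[experiment_id]
    except KeyError:
        raise StimulusError(f"unknown experiment {experiment_id!r}") from None
    if kind == "patch":
        channels = (_SHAPE_CHANNEL,) + tuple(
            Channel(f"loc{i}", N_COLOURS + 1, BACKGROUND, N_COLOURS)
            for i in range(1, N_CATEGORIES + 1))
        return FeatureSchema(experiment_id, channels)
    if kind == "segment":
        channels = (_SHAPE_CHANNEL,) + tuple(
            Channel(f"count_colour{i}", N_SEGMENTS + 1, 0, N_SEGMENTS)
            for i in range(1, N_COLOURS + 1))
        return FeatureSchema(experiment_id, channels,
                             count_block=(1, 1 + N_COLOURS))
    if kind == "size":
        channels = (_SHAPE_CHANNEL, Channel("size", 6, 1, 6))
        return FeatureSchema(experiment_id, channels)
    channels = (_SHAPE_CHANNEL, Channel("global_colour", N_COLOURS, 1, N_COLOURS))
    return FeatureSchema(experiment_id, channels)


def extract(spec: StimulusSpec, schema: FeatureSchema | None = None) -> FeatureVector:
    """Symbolic feature vector of a spec (never touches pixels).

    Deterministic: repeated extraction of the same spec yields the same
    vector, and it matches what the renderer draws.
    """
    if schema is None:
        schema = schema_for(spec.experiment_id)
    if schema.experiment_id != spec.experiment_id:
        raise StimulusError(
            f"schema for {schema.experiment_id!r} cannot read a "
            f"{spec.experiment_id!r} spec")
    shape_val = SCRAMBLED if spec.shape_id is None else spec.shape_id
    kind = spec.feature_kind
    if kind == "patch":
        values = [shape_val] + [BACKGROUND] * N_CATEGORIES
        loc = spec.diagnostic_values.get("location")
        if loc is not None:
            values[loc] = spec.diagnostic_values["colour"]
    elif kind == "segment":
        colours = realise_symbolic(spec).segment_colours
        counts = np.bincount(np.asarray(colours), minlength=N_COLOURS + 1)[1:]
        values = [shape_val] + [int(c) for c in counts]
    elif kind == "size":
        values = [shape_val, spec.diagnostic_values["size_level"]]
    else:
        values = [shape_val, spec.diagnostic_values["global_colour"]]
    return FeatureVector(schema, tuple(values))


def extract_many(specs, schema: FeatureSchema | None = None) -> list[FeatureVector]:
    specs = list(specs)
    if schema is None and specs:
        schema = schema_for(specs[0].experiment_id)
    return [extract(s, schema) for s in specs]


def vectors_to_frame(vectors):
    """Wide table (one column per channel) for serialising feature vectors."""
    import pandas as pd

    if not vectors:
        raise StimulusError("no feature vectors to tabulate")
    schema = vectors[0].schema
    data = {ch.name: [fv.values[i] for fv in vectors]
            for i, ch in enumerate(schema.channels)}
    return pd.DataFrame(data)
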