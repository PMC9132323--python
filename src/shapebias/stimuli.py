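"""Procedural generation of patch/segment category-learning stimuli.

Each stimulus is a figure made of five segments (four short, one long) of
small coloured square patches on a white canvas.  Five categories are each
paired with a unique spatial configuration of segments (the *shape*) and with
one category-specific non-shape feature, which differs by experiment:

===========  ====================================  =========================
experiment   non-shape diagnostic feature          feature domain
===========  ====================================  =========================
exp1         colour of a patch at a fixed          5 locations x 20 colours
             canvas location
exp2         colour of one of the five segments    20 colours
exp3         mean patch size                       5 size levels
exp4         colour of every patch in the figure   20 colours
exp5_*       as above, but no category has a
             diagnostic shape (between-group)
===========  ====================================  =========================

Variants: ``a`` (shape present and diagnostic on 100% of training trials),
``b`` (80%, exactly stratified) and ``noshape`` (0%, used by the exp5_*
datasets).  Test conditions: ``both`` (shape and non-shape cue agree),
``conflict`` (shape from one category, non-shape cue from another),
``shape`` (shape only, non-diagnostic value on the other channel) and
``nonshape`` (scrambled segments, non-shape cue only).

All per-image randomness is derived from a per-row integer seed so that a
dataset, its manifests and its rendered rasters are byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

GENERATOR_VERSION = "1.0"

N_CATEGORIES = 5
N_COLOURS = 20
N_DIAG_COLOURS = 5          # colours 1..5 are reserved as category-diagnostic
N_SEGMENTS = 5
SHORT_RANGE = (5, 10)       # patches per short segment (inclusive)
LONG_RANGE = (10, 15)       # patches per long segment (inclusive)
PATCH_COUNT_RANGE = (30, 55)
N_SIZE_LEVELS = 5
SUPER_SIZE_LEVEL = 6        # Shape-condition test level for exp3, larger than all

EXPERIMENTS = (
    "exp1", "exp2", "exp3", "exp4",
    "exp5_patch", "exp5_segment", "exp5_size", "exp5_colour",
)
VARIANTS = ("a", "b", "noshape")
TRAIN = "train"
TEST_CONDITIONS = ("both", "conflict", "shape", "nonshape")
SHAPE_PROB = {"a": 1.0, "b": 0.8, "noshape": 0.0}

#: which non-shape feature family an experiment uses
FEATURE_KIND = {
    "exp1": "patch", "exp2": "segment", "exp3": "size", "exp4": "colour",
    "exp5_patch": "patch", "exp5_segment": "segment",
    "exp5_size": "size", "exp5_colour": "colour",
}

#: exp5_* datasets have no shape feature, and only the nonshape test condition
NO_SHAPE_EXPERIMENTS = frozenset(e for e in EXPERIMENTS if e.startswith("exp5"))


class StimulusError(ValueError):
    """Invalid stimulus specification or rendering request."""


class ManifestError(ValueError):
    """Malformed manifest file."""


# --------------------------------------------------------------------------
# palette
# --------------------------------------------------------------------------

_DEFAULT_COLOURS = (
    (220, 30, 30),    # 1  red        (diagnostic: category 1)
    (40, 70, 220),    # 2  blue       (category 2)
    (30, 160, 50),    # 3  green      (category 3)
    (245, 130, 10),   # 4  orange     (category 4)
    (135, 35, 185),   # 5  purple     (category 5)
    (0, 185, 205),    # 6  cyan
    (230, 40, 150),   # 7  magenta
    (240, 210, 0),    # 8  yellow
    (140, 85, 30),    # 9  brown
    (250, 150, 170),  # 10 pink
    (0, 120, 110),    # 11 teal
    (135, 145, 20),   # 12 olive
    (15, 25, 120),    # 13 navy
    (135, 0, 35),     # 14 maroon
    (150, 230, 50),   # 15 lime
    (180, 160, 250),  # 16 lavender
    (120, 120, 120),  # 17 grey
    (200, 170, 90),   # 18 gold
    (100, 180, 250),  # 19 sky blue
    (10, 80, 15),     # 20 dark green
)


@dataclass(frozen=True)
class Palette:
    """Twenty distinct patch colours plus the background colour.

    Colour indices are 1-based and stable across a dataset; indices 1..5 are
    the category-diagnostic colours, 6..20 are the non-diagnostic pool.
    """

    colours: tuple[tuple[int, int, int], ...] = _DEFAULT_COLOURS
    background: tuple[int, int, int] = (255, 255, 255)

    def __post_init__(self) -> None:
        if len(self.colours) != N_COLOURS:
            raise StimulusError(f"palette needs {N_COLOURS} colours, got {len(self.colours)}")
        if len(set(self.colours)) != N_COLOURS or self.background in self.colours:
            raise StimulusError("palette colours must be pairwise distinct and non-background")

    def rgb(self, index: int) -> tuple[int, int, int]:
        """RGB triple for 1-based colour index."""
        if not 1 <= index <= N_COLOURS:
            raise StimulusError(f"colour index {index} outside 1..{N_COLOURS}")
        return self.colours[index - 1]

    @property
    def nondiagnostic(self) -> tuple[int, ...]:
        """Colour indices never used as a category's diagnostic colour."""
        return tuple(range(N_DIAG_COLOURS + 1, N_COLOURS + 1))


# --------------------------------------------------------------------------
# shape templates
# --------------------------------------------------------------------------

# nominal segment lengths, used for template geometry and congruence checks;
# realised lengths are resampled per image within SHORT_RANGE / LONG_RANGE
_NOMINAL_SHORT = 7
_NOMINAL_LONG = 12
# nominal bounding box cap (grid cells) so realised figures (each segment may
# extend up to 3 cells past nominal) always fit the canvas after translation
_MAX_TEMPLATE_SPAN = 16
_SCRAMBLE_GRID = _MAX_TEMPLATE_SPAN + 6


@dataclass(frozen=True)
class Segment:
    """One run of patches: anchor cell (grid units), orientation, role."""

    ax: int
    ay: int
    orientation: str  # "h" or "v"
    role: str         # "short" or "long"

    @property
    def direction(self) -> tuple[int, int]:
        return (1, 0) if self.orientation == "h" else (0, 1)

    def nominal_length(self) -> int:
        return _NOMINAL_LONG if self.role == "long" else _NOMINAL_SHORT

    def cells(self, length: int | None = None) -> list[tuple[int, int]]:
        n = self.nominal_length() if length is None else length
        dx, dy = self.direction
        return [(self.ax + i * dx, self.ay + i * dy) for i in range(n)]


@dataclass(frozen=True)
class ShapeTemplate:
    """Spatial configuration of five segments defining one category's shape."""

    category_id: int
    segments: tuple[Segment, ...]

    def __post_init__(self) -> None:
        if len(self.segments) != N_SEGMENTS:
            raise StimulusError("a shape template has exactly 5 segments")
        if sum(s.role == "long" for s in self.segments) != 1:
            raise StimulusError("a shape template has exactly one long segment")


def _rotate_cell(x: int, y: int, k: int) -> tuple[int, int]:
    """Rotate a grid cell by k quarter turns about the origin."""
    for _ in range(k % 4):
        x, y = -y, x
    return x, y


def template_signature(template: ShapeTemplate) -> tuple:
    """Canonical form of a template's occupied cells under quarter-turn
    rotations and translation; equal signatures mean congruent shapes."""
    best = None
    cells = [c for seg in template.segments for c in seg.cells()]
    for k in range(4):
        rot = [_rotate_cell(x, y, k) for x, y in cells]
        mx = min(x for x, _ in rot)
        my = min(y for _, y in rot)
        sig = tuple(sorted(set((x - mx, y - my) for x, y in rot)))
        best = sig if best is None or sig < best else best
    return best


def _random_template(category_id: int, rng: np.random.Generator) -> ShapeTemplate:
    long_orient = "h" if rng.random() < 0.5 else "v"
    long_seg = Segment(0, 0, long_orient, "long")
    segments = [long_seg]
    occupied = set(long_seg.cells())
    while len(segments) < N_SEGMENTS:
        base = segments[int(rng.integers(len(segments)))]
        bcells = base.cells()
        cx, cy = bcells[int(rng.integers(len(bcells)))]
        orient = "v" if base.orientation == "h" else "h"
        dx, dy = (1, 0) if orient == "h" else (0, 1)
        n = _NOMINAL_SHORT
        if rng.random() < 0.5:  # extend in the positive direction from the joint
            ax, ay = cx + dx, cy + dy
        else:                   # extend in the negative direction
            ax, ay = cx - n * dx, cy - n * dy
        cand = Segment(ax, ay, orient, "short")
        if not occupied.isdisjoint(cand.cells()):
            continue
        cells = occupied | set(cand.cells())
        xs = [x for x, _ in cells]
        ys = [y for _, y in cells]
        if (max(xs) - min(xs) >= _MAX_TEMPLATE_SPAN
                or max(ys) - min(ys) >= _MAX_TEMPLATE_SPAN):
            continue
        segments.append(cand)
        occupied = cells
    return ShapeTemplate(category_id, tuple(segments))


def make_templates(seed: int) -> list[ShapeTemplate]:
    """Generate five pairwise non-congruent shape templates.

    Deterministic given ``seed``.  Congruence is checked under the four
    global quarter-turn orientations and translation.
    """
    rng = np.random.default_rng(seed)
    templates: list[ShapeTemplate] = []
    signatures: set[tuple] = set()
    while len(templates) < N_CATEGORIES:
        cand = _random_template(len(templates) + 1, rng)
        sig = template_signature(cand)
        if sig not in signatures:
            signatures.add(sig)
            templates.append(cand)
    return templates


# --------------------------------------------------------------------------
# stimulus specifications
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class StimulusSpec:
    """Complete symbolic ground truth for one image.

    ``label`` is the scored category; ``shape_id`` / ``nonshape_category``
    say which category's shape / non-shape feature the image carries (None
    when that cue is absent).  ``seed`` drives every per-image random draw,
    so rendering and symbolic realisation are pure functions of the spec.
    """

    experiment_id: str
    variant: str
    condition: str
    label: int
    shape_id: int | None
    nonshape_category: int | None
    diagnostic_values: dict
    orientation_index: int
    translation: tuple[float, float]
    seed: int

    def __post_init__(self) -> None:
        if self.experiment_id not in EXPERIMENTS:
            raise StimulusError(f"unknown experiment {self.experiment_id!r}")
        if not 1 <= self.label <= N_CATEGORIES:
            raise StimulusError(f"label {self.label} outside 1..{N_CATEGORIES}")
        if self.condition == "conflict":
            if self.shape_id is None or self.nonshape_category is None:
                raise StimulusError("conflict specs need both cue categories")
            if self.shape_id == self.nonshape_category:
                raise StimulusError("conflict specs pair distinct categories")
        if self.condition == "shape" and self.nonshape_category is not None:
            raise StimulusError("shape-condition specs carry no non-shape category")
        if self.condition == "nonshape" and self.shape_id is not None:
            raise StimulusError("nonshape-condition specs carry no shape")

    @property
    def feature_kind(self) -> str:
        return FEATURE_KIND[self.experiment_id]


def conflict_partner(label: int) -> int:
    """Fixed derangement pairing a shape category with the category whose
    non-shape feature a Conflict image carries."""
    return label % N_CATEGORIES + 1


def _diag_values(kind: str, category: int) -> dict:
    if kind == "patch":
        return {"location": category, "colour": category}
    if kind == "segment":
        return {"segment_colour": category}
    if kind == "size":
        return {"size_level": category}
    return {"global_colour": category}


def _transform_draws(rng: np.random.Generator) -> tuple[int, tuple[float, float]]:
    ori = int(rng.integers(4))
    tx, ty = rng.random(2)
    return ori, (float(tx), float(ty))


def _spec_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31 - 1))


def sample_training_spec(
    experiment_id: str,
    variant: str,
    label: int,
    shape_prob: float | None = None,
    rng: np.random.Generator | None = None,
    has_shape: bool | None = None,
) -> StimulusSpec:
    """Draw one training spec.

    The non-shape feature always carries the label's category-specific value
    (it is 100% predictive); the shape feature is present with probability
    ``shape_prob`` (1.0 / 0.8 / 0.0 for variants a / b / noshape).  Dataset
    generation passes ``has_shape`` explicitly to realise the 80% fraction by
    exact stratification rather than per-trial coin flips.
    """
    rng = np.random.default_rng() if rng is None else rng
    if shape_prob is None:
        shape_prob = SHAPE_PROB[variant]
    if not 0.0 <= shape_prob <= 1.0:
        raise StimulusError(f"shape_prob {shape_prob} outside [0, 1]")
    if variant == "noshape" and has_shape:
        raise StimulusError("noshape variant cannot carry a shape")
    if has_shape is None:
        has_shape = bool(rng.random() < shape_prob)
    kind = FEATURE_KIND[experiment_id]
    ori, trans = _transform_draws(rng)
    return StimulusSpec(
        experiment_id=experiment_id,
        variant=variant,
        condition=TRAIN,
        label=label,
        shape_id=label if has_shape else None,
        nonshape_category=label,
        diagnostic_values=_diag_values(kind, label),
        orientation_index=ori,
        translation=trans,
        seed=_spec_seed(rng),
    )


def sample_test_spec(
    experiment_id: str,
    condition: str,
    label: int,
    rng: np.random.Generator | None = None,
    variant: str = "a",
) -> StimulusSpec:
    """Draw one test spec for one of the four test conditions.

    For the no-shape experiments (exp5_*) only the ``nonshape`` condition is
    defined: their test block repeats the training distribution with novel
    images.
    """
    rng = np.random.default_rng() if rng is None else rng
    if condition not in TEST_CONDITIONS:
        raise StimulusError(f"unknown test condition {condition!r}")
    if experiment_id in NO_SHAPE_EXPERIMENTS and condition != "nonshape":
        raise StimulusError(f"{experiment_id} only defines the nonshape test condition")
    kind = FEATURE_KIND[experiment_id]
    ori, trans = _transform_draws(rng)
    shape_id: int | None
    nonshape: int | None
    if condition == "both":
        shape_id, nonshape = label, label
        diag = _diag_values(kind, label)
    elif condition == "conflict":
        shape_id, nonshape = label, conflict_partner(label)
        diag = _diag_values(kind, nonshape)
    elif condition == "shape":
        shape_id, nonshape = label, None
        if kind == "size":
            # mean patch size larger than any category's diagnostic level
            diag = {"size_level": SUPER_SIZE_LEVEL}
        elif kind == "colour":
            # a global colour that is not diagnostic of any category
            palette = Palette()
            diag = {"global_colour": int(rng.choice(palette.nondiagnostic))}
        else:
            diag = {}  # exp1: no diagnostic patch; exp2: no diagnostic segment
    else:  # nonshape
        shape_id, nonshape = None, label
        diag = _diag_values(kind, label)
    return StimulusSpec(
        experiment_id=experiment_id,
        variant=variant,
        condition=condition,
        label=label,
        shape_id=shape_id,
        nonshape_category=nonshape,
        diagnostic_values=diag,
        orientation_index=ori,
        translation=trans,
        seed=_spec_seed(rng),
    )


# --------------------------------------------------------------------------
# symbolic realisation (shared by the renderer and the feature extractor)
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SymbolicRealisation:
    """Per-image symbolic draws: segment patch counts and colour assignment."""

    segment_counts: tuple[int, ...]          # patches per segment (long last)
    segment_colours: tuple[int, ...] | None  # exp2-family: colour per segment
    carrier_index: int | None                # exp2-family: diagnostic segment


def _symbolic_rng(spec: StimulusSpec) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(0,)))


def _geometry_rng(spec: StimulusSpec) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(1,)))


def realise_symbolic(spec: StimulusSpec) -> SymbolicRealisation:
    """Deterministic symbolic draws for a spec (pure function of the spec).

    Draw order is fixed: patch counts first, then colours, so that the
    feature extractor and the renderer agree without touching pixels.
    """
    rng = _symbolic_rng(spec)
    has_diag_patch = spec.feature_kind == "patch" and "location" in spec.diagnostic_values
    while True:
        shorts = rng.integers(SHORT_RANGE[0], SHORT_RANGE[1] + 1, size=N_SEGMENTS - 1)
        long_n = rng.integers(LONG_RANGE[0], LONG_RANGE[1] + 1)
        total = int(shorts.sum() + long_n) + int(has_diag_patch)
        if total <= PATCH_COUNT_RANGE[1]:
            break
    counts = tuple(int(v) for v in shorts) + (int(long_n),)

    colours: tuple[int, ...] | None = None
    carrier: int | None = None
    if spec.feature_kind == "segment":
        nondiag = Palette().nondiagnostic
        diag_colour = spec.diagnostic_values.get("segment_colour")
        if diag_colour is not None:
            carrier = int(rng.integers(N_SEGMENTS))
            others = rng.choice(nondiag, size=N_SEGMENTS - 1, replace=False)
            cols = list(others[: carrier]) + [diag_colour] + list(others[carrier:])
        else:  # shape condition: five distinct non-diagnostic colours
            cols = list(rng.choice(nondiag, size=N_SEGMENTS, replace=False))
        colours = tuple(int(c) for c in cols)
    return SymbolicRealisation(counts, colours, carrier)


def segment_colours_for(spec: StimulusSpec) -> tuple[int, ...]:
    """Colour index of each of the five segments (exp2-family only)."""
    if spec.feature_kind != "segment":
        raise StimulusError("segment colours are defined for the segment-colour experiments")
    real = realise_symbolic(spec)
    assert real.segment_colours is not None
    return real.segment_colours


# --------------------------------------------------------------------------
# rendering
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class RenderConfig:
    """Geometry of the rendered raster.

    All lengths scale with ``canvas_size`` (reference canvas: 600 px,
    patch pitch 30 px, default patch side 18 px).
    """

    canvas_size: int = 600
    pitch_frac: float = 0.035          # inter-patch pitch / canvas
    patch_frac: float = 0.03           # default patch side / canvas
    jitter: float = 0.30               # +/- fraction on patch centre and side
    #: allowed global orientations as quarter turns; a spec's
    #: orientation_index selects from this tuple
    orientation_turns: tuple[int, ...] = (0, 1, 2, 3)
    #: nominal patch side / canvas for exp3 size levels 1..5 plus the
    #: super-diagnostic Shape-condition level 6
    size_level_fracs: tuple[float, ...] = (
        0.015, 0.02167, 0.02833, 0.035, 0.04167, 0.055)
    #: absolute canvas-fraction positions of the five exp1 diagnostic locations
    diag_locations: tuple[tuple[float, float], ...] = (
        (0.15, 0.15), (0.85, 0.15), (0.5, 0.5), (0.15, 0.85), (0.85, 0.85))
    max_translation_tries: int = 200

    @property
    def pitch(self) -> float:
        return self.pitch_frac * self.canvas_size

    def patch_side(self, spec: StimulusSpec) -> float:
        if spec.feature_kind == "size":
            level = spec.diagnostic_values["size_level"]
            return self.size_level_fracs[level - 1] * self.canvas_size
        return self.patch_frac * self.canvas_size


@dataclass
class RenderedStimulus:
    """Pixel raster realising a spec (H x W x 3 uint8) plus its ground truth."""

    raster: np.ndarray
    spec: StimulusSpec


def _figure_cells(spec: StimulusSpec, templates: Sequence[ShapeTemplate],
                  counts: Sequence[int], rng: np.random.Generator,
                  turns: Sequence[int] = (0, 1, 2, 3),
                  ) -> list[tuple[int, int]]:
    """Grid cells of every patch, either from the shape template or from
    scrambled segment placement, rotated by the spec's orientation."""
    if spec.shape_id is not None:
        template = templates[spec.shape_id - 1]
        cells = []
        for seg, n in zip(template.segments, counts):
            cells.extend(seg.cells(n))
        k = turns[spec.orientation_index % len(turns)]
        return [_rotate_cell(x, y, k) for x, y in cells]
    # scrambled: five segments at independent random positions/orientations
    # within a virtual grid comparable to the largest figure footprint
    grid = _SCRAMBLE_GRID
    placed: list[tuple[int, int]] = []
    occupied: set[tuple[int, int]] = set()
    roles = [("short", n) for n in counts[:-1]] + [("long", counts[-1])]
    for _role, n in roles:
        for attempt in range(100):
            orient = "h" if rng.random() < 0.5 else "v"
            dx, dy = (1, 0) if orient == "h" else (0, 1)
            ax = int(rng.integers(0, grid - (n if orient == "h" else 0) - 1))
            ay = int(rng.integers(0, grid - (n if orient == "v" else 0) - 1))
            seg_cells = [(ax + i * dx, ay + i * dy) for i in range(n)]
            if occupied.isdisjoint(seg_cells) or attempt == 99:
                placed.extend(seg_cells)
                occupied.update(seg_cells)
                break
    return placed


def render(spec: StimulusSpec,
           palette: Palette | None = None,
           templates: Sequence[ShapeTemplate] | None = None,
           config: RenderConfig | None = None) -> RenderedStimulus:
    """Rasterise a spec deterministically (same spec => identical raster).

    Patch centres are jittered by +/- ``jitter`` of the pitch and patch sides
    by +/- ``jitter`` of the nominal side.  The figure is translated to a
    random canvas position; translations that would push it off-canvas, or
    (exp1-family) cover a diagnostic location, are resampled, never clipped.
    """
    palette = Palette() if palette is None else palette
    config = RenderConfig() if config is None else config
    if templates is None:
        templates = make_templates(0)
    rng = _geometry_rng(spec)
    sym = realise_symbolic(spec)
    size = config.canvas_size
    pitch = config.pitch
    side = config.patch_side(spec)

    cells = _figure_cells(spec, templates, sym.segment_counts, rng,
                          config.orientation_turns)
    xs = np.array([c[0] for c in cells], dtype=float)
    ys = np.array([c[1] for c in cells], dtype=float)
    # per-patch jitter on centre and side
    jx = rng.uniform(-config.jitter, config.jitter, len(cells)) * pitch
    jy = rng.uniform(-config.jitter, config.jitter, len(cells)) * pitch
    sides = side * rng.uniform(1 - config.jitter, 1 + config.jitter, len(cells))
    px = xs * pitch + jx
    py = ys * pitch + jy

    margin = pitch
    half = sides.max() / 2.0
    x0, x1 = px.min() - half, px.max() + half
    y0, y1 = py.min() - half, py.max() + half
    free_x = size - 2 * margin - (x1 - x0)
    free_y = size - 2 * margin - (y1 - y0)
    if free_x < 0 or free_y < 0:
        raise StimulusError(
            f"figure extent ({x1 - x0:.0f}x{y1 - y0:.0f}) exceeds canvas {size}")

    kind = spec.feature_kind
    diag_loc = spec.diagnostic_values.get("location") if kind == "patch" else None
    diag_centres = np.array(config.diag_locations) * size

    tx, ty = spec.translation
    for attempt in range(config.max_translation_tries):
        off_x = margin - x0 + tx * free_x
        off_y = margin - y0 + ty * free_y
        cx, cy = px + off_x, py + off_y
        if kind != "patch":
            break
        # exp1-family: keep every diagnostic location clear of figure patches
        clear = True
        guard = config.patch_frac * size  # diagnostic patch nominal side
        for (dx_, dy_) in diag_centres:
            d = np.maximum(np.abs(cx - dx_), np.abs(cy - dy_))
            if np.any(d < (sides / 2 + guard)):
                clear = False
                break
        if clear:
            break
        tx, ty = rng.random(2)
    else:
        raise StimulusError("could not place figure clear of diagnostic locations")

    # colours
    n_patches = len(cells)
    if kind == "colour":
        colour_idx = np.full(n_patches, spec.diagnostic_values["global_colour"])
    elif kind == "segment":
        assert sym.segment_colours is not None
        per_seg = np.repeat(sym.segment_colours, sym.segment_counts)
        colour_idx = per_seg
    elif kind == "patch":
        pool = palette.nondiagnostic
        colour_idx = rng.choice(pool, size=n_patches)
    else:  # size: any of the twenty colours, none diagnostic in exp3
        colour_idx = rng.integers(1, N_COLOURS + 1, size=n_patches)

    raster = np.empty((size, size, 3), dtype=np.uint8)
    raster[:] = palette.background

    def paint(x: float, y: float, s: float, rgb: tuple[int, int, int]) -> None:
        a0 = max(int(round(x - s / 2)), 0)
        b0 = max(int(round(y - s / 2)), 0)
        a1 = min(int(round(x + s / 2)), size)
        b1 = min(int(round(y + s / 2)), size)
        raster[b0:b1, a0:a1] = rgb

    for i in range(n_patches):
        paint(cx[i], cy[i], sides[i], palette.rgb(int(colour_idx[i])))

    if diag_loc is not None:
        dcx, dcy = diag_centres[diag_loc - 1]
        djx, djy = rng.uniform(-config.jitter, config.jitter, 2) * pitch * 0.5
        dside = config.patch_frac * size * rng.uniform(1 - config.jitter, 1 + config.jitter)
        paint(dcx + djx, dcy + djy, dside, palette.rgb(spec.diagnostic_values["colour"]))

    return RenderedStimulus(raster, spec)


def patch_count(spec: StimulusSpec) -> int:
    """Total patches the rendered image will contain (figure + any
    free-standing diagnostic patch)."""
    sym = realise_symbolic(spec)
    extra = int(spec.feature_kind == "patch" and "location" in spec.diagnostic_values)
    return sum(sym.segment_counts) + extra


# --------------------------------------------------------------------------
# dataset generation and manifests
# --------------------------------------------------------------------------


@dataclass
class DatasetManifest:
    """All specs of one dataset plus dataset-level metadata."""

    experiment_id: str
    variant: str
    seed: int
    rows: list[StimulusSpec]
    image_paths: list[str | None]
    palette: Palette = field(default_factory=Palette)
    templates: list[ShapeTemplate] = field(default_factory=list)

    def subset(self, condition: str) -> list[StimulusSpec]:
        return [r for r in self.rows if r.condition == condition]

    @property
    def train_rows(self) -> list[StimulusSpec]:
        return self.subset(TRAIN)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DatasetManifest):
            return NotImplemented
        return (
            self.experiment_id == other.experiment_id
            and self.variant == other.variant
            and self.seed == other.seed
            and self.rows == other.rows
            and self.image_paths == other.image_paths
            and self.palette == other.palette
            and self.templates == other.templates
        )


def training_shape_flags(n: int, shape_prob: float, rng: np.random.Generator) -> np.ndarray:
    """Exactly-stratified boolean flags: round(n * shape_prob) of them True,
    in shuffled order (removes sampling noise from the realised fraction)."""
    n_shape = int(round(n * shape_prob))
    flags = np.zeros(n, dtype=bool)
    flags[:n_shape] = True
    rng.shuffle(flags)
    return flags


def generate_dataset(
    experiment_id: str,
    variant: str,
    n_train: int = 2000,
    n_test_per_condition: int = 500,
    seed: int = 0,
    symbolic_only: bool = True,
    out_dir: str | Path | None = None,
    render_config: RenderConfig | None = None,
) -> DatasetManifest:
    """Generate one dataset: balanced training split plus balanced test
    splits for every condition the experiment defines.

    ``symbolic_only`` skips rasterisation (fast path for the ideal
    observer); with ``out_dir`` set PNG files are written and referenced
    from the manifest.
    """
    if experiment_id not in EXPERIMENTS:
        raise StimulusError(f"unknown experiment {experiment_id!r}")
    if variant not in VARIANTS:
        raise StimulusError(f"unknown variant {variant!r}")
    if experiment_id in NO_SHAPE_EXPERIMENTS and variant != "noshape":
        raise StimulusError(f"{experiment_id} is only defined for the noshape variant")
    if n_train % N_CATEGORIES or n_test_per_condition % N_CATEGORIES:
        raise StimulusError("split sizes must be divisible by the 5 categories")

    root = np.random.SeedSequence(seed)
    template_rng, spec_rng = [np.random.default_rng(s) for s in root.spawn(2)]
    templates = make_templates(int(template_rng.integers(2**31 - 1)))
    shape_prob = SHAPE_PROB[variant]

    rows: list[StimulusSpec] = []
    per_label = n_train // N_CATEGORIES
    flags_by_label = {
        label: training_shape_flags(per_label, shape_prob, spec_rng)
        for label in range(1, N_CATEGORIES + 1)
    }
    order = np.repeat(np.arange(1, N_CATEGORIES + 1), per_label)
    spec_rng.shuffle(order)
    used = {label: 0 for label in range(1, N_CATEGORIES + 1)}
    for label in order:
        label = int(label)
        has_shape = bool(flags_by_label[label][used[label]])
        used[label] += 1
        rows.append(sample_training_spec(
            experiment_id, variant, label, shape_prob, spec_rng, has_shape=has_shape))

    conditions = (("nonshape",) if experiment_id in NO_SHAPE_EXPERIMENTS
                  else TEST_CONDITIONS)
    per_label_test = n_test_per_condition // N_CATEGORIES
    for condition in conditions:
        for label in range(1, N_CATEGORIES + 1):
            for _ in range(per_label_test):
                rows.append(sample_test_spec(
                    experiment_id, condition, label, spec_rng, variant=variant))

    image_paths: list[str | None] = [None] * len(rows)
    manifest = DatasetManifest(experiment_id, variant, seed, rows, image_paths,
                               Palette(), list(templates))
    if not symbolic_only and out_dir is not None:
        from PIL import Image

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for i, spec in enumerate(rows):
            rendered = render(spec, manifest.palette, templates, render_config)
            name = f"{experiment_id}_{variant}_{spec.condition}_{i:05d}.png"
            Image.fromarray(rendered.raster).save(out / name)
            image_paths[i] = name
    return manifest


# --------------------------------------------------------------------------
# manifest I/O (CSV rows + JSON metadata sidecar)
# --------------------------------------------------------------------------

MANIFEST_COLUMNS = ("image", "experiment", "variant", "condition", "label",
                    "shape_id", "nonshape_category", "diag_json", "seed")


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".meta.json")


def write_manifest(manifest: DatasetManifest, path: str | Path) -> None:
    """Write rows as CSV and dataset metadata as a JSON sidecar
    (``<path>.meta.json``); the pair round-trips losslessly."""
    path = Path(path)
    records = []
    for spec, img in zip(manifest.rows, manifest.image_paths):
        payload = {
            "diag": spec.diagnostic_values,
            "ori": spec.orientation_index,
            "tx": spec.translation[0],
            "ty": spec.translation[1],
        }
        records.append({
            "image": "" if img is None else img,
            "experiment": spec.experiment_id,
            "variant": spec.variant,
            "condition": spec.condition,
            "label": spec.label,
            "shape_id": "" if spec.shape_id is None else spec.shape_id,
            "nonshape_category": ("" if spec.nonshape_category is None
                                  else spec.nonshape_category),
            "diag_json": json.dumps(payload, sort_keys=True),
            "seed": spec.seed,
        })
    pd.DataFrame.from_records(records, columns=list(MANIFEST_COLUMNS)).to_csv(
        path, index=False)
    meta = {
        "generator_version": GENERATOR_VERSION,
        "experiment": manifest.experiment_id,
        "variant": manifest.variant,
        "seed": manifest.seed,
        "n_rows": len(manifest.rows),
        "palette": {"colours": [list(c) for c in manifest.palette.colours],
                    "background": list(manifest.palette.background)},
        "templates": [
            {"category_id": t.category_id,
             "segments": [dataclasses.asdict(s) for s in t.segments]}
            for t in manifest.templates
        ],
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1, sort_keys=True))


def read_manifest(path: str | Path) -> DatasetManifest:
    """Read a manifest written by :func:`write_manifest`; malformed rows are
    reported with their (0-based) row number."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if tuple(df.columns) != MANIFEST_COLUMNS:
        raise ManifestError(f"unexpected columns {tuple(df.columns)}")
    meta = json.loads(_sidecar_path(path).read_text())
    palette = Palette(
        colours=tuple(tuple(c) for c in meta["palette"]["colours"]),
        background=tuple(meta["palette"]["background"]),
    )
    templates = [
        ShapeTemplate(t["category_id"],
                      tuple(Segment(**s) for s in t["segments"]))
        for t in meta["templates"]
    ]
    rows: list[StimulusSpec] = []
    image_paths: list[str | None] = []
    for i, rec in enumerate(df.itertuples(index=False)):
        try:
            payload = json.loads(rec.diag_json)
            diag = {k: int(v) for k, v in payload["diag"].items()}
            rows.append(StimulusSpec(
                experiment_id=rec.experiment,
                variant=rec.variant,
                condition=rec.condition,
                label=int(rec.label),
                shape_id=None if rec.shape_id == "" else int(rec.shape_id),
                nonshape_category=(None if rec.nonshape_category == ""
                                   else int(rec.nonshape_category)),
                diagnostic_values=diag,
                orientation_index=int(payload["ori"]),
                translation=(float(payload["tx"]), float(payload["ty"])),
                seed=int(rec.seed),
            ))
        except (ValueError, KeyError, StimulusError) as exc:
            raise ManifestError(f"row {i}: {exc}") from exc
        image_paths.append(None if rec.image == "" else rec.image)
    return DatasetManifest(meta["experiment"], meta["variant"], meta["seed"],
                           rows, image_paths, palette, templates)
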