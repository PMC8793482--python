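"""Synthetic test imagery: pop-out arrays and sea scenes with ships.

Two generators cover the test needs of the whole pipeline without any
external dataset: psychophysical search arrays where one singleton item
differs from identical distractors in exactly one feature dimension, and
maritime scenes with oriented bright ship blobs over cluttered water
(low-frequency heterogeneity, directional wave texture, optional wakes).

Every generator is driven by one ``numpy.random.default_rng`` stream
seeded from a single integer, so the same spec + seed reproduces the
image and its ground truth bitwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "LabeledImage",
    "POPOUT_KINDS",
    "popout_pattern",
    "sea_scene",
    "random_sea_scene",
]

POPOUT_KINDS = ("color", "orientation", "shape", "missing_feature", "conjunction")

_RED = np.array([0.85, 0.10, 0.10])
_GREEN = np.array([0.10, 0.75, 0.10])
_BACKGROUND = np.array([0.92, 0.92, 0.92])


@dataclass
class LabeledImage:
    """A generated image with its pixel-level ground truth."""

    image: np.ndarray  # H x W x 3 float in [0, 1]
    target_mask: np.ndarray  # H x W bool
    target_boxes: list[tuple[int, int, int, int]]  # top, left, height, width
    spec: dict = field(default_factory=dict)
    seed: int = 0


def _mask_bbox(mask: np.ndarray) -> tuple[int, int, int, int]:
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    top, bottom = int(rows[0]), int(rows[-1])
    left, right = int(cols[0]), int(cols[-1])
    return (top, left, bottom - top + 1, right - left + 1)


# ---------------------------------------------------------------------------
# Pop-out patterns

def _paint_bar(canvas, mask, center, length, width, horizontal, color):
    h, w = mask.shape
    half_l, half_w = length // 2, width // 2
    if horizontal:
        r0, r1 = center[0] - half_w, center[0] + half_w + 1
        c0, c1 = center[1] - half_l, center[1] + half_l + 1
    else:
        r0, r1 = center[0] - half_l, center[0] + half_l + 1
        c0, c1 = center[1] - half_w, center[1] + half_w + 1
    r0, r1 = max(r0, 0), min(r1, h)
    c0, c1 = max(c0, 0), min(c1, w)
    canvas[r0:r1, c0:c1] = color
    mask[r0:r1, c0:c1] = True


def _paint_disc(canvas, mask, center, radius, color):
    h, w = mask.shape
    rows = np.arange(h)[:, None] - center[0]
    cols = np.arange(w)[None, :] - center[1]
    disc = rows**2 + cols**2 <= radius**2
    canvas[disc] = color
    mask |= disc


def _paint_item(canvas, mask, center, kind, is_singleton, species):
    """Draw one search item; canvas/mask are mutated in place.

    ``species`` selects the distractor variant for the conjunction kind
    (0 = red-vertical, 1 = green-horizontal); ignored elsewhere.
    """
    length, width = 13, 3
    if kind == "color":
        color = _RED if is_singleton else _GREEN
        _paint_bar(canvas, mask, center, length, width, False, color)
    elif kind == "orientation":
        _paint_bar(canvas, mask, center, length, width, is_singleton, _RED)
    elif kind == "shape":
        if is_singleton:
            _paint_disc(canvas, mask, center, 6, _RED)
        else:
            _paint_bar(canvas, mask, center, length, width, False, _RED)
    elif kind == "missing_feature":
        _paint_bar(canvas, mask, center, length, width, False, _RED)
        if not is_singleton:
            # distractors carry an extra perpendicular stroke
            _paint_bar(canvas, mask, center, length, width, True, _RED)
    elif kind == "conjunction":
        if is_singleton:
            _paint_bar(canvas, mask, center, length, width, True, _RED)
        elif species == 0:
            _paint_bar(canvas, mask, center, length, width, False, _RED)
        else:
            _paint_bar(canvas, mask, center, length, width, True, _GREEN)
    else:
        raise ValueError(
            f"unknown pop-out kind {kind!r}; expected one of {POPOUT_KINDS}"
        )


def popout_pattern(
    kind: str,
    grid: tuple[int, int] | None = None,
    image_size: tuple[int, int] = (128, 128),
    singleton_cell: tuple[int, int] | None = None,
    jitter: int | None = None,
    seed: int = 0,
) -> LabeledImage:
    """Render a search array with one feature singleton.

    ``kind`` selects the dimension the singleton differs in: color (hue
    flip), orientation (bar rotated 90 degrees), shape (disc among
    bars), missing_feature (item lacking the distractors' internal
    stroke, rendered as a dense texture-defect lattice), or conjunction
    (unique color-orientation pair among a balanced mix of red-vertical
    and green-horizontal distractors).  The GT mask covers exactly the
    singleton's pixels.

    Unless given, the singleton cell is drawn uniformly from the grid
    interior (targets at the outermost ring confound pop-out with
    array-boundary effects, so psychophysical displays avoid them), the
    grid defaults to 5x5 (7x7 for missing_feature), and item jitter is
    +-1 px (0 for missing_feature, whose defect must sit in a regular
    lattice).
    """
    if kind not in POPOUT_KINDS:
        raise ValueError(
            f"unknown pop-out kind {kind!r}; expected one of {POPOUT_KINDS}"
        )
    if grid is None:
        grid = (7, 7) if kind == "missing_feature" else (5, 5)
    if jitter is None:
        jitter = 0 if kind == "missing_feature" else 1
    rows, cols = grid
    h, w = image_size
    rng = np.random.default_rng(seed)
    if singleton_cell is None:
        if rows > 2 and cols > 2:
            singleton_cell = (
                int(rng.integers(1, rows - 1)),
                int(rng.integers(1, cols - 1)),
            )
        else:
            singleton_cell = (int(rng.integers(rows)), int(rng.integers(cols)))
    if not (0 <= singleton_cell[0] < rows and 0 <= singleton_cell[1] < cols):
        raise ValueError(f"singleton cell {singleton_cell} outside grid {grid}")

    # balanced split so neither distractor population is rare enough to
    # grab the channel-weight boost meant for the singleton
    n_distractors = rows * cols - 1
    species = np.array(
        [0] * (n_distractors // 2) + [1] * (n_distractors - n_distractors // 2)
    )
    rng.shuffle(species)

    canvas = np.ones((h, w, 3)) * _BACKGROUND
    singleton_mask = np.zeros((h, w), dtype=bool)
    scratch = np.zeros((h, w), dtype=bool)

    cell_h, cell_w = h / rows, w / cols
    k = 0
    for i in range(rows):
        for j in range(cols):
            center = [
                int(round((i + 0.5) * cell_h)),
                int(round((j + 0.5) * cell_w)),
            ]
            if jitter > 0:
                center[0] += int(rng.integers(-jitter, jitter + 1))
                center[1] += int(rng.integers(-jitter, jitter + 1))
            is_singleton = (i, j) == tuple(singleton_cell)
            target = singleton_mask if is_singleton else scratch
            item_species = None
            if not is_singleton:
                item_species = int(species[k])
                k += 1
            _paint_item(
                canvas, target, tuple(center), kind, is_singleton, item_species
            )

    return LabeledImage(
        image=np.clip(canvas, 0.0, 1.0),
        target_mask=singleton_mask,
        target_boxes=[_mask_bbox(singleton_mask)],
        spec={
            "kind": kind,
            "grid": list(grid),
            "image_size": list(image_size),
            "singleton_cell": list(singleton_cell),
            "jitter": jitter,
        },
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Sea scenes

_WATER = np.array([0.16, 0.24, 0.34])


def _ellipse_mask(shape, center, length, aspect, heading_deg):
    h, w = shape
    a = max(length / 2.0, 1.0)
    b = max(length / (2.0 * aspect), 0.6)
    theta = math.radians(heading_deg)
    rows = np.arange(h)[:, None] - center[0]
    cols = np.arange(w)[None, :] - center[1]
    u = rows * math.sin(theta) + cols * math.cos(theta)
    v = -rows * math.cos(theta) + cols * math.sin(theta)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _wake_mask(shape, center, length, heading_deg):
    h, w = shape
    theta = math.radians(heading_deg)
    rows = np.arange(h)[:, None] - center[0]
    cols = np.arange(w)[None, :] - center[1]
    u = rows * math.sin(theta) + cols * math.cos(theta)
    v = -rows * math.cos(theta) + cols * math.sin(theta)
    # streak trailing the stern, widening slightly
    behind = (u < -length / 2.0) & (u > -length * 2.5)
    return behind & (np.abs(v) <= 1.0 + np.abs(u) / (length * 2.0))


def sea_scene(
    size: tuple[int, int] = (512, 512),
    ships: list[dict] | None = None,
    clutter: dict | None = None,
    seed: int = 0,
    max_retries: int = 200,
) -> LabeledImage:
    """Render a cluttered water scene with oriented ship blobs.

    Each entry of ``ships`` may give ``length`` (major-axis pixels, >=2),
    ``aspect`` (length/width ratio), ``heading`` (degrees), ``intensity``
    (blob brightness), and optionally ``position`` (row, col).  Unplaced
    ships get random non-overlapping positions.  ``clutter`` accepts
    ``wave_amp``, ``heterogeneity_scale``, and ``wake``.
    """
    ships = list(ships or [])
    clutter = dict(clutter or {})
    wave_amp = float(clutter.get("wave_amp", 0.03))
    het_scale = float(clutter.get("heterogeneity_scale", 40.0))
    wake = bool(clutter.get("wake", True))

    h, w = size
    rng = np.random.default_rng(seed)

    # water base + low-frequency heterogeneity + directional wave texture,
    # normalized so the per-channel background std equals wave_amp
    canvas = np.ones((h, w, 3)) * _WATER
    het = gaussian_filter(rng.normal(size=(h, w)), sigma=het_scale)
    rr = np.arange(h)[:, None]
    cc = np.arange(w)[None, :]
    waves = np.zeros((h, w))
    for _ in range(3):
        theta = rng.uniform(0, math.pi)
        lam = rng.uniform(6.0, 14.0)
        phase = rng.uniform(0, 2 * math.pi)
        waves += np.sin(
            2 * math.pi * (rr * math.sin(theta) + cc * math.cos(theta)) / lam
            + phase
        )
    if het.std() > 0:
        het = het / het.std()
    texture = 1.5 * het + waves / 3.0 + rng.normal(scale=0.25, size=(h, w))
    if texture.std() > 0 and wave_amp > 0:
        texture = texture / texture.std() * wave_amp
    canvas += texture[:, :, None]

    target_mask = np.zeros((h, w), dtype=bool)
    boxes: list[tuple[int, int, int, int]] = []
    placed: list[tuple[float, float, float]] = []  # row, col, radius

    for ship in ships:
        length = float(ship.get("length", 8))
        if length < 2:
            raise ValueError(f"ship length must be >= 2 px, got {length}")
        aspect = float(ship.get("aspect", 3.0))
        heading = float(
            ship["heading"] if "heading" in ship else rng.uniform(0, 180)
        )
        intensity = float(ship.get("intensity", 0.9))
        radius = length / 2.0 + 3.0

        if "position" in ship:
            center = tuple(float(v) for v in ship["position"])
        else:
            margin = radius + 4.0
            if 2 * margin >= min(h, w):
                raise ValueError(f"ship of length {length} does not fit frame")
            center = None
            for _ in range(max_retries):
                cand = (
                    rng.uniform(margin, h - margin),
                    rng.uniform(margin, w - margin),
                )
                if all(
                    math.hypot(cand[0] - r, cand[1] - c) > radius + pr
                    for r, c, pr in placed
                ):
                    center = cand
                    break
            if center is None:
                raise ValueError(
                    "could not place ships without overlap; "
                    "reduce count or sizes"
                )
        placed.append((center[0], center[1], radius))

        blob = _ellipse_mask((h, w), center, length, aspect, heading)
        if wake:
            wk = _wake_mask((h, w), center, length, heading)
            canvas[wk] += 0.10
        canvas[blob] = intensity
        # dimmer superstructure stripe keeps the blob from being flat
        core = _ellipse_mask((h, w), center, length * 0.5, aspect * 1.5, heading)
        canvas[core] = min(intensity + 0.07, 1.0)
        target_mask |= blob
        boxes.append(_mask_bbox(blob))

    return LabeledImage(
        image=np.clip(canvas, 0.0, 1.0),
        target_mask=target_mask,
        target_boxes=boxes,
        spec={
            "size": list(size),
            "ships": ships,
            "clutter": {
                "wave_amp": wave_amp,
                "heterogeneity_scale": het_scale,
                "wake": wake,
            },
        },
        seed=seed,
    )


def random_sea_scene(
    seed: int,
    n_ships: int | None = None,
    size: tuple[int, int] = (512, 512),
    clutter: dict | None = None,
) -> LabeledImage:
    """Sea scene with 1-5 random ships spanning the 4-100 px size range.

    Ship lengths mix the small (4-10 px) and large (20-100 px) regimes.
    The ship list is drawn from a seed-derived stream, then rendering
    reuses the same seed, so the scene is fully reproducible.
    """
    rng = np.random.default_rng(seed)
    if n_ships is None:
        n_ships = int(rng.integers(1, 6))
    # cap large hulls so several ships still fit without overlap
    max_large = min(100.0, min(size) / 5.0)
    ships = []
    for _ in range(n_ships):
        if rng.random() < 0.5:
            length = float(rng.uniform(4, 10))
        else:
            length = float(rng.uniform(20, max_large))
        ships.append(
            {
                "length": length,
                "aspect": float(rng.uniform(2.5, 4.0)),
                "heading": float(rng.uniform(0, 180)),
                "intensity": float(rng.uniform(0.82, 0.95)),
            }
        )
    return sea_scene(size=size, ships=ships, clutter=clutter, seed=seed)
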