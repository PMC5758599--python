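"""Contour extraction and linear traits from binary leaf silhouettes.

Coordinates follow the (x, y) = (column, row) convention with y increasing
downward in image space; contours are traced as ordered sequences of
8-adjacent boundary pixels so they can be encoded losslessly as Freeman
chain codes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage import measure as sk_measure
from skimage import morphology as sk_morph

from leafscape.errors import ParameterError, ShapeError, TreeExcludedError

__all__ = [
    "BinaryLeafImage",
    "LinearTraits",
    "TreeSummary",
    "extract_contour",
    "linear_traits",
    "leaf_mass_per_area",
    "coefficient_of_variation",
    "summarize_tree",
    "summarize_trees",
]

#: 300 DPI scanner resolution, cm per pixel
DEFAULT_SCALE = 1.0 / 118.11


@dataclass
class BinaryLeafImage:
    """A single-leaf binary silhouette with its physical pixel size."""

    pixels: np.ndarray  # 2D bool
    scale: float = DEFAULT_SCALE  # cm per pixel

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels).astype(bool)
        if self.pixels.ndim != 2:
            raise ShapeError("image must be 2D")
        if self.scale <= 0:
            raise ParameterError("scale must be > 0 (cm per pixel)")

    @classmethod
    def read(cls, path, scale: float = DEFAULT_SCALE) -> "BinaryLeafImage":
        """Read a PNG/BMP image; any nonzero pixel is foreground."""
        import imageio.v3 as iio

        arr = iio.imread(path)
        if arr.ndim == 3:
            arr = arr[..., :3].max(axis=-1)
        return cls(pixels=arr > 0, scale=scale)

    def write(self, path) -> None:
        import imageio.v3 as iio

        iio.imwrite(path, (self.pixels.astype(np.uint8) * 255))


@dataclass(frozen=True)
class LinearTraits:
    """Per-leaf linear measurements (cm / cm^2 units)."""

    area: float
    length: float
    width: float
    major: float
    minor: float
    aspect_ratio: float
    dry_weight: float | None = None
    lma: float | None = None

    def as_dict(self) -> dict:
        d = {
            "area_cm2": self.area,
            "length_cm": self.length,
            "width_cm": self.width,
            "major_cm": self.major,
            "minor_cm": self.minor,
            "aspect_ratio": self.aspect_ratio,
        }
        if self.dry_weight is not None:
            d["dry_weight_g"] = self.dry_weight
        if self.lma is not None:
            d["lma_g_cm2"] = self.lma
        return d


@dataclass
class TreeSummary:
    """Per-tree trait means and within-tree coefficients of variation."""

    means: dict
    cvs: dict
    n_leaves: int
    lma: float | None = None


def _largest_component(pixels: np.ndarray) -> np.ndarray:
    labels = sk_measure.label(pixels, connectivity=2)
    if labels.max() == 0:
        raise ShapeError("image has no foreground pixels")
    counts = np.bincount(labels.ravel())[1:]
    best = counts.max()
    winners = np.flatnonzero(counts == best) + 1
    if len(winners) > 1:
        raise ShapeError(
            f"ambiguous largest component: {len(winners)} components share size {best}"
        )
    return labels == winners[0]


# Moore neighborhood in clockwise order starting east, as (dx, dy) with y down.
_MOORE = [(1, 0), (1, 1), (0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1)]


def extract_contour(img: BinaryLeafImage) -> np.ndarray:
    """Trace the outer boundary of the largest 8-connected component.

    Returns an (n, 2) int array of (x, y) boundary pixels, ordered by a
    Moore-neighbor trace with Jacob's stopping criterion, starting at the
    topmost-then-leftmost boundary pixel.  Consecutive pixels are
    8-adjacent; the sequence is closed (last pixel is 8-adjacent to the
    first).
    """
    mask = _largest_component(img.pixels)
    rows, cols = np.nonzero(mask)
    # topmost, then leftmost
    i0 = np.lexsort((cols, rows))[0]
    start = (int(cols[i0]), int(rows[i0]))
    h, w = mask.shape

    def fg(x, y):
        return 0 <= x < w and 0 <= y < h and mask[y, x]

    if not any(fg(start[0] + dx, start[1] + dy) for dx, dy in _MOORE):
        return np.array([start], dtype=int)

    contour: list[tuple[int, int]] = []
    cur = start
    # backtrack: start's west neighbor is background because start is the
    # topmost-then-leftmost foreground pixel
    back = (start[0] - 1, start[1])
    state0 = None
    limit = 4 * mask.size + 8
    while True:
        k0 = _MOORE.index((back[0] - cur[0], back[1] - cur[1]))
        nxt = None
        for step in range(1, 9):
            k = (k0 + step) % 8
            cand = (cur[0] + _MOORE[k][0], cur[1] + _MOORE[k][1])
            if fg(*cand):
                nxt = cand
                break
            back = cand
        if state0 is None:
            state0 = (cur, nxt)
        elif (cur, nxt) == state0:
            break  # Jacob's criterion: start re-entered the same way
        contour.append(cur)
        cur = nxt
        if len(contour) > limit:
            raise ShapeError("contour tracing failed to terminate")
    return np.array(contour, dtype=int)


def linear_traits(
    img: BinaryLeafImage,
    petiole_mask: np.ndarray | None = None,
    petiole_disk_radius: int | None = None,
    dry_weight: float | None = None,
) -> LinearTraits:
    """Measure the linear traits of one leaf.

    * ``area``: foreground pixel count x scale^2 (whole leaf, cm^2).
    * ``length`` / ``width``: bounding-box extents of the whole leaf along
      the image y (rows) and x (columns) axes (petiole included).
    * ``major`` / ``minor``: full axes of the moment-matched ellipse of the
      blade mask with the petiole removed, in cm; ``aspect_ratio`` is
      their ratio.

    The petiole is removed either with an explicit ``petiole_mask`` (True
    where petiole) or by morphological opening with a disk whose radius
    defaults to ~1.5% of the major image extent of the leaf (minimum 3 px).
    """
    mask = _largest_component(img.pixels)
    s = img.scale
    area = float(mask.sum()) * s * s
    rows, cols = np.nonzero(mask)
    length = float(rows.max() - rows.min() + 1) * s
    width = float(cols.max() - cols.min() + 1) * s

    if petiole_mask is not None:
        blade = mask & ~np.asarray(petiole_mask, dtype=bool)
    else:
        extent = max(rows.max() - rows.min(), cols.max() - cols.min()) + 1
        r = petiole_disk_radius if petiole_disk_radius is not None else max(3, round(0.015 * extent))
        blade = sk_morph.opening(mask, sk_morph.disk(r))
    if not blade.any():
        blade = mask  # opening destroyed the leaf; fall back to whole mask
    blade_lab = sk_measure.label(blade, connectivity=2)
    counts = np.bincount(blade_lab.ravel())[1:]
    blade = blade_lab == (int(np.argmax(counts)) + 1)

    props = sk_measure.regionprops(blade.astype(np.uint8))[0]
    major = float(props.axis_major_length) * s
    minor = float(props.axis_minor_length) * s
    if minor <= 0:
        raise ShapeError("degenerate blade mask: moment ellipse has zero minor axis")
    lma = None
    if dry_weight is not None:
        lma = leaf_mass_per_area(dry_weight, area)
    return LinearTraits(
        area=area,
        length=length,
        width=width,
        major=major,
        minor=minor,
        aspect_ratio=major / minor,
        dry_weight=dry_weight,
        lma=lma,
    )


def leaf_mass_per_area(dry_weight: float, total_area: float) -> float:
    """Dry weight / surface area, g per cm^2."""
    if dry_weight <= 0:
        raise ParameterError(f"dry_weight must be > 0, got {dry_weight}")
    if total_area <= 0:
        raise ParameterError(f"total_area must be > 0, got {total_area}")
    return dry_weight / total_area


def coefficient_of_variation(values) -> float:
    """100 x sample standard deviation (n-1) / mean."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ParameterError("need at least 2 values for a CV")
    mean = v.mean()
    if mean == 0:
        raise ParameterError("CV undefined for zero mean")
    return float(100.0 * v.std(ddof=1) / mean)


_CV_TRAITS = ("area_cm2", "length_cm", "width_cm", "major_cm", "minor_cm", "aspect_ratio")


def summarize_tree(
    leaf_traits: list[LinearTraits],
    tree_dry_weight: float | None = None,
    n_leaves_range: tuple[int, int] = (8, 10),
    lma_requires_all: int = 10,
) -> TreeSummary:
    """Average leaf traits within a tree and compute within-tree CVs.

    Trees whose leaf count falls outside ``n_leaves_range`` raise
    :class:`TreeExcludedError`.  Leaf mass per area is computed from the
    tree-level dry weight only when exactly ``lma_requires_all`` leaves
    contributed surface area, and is left missing otherwise.
    """
    n = len(leaf_traits)
    if n == 0:
        raise ParameterError("empty leaf list")
    lo, hi = n_leaves_range
    if not lo <= n <= hi:
        raise TreeExcludedError(f"tree has {n} leaves, outside [{lo}, {hi}]")
    table = pd.DataFrame([t.as_dict() for t in leaf_traits])
    means = {k: float(table[k].mean()) for k in table.columns}
    cvs = {
        f"{k}_var": coefficient_of_variation(table[k].values)
        for k in _CV_TRAITS
        if k in table
    }
    lma = None
    if tree_dry_weight is not None and n == lma_requires_all and table["area_cm2"].notna().all():
        lma = leaf_mass_per_area(tree_dry_weight, float(table["area_cm2"].sum()))
    return TreeSummary(means=means, cvs=cvs, n_leaves=n, lma=lma)


def summarize_trees(
    per_tree_traits: dict[str, list[LinearTraits]],
    dry_weights: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Summarize many trees, silently dropping excluded ones."""
    rows = {}
    for tree_id, traits in per_tree_traits.items():
        dw = (dry_weights or {}).get(tree_id)
        try:
            summ = summarize_tree(traits, tree_dry_weight=dw)
        except TreeExcludedError as exc:
            warnings.warn(f"{tree_id}: {exc}", stacklevel=2)
            continue
        row = dict(summ.means)
        row.update(summ.cvs)
        row["n_leaves"] = summ.n_leaves
        if summ.lma is not None:
            row["lma_g_cm2"] = summ.lma
        rows[tree_id] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "tree_id"
    return out
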