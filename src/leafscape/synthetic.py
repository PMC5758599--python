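"""Synthetic leaves, orchards, genotypes, and phenotypes.

The generators emulate the statistical structure the downstream analysis
assumes: leaf silhouettes whose dominant axis of variation is the
length-to-width (aspect) ratio of the blade, an orchard laid out on a
row-grid x column-grid with replicated control accessions, and biallelic SNP
genotypes carrying a polygenic additive architecture of known narrow-sense
heritability.

All randomness flows through explicit :class:`numpy.random.Generator`
instances derived from integer seeds; no global state is touched, so every
output is bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon
from shapely.geometry.polygon import orient

from leafscape.errors import ParameterError, ShapeError
from leafscape.measure import BinaryLeafImage

__all__ = [
    "LeafParams",
    "GeneticArchitecture",
    "OrchardDesignSim",
    "generate_leaf_outline",
    "rasterize_outline",
    "simulate_genotypes",
    "simulate_phenotype",
    "simulate_orchard",
    "simulate_leaf_population",
]


@dataclass(frozen=True)
class LeafParams:
    """Parameters of a single synthetic leaf silhouette.

    aspect_ratio
        Blade length / blade width (petiole excluded), > 0.
    blade_scale
        Blade length in pixels.
    serration_amplitude
        Peak outward tooth height as a fraction of the local radius, in
        [0, 0.3].
    serration_count
        Number of teeth around the outline (0 = entire margin).
    petiole_length
        Petiole length as a fraction of blade length, in [0, 0.5].
    asymmetry
        Signed left/right blade imbalance, in [-0.2, 0.2].
    seed
        Controls the serration phase; outlines with equal params and seed
        are identical.
    """

    aspect_ratio: float = 1.8
    blade_scale: float = 400.0
    serration_amplitude: float = 0.0
    serration_count: int = 0
    petiole_length: float = 0.15
    asymmetry: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if not self.aspect_ratio > 0:
            raise ParameterError(f"aspect_ratio must be > 0, got {self.aspect_ratio}")
        if not 0 <= self.serration_amplitude <= 0.3:
            raise ParameterError(
                f"serration_amplitude must be in [0, 0.3], got {self.serration_amplitude}"
            )
        if self.serration_count < 0:
            raise ParameterError("serration_count must be >= 0")
        if not 0 <= self.petiole_length <= 0.5:
            raise ParameterError(
                f"petiole_length must be in [0, 0.5], got {self.petiole_length}"
            )
        if not -0.2 <= self.asymmetry <= 0.2:
            raise ParameterError(f"asymmetry must be in [-0.2, 0.2], got {self.asymmetry}")
        if self.blade_scale <= 0:
            raise ParameterError("blade_scale must be > 0")


@dataclass(frozen=True)
class GeneticArchitecture:
    """Polygenic additive architecture for genotype/phenotype simulation."""

    n_individuals: int = 500
    n_snps: int = 2000
    maf_low: float = 0.05
    maf_high: float = 0.5
    n_causal: int = 200
    h2_true: float = 0.5
    ld_block_size: int = 10
    seed: int = 0

    def validate(self) -> None:
        if self.n_individuals < 2 or self.n_snps < 1:
            raise ParameterError("need >= 2 individuals and >= 1 SNP")
        if not 0 < self.maf_low <= self.maf_high <= 0.5:
            raise ParameterError("require 0 < maf_low <= maf_high <= 0.5")
        if not 0 <= self.n_causal <= self.n_snps:
            raise ParameterError("n_causal must be in [0, n_snps]")
        if not 0 <= self.h2_true <= 1:
            raise ParameterError(f"h2_true must be in [0, 1], got {self.h2_true}")
        if self.ld_block_size < 1:
            raise ParameterError("ld_block_size must be >= 1")
        if self.n_snps < self.ld_block_size:
            raise ParameterError("n_snps must be >= ld_block_size")


@dataclass(frozen=True)
class OrchardDesignSim:
    """Row-grid x column-grid orchard with replicated control accessions.

    Mirrors an incomplete block design in which each grid cell holds one of
    a small set of control ("standard") accessions plus a share of the
    unreplicated accessions, so positional variance components are
    estimable.
    """

    n_rgrid: int = 5
    n_cgrid: int = 5
    var_r: float = 1.0
    var_c: float = 1.0
    var_rc: float = 0.5
    var_resid: float = 1.0
    control_accessions: tuple = ("CTRL_A", "CTRL_B", "CTRL_C")
    seed: int = 0

    def validate(self) -> None:
        if self.n_rgrid < 1 or self.n_cgrid < 1:
            raise ParameterError("grid counts must be >= 1")
        for name in ("var_r", "var_c", "var_rc", "var_resid"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")


# ---------------------------------------------------------------------------
# leaves
# ---------------------------------------------------------------------------


def _blade_curve(params: LeafParams, n_points: int, rng: np.random.Generator) -> np.ndarray:
    """Smooth ovate blade, tip at +x, base at -x, rescaled to an exact
    aspect_ratio bounding box."""
    t = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=False)
    # ovate base curve: widest slightly toward the base (negative x)
    x = 0.5 * np.cos(t)
    y = 0.5 * np.sin(t) * (1.0 + 0.25 * np.cos(t) ** 2) * (1.0 - 0.18 * np.cos(t))
    # smooth bilateral asymmetry
    y = y * (1.0 + params.asymmetry * np.sin(t))
    if params.serration_amplitude > 0 and params.serration_count > 0:
        phase = rng.uniform(0.0, 2.0 * np.pi)
        tooth = 0.5 * (1.0 + np.sin(params.serration_count * t + phase))
        factor = 1.0 + params.serration_amplitude * tooth
        x = x * factor
        y = y * factor
    # affine rescale to the exact blade bounding box
    L = params.blade_scale
    W = params.blade_scale / params.aspect_ratio
    x = (x - x.min()) / (x.max() - x.min()) * L - 0.5 * L
    y = (y - y.min()) / (y.max() - y.min()) * W - 0.5 * W
    return np.column_stack([x, y])


def generate_leaf_outline(params: LeafParams, n_points: int = 512) -> np.ndarray:
    """Generate a simple closed leaf outline as an (n_points, 2) array.

    The blade is a smooth ovate curve with optional sinusoidal serration;
    the petiole, when requested, is a thin rectangle merged onto the base
    (at -x).  Vertices are ordered counter-clockwise and the blade bounding
    box matches ``params.aspect_ratio`` exactly before the petiole is
    attached.
    """
    params.validate()
    if n_points < 64:
        raise ParameterError(f"n_points must be >= 64, got {n_points}")
    rng = np.random.default_rng(params.seed)
    blade = _blade_curve(params, max(n_points, 256), rng)
    poly = Polygon(blade)
    if not poly.is_valid:  # extreme serration may self-intersect; heal
        poly = poly.buffer(0)
    if params.petiole_length > 0:
        L = params.blade_scale
        W = params.blade_scale / params.aspect_ratio
        pl = params.petiole_length * L
        half_w = max(1.5, 0.02 * W)
        base = blade[int(np.argmin(blade[:, 0]))]
        x0, y0 = float(base[0]), float(base[1])
        petiole = Polygon(
            [
                (x0 - pl, y0 - half_w),
                (x0 + 0.05 * L, y0 - half_w),
                (x0 + 0.05 * L, y0 + half_w),
                (x0 - pl, y0 + half_w),
            ]
        )
        poly = poly.union(petiole)
    if poly.geom_type == "MultiPolygon":  # disconnected sliver: keep the leaf
        poly = max(poly.geoms, key=lambda g: g.area)
    poly = orient(poly, sign=1.0)  # counter-clockwise exterior
    ring = np.asarray(poly.exterior.coords)[:-1]
    return _resample_closed(ring, n_points)


def _resample_closed(ring: np.ndarray, n_points: int) -> np.ndarray:
    """Resample a closed polygon to n_points at uniform arc length."""
    closed = np.vstack([ring, ring[:1]])
    seg = np.hypot(*np.diff(closed, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        raise ShapeError("degenerate outline with zero perimeter")
    target = np.linspace(0.0, total, n_points, endpoint=False)
    x = np.interp(target, s, closed[:, 0])
    y = np.interp(target, s, closed[:, 1])
    return np.column_stack([x, y])


def rasterize_outline(
    contour: np.ndarray,
    image_px: int | None = None,
    scale: float = 1.0 / 118.11,
    margin: int = 4,
) -> BinaryLeafImage:
    """Fill a closed polygon into a binary image.

    The polygon is translated so it sits ``margin`` pixels inside the
    canvas.  When ``image_px`` is None the canvas is sized to fit.  ``scale``
    is the physical size of one pixel in cm (default: a 300 DPI scanner).
    """
    contour = np.asarray(contour, dtype=float)
    if contour.ndim != 2 or contour.shape[0] < 3:
        raise ShapeError("contour must be an (n>=3, 2) array")
    from skimage.draw import polygon as sk_polygon

    xy = contour - contour.min(axis=0) + margin
    extent = xy.max(axis=0) + margin
    if image_px is None:
        image_px = int(math.ceil(extent.max())) + 1
    if extent[0] > image_px or extent[1] > image_px:
        raise ShapeError(
            f"contour extent {extent} exceeds canvas of {image_px} px"
        )
    # image rows = y, cols = x
    rr, cc = sk_polygon(xy[:, 1], xy[:, 0], shape=(image_px, image_px))
    pixels = np.zeros((image_px, image_px), dtype=bool)
    pixels[rr, cc] = True
    if not pixels.any():
        raise ShapeError("rasterization produced an empty image")
    return BinaryLeafImage(pixels=pixels, scale=scale)


def simulate_leaf_population(
    n_trees: int = 100,
    leaves_per_tree: tuple[int, int] = (8, 10),
    mean_log_aspect: float = math.log(1.8),
    sd_log_aspect: float = 0.10,
    within_tree_sd: float = 0.03,
    blade_scale: float = 300.0,
    serration_amplitude: float = 0.0,
    serration_count: int = 24,
    petiole_length: float = 0.15,
    seed: int = 0,
    n_points: int = 512,
) -> tuple[list[list[np.ndarray]], pd.DataFrame]:
    """Population of trees whose leaves vary chiefly in aspect ratio.

    Per-tree aspect ratios are lognormal; leaves within a tree jitter
    around the tree value on the log scale.  Returns (outlines, truth)
    where ``outlines[i]`` is the list of leaf contours of tree i and
    ``truth`` records each tree's aspect ratio and leaf count.
    """
    rng = np.random.default_rng(seed)
    lo, hi = leaves_per_tree
    outlines: list[list[np.ndarray]] = []
    rows = []
    for i in range(n_trees):
        ar_tree = math.exp(rng.normal(mean_log_aspect, sd_log_aspect))
        n_leaves = int(rng.integers(lo, hi + 1))
        asym = float(np.clip(rng.normal(0.0, 0.03), -0.2, 0.2))
        leaves = []
        for j in range(n_leaves):
            ar_leaf = ar_tree * math.exp(rng.normal(0.0, within_tree_sd))
            scale_leaf = blade_scale * math.exp(rng.normal(0.0, 0.05))
            params = LeafParams(
                aspect_ratio=ar_leaf,
                blade_scale=scale_leaf,
                serration_amplitude=serration_amplitude,
                serration_count=serration_count,
                petiole_length=petiole_length,
                asymmetry=asym,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            leaves.append(generate_leaf_outline(params, n_points=n_points))
        outlines.append(leaves)
        rows.append(
            {"tree_id": f"T{i:04d}", "aspect_ratio": ar_tree, "n_leaves": n_leaves}
        )
    return outlines, pd.DataFrame(rows).set_index("tree_id")


# ---------------------------------------------------------------------------
# genotypes and phenotypes
# ---------------------------------------------------------------------------


def simulate_genotypes(arch: GeneticArchitecture, rng: np.random.Generator | None = None):
    """Simulate biallelic 0/1/2 genotypes with block LD.

    Within an LD block every SNP shares the same allele frequency and each
    haplotype allele is copied from the previous SNP with probability 0.9
    (resampled from the population frequency with probability 0.1), which
    yields adjacent-SNP correlation ~0.9 within blocks and independence
    across blocks.
    """
    from leafscape.genomics import GenotypeMatrix

    arch.validate()
    if rng is None:
        rng = np.random.default_rng([arch.seed, 101])
    n, m, b = arch.n_individuals, arch.n_snps, arch.ld_block_size
    n_blocks = int(math.ceil(m / b))
    hap = np.empty((2 * n, m), dtype=np.int8)
    for blk in range(n_blocks):
        j0, j1 = blk * b, min((blk + 1) * b, m)
        p = rng.uniform(arch.maf_low, arch.maf_high)
        hap[:, j0] = rng.random(2 * n) < p
        for j in range(j0 + 1, j1):
            fresh = rng.random(2 * n) < 0.1
            hap[:, j] = np.where(fresh, rng.random(2 * n) < p, hap[:, j - 1])
    codes = (hap[0::2] + hap[1::2]).astype(np.int8)
    return GenotypeMatrix(
        codes=codes,
        sample_ids=[f"IND{i:05d}" for i in range(n)],
        snp_ids=[f"S{j:06d}" for j in range(m)],
        chrom=np.array(["1"] * m, dtype=object),
        pos=np.arange(1, m + 1, dtype=np.int64) * 100,
    )


def simulate_phenotype(
    G,
    arch: GeneticArchitecture,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Additive polygenic phenotype with target heritability.

    y = sum_j beta_j g_j + e, with beta ~ N(0, 1) on ``arch.n_causal``
    randomly chosen SNPs and e scaled so var(g)/var(y) = h2_true in
    expectation.  Returns (phenotypes, breeding_values).
    """
    arch.validate()
    if rng is None:
        rng = np.random.default_rng([arch.seed, 202])
    codes = np.asarray(G.codes, dtype=float)
    n, m = codes.shape
    if arch.n_causal > m:
        raise ParameterError("n_causal exceeds number of SNPs")
    causal = rng.choice(m, size=arch.n_causal, replace=False)
    beta = rng.normal(0.0, 1.0, size=arch.n_causal)
    g = codes[:, causal] @ beta
    g = g - g.mean()
    var_g = float(g.var())
    h2 = arch.h2_true
    if h2 == 0.0 or var_g == 0.0:
        e = rng.normal(0.0, 1.0 if var_g == 0 else math.sqrt(var_g), size=n)
        return e, g
    if h2 == 1.0:
        return g.copy(), g
    var_e = var_g * (1.0 - h2) / h2
    e = rng.normal(0.0, math.sqrt(var_e), size=n)
    return g + e, g


# ---------------------------------------------------------------------------
# orchard
# ---------------------------------------------------------------------------


def simulate_orchard(
    accession_values: pd.Series | pd.DataFrame,
    design: OrchardDesignSim,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Place accessions on the orchard grid and add positional effects.

    Every grid cell receives one control tree (cycling through
    ``design.control_accessions``) and the remaining accessions are dealt
    across cells.  Each observation is

        accession value + rGrid effect + cGrid effect + rGrid:cGrid effect
        + residual,

    with the four components drawn from centered Gaussians with the stated
    variances.  Returns a tree-level table with columns ``accession``,
    ``rGrid``, ``cGrid`` and one column per trait.
    """
    design.validate()
    if rng is None:
        rng = np.random.default_rng([design.seed, 303])
    if isinstance(accession_values, pd.Series):
        values = accession_values.to_frame(accession_values.name or "value")
    else:
        values = accession_values
    traits = list(values.columns)
    controls = [c for c in design.control_accessions if c in values.index]
    regular = [a for a in values.index if a not in controls]

    nr, nc = design.n_rgrid, design.n_cgrid
    cells = [(r, c) for r in range(nr) for c in range(nc)]
    assignments: list[tuple[str, int, int]] = []
    for k, (r, c) in enumerate(cells):
        if controls:
            assignments.append((controls[k % len(controls)], r, c))
    perm = rng.permutation(len(regular))
    for k, idx in enumerate(perm):
        r, c = cells[k % len(cells)]
        assignments.append((regular[idx], r, c))

    rows = pd.DataFrame(
        [
            {
                "tree_id": f"TREE{t:04d}",
                "accession": acc,
                "rGrid": f"R{r:02d}",
                "cGrid": f"C{c:02d}",
                "_r": r,
                "_c": c,
            }
            for t, (acc, r, c) in enumerate(assignments)
        ]
    ).set_index("tree_id")
    # positional effects drawn independently per trait
    for trait in traits:
        eff_r = rng.normal(0.0, math.sqrt(design.var_r), size=nr)
        eff_c = rng.normal(0.0, math.sqrt(design.var_c), size=nc)
        eff_rc = rng.normal(0.0, math.sqrt(design.var_rc), size=(nr, nc))
        resid = rng.normal(0.0, math.sqrt(design.var_resid), size=len(rows))
        base = values[trait].loc[rows["accession"]].to_numpy(dtype=float)
        rows[trait] = (
            base
            + eff_r[rows["_r"]]
            + eff_c[rows["_c"]]
            + eff_rc[rows["_r"], rows["_c"]]
            + resid
        )
    return rows.drop(columns=["_r", "_c"])
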