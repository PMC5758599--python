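"""Elliptical Fourier descriptors (EFDs) of closed leaf outlines.

A raster contour is first encoded as a Freeman 8-direction chain code (a
lossless step-by-step encoding of the boundary), then decomposed into a
harmonic series: for harmonic n the quadruple (a_n, b_n, c_n, d_n) holds the
cosine/sine coefficients of the x and y traversal.  Normalization against
the first-harmonic ellipse removes size, rotation, translation, and
starting-point effects; zeroing the b and c series afterwards removes
bilaterally asymmetric variation, leaving shapes mirror-symmetric about
their major axis.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from leafscape.errors import ParameterError, ShapeError

__all__ = [
    "ChainCode",
    "EFDCoefficients",
    "chain_code",
    "decode_chain",
    "efd_coefficients",
    "normalize_efd",
    "drop_asymmetric",
    "reconstruct",
    "efd_feature_matrix",
]

# Freeman directions, code k -> (dx, dy) with y pointing up
_FREEMAN = np.array(
    [(1, 0), (1, 1), (0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1)],
    dtype=int,
)
_FREEMAN_LOOKUP = {tuple(d): k for k, d in enumerate(_FREEMAN)}


@dataclass(frozen=True)
class ChainCode:
    """Freeman 8-direction chain code with its start pixel."""

    start: tuple[int, int]
    codes: np.ndarray  # int array of directions in {0..7}

    def __len__(self) -> int:
        return len(self.codes)


@dataclass(frozen=True)
class EFDCoefficients:
    """Per-harmonic (a, b, c, d) quadruples plus the DC terms (A0, C0).

    ``a``/``b`` drive x(t), ``c``/``d`` drive y(t).  ``normalized`` marks
    coefficients that passed through :func:`normalize_efd` (a1 = 1,
    b1 = c1 = 0).
    """

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    d: np.ndarray
    a0: float = 0.0
    c0: float = 0.0
    normalized: bool = False

    @property
    def n_harmonics(self) -> int:
        return len(self.a)

    def quadruples(self) -> np.ndarray:
        """(n_harmonics, 4) array of (a, b, c, d) rows."""
        return np.column_stack([self.a, self.b, self.c, self.d])

    def symmetric_features(self) -> np.ndarray:
        """Flattened (a_1..a_H, d_1..d_H) feature vector."""
        return np.concatenate([self.a, self.d])


def chain_code(contour: np.ndarray, closed: bool = True) -> ChainCode:
    """Encode an 8-adjacent pixel contour as a Freeman chain code.

    With ``closed=True`` (the default) a final step from the last pixel
    back to the first is appended, so replaying the code traverses the
    closed boundary losslessly.
    """
    pts = np.asarray(contour, dtype=int)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 1:
        raise ShapeError("contour must be an (n, 2) integer array")
    if closed and len(pts) > 1:
        steps = np.diff(np.vstack([pts, pts[:1]]), axis=0)
    else:
        steps = np.diff(pts, axis=0)
    codes = np.empty(len(steps), dtype=int)
    for i, (dx, dy) in enumerate(steps):
        key = (int(dx), int(dy))
        if key not in _FREEMAN_LOOKUP:
            raise ShapeError(
                f"consecutive contour points not 8-adjacent at index {i}: step {key}"
            )
        codes[i] = _FREEMAN_LOOKUP[key]
    return ChainCode(start=(int(pts[0, 0]), int(pts[0, 1])), codes=codes)


def decode_chain(chain: ChainCode) -> np.ndarray:
    """Replay a chain code into pixel coordinates (start pixel included).

    For a closed chain the final step returns to the start and is not
    emitted as a duplicate point.
    """
    steps = _FREEMAN[chain.codes]
    pts = np.vstack([[chain.start], np.array(chain.start) + np.cumsum(steps, axis=0)])
    if len(pts) > 1 and tuple(pts[-1]) == chain.start:
        pts = pts[:-1]
    return pts


def _traversal(points: np.ndarray, parameterization: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Closed piecewise-linear traversal: per-segment dx, dy, dt."""
    closed = np.vstack([points, points[:1]])
    d = np.diff(closed, axis=0)
    if parameterization == "arclength":
        dt = np.hypot(d[:, 0], d[:, 1])
        if np.any(dt == 0):
            keep = dt > 0
            d, dt = d[keep], dt[keep]
        if len(dt) == 0:
            raise ShapeError("contour has zero perimeter")
    elif parameterization == "uniform":
        dt = np.ones(len(d))
    else:
        raise ParameterError(f"unknown parameterization {parameterization!r}")
    return d[:, 0], d[:, 1], dt


def efd_coefficients(
    source,
    n_harmonics: int = 20,
    parameterization: str = "arclength",
) -> EFDCoefficients:
    """Elliptic Fourier coefficients of a closed contour or chain code.

    The contour is treated as a closed piecewise-linear curve and the
    standard elliptic-Fourier integrals are evaluated segment by segment.
    ``parameterization="arclength"`` (default, the chain-code convention,
    where each step advances by its chord length) or ``"uniform"`` (each
    vertex advances the parameter by 1, matching the closed-form Fourier
    series of a curve sampled uniformly in its own parameter).
    """
    if n_harmonics < 1:
        raise ParameterError(f"n_harmonics must be >= 1, got {n_harmonics}")
    if isinstance(source, ChainCode):
        points = decode_chain(source).astype(float)
    else:
        points = np.asarray(source, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2 or len(points) < 3:
        raise ShapeError("need a closed contour with >= 3 points")

    dx, dy, dt = _traversal(points, parameterization)
    t = np.concatenate([[0.0], np.cumsum(dt)])
    T = t[-1]
    phi = 2.0 * np.pi * t / T
    n = np.arange(1, n_harmonics + 1)[:, None]
    dcos = np.diff(np.cos(n * phi), axis=1)
    dsin = np.diff(np.sin(n * phi), axis=1)
    k = T / (2.0 * (n.ravel() ** 2) * np.pi**2)
    vx = dx / dt
    vy = dy / dt
    a = k * (dcos @ vx)
    b = k * (dsin @ vx)
    c = k * (dcos @ vy)
    d = k * (dsin @ vy)

    # DC terms (piecewise-linear closed-form)
    # xi_p = sum_{j<p} dx_j - (dx_p/dt_p) sum_{j<p} dt_j; the p-th terms of
    # the cumulative sums cancel, so no index shift is needed
    xi = np.cumsum(dx) - dx / dt * np.cumsum(dt)
    delta = np.cumsum(dy) - dy / dt * np.cumsum(dt)
    t1, t2 = t[:-1], t[1:]
    a0 = points[0, 0] + (1.0 / T) * np.sum(
        dx / (2.0 * dt) * (t2**2 - t1**2) + xi * dt
    )
    c0 = points[0, 1] + (1.0 / T) * np.sum(
        dy / (2.0 * dt) * (t2**2 - t1**2) + delta * dt
    )
    return EFDCoefficients(a=a, b=b, c=c, d=d, a0=float(a0), c0=float(c0))


def _rotate_start(coef: EFDCoefficients, theta: float) -> EFDCoefficients:
    """Shift the traversal starting point by phase theta."""
    n = np.arange(1, coef.n_harmonics + 1)
    ct, st = np.cos(n * theta), np.sin(n * theta)
    a = coef.a * ct + coef.b * st
    b = -coef.a * st + coef.b * ct
    c = coef.c * ct + coef.d * st
    d = -coef.c * st + coef.d * ct
    return replace(coef, a=a, b=b, c=c, d=d)


def _rotate_plane(coef: EFDCoefficients, psi: float) -> EFDCoefficients:
    """Rotate the shape by -psi in the plane."""
    cp, sp = np.cos(psi), np.sin(psi)
    a = cp * coef.a + sp * coef.c
    b = cp * coef.b + sp * coef.d
    c = -sp * coef.a + cp * coef.c
    d = -sp * coef.b + cp * coef.d
    return replace(coef, a=a, b=b, c=c, d=d)


def _positive_x_area(coef: EFDCoefficients) -> float:
    """Area of the reconstructed outline lying at x > 0 (tie-break metric)."""
    from shapely.geometry import Polygon, box

    pts = reconstruct(coef, n_points=256)
    poly = Polygon(pts)
    if not poly.is_valid:
        poly = poly.buffer(0)
    r = max(abs(pts).max(), 1.0) * 2
    return float(poly.intersection(box(0, -r, r, r)).area)


def normalize_efd(coef: EFDCoefficients) -> EFDCoefficients:
    """Normalize for translation, scale, rotation, and starting point.

    After normalization a1 = 1 and b1 = c1 = 0; d1 holds the signed
    first-harmonic axis ratio.  The traversal is canonicalized to
    counter-clockwise (d1 >= 0).  The remaining half-turn ambiguity of the
    first-harmonic ellipse is resolved by placing the wider half of the
    shape (larger reconstructed area) at positive x; ties fall back to the
    smaller phase, so the result is deterministic.
    """
    a1, b1, c1, d1 = coef.a[0], coef.b[0], coef.c[0], coef.d[0]
    if a1 * a1 + b1 * b1 + c1 * c1 + d1 * d1 <= 0:
        raise ShapeError("degenerate first harmonic")
    # canonical counter-clockwise traversal: a1*d1 - b1*c1 is the signed
    # first-harmonic area; flip the parameter direction if negative
    if a1 * d1 - b1 * c1 < 0:
        coef = replace(coef, b=-coef.b, d=-coef.d)
        a1, b1, c1, d1 = coef.a[0], coef.b[0], coef.c[0], coef.d[0]

    theta = 0.5 * np.arctan2(
        2.0 * (a1 * b1 + c1 * d1), a1 * a1 + c1 * c1 - b1 * b1 - d1 * d1
    )
    candidates = []
    # the half-angle solution locates one first-harmonic axis; quarter-turn
    # shifts cover the other axis and both traversal entries, so we pick the
    # candidates that place the major axis on x
    for k in range(4):
        th = (theta + k * np.pi / 2.0) % (2.0 * np.pi)
        cand = _rotate_start(coef, th)
        psi = np.arctan2(cand.c[0], cand.a[0])
        cand = _rotate_plane(cand, psi)
        scale = cand.a[0]
        if scale <= 0:
            raise ShapeError("degenerate first harmonic after rotation")
        cand = replace(
            cand,
            a=cand.a / scale,
            b=cand.b / scale,
            c=cand.c / scale,
            d=cand.d / scale,
            a0=0.0,
            c0=0.0,
            normalized=True,
        )
        candidates.append(cand)
    major = [c for c in candidates if abs(c.d[0]) <= 1.0 + 1e-9]
    if not major:
        major = candidates
    if len(major) == 1:
        return major[0]
    # wider half at positive x; if the areas tie (symmetric shapes) fall
    # back to an input-invariant lexicographic comparison of coefficients
    areas = np.array([_positive_x_area(c) for c in major])
    spread = areas.max() - areas.min()
    if spread > 1e-6 * max(areas.max(), 1.0):
        return major[int(np.argmax(areas))]
    return _lex_max(major)


def _lex_max(cands: list[EFDCoefficients], tol: float = 1e-7) -> EFDCoefficients:
    """Deterministic, input-invariant pick among near-tied candidates."""
    best = cands[0]
    for cand in cands[1:]:
        va = np.concatenate([best.a, best.b, best.c, best.d])
        vb = np.concatenate([cand.a, cand.b, cand.c, cand.d])
        diff = vb - va
        idx = np.flatnonzero(np.abs(diff) > tol)
        if len(idx) and diff[idx[0]] > 0:
            best = cand
    return best


def drop_asymmetric(coef: EFDCoefficients) -> EFDCoefficients:
    """Zero the b and c series, removing bilaterally asymmetric variation."""
    return replace(coef, b=np.zeros_like(coef.b), c=np.zeros_like(coef.c))


def reconstruct(
    coef: EFDCoefficients,
    n_points: int = 256,
    amplification=None,
) -> np.ndarray:
    """Inverse Fourier sum, optionally amplifying individual harmonics.

    ``amplification`` is a per-harmonic factor >= 0: 0 removes a harmonic,
    1 leaves it unchanged, larger values exaggerate its contribution.
    """
    H = coef.n_harmonics
    if n_points < 4 * H:
        raise ParameterError(f"n_points must be >= 4 * n_harmonics = {4 * H}")
    if amplification is None:
        amp = np.ones(H)
    else:
        amp = np.asarray(amplification, dtype=float)
        if amp.shape != (H,):
            raise ParameterError(f"amplification must have shape ({H},)")
        if np.any(amp < 0):
            raise ParameterError("amplification factors must be >= 0")
    t = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=False)
    n = np.arange(1, H + 1)[:, None]
    cos_nt = np.cos(n * t)
    sin_nt = np.sin(n * t)
    x = coef.a0 + (amp * coef.a) @ cos_nt + (amp * coef.b) @ sin_nt
    y = coef.c0 + (amp * coef.c) @ cos_nt + (amp * coef.d) @ sin_nt
    return np.column_stack([x, y])


def efd_feature_matrix(per_tree_coefs: list[list[EFDCoefficients]]) -> np.ndarray:
    """Per-tree mean of flattened symmetric (a, d) coefficients.

    Rows follow the input tree order; every leaf must carry the same
    number of harmonics.
    """
    if len(per_tree_coefs) == 0:
        raise ParameterError("no trees")
    H = None
    rows = []
    for i, leaves in enumerate(per_tree_coefs):
        if len(leaves) == 0:
            raise ParameterError(f"tree {i} has no leaves")
        feats = []
        for coef in leaves:
            if H is None:
                H = coef.n_harmonics
            elif coef.n_harmonics != H:
                raise ParameterError(
                    f"ragged harmonic counts: {coef.n_harmonics} != {H}"
                )
            feats.append(coef.symmetric_features())
        rows.append(np.mean(feats, axis=0))
    return np.vstack(rows)
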