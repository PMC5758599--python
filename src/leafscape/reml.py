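"""REML adjustment of tree-level phenotypes for orchard position.

The orchard is an incomplete block design on a row-grid x column-grid with
replicated control accessions.  Each phenotype is adjusted with the mixed
model

    phenotype ~ accession + (1 | rGrid) + (1 | cGrid) + (1 | rGrid:cGrid)

where accession is a fixed effect (most accessions are singletons; the
replicated controls identify the positional variance components).  The
restricted likelihood is maximized over the three variance ratios
gamma_k = sigma^2_k / sigma^2_e with the residual variance profiled out;
least-squares means — the GLS accession effects with random effects at
their zero mean — give one positionally adjusted value per accession.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from leafscape.errors import ConvergenceError, ParameterError, ShapeError

__all__ = ["MixedModelFit", "fit_reml", "ls_means", "adjust_traits"]

_RANDOM_TERMS = ("rGrid", "cGrid", "rGrid:cGrid")


@dataclass
class MixedModelFit:
    """A converged REML fit of the positional mixed model."""

    accessions: list
    beta: np.ndarray  # fixed accession effects (cell-means coding)
    varcomp: dict  # sigma^2 per random term + "residual"
    loglik: float  # restricted log-likelihood at the optimum
    converged: bool
    n_obs: int

    def __post_init__(self):
        if len(self.accessions) != len(self.beta):
            raise ShapeError("beta length must match accession count")


def _indicator(labels: pd.Series) -> tuple[np.ndarray, list]:
    levels = list(pd.unique(labels))
    lookup = {lv: i for i, lv in enumerate(levels)}
    Z = np.zeros((len(labels), len(levels)))
    Z[np.arange(len(labels)), [lookup[v] for v in labels]] = 1.0
    return Z, levels


def _design(design: pd.DataFrame):
    for col in ("accession", "rGrid", "cGrid"):
        if col not in design.columns:
            raise ParameterError(f"design table missing column {col!r}")
    X, accessions = _indicator(design["accession"])
    Zs = {}
    Zr, r_levels = _indicator(design["rGrid"])
    Zc, c_levels = _indicator(design["cGrid"])
    inter = design["rGrid"].astype(str) + ":" + design["cGrid"].astype(str)
    Zrc, _ = _indicator(inter)
    for name, Z, n_lv in (
        ("rGrid", Zr, len(r_levels)),
        ("cGrid", Zc, len(c_levels)),
        ("rGrid:cGrid", Zrc, Zrc.shape[1]),
    ):
        if n_lv < 2:
            warnings.warn(
                f"random term {name!r} has a single level and is dropped",
                stacklevel=3,
            )
            continue
        Zs[name] = Z
    return X, accessions, Zs


def _restricted_loglik(log_gamma, y, X, Z_list):
    """-2 * restricted log-likelihood (up to a constant), residual profiled."""
    n, p = X.shape
    V = np.eye(n)
    for lg, Z in zip(log_gamma, Z_list):
        V += math.exp(lg) * (Z @ Z.T)
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        return 1e30, None, None
    logdet_V = 2.0 * float(np.log(np.diag(L)).sum())
    Vi_y = np.linalg.solve(V, y)
    Vi_X = np.linalg.solve(V, X)
    XtViX = X.T @ Vi_X
    sign, logdet_XVX = np.linalg.slogdet(XtViX)
    if sign <= 0:
        return 1e30, None, None
    beta = np.linalg.solve(XtViX, X.T @ Vi_y)
    resid_quad = float(y @ Vi_y - (X.T @ Vi_y) @ beta)
    if resid_quad <= 0:
        return 1e30, None, None
    sigma2_e = resid_quad / (n - p)
    neg2 = logdet_V + logdet_XVX + (n - p) * math.log(resid_quad)
    return neg2, beta, sigma2_e


def fit_reml(
    y,
    design: pd.DataFrame,
    tol: float = 1e-8,
) -> MixedModelFit:
    """Fit the positional mixed model by REML.

    ``y`` is the tree-level phenotype vector aligned with ``design`` (a
    table with columns accession, rGrid, cGrid).  The three variance
    ratios are optimized on the log scale by bounded quasi-Newton from an
    equal-partition start; the all-zero boundary is also evaluated and the
    better point is kept.  Components whose ratio hits the lower bound are
    clamped to exactly zero.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or len(y) != len(design):
        raise ParameterError("y must be 1D and aligned with the design table")
    if not np.all(np.isfinite(y)):
        raise ParameterError("y contains non-finite values")
    X, accessions, Zs = _design(design)
    n, p = X.shape
    if n <= p:
        raise ParameterError(
            f"no residual degrees of freedom: {n} trees, {p} accessions "
            "(replicated accessions are required)"
        )
    names = list(Zs.keys())
    Z_list = [Zs[k] for k in names]
    q = len(Z_list)

    lower, upper = -20.0, 8.0
    if q == 0:
        neg2, beta, s2e = _restricted_loglik([], y, X, [])
        return MixedModelFit(
            accessions=accessions,
            beta=beta,
            varcomp={"residual": s2e},
            loglik=-0.5 * neg2,
            converged=True,
            n_obs=n,
        )

    def objective(lg):
        return _restricted_loglik(lg, y, X, Z_list)[0]

    start = np.full(q, math.log(1.0 / q))
    res = optimize.minimize(
        objective,
        start,
        method="L-BFGS-B",
        bounds=[(lower, upper)] * q,
        options={"ftol": 1e-13, "gtol": 1e-11},
    )
    best = np.asarray(res.x)
    # compare against the all-zero-variance boundary; REML loglik at the
    # optimum must be at least as good
    zero = np.full(q, lower)
    if objective(zero) < objective(best):
        best = zero
    # parsimony cleanup: the design can leave a variance component
    # confounded with the residual (a flat likelihood ridge, e.g. the
    # rGrid:cGrid term when no cell holds two replicated trees); collapse
    # any component to the zero boundary when doing so costs no restricted
    # likelihood beyond numerical tolerance
    cur_obj = objective(best)
    for k in range(q):
        if best[k] <= lower + 1e-9:
            continue
        free = [j for j in range(q) if j != k and best[j] > lower + 1e-9]

        def restricted(lg_free, k=k, free=free):
            lg = np.full(q, lower)
            lg[free] = lg_free
            lg[k] = lower
            return objective(lg)

        if free:
            sub = optimize.minimize(
                restricted,
                best[free],
                method="L-BFGS-B",
                bounds=[(lower, upper)] * len(free),
                options={"ftol": 1e-13, "gtol": 1e-11},
            )
            trial_obj = sub.fun
            trial = np.full(q, lower)
            trial[free] = sub.x
        else:
            trial = np.full(q, lower)
            trial_obj = objective(trial)
        if trial_obj <= cur_obj + 1e-4:
            best, cur_obj = trial, trial_obj
    neg2, beta, s2e = _restricted_loglik(best, y, X, Z_list)
    if beta is None:
        raise ConvergenceError("REML objective undefined at the optimum")
    varcomp = {"residual": s2e}
    for name, lg in zip(names, best):
        gamma = math.exp(lg)
        varcomp[name] = 0.0 if (lg <= lower + 1e-9 or gamma < 1e-8) else gamma * s2e
    for name in _RANDOM_TERMS:
        varcomp.setdefault(name, 0.0)
    return MixedModelFit(
        accessions=accessions,
        beta=beta,
        varcomp=varcomp,
        loglik=-0.5 * neg2,
        converged=bool(np.isfinite(neg2)) and neg2 < 1e29,
        n_obs=n,
    )


def ls_means(fit: MixedModelFit) -> pd.Series:
    """Least-squares mean per accession: the GLS fixed effect with random
    effects at their zero mean.  Exactly one value per accession."""
    if not fit.converged:
        raise ConvergenceError("cannot compute ls-means from an unconverged fit")
    return pd.Series(fit.beta, index=fit.accessions, name="lsmean")


def adjust_traits(traits: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """REML-adjust every trait column; returns accessions x traits."""
    out = {}
    for col in traits.columns:
        mask = traits[col].notna()
        fit = fit_reml(traits.loc[mask, col].values, design.loc[mask])
        out[col] = ls_means(fit)
    return pd.DataFrame(out)
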