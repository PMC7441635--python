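"""Heritability of gene content: single-kinship REML.

Treating the gene content of a locus as a quantitative trait with covariance
K * 2pq turns relationship-matrix checking into variance-component
estimation: if K models the locus's inheritance correctly the estimated
heritability is 1, and systematically lower values expose a mismatched
matrix (e.g., the autosomal A used for an X-linked locus). The model is

    y = 1*mu + u + e,   u ~ N(0, sigma2_u K),  e ~ N(0, sigma2_e I).

For a single kinship plus an identity residual, REML reduces exactly to a
one-dimensional profile likelihood over the variance ratio after one
eigendecomposition of K, so no iterative algorithm (and no convergence
tuning) is needed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .genomic import GenotypeMatrix, X_SPECIFIC
from .matrices import RelationshipMatrix

__all__ = ["VarianceComponents", "reml_single_kinship", "h2_scan"]

_LOG_RATIO_LO, _LOG_RATIO_HI = np.log(1e-6), np.log(1e6)


@dataclass
class VarianceComponents:
    sigma2_u: float
    sigma2_e: float
    h2: float
    logLik: float
    converged: bool
    boundary: bool = False


def _eigen(K: np.ndarray):
    w, U = np.linalg.eigh(0.5 * (K + K.T))
    return np.clip(w, 0.0, None), U


def _neg2_restricted_ll(log_ratio, w, y_rot, x_rot):
    lam = np.exp(log_ratio)
    d = lam * w + 1.0
    xtwx = np.sum(x_rot * x_rot / d)
    xtwy = np.sum(x_rot * y_rot / d)
    mu = xtwy / xtwx
    r = y_rot - mu * x_rot
    n = len(y_rot)
    rss = np.sum(r * r / d)
    sigma2_e = rss / (n - 1)
    return (
        (n - 1) * (np.log(sigma2_e) + 1.0)
        + np.sum(np.log(d))
        + np.log(xtwx)
    ), sigma2_e, mu


def reml_single_kinship(
    y: np.ndarray,
    K: RelationshipMatrix | np.ndarray,
    eig=None,
) -> VarianceComponents:
    """REML fit of the single-kinship model with an intercept.

    Parameters
    ----------
    y : array
        Trait values (gene content, or any phenotype), one per row of K.
    K : RelationshipMatrix or ndarray
        Relationship matrix; positive semidefinite.
    eig : (eigenvalues, eigenvectors), optional
        Reusable eigendecomposition of K (one decomposition serves every
        locus in a scan).

    The variance ratio sigma2_u/sigma2_e is profiled on a log scale over
    [1e-6, 1e6]; estimates at either end are reported converged with
    ``boundary=True`` (a ratio of 1e6 is an h2 of ~1 for practical
    purposes).
    """
    y = np.asarray(y, dtype=float)
    kv = K.values if isinstance(K, RelationshipMatrix) else np.asarray(K, float)
    if len(y) != kv.shape[0]:
        raise ValueError("y length does not match K")
    if np.isnan(y).any():
        raise ValueError("y contains missing values")
    w, U = _eigen(kv) if eig is None else eig
    y_rot = U.T @ y
    x_rot = U.T @ np.ones(len(y))

    res = minimize_scalar(
        lambda t: _neg2_restricted_ll(t, w, y_rot, x_rot)[0],
        bounds=(_LOG_RATIO_LO, _LOG_RATIO_HI),
        method="bounded",
        options={"xatol": 1e-10},
    )
    neg2ll, sigma2_e, _ = _neg2_restricted_ll(res.x, w, y_rot, x_rot)
    lam = float(np.exp(res.x))
    sigma2_u = lam * sigma2_e
    boundary = res.x < _LOG_RATIO_LO + 1e-6 or res.x > _LOG_RATIO_HI - 1e-6
    return VarianceComponents(
        sigma2_u=float(sigma2_u),
        sigma2_e=float(sigma2_e),
        h2=float(lam / (1.0 + lam)),
        logLik=float(-0.5 * neg2ll),
        converged=bool(res.success),
        boundary=bool(boundary),
    )


def h2_scan(
    G: GenotypeMatrix,
    K: RelationshipMatrix,
    maf_min: float = 0.05,
    subset: str = "all",
    region: str = X_SPECIFIC,
):
    """Per-locus heritability of gene content.

    The trait at each locus is the raw gene content ({0,1} males, {0,1,2}
    females). ``subset`` restricts both trait and kinship to ``all`` or
    ``males``; the minor-allele-frequency filter is computed on the analyzed
    subset (a locus common overall can be near-monomorphic among males).

    Returns a DataFrame indexed by locus with columns maf, sigma2_u,
    sigma2_e, h2, boundary, plus a ``summary()``-style mean accessible as
    ``df["h2"].mean()``.
    """
    if subset not in ("all", "males"):
        raise ValueError(f"unknown subset {subset!r}")
    keep_ind = np.ones(G.n, dtype=bool) if subset == "all" else G.is_male
    if not keep_ind.any():
        raise ValueError("empty individual subset")
    mask = G.region_mask(region)
    vals = G.values[np.ix_(keep_ind, mask)]
    male = G.is_male[keep_ind]
    # allele frequency on the analyzed subset, males = one copy
    n_alleles = male.sum() + 2 * (~male).sum()
    p = vals.sum(axis=0) / n_alleles
    maf = np.minimum(p, 1.0 - p)
    sel = maf >= maf_min
    if not sel.any():
        raise ValueError(f"no loci with MAF >= {maf_min} on subset {subset!r}")

    ksub = K.values[np.ix_(keep_ind, keep_ind)]
    eig = _eigen(ksub)
    rows = []
    names = G.loci.index[mask][sel]
    for j, name in zip(np.flatnonzero(sel), names):
        fit = reml_single_kinship(vals[:, j], ksub, eig=eig)
        rows.append(
            (name, maf[j], fit.sigma2_u, fit.sigma2_e, fit.h2, fit.boundary)
        )
    import pandas as pd

    return pd.DataFrame(
        rows, columns=["locus", "maf", "sigma2_u", "sigma2_e", "h2", "boundary"]
    ).set_index("locus")
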