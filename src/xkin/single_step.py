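"""Combining pedigree (S) and genomic (G^X) relationships.

Ungenotyped individuals enter through their conditional expectation given
genotyped relatives: gene content behaves as a heritability-1 quantitative
trait whose covariance is S * 2pq, so the best linear prediction of the
centered gene content of ungenotyped individuals (block 1) from genotyped
ones (block 2) is ``S12 S22^-1 z2``. Propagating the genomic covariance of
block 2 through that regression yields the single-step relationship matrix
H^X and its sparse-friendly inverse.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg as sla

from .matrices import RelationshipMatrix, SparseSymmetricMatrix

__all__ = [
    "PartitionedS",
    "partition_S",
    "predict_gene_content",
    "build_HX",
    "build_HX_inverse",
    "blend",
]

CONDITION_LIMIT = 1e10


@dataclass
class PartitionedS:
    """S split into ungenotyped (1) and genotyped (2) blocks."""

    ids1: list
    ids2: list
    S11: np.ndarray
    S12: np.ndarray
    S22: np.ndarray
    kind: str = "S"

    @property
    def n1(self):
        return len(self.ids1)

    @property
    def n2(self):
        return len(self.ids2)


def partition_S(S: RelationshipMatrix, genotyped_ids) -> PartitionedS:
    """Split S by genotyped status, preserving within-group pedigree order."""
    genotyped = set(genotyped_ids)
    missing = genotyped - set(S.ids)
    if missing:
        raise ValueError(f"genotyped ids absent from S: {sorted(missing)}")
    idx1 = [i for i, lab in enumerate(S.ids) if lab not in genotyped]
    idx2 = [i for i, lab in enumerate(S.ids) if lab in genotyped]
    v = S.values
    return PartitionedS(
        ids1=[S.ids[i] for i in idx1],
        ids2=[S.ids[i] for i in idx2],
        S11=v[np.ix_(idx1, idx1)],
        S12=v[np.ix_(idx1, idx2)],
        S22=v[np.ix_(idx2, idx2)],
        kind=S.kind,
    )


def _solve_S22(Spart: PartitionedS, B: np.ndarray) -> np.ndarray:
    try:
        c, low = sla.cho_factor(Spart.S22)
    except sla.LinAlgError as exc:
        raise ValueError(
            "S22 is singular; blend the genotyped block first"
        ) from exc
    return sla.cho_solve((c, low), B)


def predict_gene_content(Spart: PartitionedS, z2: np.ndarray, pq: float):
    """Predict centered gene content of ungenotyped individuals.

    Returns ``(z1_hat, cond_var)`` with ``z1_hat = S12 S22^-1 z2`` and the
    conditional (co)variance ``(S11 - S12 S22^-1 S21) * 2pq``.
    """
    z2 = np.asarray(z2, dtype=float)
    if z2.shape[0] != Spart.n2:
        raise ValueError("z2 length does not match genotyped block")
    sol = _solve_S22(Spart, np.column_stack([Spart.S12.T, z2.reshape(Spart.n2, -1)]))
    s22inv_s21 = sol[:, : Spart.n1]
    z1_hat = Spart.S12 @ sol[:, Spart.n1:]
    if z2.ndim == 1:
        z1_hat = z1_hat.ravel()
    cond_var = (Spart.S11 - Spart.S12 @ s22inv_s21) * (2.0 * pq)
    return z1_hat, cond_var


def build_HX(Spart: PartitionedS, GX: RelationshipMatrix) -> RelationshipMatrix:
    """Single-step relationship matrix H^X.

    Blocks: upper-left ``S11 - S12 S22^-1 S21 + S12 S22^-1 G^X S22^-1 S21``,
    off-diagonal ``S12 S22^-1 G^X``, lower-right ``G^X``.
    """
    if list(GX.ids) != list(Spart.ids2):
        raise ValueError("GX ids do not match the genotyped block of S")
    g = GX.values
    s22inv_s21 = _solve_S22(Spart, Spart.S12.T)
    P = s22inv_s21.T  # S12 S22^-1
    h11 = Spart.S11 - Spart.S12 @ s22inv_s21 + P @ g @ P.T
    h12 = P @ g
    n1, n2 = Spart.n1, Spart.n2
    h = np.empty((n1 + n2, n1 + n2))
    h[:n1, :n1] = 0.5 * (h11 + h11.T)
    h[:n1, n1:] = h12
    h[n1:, :n1] = h12.T
    h[n1:, n1:] = 0.5 * (g + g.T)
    return RelationshipMatrix(
        ids=Spart.ids1 + Spart.ids2, values=h, kind="HX",
        params={"n_genotyped": n2},
    )


def build_HX_inverse(
    S_inv: SparseSymmetricMatrix,
    Spart: PartitionedS,
    GX: RelationshipMatrix,
) -> SparseSymmetricMatrix:
    """Sparse-form inverse of H^X: ``S^-1 + [[0, 0], [0, GX^-1 - S22^-1]]``.

    The correction touches only the genotyped block. Rows/cols follow the
    ordering of ``S_inv`` (pedigree order), not the partitioned ordering.
    """
    if list(GX.ids) != list(Spart.ids2):
        raise ValueError("GX ids do not match the genotyped block of S")
    g = GX.values
    cond = np.linalg.cond(g)
    if not np.isfinite(cond) or cond > CONDITION_LIMIT:
        raise ValueError(
            f"G^X is numerically singular (condition number {cond:.3g}); "
            "blend with S first"
        )
    g_inv = sla.inv(g)
    g_inv = 0.5 * (g_inv + g_inv.T)
    s22_inv = sla.inv(Spart.S22)
    s22_inv = 0.5 * (s22_inv + s22_inv.T)
    corr = g_inv - s22_inv

    pos = {lab: i for i, lab in enumerate(S_inv.ids)}
    gidx = np.array([pos[lab] for lab in Spart.ids2])
    rows, cols, vals = [list(S_inv.rows), list(S_inv.cols), list(S_inv.vals)]
    n2 = Spart.n2
    for a in range(n2):
        for b in range(a + 1):
            rows.append(gidx[a])
            cols.append(gidx[b])
            vals.append(corr[a, b])
    return SparseSymmetricMatrix(ids=S_inv.ids, rows=rows, cols=cols, vals=vals)


def _moment_match(GX: RelationshipMatrix, S: RelationshipMatrix, is_male: np.ndarray):
    """Two-point linear rescaling of G^X onto S's first moments.

    Solves slope/intercept so that the mean diagonal and the overall mean of
    the adjusted matrix equal those of S, on the variance-equalized scale
    where each male axis is multiplied by sqrt(2) (males carry one X copy,
    so their relationship scale is half the female one).
    """
    w = np.where(is_male, np.sqrt(2.0), 1.0)
    scale = np.outer(w, w)
    g = GX.values * scale
    s = S.values * scale
    mdiag_g, mdiag_s = np.mean(np.diag(g)), np.mean(np.diag(s))
    mall_g, mall_s = g.mean(), s.mean()
    denom = mdiag_g - mall_g
    if abs(denom) < 1e-14:
        slope, intercept = 1.0, mdiag_s - mdiag_g
    else:
        slope = (mdiag_s - mall_s) / denom
        intercept = mall_s - slope * mall_g
    adjusted = (intercept + slope * g) / scale
    return adjusted, slope, intercept


def blend(
    S: RelationshipMatrix,
    GX: RelationshipMatrix,
    alpha: float,
    is_male: np.ndarray | None = None,
    beta: float | None = None,
    moment_match: bool = True,
) -> RelationshipMatrix:
    """Combine ``alpha * S + beta * G^X`` after moment-matching G^X onto S.

    The genomic matrix is first linearly rescaled so its mean diagonal and
    overall mean equal those of S (computed on the male/female
    variance-equalized scale, then mapped back), which removes the
    base-allele-frequency offset; the convex combination then restores
    positive definiteness (alpha around 0.05 suffices in practice).
    ``beta`` defaults to ``1 - alpha``.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha={alpha} outside [0, 1]")
    if beta is None:
        beta = 1.0 - alpha
    if list(S.ids) != list(GX.ids):
        raise ValueError("S and GX must share ids and ordering")
    if is_male is None:
        is_male = np.zeros(S.n, dtype=bool)
    else:
        is_male = np.asarray(is_male, dtype=bool)
    if moment_match:
        g_adj, slope, intercept = _moment_match(GX, S, is_male)
    else:
        g_adj, slope, intercept = GX.values, 1.0, 0.0
    vals = alpha * S.values + beta * g_adj
    return RelationshipMatrix(
        ids=S.ids,
        values=0.5 * (vals + vals.T),
        kind="blended",
        params={"alpha": alpha, "beta": beta, "slope": slope,
                "intercept": intercept},
    )
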