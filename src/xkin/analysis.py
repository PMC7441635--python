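"""Diagnostics for comparing expected and realized relationship matrices.

Correlation rescaling, pedigree pair classification (sire/son, half-sibs by
sex, ...), per-class summaries, matrix-vs-matrix correlations, SVD
dimensionality and the frequency of near-identical pairs — the machinery
used to contrast the X-chromosome GRM with its autosomal counterpart.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .matrices import RelationshipMatrix
from .pedigree import MALE, UNKNOWN, Pedigree

__all__ = [
    "to_correlation",
    "classify_pairs",
    "class_summary",
    "matrix_correlation",
    "svd_dimensionality",
    "high_relationship_proportions",
]

log = logging.getLogger(__name__)

SV_ZERO_REL = 1e-10  # singular values below this fraction of max count as zero


def to_correlation(M: RelationshipMatrix) -> RelationshipMatrix:
    """Rescale relationships to correlations between additive effects.

    ``c_ij = m_ij / sqrt(m_ii m_jj)``; e.g., a dam/son relationship of 0.5
    with diagonals (1, 0.5) becomes 0.71. Requires a strictly positive
    diagonal.
    """
    d = np.diag(M.values)
    bad = np.flatnonzero(d <= 0)
    if bad.size:
        raise ValueError(
            f"non-positive diagonal for individual {M.ids[bad[0]]!r}"
        )
    inv_sd = 1.0 / np.sqrt(d)
    vals = M.values * np.outer(inv_sd, inv_sd)
    return RelationshipMatrix(
        ids=M.ids, values=vals, kind=M.kind,
        params={**M.params, "scale": "correlation"},
    )


def _sex_tag(sex_i: int, sex_j: int) -> str:
    if sex_i == MALE and sex_j == MALE:
        return "two males"
    if sex_i != MALE and sex_j != MALE:
        return "two females"
    return "male/female"


def classify_pairs(ped: Pedigree) -> pd.DataFrame:
    """Classify individual pairs by their pedigree link.

    Classes follow the conventional categories: parent/offspring split by
    both sexes, full-sibs and paternal/maternal half-sibs split by the sex
    pair, and the two diagonal classes. Half-sibs require the non-shared
    parents to be known and distinct; full-sibs are not double-counted as
    half-sibs. Pairs fitting no class are labeled ``other``.
    """
    rows = []
    n = ped.n
    sire, dam, sex = ped.sire, ped.dam, ped.sex
    for i in range(n):
        rows.append(
            ("male diagonal" if sex[i] == MALE else "female diagonal",
             ped.ids[i], ped.ids[i])
        )
    for i in range(n):
        for j in range(i + 1, n):
            cls = None
            # parent/offspring (i earlier than j in topological order)
            if sire[j] == i:
                cls = "sire/son" if sex[j] == MALE else "sire/daughter"
            elif dam[j] == i:
                cls = "dam/son" if sex[j] == MALE else "dam/daughter"
            else:
                same_sire = sire[i] != UNKNOWN and sire[i] == sire[j]
                same_dam = dam[i] != UNKNOWN and dam[i] == dam[j]
                tag = _sex_tag(sex[i], sex[j])
                if same_sire and same_dam:
                    cls = f"full-sibs ({tag})"
                elif same_sire and dam[i] != UNKNOWN and dam[j] != UNKNOWN \
                        and dam[i] != dam[j]:
                    cls = f"paternal half-sibs ({tag})"
                elif same_dam and sire[i] != UNKNOWN and sire[j] != UNKNOWN \
                        and sire[i] != sire[j]:
                    cls = f"maternal half-sibs ({tag})"
            rows.append((cls or "other", ped.ids[i], ped.ids[j]))
    return pd.DataFrame(rows, columns=["class", "id1", "id2"])


def class_summary(M: RelationshipMatrix, classes: pd.DataFrame) -> pd.DataFrame:
    """Mean/SD/count of matrix entries within each pair class."""
    pos = {lab: i for i, lab in enumerate(M.ids)}
    out = []
    for cls, grp in classes.groupby("class", sort=False):
        try:
            vals = np.array(
                [M.values[pos[a], pos[b]] for a, b in zip(grp["id1"], grp["id2"])]
            )
        except KeyError:
            log.info("class %s references ids absent from matrix; skipped", cls)
            continue
        if vals.size == 0:
            log.info("empty relationship class %s", cls)
            continue
        out.append((cls, vals.mean(), vals.std(ddof=1) if vals.size > 1 else 0.0,
                    vals.size))
    return pd.DataFrame(out, columns=["class", "mean", "sd", "n"]).set_index("class")


def _scope_mask(n: int, scope: str, is_male=None) -> np.ndarray:
    iu = np.triu_indices(n, k=0 if scope == "all" else 1)
    if scope == "offdiag-males":
        if is_male is None:
            raise ValueError("offdiag-males scope requires is_male")
        is_male = np.asarray(is_male, dtype=bool)
        keep = is_male[iu[0]] & is_male[iu[1]]
        return iu[0][keep], iu[1][keep]
    return iu


def matrix_correlation(
    Mexp: RelationshipMatrix,
    Mreal: RelationshipMatrix,
    scope: str = "all",
    is_male=None,
) -> float:
    """Pearson correlation between two relationship matrices.

    ``scope``: ``all`` (upper triangle incl. diagonal), ``offdiag``, or
    ``offdiag-males`` (off-diagonal male-male pairs only).
    """
    if list(Mexp.ids) != list(Mreal.ids):
        raise ValueError("matrices must share ids and ordering")
    if scope not in ("all", "offdiag", "offdiag-males"):
        raise ValueError(f"unknown scope {scope!r}")
    r, c = _scope_mask(Mexp.n, scope, is_male)
    return float(np.corrcoef(Mexp.values[r, c], Mreal.values[r, c])[0, 1])


def svd_dimensionality(
    M: RelationshipMatrix, thresholds=(0.90, 0.95, 0.99, 0.999)
):
    """Singular values and the number needed to capture variance fractions.

    The variance share of mode i is ``sv_i^2 / sum(sv_j^2)``. Also reports
    the number of positive singular values (those above 1e-10 of the
    largest).
    """
    sv = np.linalg.svd(M.values, compute_uv=False)
    frac = sv**2 / np.sum(sv**2)
    cum = np.cumsum(frac)
    counts = {
        t: int(np.searchsorted(cum, t - 1e-12) + 1) for t in thresholds
    }
    n_positive = int(np.sum(sv > SV_ZERO_REL * sv.max()))
    return sv, counts, n_positive


def high_relationship_proportions(
    M: RelationshipMatrix, thresholds=(0.90, 0.95, 0.99), subset: str = "all",
    is_male=None,
) -> dict:
    """Proportion of off-diagonal unordered pairs at or above each threshold.

    Pass a correlation-scaled matrix to reproduce the usual "share of
    near-identical pairs" statistic; ``subset="males"`` restricts to
    male-male pairs.
    """
    if subset == "males":
        if is_male is None:
            raise ValueError("subset='males' requires is_male")
        r, c = _scope_mask(M.n, "offdiag-males", is_male)
    else:
        r, c = _scope_mask(M.n, "offdiag")
    vals = M.values[r, c]
    if vals.size == 0:
        return {t: 0.0 for t in thresholds}
    return {t: float(np.mean(vals >= t)) for t in thresholds}
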