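"""Labeled relationship-matrix containers.

Every expected or realized relationship matrix in this package (A, S, S-gamma,
P^r, G, G^X, H^X, blended combinations) is carried as a
:class:`RelationshipMatrix`: an ordered list of individual labels plus a dense
symmetric array of dimensionless relationships. Sparse pedigree inverses
(S^-1, H^X-inverse contributions) travel as symmetric triplets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["RelationshipMatrix", "SparseSymmetricMatrix"]

_SYMMETRY_TOL = 1e-12


@dataclass
class RelationshipMatrix:
    """A labeled symmetric matrix of additive genetic relationships.

    Parameters
    ----------
    ids : list of str
        Individual labels, in pedigree (topological) order.
    values : ndarray of shape (n, n)
        Relationship values; symmetric within 1e-12.
    kind : str
        One of ``A``, ``S``, ``S_gamma``, ``P_r``, ``G``, ``GX``, ``HX``,
        ``blended``.
    params : dict
        Free-form provenance (recombination fraction r, dosage factor k,
        blending weight alpha, allele-frequency source, ...).
    root : ndarray or None
        Optional n x m factor with ``values = root @ root.T``; carried by
        genomic matrices so downstream low-rank algebra (bivariate REML) can
        avoid an eigendecomposition. Never required.
    """

    ids: list
    values: np.ndarray
    kind: str = "A"
    params: dict = field(default_factory=dict)
    root: np.ndarray | None = None

    def __post_init__(self):
        self.ids = list(self.ids)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match {n} ids"
            )
        if n and np.max(np.abs(self.values - self.values.T)) > _SYMMETRY_TOL:
            raise ValueError("relationship matrix is not symmetric within 1e-12")

    @property
    def n(self) -> int:
        return len(self.ids)

    def index(self, label) -> int:
        return self.ids.index(label)

    def loc(self, i, j) -> float:
        """Entry by labels."""
        return float(self.values[self.index(i), self.index(j)])

    def submatrix(self, labels) -> "RelationshipMatrix":
        idx = [self.index(l) for l in labels]
        return RelationshipMatrix(
            ids=[self.ids[i] for i in idx],
            values=self.values[np.ix_(idx, idx)],
            kind=self.kind,
            params=dict(self.params),
        )


@dataclass
class SparseSymmetricMatrix:
    """Symmetric matrix in triplet form; only one triangle need be stored."""

    ids: list
    rows: np.ndarray
    cols: np.ndarray
    vals: np.ndarray

    def __post_init__(self):
        self.ids = list(self.ids)
        self.rows = np.asarray(self.rows, dtype=int)
        self.cols = np.asarray(self.cols, dtype=int)
        self.vals = np.asarray(self.vals, dtype=float)

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def nnz(self) -> int:
        return len(self.vals)

    def to_dense(self) -> np.ndarray:
        out = np.zeros((self.n, self.n))
        np.add.at(out, (self.rows, self.cols), self.vals)
        # mirror: triplets carry each off-diagonal pair once
        off = self.rows != self.cols
        np.add.at(out, (self.cols[off], self.rows[off]), self.vals[off])
        return out

    def triplets(self):
        """Yield (row-label, col-label, value)."""
        for r, c, v in zip(self.rows, self.cols, self.vals):
            yield self.ids[r], self.ids[c], float(v)
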