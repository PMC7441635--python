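"""Realized (marker-based) relationship matrices.

The X-chromosome GRM uses the natural gene-content coding for hemizygous
males, {0,1}, centered by p (not 2p), alongside the usual {0,1,2} female
coding centered by 2p:

    G^X = Z^X Z^X' / (2 * sum(p_j q_j))

The denominator refers to the genetic variance of an ideal female
population, so that under this scaling the expected diagonal is 0.5 for
males and 1 for females, matching the pedigree matrix S. An explicit
dosage-compensation factor k multiplies the centered male rows, giving the
family of GRMs whose k = 1, sqrt(2) and 2 members correspond to no
compensation, equal genotypic variance and full compensation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrices import RelationshipMatrix

__all__ = [
    "GenotypeMatrix",
    "AlleleFrequencies",
    "estimate_allele_freq_x",
    "build_GX",
    "build_G_auto",
    "recode_male_coding",
]

log = logging.getLogger(__name__)

X_SPECIFIC, PAR, AUTOSOME = "X", "PAR", "AUTO"


@dataclass
class GenotypeMatrix:
    """Individuals x loci gene content with sex-aware coding.

    ``values`` holds gene content: males in {0,1} and females in {0,1,2} on
    X-specific loci, both sexes {0,1,2} elsewhere; ``np.nan`` marks missing.
    ``loci`` is a DataFrame indexed by locus name with columns ``region``
    (one of ``X``, ``PAR``, ``AUTO``), ``bp`` and ``cm``.
    """

    ids: list
    sex: np.ndarray  # 1 = male, 2 = female
    values: np.ndarray
    loci: pd.DataFrame
    male_x_coding: str = "01"  # "01" (natural, hemizygous) or "02"

    def __post_init__(self):
        self.ids = list(self.ids)
        self.sex = np.asarray(self.sex, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        n, m = self.values.shape
        if len(self.ids) != n or len(self.loci) != m:
            raise ValueError("genotype matrix dimensions do not match labels")
        if self.male_x_coding == "01":
            male_x = self.values[np.ix_(self.sex == 1, self.region_mask(X_SPECIFIC))]
            if male_x.size and np.nanmax(male_x, initial=0.0) > 1.0:
                raise ValueError(
                    "male gene content > 1 on an X-specific locus; "
                    "recode {0,2} male coding first (recode_male_coding)"
                )

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def is_male(self) -> np.ndarray:
        return self.sex == 1

    def region_mask(self, region: str) -> np.ndarray:
        return (self.loci["region"] == region).to_numpy()

    def subset_loci(self, mask) -> "GenotypeMatrix":
        return GenotypeMatrix(
            ids=self.ids,
            sex=self.sex,
            values=self.values[:, mask],
            loci=self.loci.loc[np.asarray(mask)],
        )


@dataclass
class AlleleFrequencies:
    """Per-locus reference-allele frequencies with their provenance."""

    p: np.ndarray
    source: str = "sample"  # sample | base | fixed-0.5
    monomorphic: np.ndarray = field(default=None)

    def __post_init__(self):
        self.p = np.asarray(self.p, dtype=float)
        if self.monomorphic is None:
            self.monomorphic = (self.p <= 0.0) | (self.p >= 1.0)
        self.monomorphic = np.asarray(self.monomorphic, dtype=bool)


def estimate_allele_freq_x(G: GenotypeMatrix, mask=None) -> AlleleFrequencies:
    """Allele frequencies on X-specific loci, males counted as one allele.

    ``p = (sum male copies + sum female copies) / (n_males + 2 n_females)``,
    with missing entries excluded per locus.
    """
    if mask is None:
        mask = G.region_mask(X_SPECIFIC)
    vals = G.values[:, mask]
    male = G.is_male
    obs = ~np.isnan(vals)
    if not obs.any(axis=0).all():
        bad = np.flatnonzero(~obs.any(axis=0))
        names = list(G.loci.index[mask][bad])
        raise ValueError(f"loci with all genotypes missing: {names}")
    copies = np.nansum(vals, axis=0)
    n_alleles = obs[male].sum(axis=0) + 2 * obs[~male].sum(axis=0)
    p = copies / n_alleles
    freqs = AlleleFrequencies(p=p, source="sample")
    if freqs.monomorphic.any():
        log.info("%d monomorphic X loci flagged", int(freqs.monomorphic.sum()))
    return freqs


def _impute_to_sex_mean(vals: np.ndarray, male: np.ndarray) -> np.ndarray:
    """Fill missing entries with the per-locus mean of the same sex."""
    out = vals.copy()
    for sel in (male, ~male):
        block = out[sel]
        if not block.size:
            continue
        miss = np.isnan(block)
        if miss.any():
            with np.errstate(invalid="ignore"):
                col_mean = np.nanmean(block, axis=0)
            col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
            block[miss] = np.broadcast_to(col_mean, block.shape)[miss]
            out[sel] = block
    return out


def _centered_Z(vals, male, p, k):
    center = np.where(male[:, None], p[None, :], 2.0 * p[None, :])
    z = vals - center
    z[male] *= k
    return z


def build_GX(
    G: GenotypeMatrix,
    freqs: AlleleFrequencies,
    k: float = 1.0,
    weighted: bool = False,
) -> RelationshipMatrix:
    """X-chromosome GRM from X-specific loci.

    Centered gene content ``Z``: males ``(m - p) * k``, females ``m - 2p``;
    ``G^X = Z Z' / (2 sum p_j q_j)``. With ``weighted=True`` each locus is
    standardized by its own ``2 p_j q_j`` before an unweighted cross-product
    (rare alleles get more weight). Missing genotypes are imputed to the
    per-locus mean of the same sex; monomorphic loci are dropped.
    """
    if k <= 0:
        raise ValueError("dosage factor k must be positive")
    mask = G.region_mask(X_SPECIFIC)
    vals = G.values[:, mask]
    p = np.asarray(freqs.p, dtype=float)
    if p.shape[0] != vals.shape[1]:
        raise ValueError("allele-frequency vector does not match X-specific loci")
    keep = ~freqs.monomorphic
    if not keep.any():
        raise ValueError("all X-specific loci are monomorphic")
    dropped = int((~keep).sum())
    if dropped:
        log.info("dropping %d monomorphic loci from G^X", dropped)
    vals, p = vals[:, keep], p[keep]
    vals = _impute_to_sex_mean(vals, G.is_male)
    z = _centered_Z(vals, G.is_male, p, k)
    pq = p * (1.0 - p)
    if weighted:
        root = z / np.sqrt(2.0 * pq * len(pq))[None, :]
    else:
        root = z / np.sqrt(2.0 * pq.sum())
    gx = root @ root.T
    return RelationshipMatrix(
        ids=G.ids,
        values=gx,
        kind="GX",
        params={"k": k, "weighted": weighted, "freq_source": freqs.source,
                "n_loci": int(keep.sum())},
        root=root,
    )


def build_G_auto(
    G: GenotypeMatrix, freqs: AlleleFrequencies, region: str = AUTOSOME
) -> RelationshipMatrix:
    """Autosomal-style GRM (VanRaden method 1): Z = M - 2p, G = ZZ'/2*sum(pq).

    Also the correct construction for PAR loci, where both sexes are
    diploid; pass ``region="PAR"`` to route those loci here.
    """
    mask = G.region_mask(region)
    vals = G.values[:, mask]
    p = np.asarray(freqs.p, dtype=float)
    if p.shape[0] != vals.shape[1]:
        raise ValueError("allele-frequency vector does not match loci")
    keep = ~freqs.monomorphic
    if not keep.any():
        raise ValueError("all loci are monomorphic")
    vals, p = vals[:, keep], p[keep]
    vals = _impute_to_sex_mean(vals, G.is_male)
    z = vals - 2.0 * p[None, :]
    pq = p * (1.0 - p)
    root = z / np.sqrt(2.0 * pq.sum())
    return RelationshipMatrix(
        ids=G.ids,
        values=root @ root.T,
        kind="G",
        params={"freq_source": freqs.source, "n_loci": int(keep.sum()),
                "region": region},
        root=root,
    )


def estimate_allele_freq(G: GenotypeMatrix, region: str = AUTOSOME) -> AlleleFrequencies:
    """Sample allele frequencies for diploid (autosomal or PAR) loci."""
    mask = G.region_mask(region)
    vals = G.values[:, mask]
    obs = ~np.isnan(vals)
    if not obs.any(axis=0).all():
        bad = np.flatnonzero(~obs.any(axis=0))
        names = list(G.loci.index[mask][bad])
        raise ValueError(f"loci with all genotypes missing: {names}")
    p = np.nansum(vals, axis=0) / (2.0 * obs.sum(axis=0))
    return AlleleFrequencies(p=p, source="sample")


def recode_male_coding(G: GenotypeMatrix) -> GenotypeMatrix:
    """Convert {0,2} male coding on X-specific loci to the natural {0,1}.

    Raises on a male entry of 1 (an apparent heterozygous male), which is
    impossible on the hemizygous X-specific region.
    """
    if G.male_x_coding == "01":
        return G
    mask = G.region_mask(X_SPECIFIC)
    vals = G.values.copy()
    male_x = vals[np.ix_(G.is_male, mask)]
    odd = np.isclose(male_x, 1.0)
    if odd.any():
        raise ValueError(
            f"{int(odd.sum())} heterozygous male X genotypes under {{0,2}} coding"
        )
    male_x = male_x / 2.0
    vals[np.ix_(G.is_male, mask)] = male_x
    return GenotypeMatrix(ids=G.ids, sex=G.sex, values=vals, loci=G.loci)
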