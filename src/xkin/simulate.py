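"""Gene-dropping simulator for X-specific, pseudo-autosomal and autosomal loci.

This module is the statistical oracle of the package: alleles are dropped
through arbitrary pedigrees under the exact transmission model that the
expected-relationship recursions formalize, so that empirical gene-content
covariances can be compared with S*2pq, P^r*2pq and A*2pq.

Transmission model
------------------
* X-specific: males carry one haplotype (from the dam); daughters receive
  the sire's haplotype intact (no Mendelian sampling, no recombination);
  maternal gametes recombine along the female map (Haldane, no
  interference).
* PAR: both sexes are diploid. Male meiosis starts at the pseudo-autosomal
  boundary on the haplotype matching the offspring's sex (the Y-side
  paternal haplotype for sons, the X-side maternal haplotype for daughters)
  and switches haplotype at each Haldane crossover, producing the
  sex-gradient; female meiosis behaves autosomally.
* Autosome: standard diploid dropping with Haldane recombination.

All randomness flows through a single :class:`numpy.random.Generator` seeded
from ``SimConfig.seed``; runs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genomic import AUTOSOME, PAR, X_SPECIFIC, GenotypeMatrix
from .pedigree import FEMALE, MALE, UNKNOWN, Pedigree, haldane

__all__ = [
    "SimConfig",
    "GameteRecord",
    "simulate_pedigree",
    "gene_drop_x",
    "gene_drop_par",
    "gene_drop_autosome",
    "simulate_phenotypes",
    "transmission_profile",
]


@dataclass
class SimConfig:
    """Study conditions for a simulation run.

    Parameters
    ----------
    seed : int
        Mandatory; every random draw descends from it.
    n_generations : int
        Number of generations after the founders.
    n_males, n_females : int
        Individuals of each sex per generation.
    n_loci : int
        Loci per simulated region.
    base_freq : float or array
        Founder allele frequency (scalar or per-locus).
    map_length : float
        Female X map length in Morgan (also used for the matched autosome);
        loci are evenly spaced. 1.0 M is a realistic mammalian X scale, at
        which ~37% of female gametes carry no crossover.
    independent_loci : bool
        Drop every locus independently (infinite map); the regime of the
        covariance oracles, where linkage is irrelevant.
    par_cm : array or None
        Per-locus male-map cM distances to the PAB for PAR dropping;
        defaults to ``linspace(0, 50, n_loci)``.
    k : float
        Dosage-compensation factor scaling male genotypic values.
    r_g : float
        Cross-sex correlation of marker effects.
    h2_target : float
        Heritability of the simulated phenotype in females.
    """

    seed: int
    n_generations: int = 3
    n_males: int = 5
    n_females: int = 20
    n_loci: int = 200
    base_freq: float = 0.5
    map_length: float = 1.0
    independent_loci: bool = False
    par_cm: np.ndarray | None = None
    k: float = 1.0
    r_g: float = 1.0
    h2_target: float = 0.5

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def freqs(self) -> np.ndarray:
        return np.broadcast_to(
            np.asarray(self.base_freq, dtype=float), (self.n_loci,)
        ).copy()

    def x_cm(self) -> np.ndarray:
        return np.linspace(0.0, 100.0 * self.map_length, self.n_loci)

    def par_positions(self) -> np.ndarray:
        if self.par_cm is not None:
            return np.asarray(self.par_cm, dtype=float)
        return np.linspace(0.0, 50.0, self.n_loci)


@dataclass
class GameteRecord:
    """Per-meiosis transmission records.

    ``meioses`` has one row per recorded meiosis (parent, offspring, their
    sexes, crossover count); ``origins`` is the matching (n_meioses, n_loci)
    array with 0 = parent's paternal haplotype transmitted, 1 = maternal.
    """

    meioses: pd.DataFrame
    origins: np.ndarray


def simulate_pedigree(cfg: SimConfig) -> Pedigree:
    """Discrete-generation random-mating pedigree.

    Founders are generation 0; every later individual draws a random sire
    and dam from the previous generation.
    """
    if cfg.n_males < 1 or cfg.n_females < 1:
        raise ValueError("each generation needs at least one male and one female")
    rng = np.random.default_rng(cfg.seed + 1)  # pedigree stream
    ids, sire, dam, sex = [], [], [], []
    prev_m, prev_f = [], []
    for g in range(cfg.n_generations + 1):
        cur_m, cur_f = [], []
        for j in range(cfg.n_males + cfg.n_females):
            is_male = j < cfg.n_males
            label = f"G{g}{'M' if is_male else 'F'}{j if is_male else j - cfg.n_males}"
            idx = len(ids)
            ids.append(label)
            sex.append(MALE if is_male else FEMALE)
            if g == 0:
                sire.append(UNKNOWN)
                dam.append(UNKNOWN)
            else:
                sire.append(int(rng.choice(prev_m)))
                dam.append(int(rng.choice(prev_f)))
            (cur_m if is_male else cur_f).append(idx)
        prev_m, prev_f = cur_m, cur_f
    return Pedigree(ids=ids, sire=np.array(sire), dam=np.array(dam),
                    sex=np.array(sex))


def _meiosis_phase(rng, n_loci, cm, independent, start=None):
    """Haplotype-of-origin vector along one gamete (0/1 per locus).

    ``start`` anchors the phase at the PAB (male PAR meiosis). In the
    independent-loci regime each locus keeps its correct marginal: with an
    anchored start the switch probability at map position d is the Haldane
    fraction c(d) (odd number of Poisson crossovers in [0, d]); without an
    anchor the marginal is an even draw.
    """
    if independent:
        if start is None:
            return rng.integers(0, 2, size=n_loci)
        return start ^ (rng.random(n_loci) < haldane(cm)).astype(np.int64)
    rec = haldane(np.diff(cm))
    switches = rng.random(n_loci - 1) < rec
    first = rng.integers(0, 2) if start is None else start
    phase = np.empty(n_loci, dtype=np.int64)
    phase[0] = first
    phase[1:] = first ^ np.cumsum(switches) % 2
    return phase


def _crossovers(phase) -> int:
    return int(np.sum(phase[1:] != phase[:-1]))


def gene_drop_x(ped: Pedigree, cfg: SimConfig):
    """Drop X-specific loci through a pedigree.

    Returns the gene-content matrix ({0,1} males, {0,1,2} females) and the
    gamete records of every meiosis. Sires pass their single haplotype to
    daughters unchanged and nothing to sons.
    """
    rng = cfg.rng()
    L = cfg.n_loci
    p = cfg.freqs()
    cm = cfg.x_cm()
    hap = {}  # individual index -> (n_copies, L) array
    rec_rows, rec_origins = [], []
    for i in range(ped.n):
        d = ped.dam[i]
        s = ped.sire[i]
        if d == UNKNOWN:
            maternal = (rng.random(L) < p).astype(np.int8)
        else:
            phase = _meiosis_phase(rng, L, cm, cfg.independent_loci)
            dam_h = hap[d]
            maternal = np.where(phase == 0, dam_h[0], dam_h[1])
            rec_rows.append(
                (ped.ids[d], ped.ids[i], "F", "M" if ped.sex[i] == MALE else "F",
                 _crossovers(phase))
            )
            rec_origins.append(phase)
        if ped.sex[i] == MALE:
            hap[i] = maternal[None, :]
        else:
            if s == UNKNOWN:
                paternal = (rng.random(L) < p).astype(np.int8)
            else:
                paternal = hap[s][0].copy()  # intact, zero crossovers
                rec_rows.append((ped.ids[s], ped.ids[i], "M", "F", 0))
                rec_origins.append(np.zeros(L, dtype=np.int64))
            hap[i] = np.stack([paternal, maternal])
    values = np.stack([hap[i].sum(axis=0) for i in range(ped.n)]).astype(float)
    loci = _loci_frame(L, X_SPECIFIC, cm)
    gm = GenotypeMatrix(ids=ped.ids, sex=ped.sex, values=values, loci=loci)
    return gm, _pack_records(rec_rows, rec_origins, L)


def gene_drop_par(ped: Pedigree, cfg: SimConfig):
    """Drop pseudo-autosomal loci through a pedigree.

    Male meiosis starts on the offspring-sex-matched haplotype at the PAB
    and recombines along the male PAR map; female meiosis is autosomal-like
    on the same positions.
    """
    rng = cfg.rng()
    L = cfg.n_loci
    p = cfg.freqs()
    cm = cfg.par_positions()
    hap = {}
    rec_rows, rec_origins = [], []

    def founder():
        return (rng.random(L) < p).astype(np.int8)

    for i in range(ped.n):
        s, d = ped.sire[i], ped.dam[i]
        if s == UNKNOWN:
            paternal = founder()
        else:
            start = 0 if ped.sex[i] == MALE else 1  # Y-side for sons, X-side for daughters
            phase = _meiosis_phase(rng, L, cm, cfg.independent_loci, start=start)
            sire_h = hap[s]
            paternal = np.where(phase == 0, sire_h[0], sire_h[1])
            rec_rows.append(
                (ped.ids[s], ped.ids[i], "M", "M" if ped.sex[i] == MALE else "F",
                 _crossovers(phase))
            )
            rec_origins.append(phase)
        if d == UNKNOWN:
            maternal = founder()
        else:
            phase = _meiosis_phase(rng, L, cm, cfg.independent_loci)
            dam_h = hap[d]
            maternal = np.where(phase == 0, dam_h[0], dam_h[1])
            rec_rows.append(
                (ped.ids[d], ped.ids[i], "F", "M" if ped.sex[i] == MALE else "F",
                 _crossovers(phase))
            )
            rec_origins.append(phase)
        hap[i] = np.stack([paternal, maternal])
    values = np.stack([hap[i].sum(axis=0) for i in range(ped.n)]).astype(float)
    loci = _loci_frame(L, PAR, cm)
    gm = GenotypeMatrix(ids=ped.ids, sex=ped.sex, values=values, loci=loci)
    return gm, _pack_records(rec_rows, rec_origins, L)


def gene_drop_autosome(ped: Pedigree, cfg: SimConfig) -> GenotypeMatrix:
    """Standard diploid gene dropping (the oracle for A and the autosomal G)."""
    rng = cfg.rng()
    L = cfg.n_loci
    p = cfg.freqs()
    cm = cfg.x_cm()  # matched map length with the X preset
    hap = {}
    for i in range(ped.n):
        gametes = []
        for parent in (ped.sire[i], ped.dam[i]):
            if parent == UNKNOWN:
                gametes.append((rng.random(L) < p).astype(np.int8))
            else:
                phase = _meiosis_phase(rng, L, cm, cfg.independent_loci)
                ph = hap[parent]
                gametes.append(np.where(phase == 0, ph[0], ph[1]))
        hap[i] = np.stack(gametes)
    values = np.stack([hap[i].sum(axis=0) for i in range(ped.n)]).astype(float)
    loci = _loci_frame(L, AUTOSOME, cm)
    return GenotypeMatrix(ids=ped.ids, sex=ped.sex, values=values, loci=loci)


def _loci_frame(L, region, cm):
    names = [f"{region}_{j:05d}" for j in range(L)]
    return pd.DataFrame(
        {"region": region, "bp": (1 + np.round(cm * 1e6)).astype(int), "cm": cm},
        index=names,
    )


def _pack_records(rows, origins, L) -> GameteRecord:
    frame = pd.DataFrame(
        rows, columns=["parent", "offspring", "parent_sex", "offspring_sex",
                       "crossovers"]
    )
    arr = (np.stack(origins) if origins else np.zeros((0, L), dtype=np.int64))
    return GameteRecord(meioses=frame, origins=arr)


def simulate_phenotypes(G: GenotypeMatrix, cfg: SimConfig) -> pd.DataFrame:
    """Phenotypes under dosage compensation k and cross-sex correlation r_g.

    Marker effects for the female trait are iid standard normal; male-trait
    effects correlate r_g with them and are scaled by k, so male genotypic
    variance is k^2/2 times the female one at Hardy-Weinberg equilibrium.
    Residual noise is calibrated so the female-trait heritability equals
    ``h2_target``.
    """
    rng = np.random.default_rng(cfg.seed + 2)  # phenotype stream
    L = G.values.shape[1]
    alpha_f = rng.standard_normal(L)
    noise = rng.standard_normal(L)
    alpha_m = cfg.k * (cfg.r_g * alpha_f + np.sqrt(max(0.0, 1 - cfg.r_g**2)) * noise)
    male = G.is_male
    g = np.where(male, G.values @ alpha_m, G.values @ alpha_f)
    var_gf = float(np.var(g[~male])) if (~male).sum() > 1 else float(np.var(g))
    if cfg.h2_target <= 0:
        sd_e = np.sqrt(var_gf) if var_gf > 0 else 1.0
        g = np.zeros_like(g)
    else:
        sd_e = np.sqrt(var_gf * (1.0 - cfg.h2_target) / cfg.h2_target)
    y = g + sd_e * rng.standard_normal(G.n)
    return pd.DataFrame(
        {"id": G.ids, "sex": np.where(male, "M", "F"), "value": y}
    )


def transmission_profile(rec: GameteRecord, loci: pd.DataFrame) -> pd.DataFrame:
    """Empirical P(paternal haplotype transmitted) per locus and sex pair.

    One row per locus, columns ``sire_son``, ``sire_daughter``, ``dam_son``,
    ``dam_daughter`` plus the locus cM position. Reproduces the PAR
    sex-gradient curves from simulated truth.
    """
    out = {"cm": loci["cm"].to_numpy()}
    pairs = {
        "sire_son": ("M", "M"),
        "sire_daughter": ("M", "F"),
        "dam_son": ("F", "M"),
        "dam_daughter": ("F", "F"),
    }
    for name, (ps, os_) in pairs.items():
        sel = (
            (rec.meioses["parent_sex"] == ps)
            & (rec.meioses["offspring_sex"] == os_)
        ).to_numpy()
        if sel.any():
            out[name] = 1.0 - rec.origins[sel].mean(axis=0)
        else:
            out[name] = np.full(len(loci), np.nan)
    return pd.DataFrame(out, index=loci.index)
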