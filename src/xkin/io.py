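"""Readers and writers for pedigrees, genotypes, maps and relationship
matrices.

Formats
-------
* Pedigree: CSV/TSV with header ``id,sire,dam,sex``; unknown parent 0/NA;
  sex M/F or 1/2 (1 = male).
* Genotypes: PLINK ``.raw``-style (FID IID PAT MAT SEX PHENOTYPE + one
  additive column per SNP) or plain TSV (first column id, one column per
  locus) with sexes from a companion pedigree.
* Marker map: TSV with columns ``chrom, id, cm, bp``; loci on the X
  chromosome are X-specific up to the pseudo-autosomal boundary (PAB) and
  PAR beyond it.
* Relationship matrices: square TSV (bit-exact round trip at 12 significant
  digits), long triplet TSV, and GCTA-style text GRM (id1, id2, n_loci,
  value).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genomic import AUTOSOME, PAR, X_SPECIFIC, GenotypeMatrix
from .matrices import RelationshipMatrix, SparseSymmetricMatrix
from .pedigree import Pedigree, prepare_pedigree

__all__ = [
    "RunConfig",
    "read_pedigree",
    "read_map",
    "read_genotypes",
    "write_genotypes",
    "read_grm",
    "write_grm",
    "write_sparse",
]

log = logging.getLogger(__name__)

FLOAT_FMT = "%.12g"
# documented example: the bovine PAB on assembly ARS-UCD1.2
EXAMPLE_PAB_BP = 133_300_518


@dataclass
class RunConfig:
    """Resolved run configuration; logged in full at startup."""

    pab_bp: int = EXAMPLE_PAB_BP
    x_chrom: tuple = ("X", "x", "30", "chrX")
    male_het_tolerance: float = 0.0
    seed: int = 0
    paths: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        cfg = cls(**known)
        log.info("resolved config: %s", cfg)
        return cfg


def _sep(path) -> str:
    with open(path) as fh:
        head = fh.readline()
    return "\t" if "\t" in head else ","


def read_pedigree(path) -> Pedigree:
    df = pd.read_csv(path, sep=_sep(path), dtype=str)
    return prepare_pedigree(df)


def write_pedigree(ped: Pedigree, path) -> None:
    ped.to_frame().to_csv(path, sep="\t", index=False)


def read_map(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sep(path))
    df.columns = [c.lower() for c in df.columns]
    for need in ("chrom", "id", "cm", "bp"):
        if need not in df.columns:
            raise ValueError(f"map file missing column {need!r}")
    return df.set_index("id")


def _regions(map_df: pd.DataFrame, cfg: RunConfig) -> pd.DataFrame:
    chrom = map_df["chrom"].astype(str)
    on_x = chrom.isin([str(c) for c in cfg.x_chrom])
    region = np.where(
        on_x, np.where(map_df["bp"] <= cfg.pab_bp, X_SPECIFIC, PAR), AUTOSOME
    )
    return pd.DataFrame(
        {"region": region, "bp": map_df["bp"], "cm": map_df["cm"]},
        index=map_df.index,
    )


def read_genotypes(
    path,
    map_df: pd.DataFrame,
    cfg: RunConfig | None = None,
    pedigree: Pedigree | None = None,
    fmt: str | None = None,
) -> GenotypeMatrix:
    """Read genotypes and normalize male X coding to {0,1}.

    ``fmt`` is ``raw`` or ``tsv`` (guessed from the extension). Males coded
    {0,2} on X-specific loci are auto-halved with a logged notice;
    heterozygous male X calls above ``cfg.male_het_tolerance`` (as a
    fraction of male X genotypes) raise with the loci listed. Sexes come
    from the .raw SEX column or from ``pedigree``.
    """
    cfg = cfg or RunConfig()
    fmt = fmt or ("raw" if str(path).endswith(".raw") else "tsv")
    if fmt == "raw":
        df = pd.read_csv(path, sep=r"\s+")
        ids = df["IID"].astype(str).tolist()
        sex = df["SEX"].astype(int).to_numpy()
        snp_cols = [
            c for c in df.columns
            if c not in ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE")
        ]
        vals = df[snp_cols].to_numpy(dtype=float)
        # PLINK suffixes counted allele: SNP_A -> SNP
        names = [c.rsplit("_", 1)[0] if "_" in c else c for c in snp_cols]
    else:
        df = pd.read_csv(path, sep=_sep(path))
        ids = df.iloc[:, 0].astype(str).tolist()
        names = list(df.columns[1:])
        vals = df.iloc[:, 1:].to_numpy(dtype=float)
        sex = None
    if sex is None or (np.asarray(sex) == 0).any():
        if pedigree is None:
            raise ValueError("missing sex information: provide a pedigree")
        pos = {lab: i for i, lab in enumerate(pedigree.ids)}
        missing = [i for i in ids if i not in pos]
        if missing:
            raise ValueError(f"individuals without sex/pedigree record: {missing}")
        sex = pedigree.sex[[pos[i] for i in ids]]
    sex = np.asarray(sex, dtype=int)
    if not np.isin(sex, (1, 2)).all():
        bad = [ids[i] for i in np.flatnonzero(~np.isin(sex, (1, 2)))]
        raise ValueError(f"missing sex for individuals: {bad}")

    missing_map = [n for n in names if n not in map_df.index]
    if missing_map:
        raise ValueError(f"loci absent from map: {missing_map[:10]}")
    loci = _regions(map_df.loc[names], cfg)
    order = np.lexsort((loci["bp"].to_numpy(), loci["region"].to_numpy()))
    loci = loci.iloc[order]
    vals = vals[:, order]

    # normalize male X coding
    xmask = (loci["region"] == X_SPECIFIC).to_numpy()
    male = sex == 1
    male_x = vals[np.ix_(male, xmask)]
    # PLINK .raw additive coding is {0,2} for hemizygous males; a plain TSV
    # is taken as the natural {0,1} unless a male 2 proves otherwise
    coding02 = fmt == "raw" or (
        male_x.size and np.nanmax(male_x, initial=0.0) > 1.0
    )
    if male_x.size and coding02:
        # under {0,2} a 1 is an impossible heterozygous hemizygote
        het = np.isclose(male_x, 1.0)
        if het.any():
            frac = het.mean()
            if frac > cfg.male_het_tolerance:
                bad_loci = list(loci.index[xmask][het.any(axis=0)])
                raise ValueError(
                    f"heterozygous male X genotypes ({frac:.3%}) at loci "
                    f"{bad_loci[:10]}"
                )
            male_x[het] = np.nan
        log.info("male X genotypes coded {0,2}: halving to {0,1}")
        vals[np.ix_(male, xmask)] = male_x / 2.0
    return GenotypeMatrix(ids=ids, sex=sex, values=vals, loci=loci)


def write_genotypes(G: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(G.values, index=pd.Index(G.ids, name="id"),
                      columns=G.loci.index)
    df.to_csv(path, sep="\t", float_format="%g")


# ---------------------------------------------------------------------------
# relationship matrices
# ---------------------------------------------------------------------------

def write_grm(M: RelationshipMatrix, path, fmt: str = "square",
              n_loci: int | None = None) -> None:
    path = Path(path)
    if fmt == "square":
        df = pd.DataFrame(M.values, index=pd.Index(M.ids, name="id"),
                          columns=M.ids)
        df.to_csv(path, sep="\t", float_format=FLOAT_FMT)
    elif fmt == "triplet":
        rows, nz = [], 0
        for i in range(M.n):
            for j in range(i + 1):
                v = M.values[i, j]
                if abs(v) > 1e-12:
                    rows.append((M.ids[i], M.ids[j], v))
                else:
                    nz += 1
        with open(path, "w") as fh:
            fh.write(f"# kind={M.kind} omitted_zeros={nz}\n")
            fh.write("id1\tid2\tvalue\n")
            for a, b, v in rows:
                fh.write(f"{a}\t{b}\t{FLOAT_FMT % v}\n")
    elif fmt == "gcta-text":
        m = n_loci if n_loci is not None else M.params.get("n_loci", 0)
        with open(path, "w") as fh:
            for i in range(M.n):
                for j in range(i + 1):
                    fh.write(
                        f"{M.ids[i]}\t{M.ids[j]}\t{m}\t"
                        f"{FLOAT_FMT % M.values[i, j]}\n"
                    )
    else:
        raise ValueError(f"unknown GRM format {fmt!r}")


def read_grm(path, fmt: str = "square", kind: str = "A") -> RelationshipMatrix:
    if fmt == "square":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return RelationshipMatrix(
            ids=[str(i) for i in df.index], values=df.to_numpy(dtype=float),
            kind=kind,
        )
    if fmt in ("triplet", "gcta-text"):
        if fmt == "triplet":
            df = pd.read_csv(path, sep="\t", comment="#")
            a, b, v = df["id1"], df["id2"], df["value"]
        else:
            df = pd.read_csv(path, sep="\t",
                             names=["id1", "id2", "n", "value"])
            a, b, v = df["id1"], df["id2"], df["value"]
        ids = list(dict.fromkeys([*map(str, a), *map(str, b)]))
        pos = {lab: i for i, lab in enumerate(ids)}
        out = np.zeros((len(ids), len(ids)))
        for ai, bi, vi in zip(a, b, v):
            i, j = pos[str(ai)], pos[str(bi)]
            out[i, j] = out[j, i] = vi
        return RelationshipMatrix(ids=ids, values=out, kind=kind)
    raise ValueError(f"unknown GRM format {fmt!r}")


def write_sparse(S: SparseSymmetricMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("id1\tid2\tvalue\n")
        for a, b, v in S.triplets():
            fh.write(f"{a}\t{b}\t{FLOAT_FMT % v}\n")
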