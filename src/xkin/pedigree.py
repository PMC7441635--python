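"""Expected (pedigree-based) relationship matrices.

Four recursions live here, all driven by a topologically sorted pedigree:

* ``build_A`` -- the ordinary autosomal numerator relationship matrix
  (tabular method).
* ``build_S`` -- the X-specific relationship matrix. Males are hemizygous:
  they carry a single X copy, inherited from the dam, so a male's diagonal is
  exactly 0.5 (on the scale where the gene-content variance of an ideal
  female population is 1) and a male is unrelated to his sire.
* ``build_S_metafounders`` -- the same recursion with unknown parents
  replaced by sexed metafounder pseudo-parents carrying relationships gamma.
* ``build_P_par`` -- the expected relationship matrix for a
  pseudo-autosomal locus at recombination fraction ``r`` from the
  pseudo-autosomal boundary. Sires transmit the Y-side (paternal) haplotype
  to sons and the X-side (maternal) haplotype to daughters with probability
  1 - r, which creates a sex-gradient of relationships along the PAR; dams
  transmit either haplotype with probability 0.5.

All matrices are scaled so that ``Var(gene content) = M * 2pq`` for the
matrix ``M`` at a biallelic locus with allele frequencies p, q, males coded
{0,1} and females {0,1,2}.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrices import RelationshipMatrix, SparseSymmetricMatrix

__all__ = [
    "Pedigree",
    "PedigreeError",
    "MetafounderConfig",
    "prepare_pedigree",
    "build_A",
    "build_S",
    "build_S_inverse",
    "build_S_metafounders",
    "build_P_par",
    "rescale_S",
    "haldane",
]

MALE, FEMALE = 1, 2
UNKNOWN = -1

_MALE_CODES = {"m", "male", "1"}
_FEMALE_CODES = {"f", "female", "2"}
_UNKNOWN_CODES = {"0", "", "na", "nan", "none", ".", "unknown"}


class PedigreeError(ValueError):
    """Structural problem in a pedigree (cycle, sex conflict, duplicate id)."""


@dataclass
class Pedigree:
    """A validated, topologically sorted pedigree.

    ``sire``/``dam`` hold positional indices into ``ids`` (parents always
    precede offspring) or :data:`UNKNOWN` for base individuals. ``sex`` is
    1 for males, 2 for females.
    """

    ids: list
    sire: np.ndarray
    dam: np.ndarray
    sex: np.ndarray

    def __post_init__(self):
        self.ids = list(self.ids)
        self.sire = np.asarray(self.sire, dtype=int)
        self.dam = np.asarray(self.dam, dtype=int)
        self.sex = np.asarray(self.sex, dtype=int)

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def is_male(self) -> np.ndarray:
        return self.sex == MALE

    def index(self, label) -> int:
        return self.ids.index(label)

    def to_frame(self) -> pd.DataFrame:
        def lab(idx):
            return [self.ids[i] if i != UNKNOWN else "0" for i in idx]

        return pd.DataFrame(
            {
                "id": self.ids,
                "sire": lab(self.sire),
                "dam": lab(self.dam),
                "sex": np.where(self.is_male, "M", "F"),
            }
        )


def _parse_sex(value) -> int:
    s = str(value).strip().lower()
    if s in _MALE_CODES:
        return MALE
    if s in _FEMALE_CODES:
        return FEMALE
    raise PedigreeError(f"unrecognized sex code {value!r}")


def _is_unknown(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and np.isnan(value):
        return True
    return str(value).strip().lower() in _UNKNOWN_CODES


def prepare_pedigree(raw_records) -> Pedigree:
    """Validate and topologically sort raw pedigree records.

    Parameters
    ----------
    raw_records : DataFrame or sequence of (id, sire, dam, sex)
        Unknown parents coded 0 / NA / empty; sex coded M/F, male/female or
        1/2 (1 = male). Parents that appear only in a sire or dam column are
        added as base individuals of the implied sex.

    Raises
    ------
    PedigreeError
        On duplicated ids, a label used both as sire and dam (or recorded
        with the opposite sex), or a pedigree cycle.
    """
    if isinstance(raw_records, pd.DataFrame):
        cols = {c.lower(): c for c in raw_records.columns}
        for need in ("id", "sire", "dam", "sex"):
            if need not in cols:
                raise PedigreeError(f"missing pedigree column {need!r}")
        rows = list(
            zip(
                raw_records[cols["id"]],
                raw_records[cols["sire"]],
                raw_records[cols["dam"]],
                raw_records[cols["sex"]],
            )
        )
    else:
        rows = [tuple(r) for r in raw_records]

    ids, sire_of, dam_of, sex_of = [], {}, {}, {}
    for rid, s, d, x in rows:
        rid = str(rid).strip()
        if rid in sex_of:
            raise PedigreeError(f"duplicated id {rid!r}")
        ids.append(rid)
        sex_of[rid] = _parse_sex(x)
        sire_of[rid] = None if _is_unknown(s) else str(s).strip()
        dam_of[rid] = None if _is_unknown(d) else str(d).strip()

    # implicit founders + parental-role sex validation
    for rid in list(ids):
        s, d = sire_of[rid], dam_of[rid]
        if s is not None:
            if s in sex_of:
                if sex_of[s] != MALE:
                    raise PedigreeError(
                        f"{s!r} is recorded as female but used as sire of {rid!r}"
                    )
            else:
                sex_of[s] = MALE
                sire_of[s] = dam_of[s] = None
                ids.append(s)
        if d is not None:
            if d in sex_of:
                if sex_of[d] != FEMALE:
                    raise PedigreeError(
                        f"{d!r} is recorded as male but used as dam of {rid!r}"
                    )
            else:
                sex_of[d] = FEMALE
                sire_of[d] = dam_of[d] = None
                ids.append(d)

    # Kahn topological sort, stable in input order
    order_of_input = {rid: i for i, rid in enumerate(ids)}
    children = {rid: [] for rid in ids}
    n_parents = {rid: 0 for rid in ids}
    for rid in ids:
        for p in (sire_of[rid], dam_of[rid]):
            if p is not None:
                children[p].append(rid)
                n_parents[rid] += 1
    ready = sorted((r for r in ids if n_parents[r] == 0), key=order_of_input.get)
    out = []
    while ready:
        rid = ready.pop(0)
        out.append(rid)
        newly = []
        for c in children[rid]:
            n_parents[c] -= 1
            if n_parents[c] == 0:
                newly.append(c)
        # keep overall order as close to input order as possible
        ready = sorted(ready + newly, key=order_of_input.get)
    if len(out) < len(ids):
        stuck = next(r for r in ids if r not in set(out))
        raise PedigreeError(f"pedigree cycle detected involving {stuck!r}")

    pos = {rid: i for i, rid in enumerate(out)}
    sire = np.array(
        [pos[sire_of[r]] if sire_of[r] is not None else UNKNOWN for r in out]
    )
    dam = np.array(
        [pos[dam_of[r]] if dam_of[r] is not None else UNKNOWN for r in out]
    )
    sex = np.array([sex_of[r] for r in out])
    return Pedigree(ids=out, sire=sire, dam=dam, sex=sex)


# ---------------------------------------------------------------------------
# autosomal A (tabular method)
# ---------------------------------------------------------------------------

def build_A(ped: Pedigree) -> RelationshipMatrix:
    """Autosomal numerator relationship matrix by the tabular method.

    ``a_ii = 1 + 0.5 a_sd``; ``a_ij = 0.5 (a_js + a_jd)`` for earlier j;
    unknown parents contribute 0.
    """
    n = ped.n
    a = np.zeros((n, n))
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        if i:
            row = np.zeros(i)
            if s != UNKNOWN:
                row += 0.5 * a[s, :i]
            if d != UNKNOWN:
                row += 0.5 * a[d, :i]
            a[i, :i] = row
            a[:i, i] = row
        a[i, i] = 1.0 + (0.5 * a[s, d] if s != UNKNOWN and d != UNKNOWN else 0.0)
    return RelationshipMatrix(ids=ped.ids, values=a, kind="A")


# ---------------------------------------------------------------------------
# X-specific S
# ---------------------------------------------------------------------------

def _s_recursion(ped: Pedigree, base: np.ndarray, n_meta: int) -> np.ndarray:
    """Run the X-chromosome recursion over ``base`` (which already holds the
    founder block in rows/cols ``[0, n_meta)``); real individual i occupies
    row ``n_meta + i``."""
    s = base
    for i in range(ped.n):
        r = n_meta + i
        sr = ped.sire[i]
        dm = ped.dam[i]
        sp = n_meta + sr if sr != UNKNOWN else None
        dp = n_meta + dm if dm != UNKNOWN else None
        if r:
            row = np.zeros(r)
            if ped.sex[i] == MALE:
                if dp is not None:
                    row += 0.5 * s[dp, :r]
            else:
                if sp is not None:
                    row += s[sp, :r]
                if dp is not None:
                    row += 0.5 * s[dp, :r]
            s[r, :r] = row
            s[:r, r] = row
        if ped.sex[i] == MALE:
            s[r, r] = 0.5
        else:
            s[r, r] = 1.0 + (s[sp, dp] if sp is not None and dp is not None else 0.0)
    return s


def build_S(ped: Pedigree) -> RelationshipMatrix:
    """X-specific expected relationship matrix.

    A male inherits his single X from his dam: ``S(i, x) = 0.5 S(dam, x)``
    and ``S(i, i) = 0.5`` always. A female inherits her sire's X intact plus
    one dam gamete: ``S(i, x) = S(sire, x) + 0.5 S(dam, x)`` and
    ``S(i, i) = 1 + S(sire, dam)``. Base males have diagonal 0.5, base
    females 1.
    """
    n = ped.n
    s = _s_recursion(ped, np.zeros((n, n)), 0)
    return RelationshipMatrix(ids=ped.ids, values=s, kind="S")


def build_S_inverse(ped: Pedigree, S: RelationshipMatrix | None = None) -> SparseSymmetricMatrix:
    """Sparse inverse of S, accumulated from per-individual contributions.

    Each individual contributes ``(1/v_i) (e_i - sum_p b_p e_p)
    (e_i - sum_p b_p e_p)'`` with regression coefficients b = {0.5 on the
    dam} for males and {1 on the sire, 0.5 on the dam} for females
    (unknown-parent terms dropped), and Mendelian-sampling variance
    ``v_i = S_ii - b' S_PP b``.
    """
    if S is None:
        S = build_S(ped)
    sval = S.values
    acc: dict[tuple[int, int], float] = {}

    def add(i, j, v):
        key = (i, j) if i >= j else (j, i)
        acc[key] = acc.get(key, 0.0) + v

    for i in range(ped.n):
        parents, coefs = [], []
        if ped.sex[i] == FEMALE and ped.sire[i] != UNKNOWN:
            parents.append(ped.sire[i])
            coefs.append(1.0)
        if ped.dam[i] != UNKNOWN:
            parents.append(ped.dam[i])
            coefs.append(0.5)
        b = np.array(coefs)
        if parents:
            spp = sval[np.ix_(parents, parents)]
            v = sval[i, i] - float(b @ spp @ b)
        else:
            v = sval[i, i]
        if v <= 0:
            raise ValueError(
                f"non-positive Mendelian sampling variance for {ped.ids[i]!r}: "
                "corrupted S diagonal"
            )
        w = 1.0 / v
        add(i, i, w)
        for p, bp in zip(parents, b):
            add(i, p, -w * bp)
        for pi, bi in zip(parents, b):
            for pj, bj in zip(parents, b):
                if pi >= pj:
                    add(pi, pj, w * bi * bj)

    rows = np.array([k[0] for k in acc])
    cols = np.array([k[1] for k in acc])
    vals = np.array([acc[k] for k in acc])
    return SparseSymmetricMatrix(ids=ped.ids, rows=rows, cols=cols, vals=vals)


# ---------------------------------------------------------------------------
# metafounders
# ---------------------------------------------------------------------------

@dataclass
class MetafounderConfig:
    """Metafounder pseudo-parents absorbing unknown base relationships.

    Parameters
    ----------
    groups : dict
        Genetic group name -> (male-line label, female-line label).
    gamma : DataFrame or ndarray
        Symmetric relationships among metafounder labels, values in [0, 2].
        When an ndarray, rows/cols follow the order of labels implied by
        ``groups`` (male then female within each group).
    assign : dict, optional
        Individual id -> group name for its unknown-parent slots. May be
        omitted when there is a single group (all individuals assigned to it).
    """

    groups: dict
    gamma: object
    assign: dict | None = None

    def labels(self) -> list:
        out = []
        for m, f in self.groups.values():
            out.extend([m, f])
        return out

    def gamma_matrix(self) -> np.ndarray:
        labels = self.labels()
        if isinstance(self.gamma, pd.DataFrame):
            g = self.gamma.loc[labels, labels].to_numpy(dtype=float)
        else:
            g = np.asarray(self.gamma, dtype=float)
        if g.shape != (len(labels), len(labels)):
            raise ValueError("gamma shape does not match metafounder labels")
        if np.max(np.abs(g - g.T)) > 1e-12:
            raise ValueError("gamma must be symmetric")
        if g.min() < 0 or g.max() > 2:
            raise ValueError("gamma values must lie in [0, 2]")
        return g


def build_S_metafounders(ped: Pedigree, cfg: MetafounderConfig) -> RelationshipMatrix:
    """X-specific relationship matrix with metafounders (S-gamma).

    Unknown parent slots are replaced by the sexed metafounders of the
    individual's genetic group and the ordinary S recursion runs with the
    metafounder block seeded from gamma. The founder block entry between
    metafounders a and b is ``gamma_ab * w_a * w_b`` with ``w = 0.5`` for a
    male-line and ``1`` for a female-line metafounder, which makes the
    recursion reproduce the gametic model in which any two base gametes from
    lines a and b are identical by descent with probability ``gamma_ab / 2``
    (allele frequency 0.5 convention). With gamma = 0 the result equals
    :func:`build_S` exactly.
    """
    labels = cfg.labels()
    g = cfg.gamma_matrix()
    nm = len(labels)
    group_names = list(cfg.groups)

    def group_of(i):
        if cfg.assign is not None and ped.ids[i] in cfg.assign:
            return cfg.assign[ped.ids[i]]
        if cfg.assign is None and len(group_names) == 1:
            return group_names[0]
        raise ValueError(
            f"unknown parent of {ped.ids[i]!r} not assigned to a metafounder group"
        )

    # weights: male-line metafounders contribute a single gamete (scale 0.5)
    w = np.array([0.5, 1.0] * len(group_names))
    base = np.zeros((nm + ped.n, nm + ped.n))
    base[:nm, :nm] = g * np.outer(w, w)

    # reroute unknown parents to the group's metafounders
    ped2 = Pedigree(ids=ped.ids, sire=ped.sire.copy(), dam=ped.dam.copy(), sex=ped.sex)
    meta_pos = {lab: k for k, lab in enumerate(labels)}
    for i in range(ped.n):
        if ped.sire[i] == UNKNOWN or ped.dam[i] == UNKNOWN:
            grp = group_of(i)
            m_lab, f_lab = cfg.groups[grp]
            if ped.sire[i] == UNKNOWN:
                ped2.sire[i] = meta_pos[m_lab] - nm  # negative offset, see below
            if ped.dam[i] == UNKNOWN:
                ped2.dam[i] = meta_pos[f_lab] - nm

    # _s_recursion expects parent row = n_meta + index; encode metafounder
    # parents as negative indices so that n_meta + idx lands in the block.
    s = base
    for i in range(ped.n):
        r = nm + i
        sp = nm + ped2.sire[i]
        dp = nm + ped2.dam[i]
        row = np.zeros(r)
        if ped.sex[i] == MALE:
            row += 0.5 * s[dp, :r]
        else:
            row += s[sp, :r]
            row += 0.5 * s[dp, :r]
        s[r, :r] = row
        s[:r, r] = row
        if ped.sex[i] == MALE:
            s[r, r] = 0.5
        else:
            s[r, r] = 1.0 + s[sp, dp]

    vals = s[nm:, nm:]
    return RelationshipMatrix(
        ids=ped.ids, values=vals, kind="S_gamma", params={"groups": group_names}
    )


# ---------------------------------------------------------------------------
# pseudo-autosomal P^r
# ---------------------------------------------------------------------------

def haldane(d_cm: float) -> float:
    """Haldane map function: recombination fraction at map distance d (cM)."""
    return 0.5 * (1.0 - np.exp(-2.0 * d_cm / 100.0))


def build_P_par(ped: Pedigree, r: float) -> RelationshipMatrix:
    """Expected relationship matrix for a PAR locus at recombination
    fraction ``r`` from the pseudo-autosomal boundary.

    Gametic recursion: a son's paternal gamete is the sire's paternal
    (Y-side) gamete with probability 1 - r, a daughter's is the sire's
    maternal (X-side) gamete with probability 1 - r; maternal gametes are
    an even draw from the dam. The individual matrix averages the four
    gametic relationships; at r = 0.5 the sex-gradient vanishes and P^0.5
    equals the autosomal A exactly.
    """
    if not 0.0 <= r <= 0.5:
        raise ValueError(f"recombination fraction r={r} outside [0, 0.5]")
    n = ped.n
    gam = np.zeros((2 * n, 2 * n))  # gametes: paternal 2i, maternal 2i+1
    for i in range(n):
        p_i, m_i = 2 * i, 2 * i + 1
        s, d = ped.sire[i], ped.dam[i]
        if ped.sex[i] == MALE:
            w_pat, w_mat = 1.0 - r, r  # sons follow the Y-side haplotype
        else:
            w_pat, w_mat = r, 1.0 - r  # daughters follow the X-side haplotype
        # maternal gamete first (depends only on earlier gametes)
        if d != UNKNOWN:
            row = 0.5 * (gam[2 * d, :p_i] + gam[2 * d + 1, :p_i])
            gam[m_i, :p_i] = row
            gam[:p_i, m_i] = row
        if s != UNKNOWN:
            row = w_pat * gam[2 * s, : p_i] + w_mat * gam[2 * s + 1, : p_i]
            gam[p_i, :p_i] = row
            gam[:p_i, p_i] = row
            if d != UNKNOWN:
                cross = w_pat * gam[2 * s, m_i] + w_mat * gam[2 * s + 1, m_i]
                gam[p_i, m_i] = gam[m_i, p_i] = cross
        gam[p_i, p_i] = 1.0
        gam[m_i, m_i] = 1.0

    pat = gam[0::2, :][:, 0::2]
    mat = gam[1::2, :][:, 1::2]
    cross = gam[0::2, :][:, 1::2]
    vals = 0.5 * (pat + mat + cross + cross.T)
    return RelationshipMatrix(ids=ped.ids, values=vals, kind="P_r", params={"r": r})


# ---------------------------------------------------------------------------
# coding rescaling
# ---------------------------------------------------------------------------

def rescale_S(S: RelationshipMatrix, ped: Pedigree, k: float) -> RelationshipMatrix:
    """Rescale S for a {0, k} male gene-content coding.

    Multiplies the male-male block by k^2 and the male-female blocks by k;
    the female block is unchanged. With k = 2 this matches the {0,2} male
    coding whose gene-content variance is 4pq.
    """
    if S.kind not in ("S", "S_gamma"):
        raise ValueError(f"rescale_S expects an S or S_gamma matrix, got {S.kind!r}")
    if k <= 0:
        raise ValueError(f"scaling factor k={k} must be positive")
    scale = np.where(ped.is_male, k, 1.0)
    vals = S.values * np.outer(scale, scale)
    params = dict(S.params)
    params["k"] = k
    return RelationshipMatrix(ids=S.ids, values=vals, kind=S.kind, params=params)
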