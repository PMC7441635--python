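"""Pedigree recursions: A, S, S^-1, S-gamma, P^r and coding rescaling."""

import numpy as np
import pytest

from conftest import random_pedigree
from helpers import assert_cov_matches

from xkin.pedigree import (
    MetafounderConfig,
    PedigreeError,
    build_A,
    build_P_par,
    build_S,
    build_S_inverse,
    build_S_metafounders,
    haldane,
    prepare_pedigree,
    rescale_S,
)


class TestPreparePedigree:
    def test_parents_precede_offspring(self):
        ped = prepare_pedigree(
            [("o", "s", "d", "M"), ("s", "0", "0", "M"), ("d", "0", "0", "F")]
        )
        assert ped.ids.index("s") < ped.ids.index("o")
        assert ped.ids.index("d") < ped.ids.index("o")

    def test_sorted_pedigree_unchanged(self):
        recs = [("a", "0", "0", "M"), ("b", "0", "0", "F"), ("c", "a", "b", "F")]
        assert prepare_pedigree(recs).ids == ["a", "b", "c"]

    def test_duplicated_id_rejected(self):
        with pytest.raises(PedigreeError, match="duplicated"):
            prepare_pedigree([("a", "0", "0", "M"), ("a", "0", "0", "M")])

    def test_sire_also_dam_rejected(self):
        with pytest.raises(PedigreeError):
            prepare_pedigree(
                [("p", "0", "0", "M"), ("x", "p", "0", "M"), ("y", "0", "p", "F")]
            )

    def test_cycle_detected(self):
        with pytest.raises(PedigreeError, match="cycle"):
            prepare_pedigree(
                [("a", "b", "0", "M"), ("b", "c", "0", "M"), ("c", "a", "0", "M")]
            )

    def test_implicit_founder_gets_parent_sex(self):
        ped = prepare_pedigree([("o", "s", "d", "F")])
        assert ped.sex[ped.index("s")] == 1
        assert ped.sex[ped.index("d")] == 2


# Canonical expected relationships: (autosomal, X) per class
TABLE1 = {
    ("s1", "fsM1"): (0.50, 0.00),  # sire/son
    ("s1", "fsF1"): (0.50, 0.50),  # sire/daughter
    ("d1", "fsM1"): (0.50, 0.50),  # dam/son
    ("d1", "fsF1"): (0.50, 0.50),  # dam/daughter
    ("fsM1", "phM"): (0.25, 0.00),  # paternal half-sibs, two males
    ("fsF1", "phF"): (0.25, 0.50),  # paternal half-sibs, two females
    ("mhM1", "mhM2"): (0.25, 0.25),  # maternal half-sibs, two males
    ("mhF1", "mhF2"): (0.25, 0.25),  # maternal half-sibs, two females
    ("fsM1", "fsM2"): (0.50, 0.25),  # full brothers
    ("fsF1", "fsF2"): (0.50, 0.75),  # full sisters
    ("fsM1", "fsM1"): (1.00, 0.50),  # male diagonal
    ("fsF1", "fsF1"): (1.00, 1.00),  # female diagonal
}


class TestAandS:
    @pytest.mark.parametrize("pair,expected", TABLE1.items(),
                             ids=["_".join(k) for k in TABLE1])
    def test_canonical_relationships(self, table1_pedigree, pair, expected):
        a = build_A(table1_pedigree)
        s = build_S(table1_pedigree)
        exp_a, exp_s = expected
        assert a.loc(*pair) == pytest.approx(exp_a, abs=1e-12)
        assert s.loc(*pair) == pytest.approx(exp_s, abs=1e-12)

    def test_unrelated_base_pair(self, trio):
        assert build_A(trio).loc("s", "d") == 0.0
        assert build_S(trio).loc("s", "d") == 0.0

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_male_diagonal_exactly_half(self, seed):
        ped = random_pedigree(seed, n=30)
        s = build_S(ped)
        male_diag = np.diag(s.values)[ped.is_male]
        assert (male_diag == 0.5).all()

    def test_dam_daughter_chain_matches_A(self):
        """Along an all-female maternal line both matrices halve per step."""
        ped = prepare_pedigree(
            [("g0", "0", "0", "F"), ("g1", "0", "g0", "F"), ("g2", "0", "g1", "F")]
        )
        a, s = build_A(ped), build_S(ped)
        for pair in [("g0", "g1"), ("g1", "g2"), ("g0", "g2")]:
            assert s.loc(*pair) == a.loc(*pair)


class TestSInverse:
    def test_single_base_individuals(self):
        male = prepare_pedigree([("m", "0", "0", "M")])
        female = prepare_pedigree([("f", "0", "0", "F")])
        assert build_S_inverse(male).to_dense()[0, 0] == pytest.approx(2.0)
        assert build_S_inverse(female).to_dense()[0, 0] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", [10, 11, 12, 13, 14])
    def test_inverse_times_S_is_identity(self, seed):
        ped = random_pedigree(seed, n=20)
        s = build_S(ped)
        sinv = build_S_inverse(ped)
        prod = sinv.to_dense() @ s.values
        assert np.abs(prod - np.eye(ped.n)).max() < 1e-8

    @pytest.mark.parametrize("seed", [10, 11, 12])
    def test_sparsity_bound(self, seed):
        ped = random_pedigree(seed, n=40)
        assert build_S_inverse(ped).nnz <= 9 * ped.n


class TestMetafounders:
    CFG0 = dict(groups={"g": ("Mm", "Mf")})

    def test_zero_gamma_reduces_to_S(self):
        ped = random_pedigree(5, n=15)
        cfg = MetafounderConfig(gamma=np.zeros((2, 2)), **self.CFG0)
        sg = build_S_metafounders(ped, cfg)
        assert np.array_equal(sg.values, build_S(ped).values)

    def test_positive_gamma_relates_base_females(self):
        ped = prepare_pedigree([("b", "0", "0", "F"), ("c", "0", "0", "F")])
        cfg = MetafounderConfig(gamma=0.4 * np.ones((2, 2)), **self.CFG0)
        sg = build_S_metafounders(ped, cfg)
        assert sg.loc("b", "c") > 0

    def test_unassigned_group_raises(self):
        ped = prepare_pedigree([("b", "0", "0", "F")])
        cfg = MetafounderConfig(
            groups={"g1": ("M1", "F1"), "g2": ("M2", "F2")},
            gamma=np.zeros((4, 4)),
        )
        with pytest.raises(ValueError, match="not assigned"):
            build_S_metafounders(ped, cfg)

    def test_gene_drop_oracle_with_structured_founders(self):
        """S-gamma matches dropping where base gametes of line a are IBD to
        a shared line allele with probability s_a (gamma = 2 s s')."""
        ped = prepare_pedigree(
            [("a", "0", "0", "M"), ("b", "0", "0", "F"), ("c", "0", "0", "F"),
             ("x", "a", "b", "F"), ("y", "a", "c", "M"), ("z", "0", "b", "F"),
             ("w", "0", "c", "M"), ("v", "a", "x", "F")]
        )
        s_m, s_f = 0.6, 0.4
        gamma = 2.0 * np.outer([s_m, s_f], [s_m, s_f])
        sg = build_S_metafounders(
            ped, MetafounderConfig(gamma=gamma, **self.CFG0)
        )
        rng = np.random.default_rng(3)
        L = 200_000
        shared_allele = rng.random(L) < 0.5

        def line_gamete(s):
            from_line = rng.random(L) < s
            fresh = rng.random(L) < 0.5
            return np.where(from_line, shared_allele, fresh).astype(np.int8)

        hap = {}
        for i, lab in enumerate(ped.ids):
            si, di = ped.sire[i], ped.dam[i]
            if di == -1:
                mat = line_gamete(s_f)
            else:
                pick = rng.integers(0, 2, L)
                dh = hap[ped.ids[di]]
                mat = np.where(pick == 0, dh[0], dh[1])
            if ped.sex[i] == 1:
                hap[lab] = [mat]
            else:
                pat = line_gamete(s_m) if si == -1 else hap[ped.ids[si]][0]
                hap[lab] = [pat, mat]
        vals = np.stack([np.sum(hap[l], axis=0) for l in ped.ids]).astype(float)
        assert_cov_matches(vals, sg.values * 0.5)  # 2pq = 0.5 at p = 0.5


class TestPPar:
    def test_r_half_equals_A_exactly(self):
        ped = random_pedigree(7, n=25)
        assert np.array_equal(build_P_par(ped, 0.5).values, build_A(ped).values)

    def test_r_zero_paternal_chain(self):
        """At r = 0 a grandson's paternal PAR gamete is the grandsire's."""
        ped = prepare_pedigree(
            [("gs", "0", "0", "M"), ("d1", "0", "0", "F"), ("d2", "0", "0", "F"),
             ("s1", "gs", "d1", "M"), ("o", "s1", "d2", "M")]
        )
        assert build_P_par(ped, 0.0).loc("gs", "o") == pytest.approx(0.5)

    def test_noninbred_diagonal_is_one(self):
        ped = random_pedigree(8, n=20)
        p = build_P_par(ped, 0.2)
        a = build_A(ped)
        # individuals without inbreeding have diagonal exactly 1 in A;
        # the PAR diagonal deviates only through parental gametic correlation
        non_inbred = np.isclose(np.diag(a.values), 1.0)
        founders = (ped.sire == -1) & (ped.dam == -1)
        assert np.allclose(np.diag(p.values)[founders], 1.0)
        assert (np.diag(p.values)[non_inbred] >= 1.0 - 1e-12).all()

    @pytest.mark.parametrize("r", [-0.1, 0.6, 1.0])
    def test_r_out_of_range(self, trio, r):
        with pytest.raises(ValueError):
            build_P_par(trio, r)

    def test_haldane_limits(self):
        assert haldane(0.0) == 0.0
        assert haldane(1e9) == pytest.approx(0.5)


class TestRescaleS:
    def test_k_one_is_identity(self, table1_pedigree):
        s = build_S(table1_pedigree)
        assert np.array_equal(
            rescale_S(s, table1_pedigree, 1.0).values, s.values
        )

    def test_k_two_blocks(self, trio):
        s2 = rescale_S(build_S(trio), trio, 2.0)
        assert s2.loc("son", "son") == pytest.approx(2.0)  # 0.5 * k^2
        assert s2.loc("d", "son") == pytest.approx(1.0)  # 0.5 * k
        assert s2.loc("d", "dau") == pytest.approx(0.5)  # female block intact

    def test_invalid_inputs(self, trio):
        s = build_S(trio)
        with pytest.raises(ValueError):
            rescale_S(s, trio, 0.0)
        with pytest.raises(ValueError):
            rescale_S(build_A(trio), trio, 2.0)
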