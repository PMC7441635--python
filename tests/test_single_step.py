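"""Single-step machinery: gene-content prediction, H^X, inverse, blending."""

import numpy as np
import pytest

from conftest import random_pedigree

from xkin.matrices import RelationshipMatrix
from xkin.pedigree import build_S, build_S_inverse
from xkin.simulate import SimConfig, gene_drop_x, simulate_pedigree
from xkin.single_step import (
    blend,
    build_HX,
    build_HX_inverse,
    partition_S,
    predict_gene_content,
)


def _as_gx(S, ids):
    sub = S.submatrix(ids)
    return RelationshipMatrix(ids=sub.ids, values=sub.values, kind="GX")


class TestPredictGeneContent:
    def test_single_relative_regression(self):
        """An ungenotyped dam's prediction regresses on her genotyped son."""
        from xkin.pedigree import prepare_pedigree

        ped = prepare_pedigree(
            [("d", "0", "0", "F"), ("son", "0", "d", "M"), ("u", "0", "0", "M")]
        )
        s = build_S(ped)
        sp = partition_S(s, ["son", "u"])
        z2 = np.array([0.4, -0.1])
        z1, _ = predict_gene_content(sp, z2, pq=0.25)
        coef = s.loc("d", "son") / s.loc("son", "son")
        assert z1[0] == pytest.approx(coef * 0.4)

    def test_unrelated_prediction_zero(self):
        from xkin.pedigree import prepare_pedigree

        ped = prepare_pedigree(
            [("a", "0", "0", "F"), ("b", "0", "0", "M"), ("c", "0", "0", "F")]
        )
        s = build_S(ped)
        sp = partition_S(s, ["b", "c"])
        z1, cv = predict_gene_content(sp, np.array([0.3, 0.7]), pq=0.21)
        assert z1[0] == pytest.approx(0.0)
        assert cv[0, 0] == pytest.approx(s.loc("a", "a") * 2 * 0.21)

    def test_monte_carlo_calibration(self):
        """Squared prediction error is bounded by the conditional variance."""
        cfg = SimConfig(seed=20, n_generations=2, n_males=3, n_females=6,
                        n_loci=10_000, base_freq=0.4, independent_loci=True)
        ped = simulate_pedigree(cfg)
        G, _ = gene_drop_x(ped, cfg)
        s = build_S(ped)
        genotyped = ped.ids[::2]
        sp = partition_S(s, genotyped)
        p = 0.4
        pq = p * (1 - p)
        male = G.is_male
        center = np.where(male, p, 2 * p)
        Z = G.values - center[:, None]
        gidx = [ped.index(i) for i in sp.ids2]
        uidx = [ped.index(i) for i in sp.ids1]
        z1_hat, cond = predict_gene_content(sp, Z[gidx], pq=pq)
        mse = np.mean((Z[uidx] - z1_hat) ** 2, axis=1)
        expected = np.diag(cond)
        # MSE per ungenotyped individual should match the conditional
        # variance within Monte-Carlo noise (chi^2 over 1e4 loci)
        se = expected * np.sqrt(2 / cfg.n_loci)
        assert (mse <= expected + 5 * se).all()
        assert (mse >= expected - 5 * se).all()

    def test_singular_S22_raises(self):
        from xkin.pedigree import prepare_pedigree

        ped = prepare_pedigree([("a", "0", "0", "F"), ("b", "0", "0", "F")])
        s = build_S(ped)
        sp = partition_S(s, ["a", "b"])
        sp.S22 = np.ones((2, 2))  # deliberately singular
        with pytest.raises(ValueError, match="blend"):
            predict_gene_content(sp, np.zeros(2), pq=0.25)


class TestBuildHX:
    @pytest.mark.parametrize("seed", [30, 31])
    def test_all_genotyped_gives_GX(self, seed):
        ped = random_pedigree(seed, n=15)
        s = build_S(ped)
        sp = partition_S(s, ped.ids)
        gx = _as_gx(s, ped.ids)
        h = build_HX(sp, gx)
        assert np.allclose(h.values, gx.values)

    @pytest.mark.parametrize("seed", [30, 31])
    def test_GX_equal_S22_gives_S(self, seed):
        ped = random_pedigree(seed, n=15)
        s = build_S(ped)
        sp = partition_S(s, ped.ids[::2])
        h = build_HX(sp, _as_gx(s, sp.ids2))
        idx = [h.ids.index(i) for i in s.ids]
        assert np.allclose(h.values[np.ix_(idx, idx)], s.values, atol=1e-12)

    def test_matches_independent_block_algebra(self):
        ped = random_pedigree(32, n=15)
        s = build_S(ped)
        gids = ped.ids[:8]
        sp = partition_S(s, gids)
        rng = np.random.default_rng(0)
        B = rng.standard_normal((8, 20))
        gx = RelationshipMatrix(ids=sp.ids2, values=B @ B.T / 20, kind="GX")
        h = build_HX(sp, gx)
        # independent dense evaluation of the block formula
        s22i = np.linalg.inv(sp.S22)
        P = sp.S12 @ s22i
        h11 = sp.S11 - sp.S12 @ s22i @ sp.S12.T + P @ gx.values @ P.T
        assert np.allclose(h.values[: sp.n1, : sp.n1], h11, atol=1e-10)
        assert np.allclose(h.values[: sp.n1, sp.n1:], P @ gx.values, atol=1e-10)
        assert np.abs(h.values - h.values.T).max() < 1e-12

    def test_id_mismatch_raises(self):
        ped = random_pedigree(33, n=10)
        s = build_S(ped)
        sp = partition_S(s, ped.ids[:5])
        gx = _as_gx(s, ped.ids[5:])
        with pytest.raises(ValueError, match="ids"):
            build_HX(sp, gx)


class TestBuildHXInverse:
    def test_GX_equal_S22_gives_S_inverse(self):
        ped = random_pedigree(34, n=12)
        s = build_S(ped)
        sp = partition_S(s, ped.ids[::2])
        sinv = build_S_inverse(ped)
        hinv = build_HX_inverse(sinv, sp, _as_gx(s, sp.ids2))
        assert np.allclose(hinv.to_dense(), sinv.to_dense(), atol=1e-8)

    def test_identity_product_with_blended_GX(self):
        cfg = SimConfig(seed=40, n_generations=3, n_males=2, n_females=10,
                        n_loci=200, base_freq=0.5, map_length=0.5)
        ped = simulate_pedigree(cfg)
        from xkin.genomic import build_GX, estimate_allele_freq_x

        G, _ = gene_drop_x(ped, cfg)
        s = build_S(ped)
        gids = [i for i in ped.ids if not i.startswith("G0")]
        sp = partition_S(s, gids)
        gx = build_GX(G, estimate_allele_freq_x(G)).submatrix(gids)
        is_male2 = np.array([ped.sex[ped.index(i)] == 1 for i in gids])
        gxb = blend(s.submatrix(gids), gx, alpha=0.05, is_male=is_male2)
        h = build_HX(sp, gxb)
        hinv = build_HX_inverse(build_S_inverse(ped), sp, gxb)
        idx = [h.ids.index(i) for i in ped.ids]
        prod = hinv.to_dense() @ h.values[np.ix_(idx, idx)]
        assert np.abs(prod - np.eye(ped.n)).max() < 1e-6

    def test_singular_GX_rejected(self):
        ped = random_pedigree(35, n=10)
        s = build_S(ped)
        sp = partition_S(s, ped.ids[:6])
        rank1 = np.ones((6, 6))
        gx = RelationshipMatrix(ids=sp.ids2, values=rank1, kind="GX")
        sinv = build_S_inverse(ped)
        with pytest.raises(ValueError, match="singular"):
            build_HX_inverse(sinv, sp, gx)


class TestBlend:
    def test_alpha_one_returns_S(self):
        ped = random_pedigree(36, n=12)
        s = build_S(ped)
        gx = _as_gx(s, ped.ids)
        gx.values = gx.values + 0.3
        b = blend(s, gx, alpha=1.0)
        assert np.allclose(b.values, s.values)

    def test_alpha_zero_mean_matched_returns_GX(self):
        ped = random_pedigree(36, n=12)
        s = build_S(ped)
        gx = _as_gx(s, ped.ids)  # already moment-matched to itself
        b = blend(s, gx, alpha=0.0)
        assert np.allclose(b.values, gx.values, atol=1e-12)

    def test_moment_matching_aligns_first_moments(self):
        ped = random_pedigree(37, n=15)
        s = build_S(ped)
        gx = _as_gx(s, ped.ids)
        gx.values = 0.8 * gx.values - 0.05  # offset + shrinkage
        b = blend(s, gx, alpha=0.0, is_male=ped.is_male)
        w = np.where(ped.is_male, np.sqrt(2.0), 1.0)
        scale = np.outer(w, w)
        assert np.diag(b.values * scale).mean() == pytest.approx(
            np.diag(s.values * scale).mean()
        )
        assert (b.values * scale).mean() == pytest.approx(
            (s.values * scale).mean()
        )

    def test_restores_positive_definiteness(self):
        """Duplicated male X copies make G^X singular; alpha=0.05 repairs it."""
        cfg = SimConfig(seed=41, n_generations=3, n_males=2, n_females=20,
                        n_loci=300, base_freq=0.5, map_length=0.3)
        ped = simulate_pedigree(cfg)
        from xkin.genomic import build_GX, estimate_allele_freq_x

        G, _ = gene_drop_x(ped, cfg)
        gx = build_GX(G, estimate_allele_freq_x(G))
        assert np.linalg.eigvalsh(gx.values).min() < 1e-10  # rank deficient
        s = build_S(ped)
        b = blend(s, gx, alpha=0.05, is_male=ped.is_male)
        assert np.linalg.eigvalsh(b.values).min() > 0

    def test_alpha_out_of_range(self):
        ped = random_pedigree(38, n=5)
        s = build_S(ped)
        with pytest.raises(ValueError):
            blend(s, _as_gx(s, ped.ids), alpha=1.5)
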