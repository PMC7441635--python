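"""Shared test utilities: Monte-Carlo studentization and small simulators."""

import numpy as np
import pandas as pd

from xkin.genomic import AlleleFrequencies, GenotypeMatrix


def studentized_covariance_deviation(values: np.ndarray, expected: np.ndarray):
    """Entrywise (empirical - expected) / MC-SE for gene-content covariance.

    ``values`` is individuals x loci over independently dropped loci. The
    standard error of each covariance entry is estimated from the spread of
    the per-locus cross-products, so no distributional assumption beyond the
    CLT over loci is needed.
    """
    L = values.shape[1]
    Z = values - values.mean(axis=1, keepdims=True)
    emp = (Z @ Z.T) / L
    Z2 = Z * Z
    var_prod = (Z2 @ Z2.T) / L - emp**2
    se = np.sqrt(var_prod / L)
    return (emp - expected) / se


def assert_cov_matches(values, expected, n_entries_slack=0.03, hard=4.5):
    """Covariance oracle assertion: entrywise within 3 MC SEs up to chance.

    At 3 sigma about 0.3% of entries exceed the bound by chance, and because
    entries of one pedigree share meioses their deviations are correlated,
    so chance exceedances cluster. The check therefore allows up to
    ``n_entries_slack`` of unique entries beyond 3 SEs while requiring every
    entry within ``hard`` SEs — a real formula error sits tens of SEs away
    at the locus counts used here, so the hard cap is the discriminating
    bound.
    """
    z = studentized_covariance_deviation(values, expected)
    iu = np.triu_indices(z.shape[0])
    zz = np.abs(z[iu])
    frac_over = float(np.mean(zz > 3.0))
    assert frac_over <= n_entries_slack, (
        f"{frac_over:.2%} of entries beyond 3 MC SEs (max {zz.max():.2f})"
    )
    assert zz.max() <= hard, f"max deviation {zz.max():.2f} MC SEs"


def unrelated_x_cohort(seed, n_males, n_females, p):
    """Hardy-Weinberg X genotypes for an unrelated cohort at frequencies p."""
    rng = np.random.default_rng(seed)
    L = len(p)
    n = n_males + n_females
    sex = np.r_[np.ones(n_males, int), np.full(n_females, 2)]
    male = sex == 1
    vals = np.where(
        male[:, None],
        (rng.random((n, L)) < p),
        (rng.random((n, L)) < p).astype(int) + (rng.random((n, L)) < p).astype(int),
    ).astype(float)
    loci = pd.DataFrame(
        {"region": "X", "bp": np.arange(L) + 1, "cm": np.linspace(0, 100, L)},
        index=[f"x{j:04d}" for j in range(L)],
    )
    G = GenotypeMatrix(
        ids=[f"i{t}" for t in range(n)], sex=sex, values=vals, loci=loci
    )
    return G, AlleleFrequencies(p=np.asarray(p, float), source="base")


def dosage_phenotypes(seed, G, freqs, k=2.0, r_g=1.0, h2_f=0.5):
    """Phenotypes with male effects scaled by k and cross-sex correlation r_g."""
    rng = np.random.default_rng(seed)
    L = G.values.shape[1]
    a_f = rng.standard_normal(L)
    a_m = k * (r_g * a_f + np.sqrt(max(0.0, 1 - r_g**2)) * rng.standard_normal(L))
    male = G.is_male
    g = np.where(male, G.values @ a_m, G.values @ a_f)
    v_f = np.var(g[~male])
    sd_e = np.sqrt(v_f * (1 - h2_f) / h2_f)
    y = g + sd_e * rng.standard_normal(G.n)
    return pd.DataFrame(
        {"id": G.ids, "sex": np.where(male, "M", "F"), "value": y}
    )
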