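"""Dosage compensation: bivariate REML, solving k, and SNP-BLUP.

Male X-linked allelic effects may be scaled by a factor k relative to
females (k = 1: no dosage compensation; k = sqrt(2): equal genotypic
variance; k = 2: full compensation, equal means, doubled male variance).
For a trait recorded in both sexes, k is estimable by treating the male and
female phenotypes as two traits whose genetic effects share the covariance
structure

    Var(u_males, u_females) = Sigma (x) G^X,
    Sigma = [[sigma2_m, sigma_mf], [sigma_mf, sigma2_f]].

When the cross-sex genetic correlation is 1, Sigma = sigma2_u *
[[k^2/2, k/sqrt(2)], [k/sqrt(2), 1]], so k can be solved two ways —
k_var = sqrt(2 sigma2_m / sigma2_f) and k_cov = sqrt(2) sigma_mf /
sigma2_f — whose agreement is itself a model check.

The restricted likelihood is maximized directly (quasi-Newton on a Cholesky
parameterization of Sigma, exploiting a low-rank square root of G^X), which
is deterministic given data and starting values and remains stable at the
r_g = 1 boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg as sla
from scipy.optimize import minimize

from .genomic import AlleleFrequencies, GenotypeMatrix, X_SPECIFIC
from .matrices import RelationshipMatrix

__all__ = ["SexCovariance", "bivariate_reml", "solve_k", "snp_blup"]


@dataclass
class SexCovariance:
    """Sex-specific genetic (co)variance estimates and derived k."""

    sigma2_m: float
    sigma_mf: float
    sigma2_f: float
    sigma2_e_m: float
    sigma2_e_f: float
    logLik: float
    converged: bool

    @property
    def r_g(self) -> float:
        denom = np.sqrt(self.sigma2_m * self.sigma2_f)
        return float(self.sigma_mf / denom) if denom > 0 else np.nan

    @property
    def k_var(self) -> float:
        return float(np.sqrt(2.0 * self.sigma2_m / self.sigma2_f))

    @property
    def k_cov(self) -> float:
        return float(np.sqrt(2.0) * self.sigma_mf / self.sigma2_f)


def _low_rank_root(GX: RelationshipMatrix) -> np.ndarray:
    if GX.root is not None:
        return np.asarray(GX.root, dtype=float)
    w, U = np.linalg.eigh(0.5 * (GX.values + GX.values.T))
    keep = w > 1e-10 * max(w.max(), 1.0)
    return U[:, keep] * np.sqrt(w[keep])


def _deviance(theta, pre):
    """-2 * restricted log-likelihood (up to an additive constant).

    The genetic covariance enters only through its Cholesky factor
    L = [[a, 0], [b, c]] (Sigma = L L'), so the deviance stays finite and
    smooth as c -> 0, i.e. at the r_g = 1 boundary. With u = T (L (x) I) b,
    b ~ N(0, I), Woodbury gives V^-1 and log|V| through the always
    well-conditioned capacitance C = I + (L' (x) I) T'R^-1 T (L (x) I).
    """
    t_em, t_ef, la, lb, lc = theta
    se_m, se_f = np.exp(t_em), np.exp(t_ef)
    a, b, c = np.exp(la), lb, np.exp(lc)

    r = pre["r"]
    Bm = pre["Gm"] / se_m
    Bf = pre["Gf"] / se_f
    eye = np.eye(r)
    C = np.block(
        [
            [eye + a * a * Bm + b * b * Bf, b * c * Bf],
            [c * b * Bf, eye + c * c * Bf],
        ]
    )

    # U'R^-1 y and U'R^-1 X (X = per-sex intercepts), U = T (L (x) I)
    wm = pre["Wty_m"] / se_m
    wf = pre["Wty_f"] / se_f
    a1 = np.concatenate([a * wm + b * wf, c * wf])
    A2 = np.zeros((2 * r, 2))
    A2[:r, 0] = a * pre["Wt1_m"] / se_m
    A2[:r, 1] = b * pre["Wt1_f"] / se_f
    A2[r:, 1] = c * pre["Wt1_f"] / se_f

    try:
        cf = sla.cho_factor(C)
    except sla.LinAlgError:
        return 1e12
    sol = sla.cho_solve(cf, np.column_stack([a1, A2]))
    logdet_C = 2.0 * np.sum(np.log(np.diag(cf[0])))

    ytViy = pre["yty_m"] / se_m + pre["yty_f"] / se_f - a1 @ sol[:, 0]
    XtViy = np.array(
        [pre["y1_m"] / se_m, pre["y1_f"] / se_f]
    ) - A2.T @ sol[:, 0]
    XtViX = np.diag([pre["nm"] / se_m, pre["nf"] / se_f]) - A2.T @ sol[:, 1:]

    sign, logdet_X = np.linalg.slogdet(XtViX)
    if sign <= 0:
        return 1e12
    beta = np.linalg.solve(XtViX, XtViy)
    yPy = ytViy - XtViy @ beta
    logdet_V = logdet_C + pre["nm"] * np.log(se_m) + pre["nf"] * np.log(se_f)
    return logdet_V + logdet_X + yPy


def bivariate_reml(
    phenotypes: pd.DataFrame,
    GX: RelationshipMatrix,
    max_iter: int = 500,
) -> SexCovariance:
    """REML of the two-trait (one per sex) model with kernel G^X.

    Parameters
    ----------
    phenotypes : DataFrame with columns id, sex, value
        One record per individual; the record is assigned to the trait of
        the individual's sex (sex coded M/F or 1/2).
    GX : RelationshipMatrix
        The X-chromosome GRM over (at least) the phenotyped individuals.

    Returns the 2x2 genetic covariance, per-sex residual variances, and the
    two k solutions. Deterministic given data and the neutral starting
    values (half the phenotypic variance per component, zero covariance).
    """
    ph = phenotypes.copy()
    ph["sex"] = ph["sex"].astype(str).str.upper().replace({"1": "M", "2": "F"})
    pos = {lab: i for i, lab in enumerate(GX.ids)}
    try:
        idx = np.array([pos[str(i)] for i in ph["id"].astype(str)])
    except KeyError as exc:
        raise ValueError(f"phenotyped id {exc} absent from G^X") from exc
    male = (ph["sex"] == "M").to_numpy()
    if not male.any() or not (~male).any():
        raise ValueError(
            "phenotypes from a single sex: k is irrelevant for sex-specific "
            "traits and cannot be estimated"
        )
    y_raw = ph["value"].to_numpy(dtype=float)
    y_scale = np.std(y_raw)
    if y_scale <= 0:
        raise ValueError("phenotypes are constant")
    y = y_raw / y_scale
    # Sex-specific variances are defined on the variance-equalized kernel
    # (male axes scaled by sqrt(2), giving unit expected diagonal for both
    # sexes): this is the scale on which Sigma = sigma2_u *
    # [[k^2/2, k/sqrt(2)], [k/sqrt(2), 1]] holds and k_var/k_cov recover k.
    W0 = _low_rank_root(GX)[idx]
    W0 = W0 * np.where(male, np.sqrt(2.0), 1.0)[:, None]
    Wm, Wf = W0[male], W0[~male]
    ym, yf = y[male], y[~male]
    pre = {
        "r": W0.shape[1],
        "Gm": Wm.T @ Wm,
        "Gf": Wf.T @ Wf,
        "Wty_m": Wm.T @ ym,
        "Wty_f": Wf.T @ yf,
        "Wt1_m": Wm.sum(axis=0),
        "Wt1_f": Wf.sum(axis=0),
        "yty_m": ym @ ym,
        "yty_f": yf @ yf,
        "y1_m": ym.sum(),
        "y1_f": yf.sum(),
        "nm": len(ym),
        "nf": len(yf),
    }
    # neutral start: half the phenotypic variance per component, zero covariance
    vm, vf = np.var(ym), np.var(yf)
    theta0 = np.array(
        [np.log(0.5 * vm), np.log(0.5 * vf),
         0.5 * np.log(0.5 * vm), 0.0, 0.5 * np.log(0.5 * vf)]
    )
    bounds = [(-20, 10), (-20, 10), (-20, 10), (-50, 50), (-20, 10)]
    res = minimize(
        _deviance,
        theta0,
        args=(pre,),
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": max_iter, "ftol": 1e-13, "gtol": 1e-10},
    )
    t_em, t_ef, la, lb, lc = res.x
    L = np.array([[np.exp(la), 0.0], [lb, np.exp(lc)]])
    sigma = (L @ L.T) * y_scale**2
    return SexCovariance(
        sigma2_m=float(sigma[0, 0]),
        sigma_mf=float(sigma[0, 1]),
        sigma2_f=float(sigma[1, 1]),
        sigma2_e_m=float(np.exp(t_em) * y_scale**2),
        sigma2_e_f=float(np.exp(t_ef) * y_scale**2),
        logLik=float(-0.5 * res.fun),
        converged=bool(res.success),
    )


def solve_k(cov: SexCovariance, tol: float = 0.05):
    """Solve the dosage-compensation factor from sex covariances.

    Returns ``(k, consistent)``: k is always the variance-based solution
    ``sqrt(2 sigma2_m / sigma2_f)``; ``consistent`` is True when the
    covariance-based solution agrees within ``tol`` (relative) and the
    genetic correlation is within ``tol`` of 1 — the regime in which a
    single-trait model with a k-scaled G^X is justified.
    """
    if cov.sigma2_f <= 0:
        raise ValueError("female genetic variance must be positive to solve k")
    k_var, k_cov = cov.k_var, cov.k_cov
    consistent = (
        abs(k_var - k_cov) / k_var <= tol and abs(cov.r_g - 1.0) <= tol
    )
    return float(k_var), bool(consistent)


def snp_blup(
    y: np.ndarray,
    G: GenotypeMatrix,
    freqs: AlleleFrequencies,
    lam: float,
    k: float = 1.0,
):
    """Ridge (SNP-BLUP) solution for X-linked marker effects.

    Centered gene content Z (males ``(m - p) * k``, females ``m - 2p``),
    per-sex intercepts, and the mixed-model equations

        [X'X   X'Z ] [b]   [X'y]
        [Z'X  Z'Z+lam*I] [a] = [Z'y]

    Returns ``(alpha_hat, b_hat, g_hat)`` with ``g_hat = Z alpha_hat`` the
    genotypic values; these equal GBLUP predictions with the matching
    k-scaled G^X and variance ratio.
    """
    y = np.asarray(y, dtype=float)
    mask = G.region_mask(X_SPECIFIC)
    vals = G.values[:, mask]
    p = np.asarray(freqs.p, dtype=float)
    keep = ~freqs.monomorphic
    vals, p = vals[:, keep], p[keep]
    male = G.is_male
    center = np.where(male[:, None], p[None, :], 2.0 * p[None, :])
    Z = vals - center
    Z[male] *= k
    X = np.column_stack([male.astype(float), (~male).astype(float)])
    nfix = X.shape[1]
    m = Z.shape[1]
    lhs = np.block(
        [[X.T @ X, X.T @ Z], [Z.T @ X, Z.T @ Z + lam * np.eye(m)]]
    )
    rhs = np.concatenate([X.T @ y, Z.T @ y])
    try:
        sol = sla.solve(lhs, rhs, assume_a="sym")
    except sla.LinAlgError as exc:
        raise ValueError("singular SNP-BLUP system") from exc
    b_hat, alpha_hat = sol[:nfix], sol[nfix:]
    return alpha_hat, b_hat, Z @ alpha_hat
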