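"""Projection-based comparison of latent means across groups.

Given a loading matrix common to all groups (metric invariance), each
group's manifest mean vector is decomposed orthogonally as

    xbar = mu_kappa + nu,

where mu_kappa is the projection of xbar onto the column space of the
loadings (the common-score means, mu_kappa = Lambda kappa) and nu is the
orthogonal remainder (the specific-factor means).  Cross-group equality
of the kappa and of the nu is tested by Wald statistics with
df = (m-1)k and (m-1)(p-k); no equality of intercepts is required.
The validity index rho2_c is the fraction of squared manifest mean
differences attributable to common-score differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from . import equivalence, mgsem
from .model_io import GroupMoments, ModelSpec

__all__ = [
    "ProjectionResult",
    "WaldTest",
    "GroupComparison",
    "project_means",
    "wald_mean_tests",
    "validity_index",
    "equivalence_mean_tests",
    "bootstrap_tests",
]


@dataclass(frozen=True)
class WaldTest:
    name: str
    statistic: float
    df: int
    pvalue: float


@dataclass(frozen=True)
class GroupComparison:
    """Per-element estimates for each group plus differences vs group 1."""

    names: tuple[str, ...]
    estimates: np.ndarray   # n_elements x m
    diff: np.ndarray        # n_elements x (m-1), group j minus group 1
    se: np.ndarray          # same shape as diff
    z: np.ndarray           # same shape as diff


@dataclass
class ProjectionResult:
    lambda_hat: np.ndarray
    kappa_hat: list[np.ndarray]
    mu_kappa_hat: list[np.ndarray]
    nu_hat: list[np.ndarray]
    wald_manifest: WaldTest
    wald_common: WaldTest
    wald_specific: WaldTest
    validity: float | None
    latent: GroupComparison
    common: GroupComparison
    specific: GroupComparison


def _projector(lam: np.ndarray, weight: np.ndarray | None = None):
    """Return (P, B): the projector onto col(lam) in the chosen metric and
    the coordinate map kappa = B x."""
    lam = np.asarray(lam, float)
    p, k = lam.shape
    if np.linalg.matrix_rank(lam) < k:
        gram = lam.T @ lam
        bad = [str(c) for c in range(k)
               if np.linalg.matrix_rank(np.delete(lam, c, axis=1)) ==
               np.linalg.matrix_rank(lam)]
        raise np.linalg.LinAlgError(
            "loading matrix is rank deficient (collinear columns: "
            + ", ".join(bad or ["?"]) + ")"
        )
    if weight is None:
        B = np.linalg.solve(lam.T @ lam, lam.T)
    else:
        W = np.asarray(weight, float)
        B = np.linalg.solve(lam.T @ W @ lam, lam.T @ W)
    return lam @ B, B


def project_means(xbar: np.ndarray, lambda_hat: np.ndarray,
                  weight: np.ndarray | None = None
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Decompose a mean vector into its common-score part, the orthogonal
    remainder, and the factor-mean coordinates.

    Returns ``(mu_kappa, nu, kappa)`` with ``xbar = mu_kappa + nu`` and
    ``mu_kappa = lambda_hat @ kappa``.  ``weight`` selects a generalized
    (W-orthogonal) projection; the default is Euclidean.
    """
    xbar = np.asarray(xbar, float).ravel()
    P, B = _projector(lambda_hat, weight)
    kappa = B @ xbar
    mu_kappa = np.asarray(lambda_hat, float) @ kappa
    return mu_kappa, xbar - mu_kappa, kappa


def _stacked_wald(diffs: list[np.ndarray], covs: dict, m: int, rank: int
                  ) -> float:
    """Quadratic form d' V^+ d for stacked group-vs-baseline differences.

    ``covs[(j, l)]`` gives Cov(d_j, d_l); the shared baseline term makes
    the statistic invariant to which group is the baseline.
    """
    d = np.concatenate(diffs)
    b = diffs[0].size
    V = np.zeros((d.size, d.size))
    for j in range(m - 1):
        for l in range(m - 1):
            V[j * b:(j + 1) * b, l * b:(l + 1) * b] = covs[(j, l)]
    Vp = np.linalg.pinv(V, rcond=1e-10, hermitian=True)
    return float(d @ Vp @ d)


def wald_mean_tests(data: list[GroupMoments], lambda_hat: np.ndarray,
                    model: ModelSpec | None = None,
                    weight: np.ndarray | None = None) -> ProjectionResult:
    """Project each group's mean vector and test cross-group equality of
    the common-score and specific-factor components.

    The asymptotic covariance of each group's mean is taken as S_j / n_j
    and propagated through the fixed projection; the loading matrix is
    treated as known (use :func:`bootstrap_tests` to account for its
    sampling variability).
    """
    m = len(data)
    if m < 2:
        raise ValueError("need at least two groups")
    lam = np.asarray(lambda_hat, float)
    p, k = lam.shape
    if p - k == 0:
        raise ValueError(
            "specific-factor test undefined: p - k = 0 leaves no "
            "orthogonal complement"
        )
    P, B = _projector(lam, weight)
    Q = np.eye(p) - P

    kappas, mks, nus = [], [], []
    for gm in data:
        mk, nu, kap = project_means(gm.mean, lam, weight)
        kappas.append(kap)
        mks.append(mk)
        nus.append(nu)

    mean_covs = [gm.cov / gm.n for gm in data]

    def covs_for(T):
        out = {}
        base = T @ mean_covs[0] @ T.T
        for j in range(m - 1):
            for l in range(m - 1):
                out[(j, l)] = base.copy()
                if j == l:
                    out[(j, l)] = base + T @ mean_covs[j + 1] @ T.T
        return out

    I = np.eye(p)
    d_x = [data[j].mean - data[0].mean for j in range(1, m)]
    d_k = [kappas[j] - kappas[0] for j in range(1, m)]
    d_n = [nus[j] - nus[0] for j in range(1, m)]

    t_man = _stacked_wald(d_x, covs_for(I), m, (m - 1) * p)
    t_com = _stacked_wald(d_k, covs_for(B), m, (m - 1) * k)
    t_spe = _stacked_wald(d_n, covs_for(Q), m, (m - 1) * (p - k))
    df_man, df_com, df_spe = (m - 1) * p, (m - 1) * k, (m - 1) * (p - k)

    wald_manifest = WaldTest("fit.mvmean", t_man, df_man,
                             float(chi2.sf(t_man, df_man)))
    wald_common = WaldTest("fit.common", t_com, df_com,
                           float(chi2.sf(t_com, df_com)))
    wald_specific = WaldTest("fit.specific", t_spe, df_spe,
                             float(chi2.sf(t_spe, df_spe)))

    validity = validity_index(d_k, d_n, lam)

    def comparison(names, ests, T):
        ests = np.column_stack(ests)
        diff = ests[:, 1:] - ests[:, [0]]
        se = np.empty_like(diff)
        for j in range(1, m):
            V = T @ (mean_covs[0] + mean_covs[j]) @ T.T
            se[:, j - 1] = np.sqrt(np.maximum(np.diag(V), 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(se > 0, diff / se, np.nan)
        return GroupComparison(tuple(names), ests, diff, se, z)

    factor_names = (model.factor_names if model is not None
                    else tuple(f"f{i + 1}" for i in range(k)))
    var_names = (data[0].variables if data[0].variables
                 else tuple(f"v{i + 1}" for i in range(p)))
    latent = comparison(factor_names, kappas, B)
    common = comparison(var_names, mks, P)
    specific = comparison(var_names, nus, Q)

    return ProjectionResult(
        lambda_hat=lam, kappa_hat=kappas, mu_kappa_hat=mks, nu_hat=nus,
        wald_manifest=wald_manifest, wald_common=wald_common,
        wald_specific=wald_specific, validity=validity,
        latent=latent, common=common, specific=specific,
    )


def validity_index(kappa_diffs, nu_diffs, lambda_hat) -> float | None:
    """Fraction of squared manifest mean differences due to common-score
    differences: |Lambda kappa_d|^2 / (|Lambda kappa_d|^2 + |nu_d|^2).

    ``None`` (undefined) when both components vanish.
    """
    lam = np.asarray(lambda_hat, float)
    mu_d = np.concatenate([lam @ np.asarray(d, float).ravel()
                           for d in kappa_diffs])
    nu_d = np.concatenate([np.asarray(d, float).ravel() for d in nu_diffs])
    ss_common = float(mu_d @ mu_d)
    ss_specific = float(nu_d @ nu_d)
    if ss_common + ss_specific == 0.0:
        return None
    return ss_common / (ss_common + ss_specific)


def equivalence_mean_tests(result: ProjectionResult, n_total: int, m: int,
                           alpha: float = 0.05, divisor: str | None = None
                           ) -> dict[str, equivalence.EquivalenceResult]:
    """T-size epsilon/RMSEA with adjusted cutoffs for the three Wald tests."""
    out = {}
    for w in (result.wald_manifest, result.wald_common, result.wald_specific):
        out[w.name] = equivalence.tsize(
            w.statistic, w.df, n_total, m, alpha=alpha,
            stat_family="wald_projection", divisor=divisor,
        )
    return out


def bootstrap_tests(frames: list[pd.DataFrame], model: ModelSpec,
                    B: int = 500, seed: int | None = 0,
                    refit_loadings: bool = True,
                    weight: np.ndarray | None = None) -> dict[str, float]:
    """Bootstrap p-values for the equal-common-means and equal-specific-means
    hypotheses from per-group raw data.

    Observations are recentered to impose each null (removing the group's
    estimated common or specific mean component), then resampled with
    replacement within groups; the Wald statistic is recomputed each
    replicate, re-estimating the loading matrix when ``refit_loadings``.
    Returns ``{"common": p, "specific": p}``.
    """
    if not isinstance(frames, (list, tuple)) or not all(
            isinstance(f, pd.DataFrame) for f in frames):
        raise TypeError(
            "bootstrap requires per-group raw data frames; moments-only "
            "input cannot be resampled (absence of raw data)"
        )
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    variables = list(model.all_variables)
    arrays = [f[variables].to_numpy(float) for f in frames]
    m = len(arrays)
    if m < 2:
        raise ValueError("need at least two groups")

    def moments(arrs):
        gms = []
        for j, a in enumerate(arrs):
            n = a.shape[0]
            mean = a.mean(axis=0)
            c = a - mean
            gms.append(GroupMoments(
                label=f"g{j + 1}", n=n, mean=mean, cov=c.T @ c / n,
                variables=tuple(variables),
            ))
        return gms

    def lam_of(gms, start=None):
        fr = mgsem.fit(gms, model, "metric", start=start)
        return fr.estimates.lam[0], fr.estimates

    gms0 = moments(arrays)
    lam0, est0 = lam_of(gms0)
    res0 = wald_mean_tests(gms0, lam0, model=model, weight=weight)
    t_obs = {"common": res0.wald_common.statistic,
             "specific": res0.wald_specific.statistic}

    centered = {
        "common": [a - lam0 @ res0.kappa_hat[j] for j, a in enumerate(arrays)],
        "specific": [a - res0.nu_hat[j] for j, a in enumerate(arrays)],
    }
    exceed = {"common": 0, "specific": 0}
    for _ in range(B):
        idx = [rng.integers(0, a.shape[0], size=a.shape[0]) for a in arrays]
        for hyp in ("common", "specific"):
            arrs = [centered[hyp][j][idx[j]] for j in range(m)]
            gms = moments(arrs)
            if refit_loadings:
                try:
                    lam_b, _ = lam_of(gms, start=est0)
                except np.linalg.LinAlgError:
                    lam_b = lam0
            else:
                lam_b = lam0
            res_b = wald_mean_tests(gms, lam_b, model=model, weight=weight)
            t_b = (res_b.wald_common.statistic if hyp == "common"
                   else res_b.wald_specific.statistic)
            if t_b >= t_obs[hyp]:
                exceed[hyp] += 1
    return {hyp: (1 + exceed[hyp]) / (B + 1) for hyp in ("common", "specific")}
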