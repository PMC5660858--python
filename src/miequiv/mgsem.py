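"""Multi-group confirmatory factor models with mean structure.

Fits, by normal-theory maximum likelihood, the model

    x = gamma + Lambda xi + eps,    mu = gamma + Lambda tau,
    Sigma = Lambda Phi Lambda' + Psi   (Psi diagonal)

simultaneously in m groups under the named cross-group equality-constraint
sets of the invariance sequence (configural, metric, ..., strict.means),
and produces chi-square and chi-square-difference statistics with exact
degrees-of-freedom accounting.

Conventions
-----------
* Identification: the first indicator of each factor is a marker with its
  loading fixed at 1; factor variances are free.  Latent means are fixed
  at 0 until intercepts are constrained equal, after which the first
  group's latent means stay 0 and the others' are free.
* Statistic scale: ``T = (N - m) * F`` by default, where
  ``F = sum_j (n_j/N) F_j`` and F_j is the group discrepancy evaluated at
  divisor-n sample covariances; ``scale="n"`` gives ``T = N * F``.
* Optimization: L-BFGS-B on an unconstrained reparameterization (log
  error variances, Cholesky factor covariances) with analytic gradients
  and deterministic seeded restarts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg as sla
from scipy import optimize
from scipy.stats import chi2

from .model_io import GroupMoments, ModelSpec

__all__ = [
    "ParamSet",
    "ConstraintSet",
    "FitResult",
    "DiffResult",
    "SequenceRow",
    "CONSTRAINT_SETS",
    "SEQUENCE_PARENTS",
    "implied_moments",
    "ml_discrepancy",
    "fit",
    "dof",
    "chisq_diff",
    "run_sequence",
    "cov_equality_test",
]


# --------------------------------------------------------------------------
# parameter containers
# --------------------------------------------------------------------------

@dataclass
class ParamSet:
    """Per-group parameter values: intercepts, loadings, factor covariance,
    diagonal error variances and latent means."""

    gamma: list[np.ndarray]  # m vectors of length p
    lam: list[np.ndarray]    # m matrices p x k
    phi: list[np.ndarray]    # m matrices k x k
    psi: list[np.ndarray]    # m vectors of length p (diagonal of Psi)
    tau: list[np.ndarray]    # m vectors of length k

    @property
    def n_groups(self) -> int:
        return len(self.gamma)

    def copy(self) -> "ParamSet":
        return ParamSet(
            [g.copy() for g in self.gamma],
            [m.copy() for m in self.lam],
            [m.copy() for m in self.phi],
            [v.copy() for v in self.psi],
            [t.copy() for t in self.tau],
        )


@dataclass(frozen=True)
class ConstraintSet:
    """Named cross-group equality-constraint set.

    ``tau_mode`` is one of ``"zero"`` (all latent means fixed at 0),
    ``"baseline"`` (group 1 fixed at 0, others free) or ``"equal_zero"``
    (all groups constrained equal, hence 0 by the baseline convention).
    """

    name: str
    lambda_equal: bool = False
    gamma_equal: bool = False
    psi_equal: bool = False
    phi_equal: bool = False
    tau_mode: str = "zero"
    parent: str | None = None

    def __post_init__(self):
        if self.tau_mode not in ("zero", "baseline", "equal_zero"):
            raise ValueError(f"unknown tau_mode {self.tau_mode!r}")
        if self.tau_mode != "zero" and not self.gamma_equal:
            raise ValueError(
                "latent means are identified only with equal intercepts"
            )

    def is_nested_in(self, other: "ConstraintSet") -> bool:
        """True if self's constraints are a superset of ``other``'s."""
        tau_rank = {"zero": 0, "baseline": 0, "equal_zero": 1}
        flags_ok = all(
            getattr(self, f) or not getattr(other, f)
            for f in ("lambda_equal", "gamma_equal", "psi_equal", "phi_equal")
        )
        return flags_ok and tau_rank[self.tau_mode] >= tau_rank[other.tau_mode]


CONSTRAINT_SETS: dict[str, ConstraintSet] = {
    c.name: c
    for c in [
        ConstraintSet("configural"),
        ConstraintSet("metric", lambda_equal=True, parent="configural"),
        ConstraintSet("residuals", lambda_equal=True, psi_equal=True,
                      parent="metric"),
        ConstraintSet("varfactor", lambda_equal=True, psi_equal=True,
                      phi_equal=True, parent="residuals"),
        ConstraintSet("scalar", lambda_equal=True, gamma_equal=True,
                      tau_mode="baseline", parent="metric"),
        ConstraintSet("strong.means", lambda_equal=True, gamma_equal=True,
                      tau_mode="equal_zero", parent="scalar"),
        ConstraintSet("strict.residuals", lambda_equal=True, gamma_equal=True,
                      psi_equal=True, tau_mode="baseline", parent="scalar"),
        ConstraintSet("strict.means", lambda_equal=True, gamma_equal=True,
                      psi_equal=True, tau_mode="equal_zero",
                      parent="strict.residuals"),
    ]
}

#: difference-test parent of each row in the invariance sequence
SEQUENCE_PARENTS = {
    "fit.metric": "fit.combine.groups",
    "fit.residuals": "fit.metric",
    "fit.varfactor": "fit.residuals",
    "fit.scalar": "fit.metric",
    "fit.strong.means": "fit.scalar",
    "fit.strict.residuals": "fit.scalar",
    "fit.strict.means": "fit.strict.residuals",
}


@dataclass
class FitResult:
    """Minimized discrepancy, chi-square statistic and estimates."""

    name: str
    fml: float
    tml: float
    df: int
    pvalue: float
    estimates: ParamSet | None
    converged: bool
    n_iterations: int
    n_total: int
    n_groups: int
    warnings: tuple[str, ...] = ()


@dataclass(frozen=True)
class DiffResult:
    tdiff: float
    dfdiff: int
    pvalue: float
    warning: str | None = None


@dataclass
class SequenceRow:
    name: str
    fit: FitResult
    diff: DiffResult | None = None


# --------------------------------------------------------------------------
# model-implied moments and the ML discrepancy
# --------------------------------------------------------------------------

def implied_moments(params: ParamSet, group: int) -> tuple[np.ndarray, np.ndarray]:
    """Model-implied mean vector and covariance matrix for one group."""
    lam = params.lam[group]
    mu = params.gamma[group] + lam @ params.tau[group]
    sigma = lam @ params.phi[group] @ lam.T + np.diag(params.psi[group])
    return mu, (sigma + sigma.T) / 2.0


def _group_discrepancy(mu, sigma, gm: GroupMoments) -> float:
    p = gm.p
    try:
        c, low = sla.cho_factor(sigma, lower=True)
    except sla.LinAlgError:
        raise np.linalg.LinAlgError(
            f"implied covariance singular for group {gm.label!r}"
        ) from None
    logdet_sigma = 2.0 * np.sum(np.log(np.diag(c)))
    sign, logdet_s = np.linalg.slogdet(gm.cov)
    if sign <= 0:
        raise np.linalg.LinAlgError(
            f"sample covariance singular for group {gm.label!r}"
        )
    sinv_s = sla.cho_solve((c, low), gm.cov)
    d = gm.mean - mu
    quad = d @ sla.cho_solve((c, low), d)
    return float(logdet_sigma - logdet_s + np.trace(sinv_s) - p + quad)


def ml_discrepancy(params: ParamSet, data: list[GroupMoments]) -> float:
    """Sample-size-weighted normal-theory discrepancy
    ``F = sum_j (n_j / N) F_j``; zero iff the model reproduces every
    group's sample moments exactly."""
    N = sum(gm.n for gm in data)
    F = 0.0
    for j, gm in enumerate(data):
        mu, sigma = implied_moments(params, j)
        F += (gm.n / N) * _group_discrepancy(mu, sigma, gm)
    return F


# --------------------------------------------------------------------------
# free-parameter template: packing, unpacking, analytic gradient
# --------------------------------------------------------------------------

class _Template:
    """Maps the free-parameter vector of a constrained model to per-group
    parameter matrices and accumulates the analytic gradient."""

    def __init__(self, model: ModelSpec, constraints: ConstraintSet, m: int):
        self.model = model
        self.cs = constraints
        self.m = m
        p, k = model.n_variables, model.n_factors
        self.p, self.k = p, k
        pattern = model.loading_pattern()
        markers = model.marker_indices()
        self.lam_fixed = np.zeros((p, k))
        for c, r in enumerate(markers):
            self.lam_fixed[r, c] = 1.0
        free = []
        for c in range(k):
            for r in range(p):
                if pattern[r, c] and r != markers[c]:
                    free.append((r, c))
        self.lam_free = free                      # q positions
        self.tril = [(a, c) for a in range(k) for c in range(a + 1)]

        cs = constraints
        q = len(free)
        nt = k * (k + 1) // 2
        sizes = [
            ("gamma", p if cs.gamma_equal else m * p),
            ("lam", q if cs.lambda_equal else m * q),
            ("chol", nt if cs.phi_equal else m * nt),
            ("lpsi", p if cs.psi_equal else m * p),
            ("tau", (m - 1) * k if cs.tau_mode == "baseline" else 0),
        ]
        self.offsets = {}
        off = 0
        for name, sz in sizes:
            self.offsets[name] = (off, off + sz)
            off += sz
        self.n_free = off

    # -- packing ----------------------------------------------------------
    def _avg(self, arrs, weights):
        w = np.asarray(weights, float)
        w = w / w.sum()
        return sum(wi * a for wi, a in zip(w, arrs))

    def pack(self, ps: ParamSet, weights=None) -> np.ndarray:
        """ParamSet -> free vector.  When a block is shared but the ParamSet
        carries distinct per-group values, the weighted average is used."""
        m, cs = self.m, self.cs
        if weights is None:
            weights = [1.0] * m
        theta = np.empty(self.n_free)

        def put(name, vals):
            a, b = self.offsets[name]
            theta[a:b] = np.concatenate(vals) if vals else []

        if cs.gamma_equal:
            put("gamma", [self._avg(ps.gamma, weights)])
        else:
            put("gamma", [ps.gamma[j] for j in range(m)])
        lam_vals = [np.array([ps.lam[j][r, c] for r, c in self.lam_free])
                    for j in range(m)]
        if cs.lambda_equal:
            put("lam", [self._avg(lam_vals, weights)])
        else:
            put("lam", lam_vals)

        def chol_vec(phi):
            jitter = 1e-8 * max(np.trace(phi) / self.k, 1.0)
            L = np.linalg.cholesky(phi + jitter * np.eye(self.k))
            return np.array([L[a, c] for a, c in self.tril])

        if cs.phi_equal:
            put("chol", [chol_vec(self._avg(ps.phi, weights))])
        else:
            put("chol", [chol_vec(ps.phi[j]) for j in range(m)])
        psi_floor = 1e-10
        if cs.psi_equal:
            put("lpsi", [np.log(np.maximum(self._avg(ps.psi, weights),
                                           psi_floor))])
        else:
            put("lpsi", [np.log(np.maximum(ps.psi[j], psi_floor))
                         for j in range(m)])
        if cs.tau_mode == "baseline":
            put("tau", [ps.tau[j] for j in range(1, m)])
        return theta

    # -- unpacking --------------------------------------------------------
    def unpack(self, theta: np.ndarray) -> tuple[ParamSet, list[np.ndarray]]:
        m, p, k, cs = self.m, self.p, self.k, self.cs

        def get(name):
            a, b = self.offsets[name]
            return theta[a:b]

        g = get("gamma")
        gamma = ([g.copy() for _ in range(m)] if cs.gamma_equal
                 else [g[j * p:(j + 1) * p].copy() for j in range(m)])
        lv = get("lam")
        q = len(self.lam_free)
        lam = []
        for j in range(m):
            vals = lv if cs.lambda_equal else lv[j * q:(j + 1) * q]
            L = self.lam_fixed.copy()
            for (r, c), v in zip(self.lam_free, vals):
                L[r, c] = v
            lam.append(L)
        cv = get("chol")
        nt = len(self.tril)
        chols, phi = [], []
        for j in range(m):
            vals = cv if cs.phi_equal else cv[j * nt:(j + 1) * nt]
            L = np.zeros((k, k))
            for (a, c), v in zip(self.tril, vals):
                L[a, c] = v
            chols.append(L)
            phi.append(L @ L.T)
        sv = get("lpsi")
        psi = ([np.exp(sv) for _ in range(m)] if cs.psi_equal
               else [np.exp(sv[j * p:(j + 1) * p]) for j in range(m)])
        tau = [np.zeros(k) for _ in range(m)]
        if cs.tau_mode == "baseline":
            tv = get("tau")
            for j in range(1, m):
                tau[j] = tv[(j - 1) * k:j * k].copy()
        return ParamSet(gamma, lam, phi, psi, tau), chols

    # -- objective + gradient --------------------------------------------
    def value_and_grad(self, theta, data: list[GroupMoments]):
        m, p, k, cs = self.m, self.p, self.k, self.cs
        ps, chols = self.unpack(theta)
        N = sum(gm.n for gm in data)
        F = 0.0
        grad = np.zeros(self.n_free)
        og = self.offsets

        for j, gm in enumerate(data):
            w = gm.n / N
            lam, phi, L = ps.lam[j], ps.phi[j], chols[j]
            mu = ps.gamma[j] + lam @ ps.tau[j]
            sigma = lam @ phi @ lam.T + np.diag(ps.psi[j])
            try:
                cf = sla.cho_factor(sigma, lower=True)
            except (sla.LinAlgError, ValueError):
                return np.inf, grad
            logdet_sigma = 2.0 * np.sum(np.log(np.diag(cf[0])))
            sinv = sla.cho_solve(cf, np.eye(p))
            d = gm.mean - mu
            sd = sinv @ d
            F += w * (logdet_sigma - gm._logdet_cache
                      + float(np.sum(sinv * gm.cov)) - p + float(d @ sd))
            # dF/dSigma and dF/dmu at this group
            A = sinv - sinv @ (gm.cov + np.outer(d, d)) @ sinv
            b = -2.0 * sd

            a0, _ = og["gamma"]
            if cs.gamma_equal:
                grad[a0:a0 + p] += w * b
            else:
                grad[a0 + j * p:a0 + (j + 1) * p] += w * b
            if self.lam_free:
                ALP = A @ lam @ phi
                gl = np.array([
                    b[r] * ps.tau[j][c] + 2.0 * ALP[r, c]
                    for r, c in self.lam_free
                ])
                a0, _ = og["lam"]
                q = len(self.lam_free)
                if cs.lambda_equal:
                    grad[a0:a0 + q] += w * gl
                else:
                    grad[a0 + j * q:a0 + (j + 1) * q] += w * gl
            ML = (lam.T @ A @ lam) @ L
            gc = np.array([2.0 * ML[a, c] for a, c in self.tril])
            a0, _ = og["chol"]
            nt = len(self.tril)
            if cs.phi_equal:
                grad[a0:a0 + nt] += w * gc
            else:
                grad[a0 + j * nt:a0 + (j + 1) * nt] += w * gc
            gs = np.diag(A) * ps.psi[j]
            a0, _ = og["lpsi"]
            if cs.psi_equal:
                grad[a0:a0 + p] += w * gs
            else:
                grad[a0 + j * p:a0 + (j + 1) * p] += w * gs
            if cs.tau_mode == "baseline" and j >= 1:
                a0, _ = og["tau"]
                grad[a0 + (j - 1) * k:a0 + j * k] += w * (lam.T @ b)
        return F, grad


def _cache_logdets(data: list[GroupMoments]) -> None:
    for gm in data:
        if not hasattr(gm, "_logdet_cache"):
            sign, ld = np.linalg.slogdet(gm.cov)
            if sign <= 0:
                raise np.linalg.LinAlgError(
                    f"sample covariance singular for group {gm.label!r}"
                )
            gm._logdet_cache = ld


# --------------------------------------------------------------------------
# degrees of freedom
# --------------------------------------------------------------------------

def dof(model: ModelSpec, constraints: ConstraintSet | str, m: int,
        p: int | None = None) -> int:
    """Sample moments ``m (p + p(p+1)/2)`` minus free parameters under the
    marker-variable identification and the set's equality constraints."""
    if isinstance(constraints, str):
        if constraints == "equal.cov":
            pp = model.n_variables
            return (m - 1) * pp * (pp + 1) // 2
        if constraints == "saturated":
            return 0
        constraints = CONSTRAINT_SETS[constraints]
    if p is not None and p != model.n_variables:
        raise ValueError("p inconsistent with the model")
    p = model.n_variables
    tmpl = _Template(model, constraints, m)
    df = m * (p + p * (p + 1) // 2) - tmpl.n_free
    if df < 0:
        raise ValueError(
            f"model over-parameterized under {constraints.name!r}: df={df}"
        )
    return df


# --------------------------------------------------------------------------
# fitting
# --------------------------------------------------------------------------

def _default_start(tmpl: _Template, data: list[GroupMoments]) -> np.ndarray:
    """Marker-regression start values from the pooled sample moments."""
    m, p, k = tmpl.m, tmpl.p, tmpl.k
    N = sum(gm.n for gm in data)
    S = sum((gm.n / N) * gm.cov for gm in data)
    markers = tmpl.model.marker_indices()
    gamma = [gm.mean.copy() for gm in data]
    lam0 = tmpl.lam_fixed.copy()
    for r, c in tmpl.lam_free:
        mk = markers[c]
        lam0[r, c] = S[r, mk] / S[mk, mk]
    phi0 = np.empty((k, k))
    for a in range(k):
        for c in range(k):
            phi0[a, c] = 0.5 * S[markers[a], markers[c]]
    phi0 = (phi0 + phi0.T) / 2 + 1e-3 * np.mean(np.diag(S)) * np.eye(k)
    psi0 = 0.5 * np.diag(S).copy()
    ps = ParamSet(
        gamma,
        [lam0.copy() for _ in range(m)],
        [phi0.copy() for _ in range(m)],
        [psi0.copy() for _ in range(m)],
        [np.zeros(k) for _ in range(m)],
    )
    return tmpl.pack(ps, weights=[gm.n for gm in data])


_GTOL = 1e-6
_FTOL = 1e-12


def fit(data: list[GroupMoments], model: ModelSpec,
        constraints: ConstraintSet | str, start: ParamSet | None = None,
        scale: str = "n_minus_m", max_restarts: int = 5,
        name: str | None = None) -> FitResult:
    """Fit the constrained multi-group model by normal-theory ML.

    ``scale`` selects the chi-square convention: ``"n_minus_m"`` gives
    ``T = (N - m) F`` (default), ``"n"`` gives ``T = N F``.
    """
    if isinstance(constraints, str):
        if constraints == "equal.cov":
            return cov_equality_test(data, scale=scale)
        if constraints == "saturated":
            return _saturated_fit(data, scale=scale, name=name)
        constraints = CONSTRAINT_SETS[constraints]
    m = len(data)
    if m < 1:
        raise ValueError("no groups supplied")
    ps0 = data[0].p
    if any(gm.p != ps0 for gm in data):
        raise ValueError("groups have different numbers of variables")
    _cache_logdets(data)
    tmpl = _Template(model, constraints, m)
    df = dof(model, constraints, m)
    N = sum(gm.n for gm in data)

    theta_default = _default_start(tmpl, data)
    starts = [theta_default]
    if start is not None:
        th_warm = tmpl.pack(start, weights=[gm.n for gm in data])
        # keep warm starts off the psi -> 0 boundary (Heywood parents
        # otherwise steer the child fit into a degenerate basin)
        a, b = tmpl.offsets["lpsi"]
        floor = np.log(0.02 * np.median(
            [np.median(np.diag(gm.cov)) for gm in data]))
        th_warm[a:b] = np.maximum(th_warm[a:b], floor)
        starts.insert(0, th_warm)

    fun = lambda th: tmpl.value_and_grad(th, data)
    rng = np.random.default_rng(0)
    nit = 0
    cands: list[tuple[float, float, np.ndarray]] = []  # (F, gnorm, theta)

    def attempt(th):
        nonlocal nit
        res = optimize.minimize(
            fun, th, jac=True, method="L-BFGS-B",
            options=dict(maxiter=5000, maxfun=20000, ftol=_FTOL, gtol=1e-9),
        )
        nit += res.nit
        _, g = fun(res.x)
        gnorm = np.max(np.abs(g)) if np.all(np.isfinite(g)) else np.inf
        if np.isfinite(res.fun):
            cands.append((float(res.fun), float(gnorm), res.x))
        return np.isfinite(res.fun) and gnorm < _GTOL

    def best_candidate():
        """Lowest F among converged candidates if that matches the global
        lowest F; otherwise the global lowest (flagged unconverged)."""
        fmin = min(c[0] for c in cands)
        conv = [c for c in cands if c[1] < _GTOL]
        if conv:
            cbest = min(conv, key=lambda c: c[0])
            if cbest[0] <= fmin + 1e-9:
                return cbest
        return min(cands, key=lambda c: c[0])

    for th in starts:
        attempt(th)
    # polish: re-run from the lowest-F point while it is not yet converged
    for _ in range(3):
        if not cands or best_candidate()[1] < _GTOL:
            break
        attempt(best_candidate()[2])
    if not cands or best_candidate()[1] >= _GTOL:
        for _ in range(max_restarts):
            th = theta_default * (
                1 + 0.05 * rng.standard_normal(theta_default.size)
            ) + 0.01 * rng.standard_normal(theta_default.size)
            attempt(th)
            if best_candidate()[1] < _GTOL:
                break
    best = best_candidate() if cands else (np.inf, np.inf, theta_default)

    fval, gnorm, theta = best
    converged = bool(np.isfinite(fval) and gnorm < _GTOL)
    est, _ = tmpl.unpack(theta)
    fml = max(float(fval), 0.0)
    mult = (N - m) if scale == "n_minus_m" else N
    tml = max(mult * fml, 0.0)
    pvalue = float(chi2.sf(tml, df)) if df > 0 else float("nan")
    warns = []
    if not converged:
        warns.append(f"optimizer did not converge (grad sup-norm {gnorm:.2e})")
    psi_scale = np.median([np.median(np.diag(gm.cov)) for gm in data])
    for j in range(m):
        if np.any(est.psi[j] < 1e-4 * psi_scale):
            warns.append(
                f"group {j + 1}: error variance at boundary (Heywood-like)"
            )
            break
    return FitResult(
        name=name or constraints.name, fml=fml, tml=float(tml), df=df,
        pvalue=pvalue, estimates=est, converged=converged, n_iterations=nit,
        n_total=N, n_groups=m, warnings=tuple(warns),
    )


def _saturated_fit(data: list[GroupMoments], scale: str = "n_minus_m",
                   name: str | None = None) -> FitResult:
    """Fully saturated model: mu_j = xbar_j, Sigma_j = S_j, F = 0, df = 0."""
    N = sum(gm.n for gm in data)
    return FitResult(
        name=name or "saturated", fml=0.0, tml=0.0, df=0,
        pvalue=float("nan"), estimates=None, converged=True, n_iterations=0,
        n_total=N, n_groups=len(data),
    )


def cov_equality_test(data: list[GroupMoments], scale: str = "n_minus_m",
                      name: str = "fit.pop.cov") -> FitResult:
    """Likelihood-ratio test of equal population covariance matrices.

    With saturated means the constrained ML solution is the pooled
    covariance ``sum_j (n_j/N) S_j``, giving the closed form
    ``F = log|pooled| - sum_j (n_j/N) log|S_j|``.
    """
    m = len(data)
    if m < 2:
        raise ValueError("covariance-equality test needs at least two groups")
    _cache_logdets(data)
    N = sum(gm.n for gm in data)
    pooled = sum((gm.n / N) * gm.cov for gm in data)
    sign, logdet_pooled = np.linalg.slogdet(pooled)
    if sign <= 0:
        raise np.linalg.LinAlgError("pooled covariance singular")
    F = float(logdet_pooled - sum((gm.n / N) * gm._logdet_cache
                                  for gm in data))
    F = max(F, 0.0)
    p = data[0].p
    df = (m - 1) * p * (p + 1) // 2
    mult = (N - m) if scale == "n_minus_m" else N
    tml = mult * F
    return FitResult(
        name=name, fml=F, tml=float(tml), df=df,
        pvalue=float(chi2.sf(tml, df)), estimates=None, converged=True,
        n_iterations=0, n_total=N, n_groups=m,
    )


def chisq_diff(child: FitResult, parent: FitResult) -> DiffResult:
    """Chi-square-difference statistic between nested fits."""
    if child.df < parent.df:
        raise ValueError(
            f"{child.name!r} (df={child.df}) is not nested in "
            f"{parent.name!r} (df={parent.df})"
        )
    tdiff = child.tml - parent.tml
    dfdiff = child.df - parent.df
    warning = None
    if tdiff < 0:
        warning = f"negative difference statistic ({tdiff:.4g})"
    pvalue = float(chi2.sf(max(tdiff, 0.0), dfdiff)) if dfdiff > 0 else float("nan")
    if dfdiff == 0 and child.name == parent.name:
        pvalue = float("nan")
    return DiffResult(float(tdiff), int(dfdiff), pvalue, warning)


# --------------------------------------------------------------------------
# the invariance sequence
# --------------------------------------------------------------------------

def run_sequence(data: list[GroupMoments], model: ModelSpec,
                 scale: str = "n_minus_m",
                 scope: str = "both") -> list[SequenceRow]:
    """Fit the full invariance sequence and the difference tests.

    Emits rows named ``fit.configural.g1..gm``, ``fit.combine.groups``,
    ``fit.metric``, then the covariance branch (``fit.residuals``,
    ``fit.varfactor``) and/or the mean branch (``fit.scalar``,
    ``fit.strong.means``, ``fit.strict.residuals``, ``fit.strict.means``)
    according to ``scope`` in {"both", "mean", "covariance"}.
    """
    m = len(data)
    if m < 2:
        raise ValueError("invariance sequence needs at least two groups")
    if scope not in ("both", "mean", "covariance"):
        raise ValueError(f"unknown scope {scope!r}")
    rows: list[SequenceRow] = []
    fits: dict[str, FitResult] = {}

    for j, gm in enumerate(data):
        fr = fit([gm], model, "configural", scale=scale,
                 name=f"fit.configural.g{j + 1}")
        rows.append(SequenceRow(fr.name, fr))
    combine = fit(data, model, "configural", scale=scale,
                  name="fit.combine.groups")
    fits["fit.combine.groups"] = combine
    rows.append(SequenceRow(combine.name, combine))

    order = ["metric"]
    if scope in ("both", "covariance"):
        order += ["residuals", "varfactor"]
    if scope in ("both", "mean"):
        order += ["scalar", "strong.means", "strict.residuals", "strict.means"]

    for cname in order:
        row_name = f"fit.{cname}"
        parent_name = SEQUENCE_PARENTS[row_name]
        parent = fits.get(parent_name)
        warm_name = CONSTRAINT_SETS[cname].parent
        warm = fits.get(f"fit.{warm_name}") if warm_name else None
        start = warm.estimates if (warm and warm.estimates) else (
            combine.estimates)
        fr = fit(data, model, cname, start=start, scale=scale, name=row_name)
        fits[row_name] = fr
        diff = None
        if parent is not None:
            diff = chisq_diff(fr, parent)
            if diff.warning:
                warnings.warn(f"{row_name}: {diff.warning}", RuntimeWarning,
                              stacklevel=2)
        rows.append(SequenceRow(row_name, fr, diff))
    return rows
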