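"""Seeded multi-group factor-model data generator.

Generates raw observation tables, sample moments, or exact population
moments from a per-group parameter set, with switchable invariance
violations (loading, intercept, latent-mean and specific-mean shifts)
whose magnitude can be calibrated to a target population misfit.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize

from . import mgsem
from .mgsem import ParamSet
from .model_io import GroupMoments, ModelSpec

__all__ = [
    "SimDesign",
    "VIOLATION_KINDS",
    "default_design",
    "generate",
    "population_moments",
    "make_violation",
    "calibrate_violation",
    "population_misfit",
]

VIOLATION_KINDS = (
    "loading_shift",
    "intercept_shift",
    "latent_mean_shift",
    "specific_mean_shift",
)

#: constrained model whose population discrepancy a violation inflates
_VIOLATION_MODEL = {
    "loading_shift": "metric",
    "intercept_shift": "scalar",
    "latent_mean_shift": "strong.means",
    "specific_mean_shift": "scalar",
}


@dataclass(frozen=True)
class SimDesign:
    model: ModelSpec
    params: ParamSet
    ns: tuple[int, ...]
    seed: int = 0

    def __post_init__(self):
        m = self.params.n_groups
        if len(self.ns) != m:
            raise ValueError("one sample size per group required")
        for j in range(m):
            phi = self.params.phi[j]
            if np.linalg.eigvalsh((phi + phi.T) / 2).min() < -1e-10:
                raise ValueError(f"group {j + 1}: factor covariance not PSD")
            if np.any(self.params.psi[j] < 0):
                raise ValueError(f"group {j + 1}: negative error variance")


def default_design(model: ModelSpec, ns=(200, 200), seed: int = 0,
                   loading: float = 0.8, phi_corr: float = 0.3,
                   psi: float = 0.5) -> SimDesign:
    """Invariant baseline design: identical groups, unit factor variances
    with exchangeable correlation, equal loadings, zero means."""
    p, k = model.n_variables, model.n_factors
    m = len(ns)
    lam = np.zeros((p, k))
    markers = model.marker_indices()
    pattern = model.loading_pattern()
    for c in range(k):
        for r in range(p):
            if pattern[r, c]:
                lam[r, c] = 1.0 if r == markers[c] else loading
    phi = phi_corr * np.ones((k, k)) + (1 - phi_corr) * np.eye(k)
    params = ParamSet(
        [np.zeros(p) for _ in range(m)],
        [lam.copy() for _ in range(m)],
        [phi.copy() for _ in range(m)],
        [psi * np.ones(p) for _ in range(m)],
        [np.zeros(k) for _ in range(m)],
    )
    return SimDesign(model=model, params=params, ns=tuple(int(n) for n in ns),
                     seed=seed)


def population_moments(design: SimDesign) -> list[GroupMoments]:
    """Exact model-implied moments, for noiseless identity tests."""
    out = []
    for j, n in enumerate(design.ns):
        mu, sigma = mgsem.implied_moments(design.params, j)
        out.append(GroupMoments(
            label=f"g{j + 1}", n=n, mean=mu, cov=sigma,
            variables=design.model.all_variables,
        ))
    return out


def generate(design: SimDesign, kind: str = "raw"):
    """Draw multivariate-normal data from the design's implied moments.

    ``kind``: ``"raw"`` -> list of per-group DataFrames, ``"moments"`` ->
    list of sample :class:`GroupMoments`, ``"population"`` -> exact
    implied moments.  Fully determined by ``design.seed``.
    """
    if kind == "population":
        return population_moments(design)
    rng = np.random.default_rng(design.seed)
    frames = []
    for j, n in enumerate(design.ns):
        mu, sigma = mgsem.implied_moments(design.params, j)
        x = rng.multivariate_normal(mu, sigma, size=n, method="cholesky")
        frames.append(pd.DataFrame(x, columns=design.model.all_variables))
    if kind == "raw":
        return frames
    if kind == "moments":
        out = []
        for j, f in enumerate(frames):
            a = f.to_numpy(float)
            n = a.shape[0]
            mean = a.mean(axis=0)
            c = a - mean
            out.append(GroupMoments(
                label=f"g{j + 1}", n=n, mean=mean, cov=c.T @ c / n,
                variables=design.model.all_variables,
            ))
        return out
    raise ValueError(f"unknown kind {kind!r}")


def raw_table(design: SimDesign, group_col: str = "group") -> pd.DataFrame:
    """Single stacked table with a group-membership column."""
    frames = generate(design, "raw")
    parts = []
    for j, f in enumerate(frames):
        f = f.copy()
        f[group_col] = j + 1
        parts.append(f)
    return pd.concat(parts, ignore_index=True)


def _orth_complement_direction(lam: np.ndarray) -> np.ndarray:
    """A unit vector orthogonal to col(lam)."""
    p, k = lam.shape
    Q = np.eye(p) - lam @ np.linalg.solve(lam.T @ lam, lam.T)
    w = Q @ np.cos(np.arange(1, p + 1))
    nrm = np.linalg.norm(w)
    if nrm < 1e-12:
        raise ValueError("no orthogonal complement direction (p = k?)")
    return w / nrm


def make_violation(design: SimDesign, kind: str,
                   magnitude: float) -> SimDesign:
    """Return a design whose LAST group deviates from the others.

    * ``loading_shift`` adds ``magnitude`` to every non-marker loading.
    * ``intercept_shift`` adds ``magnitude`` to every intercept of the
      non-marker indicators (breaks equal intercepts).
    * ``latent_mean_shift`` adds ``magnitude`` to every latent mean
      (nonzero kappa difference).
    * ``specific_mean_shift`` shifts the intercepts by ``magnitude`` times
      a unit vector orthogonal to col(Lambda) (nonzero nu difference,
      kappa difference unchanged).
    """
    if kind not in VIOLATION_KINDS:
        raise ValueError(f"unknown violation kind {kind!r}")
    if magnitude == 0:
        return design
    params = design.params.copy()
    j = params.n_groups - 1
    model = design.model
    markers = set(model.marker_indices())
    pattern = model.loading_pattern()
    if kind == "loading_shift":
        lam = params.lam[j]
        for c in range(model.n_factors):
            for r in range(model.n_variables):
                if pattern[r, c] and r != model.marker_indices()[c]:
                    lam[r, c] += magnitude
    elif kind == "intercept_shift":
        for r in range(model.n_variables):
            if r not in markers:
                params.gamma[j][r] += magnitude
    elif kind == "latent_mean_shift":
        params.tau[j] = params.tau[j] + magnitude
    elif kind == "specific_mean_shift":
        w = _orth_complement_direction(params.lam[j])
        params.gamma[j] = params.gamma[j] + magnitude * w
    return replace(design, params=params)


def population_misfit(design: SimDesign, constraints: str) -> float:
    """Population discrepancy: minimized F of the constrained model fitted
    to the design's exact implied moments."""
    data = population_moments(design)
    fr = mgsem.fit(data, design.model, constraints)
    return fr.fml


def calibrate_violation(design: SimDesign, kind: str, target_fml: float,
                        constraints: str | None = None,
                        bracket: tuple[float, float] = (1e-4, 3.0),
                        tol: float = 1e-8) -> SimDesign:
    """Find the violation magnitude whose population F under the matching
    constrained model equals ``target_fml`` (root-finding on the
    population-discrepancy curve)."""
    if constraints is None:
        constraints = _VIOLATION_MODEL[kind]
    if target_fml <= 0:
        return design

    def gap(mag):
        return population_misfit(make_violation(design, kind, mag),
                                 constraints) - target_fml

    lo, hi = bracket
    glo, ghi = gap(lo), gap(hi)
    while ghi < 0 and hi < 50:
        hi *= 2
        ghi = gap(hi)
    if glo > 0 or ghi < 0:
        raise ValueError(
            f"target F={target_fml} not bracketed by magnitudes {lo}..{hi}"
        )
    mag = optimize.brentq(gap, lo, hi, xtol=tol)
    return make_violation(design, kind, mag)
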