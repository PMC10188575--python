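"""Sample correlations and the asymptotic covariance Gamma of their estimates.

Scale convention used throughout the package: ``Gamma`` is the asymptotic
covariance matrix of sqrt(n) * (s - sigma), so its entries are O(1).  All
trace terms downstream (ULSMV adjustment, lambda_u estimates, residual
covariance Sigma_e) are expressed on this scale; the per-observation residual
covariance is Gamma-projected divided by n.

Two estimators are supported:

* Pearson product-moment correlations with the normal-theory (Olkin-Siotani)
  closed form for Gamma -- appropriate for multivariate-normal data; an
  empirical fourth-moment (ADF) Gamma is available as an option.
* Tetrachoric correlations for {0,1} data: two-step pairwise maximum
  likelihood (thresholds from the margins, then the bivariate-normal
  correlation matching the joint proportion), with Gamma from the sandwich of
  the stacked per-observation estimating equations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.polynomial.legendre import leggauss
from scipy.optimize import brentq
from scipy.stats import norm

from .vech import pair_indices, unvech_off


@dataclass(frozen=True)
class SampleEstimate:
    """Estimated correlations of one sample, in canonical pair ordering."""

    r: np.ndarray
    n: int
    p: int
    type: str  # "pearson" | "tetrachoric"
    thresholds: np.ndarray | None = None
    var_names: tuple[str, ...] | None = None

    @property
    def matrix(self) -> np.ndarray:
        return unvech_off(self.r, self.p)


@dataclass(frozen=True)
class GammaMatrix:
    """Asymptotic covariance of sqrt(n)(s - sigma); symmetric PSD."""

    values: np.ndarray
    source: str  # "pearson-normal" | "tetrachoric" | "empirical"

    def __post_init__(self):
        V = np.asarray(self.values, dtype=float)
        V = 0.5 * (V + V.T)
        object.__setattr__(self, "values", V)

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.values)[0])


def _as_array(data) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(data, pd.DataFrame):
        return data.to_numpy(dtype=float), tuple(str(c) for c in data.columns)
    X = np.asarray(data, dtype=float)
    if X.ndim != 2:
        raise ValueError("data must be a 2-D table (cases x variables)")
    return X, tuple(f"v{i+1}" for i in range(X.shape[1]))


# ---------------------------------------------------------------------------
# Pearson
# ---------------------------------------------------------------------------

def pearson_correlations(data) -> SampleEstimate:
    """Product-moment correlations of a metric n x p table."""
    X, names = _as_array(data)
    n, p = X.shape
    if n < 3:
        raise ValueError(f"need n >= 3 cases, got {n}")
    if np.isnan(X).any():
        raise ValueError("data contain missing values; no imputation is performed")
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [names[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant column(s): {bad}")
    R = np.corrcoef(X, rowvar=False)
    rows, cols = pair_indices(p)
    return SampleEstimate(r=R[rows, cols], n=n, p=p, type="pearson", var_names=names)


def gamma_pearson(est: SampleEstimate | np.ndarray) -> GammaMatrix:
    """Normal-theory asymptotic covariance of Pearson correlations.

    Uses the classical four-index expression in the correlations rho,
    evaluated at the estimate (or at a supplied correlation matrix):

        cov(r_ij, r_kl) = 1/2 rho_ij rho_kl (rho_ik^2 + rho_il^2 + rho_jk^2
                          + rho_jl^2) + rho_ik rho_jl + rho_il rho_jk
                          - rho_ij (rho_jk rho_jl + rho_ik rho_il)
                          - rho_kl (rho_jk rho_ik + rho_jl rho_il)
    """
    if isinstance(est, SampleEstimate):
        if est.type != "pearson":
            raise ValueError("gamma_pearson expects a pearson SampleEstimate")
        R = est.matrix
    else:
        R = np.asarray(est, dtype=float)
    p = R.shape[0]
    I, J = pair_indices(p)
    rij = R[I, J]
    Rik = R[np.ix_(I, I)]
    Ril = R[np.ix_(I, J)]
    Rjk = R[np.ix_(J, I)]
    Rjl = R[np.ix_(J, J)]
    G = (
        0.5 * np.outer(rij, rij) * (Rik**2 + Ril**2 + Rjk**2 + Rjl**2)
        + Rik * Rjl
        + Ril * Rjk
        - rij[:, None] * (Rjk * Rjl + Rik * Ril)
        - rij[None, :] * (Rjk * Rik + Rjl * Ril)
    )
    return GammaMatrix(values=G, source="pearson-normal")


def gamma_empirical(data, est: SampleEstimate | None = None) -> GammaMatrix:
    """Distribution-free Gamma from empirical fourth moments (ADF-style).

    Influence-function estimate: for standardized variables z,
    psi_ij = z_i z_j - r_ij - r_ij (z_i^2 + z_j^2 - 2) / 2, and Gamma is the
    empirical covariance of psi.
    """
    X, _ = _as_array(data)
    n, p = X.shape
    if est is None:
        est = pearson_correlations(X)
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)
    I, J = pair_indices(p)
    r = est.r
    psi = Z[:, I] * Z[:, J] - r - 0.5 * r * (Z[:, I] ** 2 + Z[:, J] ** 2 - 2.0)
    psi -= psi.mean(axis=0)
    G = psi.T @ psi / n
    return GammaMatrix(values=G, source="empirical")


# ---------------------------------------------------------------------------
# bivariate normal CDF (Gauss-Legendre over the correlation parameter)
# ---------------------------------------------------------------------------

_GL_NODES, _GL_WEIGHTS = leggauss(96)


def bvn_cdf(h: float, k: float, rho: float) -> float:
    """P(X <= h, Y <= k) for standard bivariate normal with correlation rho.

    Phi2(h, k; rho) = Phi(h) Phi(k) + int_0^rho phi2(h, k; t) dt, with the
    integral evaluated by 96-node Gauss-Legendre quadrature (absolute accuracy
    ~1e-10 for |rho| <= 0.95, ~1e-7 out to 0.999).
    """
    if abs(rho) >= 1.0:
        if rho >= 1.0:
            return float(norm.cdf(min(h, k)))
        return float(max(0.0, norm.cdf(h) + norm.cdf(k) - 1.0))
    base = norm.cdf(h) * norm.cdf(k)
    if rho == 0.0:
        return float(base)
    t = 0.5 * rho * (_GL_NODES + 1.0)
    w = 0.5 * rho * _GL_WEIGHTS
    om = 1.0 - t * t
    dens = np.exp(-(h * h - 2.0 * t * h * k + k * k) / (2.0 * om)) / (
        2.0 * np.pi * np.sqrt(om)
    )
    return float(base + np.sum(w * dens))


def _bvn_pdf(h: float, k: float, rho: float) -> float:
    om = 1.0 - rho * rho
    return float(
        np.exp(-(h * h - 2.0 * rho * h * k + k * k) / (2.0 * om))
        / (2.0 * np.pi * np.sqrt(om))
    )


def _upper_quadrant(tau_a: float, tau_b: float, rho: float) -> float:
    """P(X > tau_a, Y > tau_b)."""
    return 1.0 - norm.cdf(tau_a) - norm.cdf(tau_b) + bvn_cdf(tau_a, tau_b, rho)


# ---------------------------------------------------------------------------
# tetrachoric
# ---------------------------------------------------------------------------

_RHO_BOUND = 0.999


def _solve_tetrachoric(p11: float, tau_a: float, tau_b: float) -> float:
    """Correlation of the latent bivariate normal matching the joint proportion.

    With the thresholds fixed at the sample margins, the pairwise ML estimate
    solves P(X > tau_a, Y > tau_b; rho) = p11 (the multinomial score in rho is
    proportional to that residual), which is monotone in rho.
    """
    def f(rho: float) -> float:
        return _upper_quadrant(tau_a, tau_b, rho) - p11

    lo, hi = -_RHO_BOUND, _RHO_BOUND
    flo, fhi = f(lo), f(hi)
    if flo >= 0.0:
        return lo
    if fhi <= 0.0:
        return hi
    return float(brentq(f, lo, hi, xtol=1e-12, rtol=8.9e-16))


def _validate_binary(X: np.ndarray, names) -> None:
    vals = np.unique(X)
    if not np.all(np.isin(vals, (0.0, 1.0))):
        raise ValueError("dichotomous data must be coded {0,1}")
    means = X.mean(axis=0)
    bad = [names[i] for i in np.flatnonzero((means == 0) | (means == 1))]
    if bad:
        raise ValueError(f"column(s) with a single category: {bad}")


def tetrachoric_correlations(data) -> SampleEstimate:
    """Pairwise two-step ML tetrachoric correlations of an n x p {0,1} table.

    Thresholds come from the marginal proportions via the inverse normal CDF;
    each pairwise correlation then matches the 2x2 joint proportion exactly
    (the ML solution given the thresholds).  An empty cell in a pairwise
    table triggers the +0.5 continuity correction with a warning.
    """
    X, names = _as_array(data)
    n, p = X.shape
    _validate_binary(X, names)
    prop1 = X.mean(axis=0)
    # threshold tau: P(Z > tau) = P(y = 1)
    tau = norm.ppf(1.0 - prop1)
    rows, cols = pair_indices(p)
    r = np.empty(rows.size)
    for a, (i, j) in enumerate(zip(rows, cols)):
        n11 = float(np.sum((X[:, i] == 1) & (X[:, j] == 1)))
        n10 = float(np.sum((X[:, i] == 1) & (X[:, j] == 0)))
        n01 = float(np.sum((X[:, i] == 0) & (X[:, j] == 1)))
        n00 = n - n11 - n10 - n01
        if min(n11, n10, n01, n00) == 0:
            warnings.warn(
                f"empty cell in the 2x2 table of ({names[i]}, {names[j]}); "
                "applying +0.5 continuity correction",
                stacklevel=2,
            )
            n11 += 0.5
            n10 += 0.5
            n01 += 0.5
            n00 += 0.5
        tot = n11 + n10 + n01 + n00
        ta = norm.ppf((n01 + n00) / tot)
        tb = norm.ppf((n10 + n00) / tot)
        r[a] = _solve_tetrachoric(n11 / tot, ta, tb)
    return SampleEstimate(
        r=r, n=n, p=p, type="tetrachoric", thresholds=tau, var_names=names
    )


def gamma_tetrachoric(data, est: SampleEstimate) -> GammaMatrix:
    """Sandwich covariance of sqrt(n)-scaled tetrachoric estimates.

    The thresholds and pairwise correlations jointly solve the stacked moment
    conditions

        g_a  = y_a - (1 - Phi(tau_a))                  (margins)
        g_ab = y_a y_b - P(X > tau_a, Y > tau_b; rho)  (joint proportions)

    so sqrt(n)(theta_hat - theta) -> N(0, A^-1 B A^-T) with A = E[dg/dtheta']
    and B = Cov(g).  Gamma is the correlation block of that sandwich, which
    propagates the threshold-estimation noise into the correlations.
    """
    if est.type != "tetrachoric":
        raise ValueError("gamma_tetrachoric expects a tetrachoric SampleEstimate")
    X, names = _as_array(data)
    n, p = X.shape
    _validate_binary(X, names)
    rows, cols = pair_indices(p)
    m = rows.size
    tau = est.thresholds
    dim = p + m
    # per-observation moment contributions
    G = np.empty((n, dim))
    pi1 = 1.0 - norm.cdf(tau)
    G[:, :p] = X - pi1
    A = np.zeros((dim, dim))
    A[np.arange(p), np.arange(p)] = norm.pdf(tau)
    sq = np.sqrt(1.0 - est.r**2)
    for a, (i, j) in enumerate(zip(rows, cols)):
        rho = est.r[a]
        pi11 = _upper_quadrant(tau[i], tau[j], rho)
        G[:, p + a] = X[:, i] * X[:, j] - pi11
        # d g_ab / d tau_i = + phi(tau_i) * P(Y > tau_j | X = tau_i)
        zi = (tau[j] - rho * tau[i]) / sq[a]
        zj = (tau[i] - rho * tau[j]) / sq[a]
        A[p + a, i] = norm.pdf(tau[i]) * (1.0 - norm.cdf(zi))
        A[p + a, j] = norm.pdf(tau[j]) * (1.0 - norm.cdf(zj))
        A[p + a, p + a] = -_bvn_pdf(tau[i], tau[j], rho)
    G -= G.mean(axis=0)
    B = G.T @ G / n
    Ainv = np.linalg.inv(A)
    V = Ainv @ B @ Ainv.T
    return GammaMatrix(values=V[p:, p:], source="tetrachoric")
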