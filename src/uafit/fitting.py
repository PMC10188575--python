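"""Fitting correlation-structure models by ML, GLS or ULS discrepancies.

F_ML  = log|Sigma_hat| - log|S| + tr(S Sigma_hat^-1) - p
F_GLS = (s - sigma_hat)' W (s - sigma_hat), W = 1/2 D'(S^-1 (x) S^-1) D
        restricted to the off-diagonal (correlation) coordinates
F_ULS = (s - sigma_hat)' (s - sigma_hat)

The test statistic is T = n * F.  The ULSMV mean-variance adjustment rescales
T_ULS with the trace constants a and d* built from the residual projector
U = I - Delta (Delta'Delta)^-1 Delta' and the correlation-estimate covariance
Gamma, so that T_adj = T_ULS / a approximates a chi-square with d* df.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .correlations import GammaMatrix
from .model import ModelSpec, implied_matrix, jacobian
from .vech import n_pairs, pair_indices, unvech_off, vech_off

_METHODS = ("ML", "GLS", "ULS")


@dataclass(frozen=True)
class FittedModel:
    theta_hat: np.ndarray
    sigma_hat: np.ndarray
    s: np.ndarray
    delta: np.ndarray
    F: float
    n: int
    df: int
    method: str
    converged: bool
    grad_norm: float
    spec: ModelSpec | None = None

    @property
    def T(self) -> float:
        return self.n * self.F

    @property
    def residuals(self) -> np.ndarray:
        return self.s - self.sigma_hat

    @property
    def T_uls(self) -> float:
        """n * squared Euclidean residual norm, whatever discrepancy was fitted."""
        e = self.residuals
        return float(self.n * e @ e)

    @property
    def F_uls(self) -> float:
        return self.T_uls / self.n


def duplication_matrix(p: int) -> np.ndarray:
    """D with D vech(M) = vec(M) for symmetric M (diagonal included)."""
    nh = p * (p + 1) // 2
    D = np.zeros((p * p, nh))
    c = 0
    for j in range(p):
        for i in range(j, p):
            D[i * p + j, c] = 1.0
            D[j * p + i, c] = 1.0
            c += 1
    return D


def gls_weight(S: np.ndarray) -> np.ndarray:
    """Normal-theory GLS weight on the off-diagonal correlation coordinates.

    Builds W_full = 1/2 D'(S^-1 (x) S^-1) D over vech (diagonal included) and
    returns the submatrix for the strict lower triangle, reordered to the
    canonical column-major pair ordering.
    """
    S = np.asarray(S, dtype=float)
    p = S.shape[0]
    sign, _ = np.linalg.slogdet(S)
    if sign <= 0:
        raise np.linalg.LinAlgError("S is not positive definite")
    Sinv = np.linalg.inv(S)
    D = duplication_matrix(p)
    Wfull = 0.5 * D.T @ np.kron(Sinv, Sinv) @ D
    # positions of the off-diagonal elements inside vech ordering
    off = []
    c = 0
    for j in range(p):
        for i in range(j, p):
            if i != j:
                off.append(c)
            c += 1
    idx = np.asarray(off)
    W = Wfull[np.ix_(idx, idx)]
    return 0.5 * (W + W.T)


def _objective(method: str, spec: ModelSpec, s: np.ndarray, W: np.ndarray | None,
               S: np.ndarray | None, logdet_S: float | None):
    p = spec.p
    rows, cols = pair_indices(p)

    def fg(theta: np.ndarray) -> tuple[float, np.ndarray]:
        Sig = implied_matrix(theta, spec)
        sig = Sig[rows, cols]
        Delta = jacobian(theta, spec)
        if method == "ULS":
            e = s - sig
            return float(e @ e), -2.0 * Delta.T @ e
        if method == "GLS":
            e = s - sig
            We = W @ e
            return float(e @ We), -2.0 * Delta.T @ We
        # ML
        try:
            L = np.linalg.cholesky(Sig)
        except np.linalg.LinAlgError:
            return 1e10, np.zeros(spec.n_params)
        logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
        Sig_inv = np.linalg.inv(Sig)
        F = logdet - logdet_S + float(np.trace(Sig_inv @ S)) - p
        Gmat = Sig_inv - Sig_inv @ S @ Sig_inv
        grad = 2.0 * Delta.T @ Gmat[rows, cols]
        return F, grad

    return fg


def fit(
    spec: ModelSpec,
    s: np.ndarray,
    n: int,
    method: str = "ML",
    start: np.ndarray | None = None,
    gtol: float = 1e-8,
    max_restarts: int = 5,
) -> FittedModel:
    """Minimize the chosen discrepancy between s and the model structure.

    Restarts from jittered starting values if the optimizer fails to converge
    or lands on an inadmissible solution (an implied correlation >= 1).
    """
    if method not in _METHODS:
        raise ValueError(f"method must be one of {_METHODS}")
    if spec.df < 0:
        raise ValueError(
            f"model has more parameters ({spec.n_params}) than "
            f"non-redundant correlations ({n_pairs(spec.p)})"
        )
    s = np.asarray(s, dtype=float)
    p = spec.p
    if s.shape != (n_pairs(p),):
        raise ValueError(f"s has length {s.size}, expected {n_pairs(p)}")
    Smat = unvech_off(s, p)
    W = None
    logdet_S = None
    if method == "GLS":
        W = gls_weight(Smat)
    elif method == "ML":
        sign, logdet_S = np.linalg.slogdet(Smat)
        if sign <= 0:
            raise np.linalg.LinAlgError(
                "the embedded correlation matrix is not positive definite"
            )
        logdet_S = float(logdet_S)
    fg = _objective(method, spec, s, W, Smat if method == "ML" else None, logdet_S)

    theta0 = spec.default_start() if start is None else np.asarray(start, dtype=float)
    jitter_rng = np.random.default_rng(12345)
    best = None
    for attempt in range(max_restarts + 1):
        t0 = theta0 if attempt == 0 else theta0 + jitter_rng.normal(0, 0.1, theta0.size)
        res = minimize(fg, t0, jac=True, method="L-BFGS-B",
                       options=dict(maxiter=2000, ftol=1e-14, gtol=gtol))
        theta = res.x
        Sig = implied_matrix(theta, spec)
        sig = vech_off(Sig)
        admissible = np.all(np.abs(sig) < 1.0)
        if method == "ML":
            admissible = admissible and np.linalg.eigvalsh(Sig)[0] > 0
        gnorm = float(np.max(np.abs(fg(theta)[1]))) if admissible else np.inf
        ok = admissible and gnorm < max(gtol, 1e-6)
        cand = (res.fun, theta, gnorm, ok)
        if best is None or (cand[3] and not best[3]) or (cand[3] == best[3] and cand[0] < best[0]):
            best = cand
        if ok:
            break
    F, theta, gnorm, ok = best
    if not ok:
        warnings.warn(
            f"{method} fit did not converge after {max_restarts} restarts "
            f"(grad norm {gnorm:.2e})",
            stacklevel=2,
        )
    K, _ = spec.unpack(theta)
    comm = np.sum(K * K, axis=1)
    if ok and np.any(comm > 0.998):
        warnings.warn("solution is Heywood-adjacent (a communality is ~1)", stacklevel=2)
    Sig = implied_matrix(theta, spec)
    return FittedModel(
        theta_hat=theta,
        sigma_hat=vech_off(Sig),
        s=s,
        delta=jacobian(theta, spec),
        F=max(float(F), 0.0),
        n=int(n),
        df=spec.df,
        method=method,
        converged=bool(ok),
        grad_norm=gnorm,
        spec=spec,
    )


def independence_fit(s: np.ndarray, n: int, p: int, method: str = "ULS") -> FittedModel:
    """The zero-parameter baseline: all correlations fixed at 0.

    F_ULS is the squared norm of s; F_ML reduces to -log|S| because the
    implied matrix is the identity.  df equals the number of correlations.
    """
    s = np.asarray(s, dtype=float)
    if s.shape != (n_pairs(p),):
        raise ValueError(f"s has length {s.size}, expected {n_pairs(p)}")
    if method == "ULS":
        F = float(s @ s)
    elif method == "ML":
        sign, logdet = np.linalg.slogdet(unvech_off(s, p))
        if sign <= 0:
            raise np.linalg.LinAlgError(
                "the embedded correlation matrix is not positive definite"
            )
        F = float(-logdet)
    else:
        raise ValueError("independence baseline supports ML or ULS")
    return FittedModel(
        theta_hat=np.empty(0),
        sigma_hat=np.zeros_like(s),
        s=s,
        delta=np.empty((s.size, 0)),
        F=F,
        n=int(n),
        df=n_pairs(p),
        method=method,
        converged=True,
        grad_norm=0.0,
        spec=None,
    )


# ---------------------------------------------------------------------------
# ULSMV adjustment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UlsmvAdjustment:
    a: float
    d_star: float
    T_adj: float
    U: np.ndarray
    tr_ugamma: float


def residual_projector(delta: np.ndarray, W: np.ndarray | None = None) -> np.ndarray:
    """U = I - Delta (Delta' W Delta)^-1 Delta' W (orthogonal when W is None).

    U annihilates the column space of Delta (U Delta = 0) and is idempotent;
    with W = None (identity weight) it is the symmetric projector used by the
    ULSMV adjustment, otherwise the oblique projector of the GLS/ML residuals.
    """
    m, t = delta.shape
    if t == 0:
        return np.eye(m)
    if W is None:
        Q, R = np.linalg.qr(delta)
        if np.min(np.abs(np.diag(R))) < 1e-10 * max(1.0, np.max(np.abs(R))):
            raise np.linalg.LinAlgError(
                "Jacobian is rank deficient (near-collinear parameters)"
            )
        return np.eye(m) - Q @ Q.T
    M = delta.T @ W @ delta
    try:
        sol = np.linalg.solve(M, delta.T @ W)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "Delta' W Delta is singular (near-collinear parameters)"
        ) from exc
    return np.eye(m) - delta @ sol


def ulsmv_adjust(fit_result: FittedModel, gamma: GammaMatrix) -> UlsmvAdjustment:
    """Mean-variance adjustment of the ULS statistic.

    a = tr[U Gamma] / d*,  d* = tr[U Gamma]^2 / tr[(U Gamma)^2],
    T_adj = T_ULS / a, with U the orthogonal residual projector at the fit.
    """
    U = residual_projector(fit_result.delta)
    M = U @ gamma.values
    tr1 = float(np.trace(M))
    tr2 = float(np.trace(M @ M))
    if tr2 <= 0 or tr1 <= 0:
        raise ValueError(
            f"degenerate ULSMV traces (tr[UG]={tr1:.3e}, tr[(UG)^2]={tr2:.3e})"
        )
    d_star = tr1 * tr1 / tr2
    a = tr1 / d_star
    return UlsmvAdjustment(
        a=a, d_star=d_star, T_adj=fit_result.T_uls / a, U=U, tr_ugamma=tr1
    )
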