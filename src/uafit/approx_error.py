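"""Unweighted approximation-error estimates lambda_u.

lambda_u is n times the squared Euclidean distance between the population
correlations and their limiting model approximation -- the population value
of the ULS discrepancy, whatever discrepancy fitted the model.  Three
estimators:

* approach 1.1: lambda_u = T_ULS - tr[U_(1.1) Gamma], the ULSMV trace term
  with the orthogonal residual projector U_(1.1) = I - D(D'D)^-1 D';
* approach 1.2: lambda_u = T_ULS - tr(Sigma_e) with the residual covariance
  Sigma_e = U_(1.2) Gamma U_(1.2)' and the oblique projector built from the
  GLS weight W (sqrt(n) scale, so the trace subtracts directly);
* approach 2: lambda_u = ADR * T_ULS, where ADR = (T - df)/T is the
  approximation discrepancy ratio of a chi-square calibrated statistic
  (typically the ML statistic) from the same sample and model.

Estimates are returned un-clamped; the max(., 0) guards live in the fit
indices so that averaging stays unbiased.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .correlations import GammaMatrix
from .fitting import FittedModel, residual_projector


@dataclass(frozen=True)
class ApproxErrorEstimate:
    lambda_u: float
    approach: str  # "1.1" | "1.2" | "2"
    T_uls: float
    n: int
    trace_term: float | None = None  # tr[U Gamma] or tr(Sigma_e), sqrt(n) scale
    adr: float | None = None
    sigma_e: np.ndarray | None = None  # sqrt(n) scale residual covariance

    @property
    def F_uls(self) -> float:
        return self.T_uls / self.n


def lambda_u_approach_11(fit_result: FittedModel, gamma: GammaMatrix) -> ApproxErrorEstimate:
    """T_ULS minus tr[U_(1.1) Gamma]."""
    U = residual_projector(fit_result.delta)
    sigma_e = U @ gamma.values @ U.T
    # U symmetric idempotent => tr(U G U') = tr(U G)
    trace = float(np.trace(U @ gamma.values))
    T_uls = fit_result.T_uls
    return ApproxErrorEstimate(
        lambda_u=T_uls - trace,
        approach="1.1",
        T_uls=T_uls,
        n=fit_result.n,
        trace_term=trace,
        sigma_e=sigma_e,
    )


def lambda_u_approach_12(
    fit_result: FittedModel, gamma: GammaMatrix, W: np.ndarray
) -> ApproxErrorEstimate:
    """T_ULS minus the trace of the residual covariance U_(1.2) Gamma U_(1.2)'."""
    U = residual_projector(fit_result.delta, W)
    sigma_e = U @ gamma.values @ U.T
    trace = float(np.trace(sigma_e))
    T_uls = fit_result.T_uls
    return ApproxErrorEstimate(
        lambda_u=T_uls - trace,
        approach="1.2",
        T_uls=T_uls,
        n=fit_result.n,
        trace_term=trace,
        sigma_e=sigma_e,
    )


def adr(T: float, df: float) -> float:
    """Approximation discrepancy ratio (T - df) / T, un-clamped."""
    if T <= 0:
        raise ValueError(f"ADR requires T > 0, got {T}")
    return (T - df) / T


def lambda_u_approach_2(
    T: float,
    df: float,
    T_uls: float,
    n: int,
    sigma_e: np.ndarray | None = None,
    same_discrepancy: bool = False,
) -> ApproxErrorEstimate:
    """ADR-weighted T_ULS.

    ``T`` and ``df`` come from a chi-square calibrated discrepancy (ML, or the
    ULSMV pair (T_adj, d*), in which case the result equals approach 1.1
    exactly); ``T_uls`` is the unweighted statistic of the same fit.
    """
    if same_discrepancy:
        warnings.warn(
            "approach 2 with T from the same (unadjusted) ULS discrepancy "
            "degenerates to the plain noncentrality estimate T - df",
            stacklevel=2,
        )
    ratio = adr(T, df)
    return ApproxErrorEstimate(
        lambda_u=ratio * T_uls,
        approach="2",
        T_uls=T_uls,
        n=n,
        adr=ratio,
        sigma_e=sigma_e,
    )
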