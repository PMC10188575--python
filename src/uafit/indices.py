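"""RMSEA_u and CFI_u with bias correction and confidence intervals.

RMSEA_u = sqrt(max(lambda_u / (n df), 0)) measures the average absolute
correlation residual due to approximation error per degree of freedom;
CFI_u = 1 - max(lambda_u, 0) / max(lambda_u, lambda_Bu) compares it to an
independence baseline.  Point estimates carry a small-sample correction
constant k derived from the variance of F_ULS,

    sigma2_F = 2 tr[(n^-1 Sigma_e)^2] + 4 (s - sigma_hat)' (n^-1 Sigma_e) (s - sigma_hat),

the delta-method variance of a quadratic form in the correlation residuals
(Sigma_e on the sqrt(n) scale of Gamma).  Approaches 1.1/1.2 use
k = 1 - sigma2_F / (4 F_ULS^2); approach 2 uses k = 1 - sigma2_F / (8 F_ULS^2).
Classic (noncentrality-based) RMSEA/CFI from the same fits are reported for
comparison.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np
from scipy.stats import norm

from .approx_error import (
    ApproxErrorEstimate,
    adr,
    lambda_u_approach_2,
    lambda_u_approach_11,
    lambda_u_approach_12,
)
from .correlations import (
    GammaMatrix,
    SampleEstimate,
    gamma_empirical,
    gamma_pearson,
    gamma_tetrachoric,
    pearson_correlations,
    tetrachoric_correlations,
)
from .fitting import (
    FittedModel,
    gls_weight,
    independence_fit,
    fit as fit_model,
    ulsmv_adjust,
)
from .model import ModelSpec


APPROACHES = ("1.1", "1.2", "2")


def sigma2_f(
    sigma_e: np.ndarray,
    residuals: np.ndarray,
    n: int,
    squared_trace: bool = True,
) -> float:
    """Variance of F_ULS from the residual covariance.

    ``sigma_e`` is on the sqrt(n) Gamma scale; internally A = sigma_e / n is
    the covariance of the residual vector itself.  The default first term is
    2 tr(A^2), the variance of a Gaussian quadratic form; ``squared_trace=False``
    computes 2 tr(A) instead (kept for comparison -- it overstates the
    variance by orders of magnitude, see the Monte-Carlo oracle test).
    """
    A = np.asarray(sigma_e, dtype=float) / n
    e = np.asarray(residuals, dtype=float)
    first = 2.0 * float(np.trace(A @ A)) if squared_trace else 2.0 * float(np.trace(A))
    return first + 4.0 * float(e @ A @ e)


def rmsea_u_raw(lambda_u: float, n: int, df: int) -> float:
    """Uncorrected RMSEA_u = sqrt(max(lambda_u / (n df), 0))."""
    if df <= 0:
        raise ValueError("RMSEA_u is undefined for df = 0 (saturated model)")
    return float(np.sqrt(max(lambda_u / (n * df), 0.0)))


def correction_constant(sigma2F: float, F_uls: float, approach: str) -> float:
    """k = 1 - sigma2_F / (c F_ULS^2), c = 4 (approaches 1.x) or 8 (approach 2)."""
    if F_uls <= 0:
        return 1.0
    c = 8.0 if approach == "2" else 4.0
    k = 1.0 - sigma2F / (c * F_uls**2)
    if k < 0.5:
        warnings.warn(
            f"correction constant k={k:.3f} clamped to 0.5 "
            "(sigma2_F is huge relative to F_ULS^2)",
            stacklevel=2,
        )
        k = 0.5
    return float(k)


def rmsea_u_se(
    sigma2F: float, F_uls: float, df: int, k: float, approach: str,
    adr_value: float | None = None,
) -> float:
    """Asymptotic standard error of the corrected RMSEA_u."""
    if F_uls <= 0:
        return 0.0
    if approach == "2":
        if adr_value is None:
            raise ValueError("approach 2 standard error needs the ADR")
        return float(np.sqrt(sigma2F * max(adr_value, 0.0) / (k**2 * 4.0 * F_uls * df)))
    return float(np.sqrt(sigma2F / (k**2 * 4.0 * df * F_uls)))


def rmsea_u_ci(estimate: float, se: float, level: float = 0.90) -> tuple[float, float]:
    """Symmetric normal interval, truncated below at 0."""
    z = norm.ppf(0.5 + level / 2.0)
    return (max(estimate - z * se, 0.0), estimate + z * se)


def cfi_u(lambda_u: float, lambda_Bu: float) -> float:
    """1 - max(lambda_u, 0) / max(lambda_u, lambda_Bu), in [0, 1]."""
    num = max(lambda_u, 0.0)
    den = max(lambda_u, lambda_Bu)
    if den <= 0.0:
        warnings.warn(
            "both model and baseline approximation errors are <= 0; CFI_u = 1",
            stacklevel=2,
        )
        return 1.0
    return 1.0 - num / den


def classic_indices(
    T: float, df: int, T_B: float, df_B: int, n: int
) -> tuple[float, float]:
    """Noncentrality-based RMSEA and CFI from (T, df) and baseline (T_B, df_B)."""
    if df <= 0:
        raise ValueError("classic RMSEA is undefined for df = 0")
    lam = T - df
    lam_B = T_B - df_B
    rmsea = float(np.sqrt(max(lam / (n * df), 0.0)))
    den = max(lam, lam_B)
    cfi = 1.0 if den <= 0 else 1.0 - max(lam, 0.0) / den
    return rmsea, float(cfi)


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FitIndexReport:
    approach: str
    estimator: str  # "ML" | "ULSMV"
    rmsea_u: float
    k: float
    sigma2_F: float
    se: float
    ci: tuple[float, float]
    ci_level: float
    cfi_u: float
    rmsea_classic: float
    cfi_classic: float
    lambda_u: float
    lambda_Bu: float
    T: float
    df: int
    T_uls: float
    n: int
    adr: float | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        d["ci"] = list(self.ci)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "FitIndexReport":
        d = dict(d)
        d["ci"] = tuple(d["ci"])
        return cls(**d)


def render_report_text(reports: dict[str, FitIndexReport]) -> str:
    """Aligned-column text rendering of per-approach reports."""
    lines = []
    first = next(iter(reports.values()))
    lines.append(
        f"estimator={first.estimator}  n={first.n}  df={first.df}  "
        f"T={first.T:.3f}  T_ULS={first.T_uls:.3f}"
    )
    hdr = (f"{'approach':>8s} {'RMSEA_u':>8s} {'k':>7s} {'se':>8s} "
           f"{'CI_lo':>7s} {'CI_hi':>7s} {'CFI_u':>7s} {'RMSEA':>7s} {'CFI':>7s}")
    lines.append(hdr)
    for name, r in reports.items():
        lines.append(
            f"{name:>8s} {r.rmsea_u:8.4f} {r.k:7.4f} {r.se:8.4f} "
            f"{r.ci[0]:7.4f} {r.ci[1]:7.4f} {r.cfi_u:7.4f} "
            f"{r.rmsea_classic:7.4f} {r.cfi_classic:7.4f}"
        )
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# end-to-end evaluation
# ---------------------------------------------------------------------------

def _approach_report(
    est: ApproxErrorEstimate,
    fit_result: FittedModel,
    lambda_Bu: float,
    classic: tuple[float, float],
    ci_level: float,
) -> FitIndexReport:
    n, df = fit_result.n, fit_result.df
    F_uls = est.F_uls
    s2F = sigma2_f(est.sigma_e, fit_result.residuals, n)
    k = correction_constant(s2F, F_uls, est.approach)
    raw = rmsea_u_raw(est.lambda_u, n, df)
    point = raw / k
    se = rmsea_u_se(s2F, F_uls, df, k, est.approach, adr_value=est.adr)
    ci = rmsea_u_ci(point, se, ci_level)
    return FitIndexReport(
        approach=est.approach,
        estimator="",
        rmsea_u=point,
        k=k,
        sigma2_F=s2F,
        se=se,
        ci=ci,
        ci_level=ci_level,
        cfi_u=cfi_u(est.lambda_u, lambda_Bu),
        rmsea_classic=classic[0],
        cfi_classic=classic[1],
        lambda_u=est.lambda_u,
        lambda_Bu=lambda_Bu,
        T=fit_result.T,
        df=df,
        T_uls=est.T_uls,
        n=n,
        adr=est.adr,
    )


def evaluate_sample(
    s_est: SampleEstimate,
    gamma: GammaMatrix,
    spec: ModelSpec,
    estimator: str = "ML",
    approaches: tuple[str, ...] = APPROACHES,
    ci_level: float = 0.90,
) -> dict[str, FitIndexReport]:
    """Fit one sample and compute all requested fit-index reports.

    With ``estimator="ML"`` the model is fitted by maximum likelihood and
    approach 2 uses the ML statistic; with ``estimator="ULSMV"`` the model is
    fitted by unweighted least squares, the mean-variance adjusted statistic
    supplies the classic indices, and approach 2 (equal to 1.1 by identity)
    uses (T_adj, d*).
    """
    if estimator not in ("ML", "ULSMV"):
        raise ValueError("estimator must be 'ML' or 'ULSMV'")
    if spec.df <= 0:
        raise ValueError("fit indices are undefined for a saturated model (df = 0)")
    unknown = set(approaches) - set(APPROACHES)
    if unknown:
        raise ValueError(f"unknown approaches: {sorted(unknown)}")
    s, n, p = s_est.r, s_est.n, s_est.p
    G = gamma.values
    W = gls_weight(s_est.matrix)

    base_uls = independence_fit(s, n, p, method="ULS")
    T_uls_B = base_uls.T
    lambda_Bu_trace = T_uls_B - float(np.trace(G))

    if estimator == "ML":
        fit_result = fit_model(spec, s, n, method="ML")
        base_ml = independence_fit(s, n, p, method="ML")
        classic = classic_indices(fit_result.T, spec.df, base_ml.T, base_uls.df, n)
        adr_T, adr_df = fit_result.T, float(spec.df)
        adr_B_T, adr_B_df = base_ml.T, float(base_uls.df)
        fit_U_is_oblique = True
    else:
        fit_result = fit_model(spec, s, n, method="ULS")
        adj = ulsmv_adjust(fit_result, gamma)
        base_adj = ulsmv_adjust(base_uls, gamma)
        classic = classic_indices(
            adj.T_adj, spec.df, base_adj.T_adj, base_uls.df, n
        )
        adr_T, adr_df = adj.T_adj, adj.d_star
        adr_B_T, adr_B_df = base_adj.T_adj, base_adj.d_star
        fit_U_is_oblique = False

    reports: dict[str, FitIndexReport] = {}
    est_11 = est_12 = None
    if "1.1" in approaches or (not fit_U_is_oblique and "2" in approaches):
        est_11 = lambda_u_approach_11(fit_result, gamma)
    if "1.2" in approaches or (fit_U_is_oblique and "2" in approaches):
        est_12 = lambda_u_approach_12(fit_result, gamma, W)

    if "1.1" in approaches:
        reports["1.1"] = _approach_report(
            est_11, fit_result, lambda_Bu_trace, classic, ci_level
        )
    if "1.2" in approaches:
        reports["1.2"] = _approach_report(
            est_12, fit_result, lambda_Bu_trace, classic, ci_level
        )
    if "2" in approaches:
        # sigma2_F for approach 2 uses the residual covariance consistent with
        # how sigma_hat was estimated (oblique for ML/GLS, orthogonal for ULS)
        sig_e = (est_12 if fit_U_is_oblique else est_11).sigma_e
        est_2 = lambda_u_approach_2(
            adr_T, adr_df, fit_result.T_uls, n, sigma_e=sig_e
        )
        lambda_Bu_2 = adr(adr_B_T, adr_B_df) * T_uls_B
        reports["2"] = _approach_report(
            est_2, fit_result, lambda_Bu_2, classic, ci_level
        )
    from dataclasses import replace

    return {k_: replace(r, estimator=estimator) for k_, r in reports.items()}


def analyze(
    data,
    spec: ModelSpec,
    data_type: str = "metric",
    estimator: str = "ML",
    approaches: tuple[str, ...] = APPROACHES,
    ci_level: float = 0.90,
    gamma_source: str = "auto",
) -> dict[str, FitIndexReport]:
    """Full pipeline from a raw data table to fit-index reports.

    ``data_type="metric"`` uses Pearson correlations with the normal-theory
    Gamma (``gamma_source="empirical"`` switches to the distribution-free
    estimate); ``data_type="dichotomous"`` expects a {0,1} table and uses
    tetrachoric correlations with the sandwich Gamma.
    """
    if data_type == "metric":
        s_est = pearson_correlations(data)
        if gamma_source == "empirical":
            gamma = gamma_empirical(data, s_est)
        else:
            gamma = gamma_pearson(s_est)
    elif data_type == "dichotomous":
        s_est = tetrachoric_correlations(data)
        gamma = gamma_tetrachoric(data, s_est)
    else:
        raise ValueError("data_type must be 'metric' or 'dichotomous'")
    if s_est.p != spec.p:
        raise ValueError(
            f"data have {s_est.p} variables but the model specifies {spec.p}"
        )
    return evaluate_sample(s_est, gamma, spec, estimator, approaches, ci_level)


def reports_to_json(reports: dict[str, FitIndexReport]) -> str:
    return json.dumps({k: r.to_dict() for k, r in reports.items()}, indent=2)


def reports_from_json(text: str) -> dict[str, FitIndexReport]:
    raw = json.loads(text)
    return {k: FitIndexReport.from_dict(v) for k, v in raw.items()}
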