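"""Diagnostics and established bias-adjusting comparator estimators.

Heterogeneity is summarised by Cochran's Q, I² and the DerSimonian–Laird
between-study variance τ². Funnel-plot asymmetry is measured by the Egger
coefficient γ: the slope of an inverse-variance weighted regression of the
effect estimates on their standard errors, tested against t with K−2
degrees of freedom. The same regression's intercept, under a
multiplicative-dispersion random-effects model, is the regression-based
extrapolation estimator — the predicted effect in a study of infinite
size. Trim-and-fill (Duval–Tweedie, L0 estimator, random-effects at both
stages) imputes mirrored pseudo-studies to symmetrise the funnel before
re-pooling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .data import EstimateResult, StudySet, ValidationError

__all__ = [
    "DiagnosticsResult",
    "TrimFillResult",
    "heterogeneity",
    "egger_test",
    "regression_extrapolation",
    "trim_and_fill",
]


@dataclass
class DiagnosticsResult:
    """Heterogeneity and asymmetry diagnostics for a study set."""

    Q: float
    i_squared: float
    tau2: float
    gamma: float | None = None
    gamma_se: float | None = None
    gamma_p: float | None = None


def _dl_pool(estimates: np.ndarray, std_errors: np.ndarray):
    """DerSimonian–Laird random-effects pooled mean.

    Returns (mu, se_mu, tau2). With K = 1 this degenerates to the study
    itself with tau2 = 0.
    """
    k = estimates.size
    w = std_errors**-2.0
    mu_fe = np.sum(w * estimates) / np.sum(w)
    if k < 2:
        return float(estimates[0]), float(std_errors[0]), 0.0
    q = float(np.sum(w * (estimates - mu_fe) ** 2))
    c = np.sum(w) - np.sum(w**2) / np.sum(w)
    tau2 = max(0.0, (q - (k - 1)) / c) if c > 0 else 0.0
    wr = 1.0 / (std_errors**2 + tau2)
    mu = float(np.sum(wr * estimates) / np.sum(wr))
    return mu, float(np.sum(wr) ** -0.5), tau2


def heterogeneity(data: StudySet) -> DiagnosticsResult:
    """Cochran Q, I² (floored at 0) and DerSimonian–Laird τ².

    Requires K ≥ 2. The Egger fields are filled in when K ≥ 3 and the
    standard errors are not all equal, otherwise left as None.
    """
    if data.k < 2:
        raise ValidationError("heterogeneity diagnostics need at least 2 studies")
    w = data.std_errors**-2.0
    mu_fe = np.sum(w * data.estimates) / np.sum(w)
    q = float(np.sum(w * (data.estimates - mu_fe) ** 2))
    i2 = max(0.0, (q - (data.k - 1)) / q) * 100.0 if q > 0 else 0.0
    c = np.sum(w) - np.sum(w**2) / np.sum(w)
    tau2 = max(0.0, (q - (data.k - 1)) / c) if c > 0 else 0.0
    res = DiagnosticsResult(Q=q, i_squared=i2, tau2=tau2)
    if data.k >= 3 and np.ptp(data.std_errors) > 0:
        res.gamma, res.gamma_se, res.gamma_p = egger_test(data)
    return res


def _egger_wls(data: StudySet):
    """WLS of β̂_j on (1, σ_j) with weights σ_j⁻².

    Returns (params, cov_unit, phi, df): coefficient vector, the
    unit-dispersion covariance (X'WX)⁻¹, the multiplicative dispersion
    estimate φ = weighted RSS/(K−2), and the residual df K−2.
    """
    if data.k < 3:
        raise ValidationError("Egger regression needs at least 3 studies")
    if np.ptp(data.std_errors) == 0:
        raise ValidationError("Egger regression undefined: all standard errors equal")
    X = sm.add_constant(data.std_errors)
    fit = sm.WLS(data.estimates, X, weights=data.std_errors**-2.0).fit()
    cov_unit = fit.normalized_cov_params
    phi = float(fit.scale)  # weighted RSS / (K - 2)
    return np.asarray(fit.params), np.asarray(cov_unit), phi, data.k - 2


def egger_test(data: StudySet, dispersion: bool = True):
    """Egger funnel-plot asymmetry test.

    γ is the slope of the inverse-variance weighted regression of the
    estimates on their standard errors; the two-sided p-value uses t with
    K−2 df. With ``dispersion=True`` (the classical test) the slope SE is
    scaled by the multiplicative dispersion √φ; ``dispersion=False``
    fixes φ = 1 (the fixed-effect variant).

    Returns (gamma, gamma_se, gamma_p).
    """
    params, cov_unit, phi, df = _egger_wls(data)
    scale = phi if dispersion else 1.0
    gamma = float(params[1])
    se = float(np.sqrt(scale * cov_unit[1, 1]))
    if se == 0.0:
        p = 0.0 if gamma != 0 else 1.0
    else:
        p = 2.0 * stats.t.sf(abs(gamma) / se, df)
    return gamma, se, float(p)


def regression_extrapolation(
    data: StudySet, alpha: float = 0.05, truncate_phi: bool = False
) -> EstimateResult:
    """Extrapolate to the effect in an infinitely large study.

    Fits β̂_j = β₀ + β₁ σ_j + error with weights σ_j⁻² under a
    multiplicative random-effects (dispersion) model; the pooled effect is
    the intercept β₀ with SE scaled by √φ, CI from t with K−2 df. φ is not
    truncated at 1 by default (type (b) selection induces genuine
    under-dispersion); ``truncate_phi`` forces φ ≥ 1.
    """
    params, cov_unit, phi, df = _egger_wls(data)
    if truncate_phi:
        phi = max(phi, 1.0)
    b0 = float(params[0])
    se = float(np.sqrt(phi * cov_unit[0, 0]))
    tq = float(stats.t.ppf(1.0 - alpha / 2.0, df))
    slope_se = float(np.sqrt(phi * cov_unit[1, 1]))
    return EstimateResult(
        method="regression_extrapolation",
        estimate=b0,
        std_error=se,
        ci_low=b0 - tq * se,
        ci_high=b0 + tq * se,
        alpha=alpha,
        extras={"slope": float(params[1]), "slope_se": slope_se, "phi": phi},
    )


@dataclass
class TrimFillResult:
    """Outcome of the Duval–Tweedie trim-and-fill procedure.

    ``side`` is where the missing studies were imputed; ``augmented``
    contains the original K studies followed by k0 mirrored pseudo-studies
    (reflections 2μ̂ − β̂_j of the trimmed extremes, σ copied).
    """

    k0: int
    side: str
    augmented: StudySet
    pooled: EstimateResult
    iterations: int

    def augmented_frame(self):
        """Augmented data as a DataFrame with a pseudo-study flag column."""
        df = self.augmented.to_frame()
        k_orig = self.augmented.k - self.k0
        df["pseudo"] = [False] * k_orig + [True] * self.k0
        return df


def trim_and_fill(
    data: StudySet, side: str = "auto", alpha: float = 0.05, max_iter: int = 50
) -> TrimFillResult:
    """Random-random effects trim-and-fill with the L0 estimator.

    Iterates: pool by DerSimonian–Laird on the currently trimmed set,
    centre all studies at μ̂, rank the absolute deviations (average-rank
    ties) and estimate the number of missing studies by
    L0 = (4·S − K(K+1)) / (2K − 1), S the rank sum of the excess side's
    positive deviations, rounded as max(0, ⌊L0 + 0.5⌋); trim that many
    extreme same-side studies and repeat until k0 stabilises. Missing
    studies are then filled as mirror images about the final μ̂ and the
    augmented set pooled by DL random effects (normal Wald CI).

    ``side`` names the side where missing studies are imputed; "auto"
    picks the side opposite the Egger slope's sign (the slope points to
    the excess side).
    """
    if data.k < 3:
        raise ValidationError("trim-and-fill needs at least 3 studies")
    if side == "auto":
        if np.ptp(data.std_errors) > 0:
            gamma, _, _ = egger_test(data)
        else:
            # equal SEs: infer the excess side from skewness about the mean
            gamma = float(np.mean(data.estimates) - np.median(data.estimates))
        side = "left" if gamma > 0 else "right"
    if side not in ("left", "right"):
        raise ValueError("side must be 'auto', 'left' or 'right'")

    est = data.estimates.copy()
    se = data.std_errors.copy()
    # reflect so the excess (to-be-trimmed) studies always sit on the right
    flip = -1.0 if side == "right" else 1.0
    est = flip * est
    k = data.k

    order = np.argsort(est)  # ascending; extreme right-side studies last
    est_sorted = est[order]
    se_sorted = se[order]

    k0 = 0
    iterations = 0
    while True:
        iterations += 1
        if iterations > max_iter:
            raise RuntimeError(
                f"trim-and-fill did not converge in {max_iter} iterations (last k0={k0})"
            )
        keep = slice(0, k - k0) if k0 > 0 else slice(0, k)
        mu, _, _ = _dl_pool(est_sorted[keep], se_sorted[keep])
        centered = est_sorted - mu
        ranks = stats.rankdata(np.abs(centered), method="average")
        s_rank = float(np.sum(ranks[centered > 0]))
        l0 = (4.0 * s_rank - k * (k + 1)) / (2.0 * k - 1.0)
        k0_new = max(0, int(np.floor(l0 + 0.5)))
        k0_new = min(k0_new, k - 2)  # keep at least two studies for pooling
        if k0_new == k0:
            break
        k0 = k0_new

    keep = slice(0, k - k0) if k0 > 0 else slice(0, k)
    mu, _, _ = _dl_pool(est_sorted[keep], se_sorted[keep])
    if k0 > 0:
        trimmed_est = est_sorted[k - k0 :]
        trimmed_se = se_sorted[k - k0 :]
        fill_est = 2.0 * mu - trimmed_est
        aug_est = np.concatenate([est, fill_est])
        aug_se = np.concatenate([se, trimmed_se])
    else:
        aug_est = est
        aug_se = se
    mu_aug, se_aug, tau2_aug = _dl_pool(aug_est, aug_se)

    mu_aug *= flip
    aug_est = flip * aug_est
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    pooled = EstimateResult(
        method="trim_and_fill",
        estimate=float(mu_aug),
        std_error=float(se_aug),
        ci_low=float(mu_aug - z * se_aug),
        ci_high=float(mu_aug + z * se_aug),
        alpha=alpha,
        extras={"k0": k0, "tau2": tau2_aug, "side": side},
    )
    labels = list(data.labels) + [f"fill_{i + 1}" for i in range(k0)]
    augmented = StudySet(
        estimates=aug_est,
        std_errors=aug_se,
        labels=labels,
        measure=data.measure,
    )
    return TrimFillResult(
        k0=k0, side=side, augmented=augmented, pooled=pooled, iterations=iterations
    )
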