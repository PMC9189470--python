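"""Heterogeneity, pleiotropy, outlier and influence diagnostics.

These are the sensitivity analyses that decide which estimator is reported
as primary: Cochran's Q (about the IVW estimate) and Rücker's Q' (about the
Egger fit) for between-SNP heterogeneity, the Egger intercept test for
directional horizontal pleiotropy, a simulation-based residual test in the
MR-PRESSO style for individual outlying instruments, and leave-one-out
re-estimation for single-SNP influence. The flowchart combining the tests:

* neither pleiotropy nor heterogeneity detected -> fixed-effect IVW;
* heterogeneity only -> IVW with multiplicative random effects (with the
  outlier test run alongside and its corrected estimate available);
* pleiotropy detected -> MR-Egger.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .estimators import (
    EggerRegression,
    MrResult,
    WaldEstimate,
    ivw,
    ivw_from_ratios,
    wald_ratios,
)
from .sumstats import HarmonizedInstrument


@dataclass(frozen=True)
class HeterogeneityResult:
    source: str  # "ivw" or "egger"
    q: float
    df: int
    pvalue: float


@dataclass(frozen=True)
class PleiotropyResult:
    egger_intercept: float
    intercept_se: float
    pvalue: float

    def detected(self, alpha: float = 0.05) -> bool:
        return self.pvalue < alpha


@dataclass(frozen=True)
class PressoResult:
    global_rss_observed: float
    global_pvalue: float
    outlier_pvalues: dict[str, float]
    outliers_flagged: tuple[str, ...]
    distortion_pvalue: float | None
    corrected_estimate: MrResult | None


@dataclass(frozen=True)
class MethodDecision:
    pleiotropy_detected: bool
    heterogeneity_detected: bool
    primary_method: str
    rationale: str


def cochran_q(ratios: Sequence[WaldEstimate]) -> HeterogeneityResult:
    """Cochran's Q about the fixed-effect IVW estimate, chi²(n-1)."""
    n = len(ratios)
    if n < 2:
        raise ValueError("Cochran's Q requires >= 2 instruments")
    b = np.array([r.ratio for r in ratios])
    se = np.array([r.se_ratio for r in ratios])
    _, _, q = ivw_from_ratios(b, se, "fe")
    return HeterogeneityResult("ivw", q, n - 1, float(stats.chi2.sf(q, n - 1)))


def rucker_q(instruments: Sequence[HarmonizedInstrument]) -> HeterogeneityResult:
    """Rücker's Q': weighted residual sum of squares about the Egger fit,
    referred to chi²(n-2)."""
    n = len(instruments)
    if n < 3:
        raise ValueError("Rücker's Q' requires >= 3 instruments")
    fit = EggerRegression().fit(instruments)
    qp = fit.q_prime_
    return HeterogeneityResult("egger", qp, n - 2, float(stats.chi2.sf(qp, n - 2)))


def egger_intercept_test(instruments: Sequence[HarmonizedInstrument]) -> PleiotropyResult:
    """Directional-pleiotropy test: the Egger intercept with its t(n-2) p."""
    res = EggerRegression().fit(instruments).result_
    return PleiotropyResult(
        egger_intercept=res.intercept,
        intercept_se=res.intercept_se,
        pvalue=res.intercept_p,
    )


def _loo_ivw_arrays(g: np.ndarray, G: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW slopes for each SNP, vectorized.

    The IVW estimate equals the through-origin WLS slope
    sum(w γ Γ)/sum(w γ²); removing one SNP subtracts its term from both sums.
    Works on 1-D arrays or on (n_sim, n) simulated batches.
    """
    num = w * g * G
    den = w * g * g
    tot_num = num.sum(axis=-1, keepdims=True)
    tot_den = den.sum(axis=-1, keepdims=True)
    return (tot_num - num) / (tot_den - den)


def mr_presso(
    instruments: Sequence[HarmonizedInstrument],
    n_sim: int = 1000,
    seed: int = 0,
    outlier_alpha: float = 0.05,
    n_distortion: int = 1000,
) -> PressoResult:
    """Simulation-based pleiotropy residual-sum and outlier test.

    Global test: the observed statistic is the sum of inverse-variance-
    weighted squared residuals of each outcome effect about the IVW
    prediction fitted without that SNP; its null distribution is built by
    parametrically resampling both effect sets (γ* ~ N(γ, se²) and
    Γ* ~ N(γ β₋ⱼ, se²)) ``n_sim`` times. Outlier test: per-SNP empirical
    p-values on the same residuals, Bonferroni-corrected. Distortion test:
    the change in the IVW estimate after removing flagged outliers is
    compared with removals of random same-size instrument sets.
    """
    n = len(instruments)
    if n < 4:
        raise ValueError("the outlier test requires >= 4 instruments")
    rng = np.random.default_rng(seed)
    g = np.array([i.beta_exposure for i in instruments])
    sg = np.array([i.se_exposure for i in instruments])
    G = np.array([i.beta_outcome for i in instruments])
    sG = np.array([i.se_outcome for i in instruments])
    rsids = [i.rsid for i in instruments]
    w = 1.0 / sG**2

    beta_loo = _loo_ivw_arrays(g, G, w)
    res_obs = w * (G - g * beta_loo) ** 2
    rss_obs = float(res_obs.sum())

    g_star = rng.normal(g, sg, size=(n_sim, n))
    G_star = rng.normal(g * beta_loo, sG, size=(n_sim, n))
    beta_loo_star = _loo_ivw_arrays(g_star, G_star, w)
    res_star = w * (G_star - g_star * beta_loo_star) ** 2
    rss_star = res_star.sum(axis=1)

    global_p = float((np.count_nonzero(rss_star >= rss_obs) + 1) / (n_sim + 1))
    per_snp_p = (np.count_nonzero(res_star >= res_obs, axis=0) + 1) / (n_sim + 1)
    corrected = np.minimum(per_snp_p * n, 1.0)
    outlier_p = {r: float(p) for r, p in zip(rsids, corrected)}
    flagged = tuple(r for r, p in zip(rsids, corrected) if p < outlier_alpha)

    if not flagged:
        return PressoResult(rss_obs, global_p, outlier_p, (), None, None)
    if len(flagged) == n:
        raise ValueError("all instruments flagged as outliers; no corrected estimate")

    ratios = wald_ratios(instruments)
    beta_full = ivw(ratios, "fe").beta
    keep = [r for r in ratios if r.rsid not in flagged]
    corrected_est = ivw(keep, "fe")
    d_obs = corrected_est.beta - beta_full

    k_out = len(flagged)
    diffs = np.empty(n_distortion)
    for i in range(n_distortion):
        drop = rng.choice(n, size=k_out, replace=False)
        subset = [ratios[j] for j in range(n) if j not in set(drop)]
        diffs[i] = ivw(subset, "fe").beta - beta_full
    distortion_p = float((np.count_nonzero(np.abs(diffs) >= abs(d_obs)) + 1) / (n_distortion + 1))
    return PressoResult(rss_obs, global_p, outlier_p, flagged, distortion_p, corrected_est)


def leave_one_out(
    instruments: Sequence[HarmonizedInstrument], method: str = "ivw_fe"
) -> list[tuple[str, MrResult]]:
    """Re-estimate excluding each instrument in turn (fixed-effect IVW)."""
    if method != "ivw_fe":
        raise ValueError("leave_one_out supports the ivw_fe estimator")
    n = len(instruments)
    if n < 2:
        raise ValueError("leave-one-out requires >= 2 instruments")
    ratios = wald_ratios(instruments)
    return [
        (ratios[j].rsid, ivw([r for i, r in enumerate(ratios) if i != j], "fe"))
        for j in range(n)
    ]


def influential_snps(
    instruments: Sequence[HarmonizedInstrument], method: str = "ivw_fe"
) -> list[str]:
    """Instruments whose exclusion makes the CI cross the null when the
    full-set CI does not."""
    full = ivw(wald_ratios(instruments), "fe")
    if full.ci_low <= 0 <= full.ci_high:
        return []
    return [
        rsid
        for rsid, res in leave_one_out(instruments, method)
        if res.ci_low <= 0 <= res.ci_high
    ]


def select_method(
    pleiotropy: PleiotropyResult,
    heterogeneity: HeterogeneityResult,
    alpha: float = 0.05,
) -> MethodDecision:
    """Flowchart choice of the primary estimator from the two tests."""
    pleio = pleiotropy.pvalue < alpha
    het = heterogeneity.pvalue < alpha
    if pleio:
        method = "egger"
        why = "horizontal pleiotropy detected: MR-Egger regression"
    elif het:
        method = "ivw_mre"
        why = (
            "heterogeneity without pleiotropy: IVW with multiplicative random "
            "effects (outlier-robust estimate reported alongside)"
        )
    else:
        method = "ivw_fe"
        why = "neither pleiotropy nor heterogeneity detected: fixed-effect IVW"
    return MethodDecision(pleio, het, method, why)


def direction_concordance(results: Sequence[MrResult]) -> bool:
    """True iff the signs of all estimates agree (zero matches either sign)."""
    if len(results) < 2:
        raise ValueError("direction check needs >= 2 results")
    signs = {np.sign(r.beta) for r in results} - {0.0}
    return len(signs) <= 1
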