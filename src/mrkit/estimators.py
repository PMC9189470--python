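"""Causal-effect estimators for two-sample Mendelian randomization.

Each estimator combines per-SNP Wald ratios (SNP-outcome effect divided by
SNP-exposure effect) into a single causal estimate of the outcome per unit
of exposure:

* IVW — inverse-variance-weighted mean of the ratios; fixed-effect, or
  multiplicative random effects where the standard error is inflated by
  sqrt(Q/(n-1)) under heterogeneity (never deflated).
* MR-Egger — weighted regression of outcome on exposure effects with a free
  intercept; the slope is consistent under directional pleiotropy provided
  InSIDE holds, and the intercept is the pleiotropy test.
* Weighted median — consistent when at least half the weight comes from
  valid instruments.
* Weighted mode — consistent when the largest group of instruments with
  equal ratio estimates is valid (ZEMPA).

The estimators are scikit-learn style: construct with hyper-parameters,
``fit`` on a harmonized instrument set, read fitted attributes
(``beta_``, ``se_``, ``result_``). Module-level functions (:func:`ivw`,
:func:`egger`, ...) are thin wrappers over the classes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator

from .sumstats import HarmonizedInstrument

Z95 = 1.959963984540054  # Phi^-1(0.975)


@dataclass(frozen=True)
class WaldEstimate:
    """Per-SNP causal estimate Γ/γ with first-order standard error."""

    rsid: str
    ratio: float
    se_ratio: float

    def __post_init__(self) -> None:
        if not self.se_ratio > 0:
            raise ValueError(f"{self.rsid}: se_ratio must be positive")

    @property
    def weight(self) -> float:
        return 1.0 / self.se_ratio**2


@dataclass(frozen=True)
class MrResult:
    """One estimator's causal estimate on the log scale."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_snp: int
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None


def wald_ratios(instruments: Sequence[HarmonizedInstrument]) -> list[WaldEstimate]:
    """Per-SNP Wald ratios Γⱼ/γⱼ with se(Γⱼ)/|γⱼ| standard errors."""
    out = []
    for inst in instruments:
        if inst.beta_exposure == 0:
            raise ValueError(f"{inst.rsid}: zero exposure effect, Wald ratio undefined")
        out.append(
            WaldEstimate(
                rsid=inst.rsid,
                ratio=inst.beta_outcome / inst.beta_exposure,
                se_ratio=inst.se_outcome / abs(inst.beta_exposure),
            )
        )
    return out


def _ratio_arrays(ratios: Sequence[WaldEstimate]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    b = np.array([r.ratio for r in ratios], dtype=float)
    se = np.array([r.se_ratio for r in ratios], dtype=float)
    return b, se, 1.0 / se**2


def _instrument_arrays(
    instruments: Sequence[HarmonizedInstrument],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    g = np.array([i.beta_exposure for i in instruments], dtype=float)
    sg = np.array([i.se_exposure for i in instruments], dtype=float)
    G = np.array([i.beta_outcome for i in instruments], dtype=float)
    sG = np.array([i.se_outcome for i in instruments], dtype=float)
    return g, sg, G, sG


def _as_instruments(X) -> list[HarmonizedInstrument]:
    """Accept a list of instruments or a DataFrame with the field columns."""
    if isinstance(X, pd.DataFrame):
        return [
            HarmonizedInstrument(
                rsid=str(row.get("rsid", i)),
                beta_exposure=float(row["beta_exposure"]),
                se_exposure=float(row["se_exposure"]),
                beta_outcome=float(row["beta_outcome"]),
                se_outcome=float(row["se_outcome"]),
            )
            for i, row in X.iterrows()
        ]
    return list(X)


def ivw_from_ratios(b: np.ndarray, se: np.ndarray, effects_model: str = "fe") -> tuple[float, float, float]:
    """Core IVW computation: returns (beta, se, Q)."""
    w = 1.0 / se**2
    beta = float(np.sum(w * b) / np.sum(w))
    se_fe = float(np.sqrt(1.0 / np.sum(w)))
    q = float(np.sum(w * (b - beta) ** 2))
    if effects_model == "fe" or b.size < 2:
        return beta, se_fe, q
    if effects_model == "mre":
        # multiplicative random effects: inflate, never deflate
        return beta, se_fe * max(1.0, np.sqrt(q / (b.size - 1))), q
    raise ValueError(f"unknown effects model {effects_model!r}")


def _normal_result(method: str, beta: float, se: float, n_snp: int, **extra) -> MrResult:
    p = float(2 * stats.norm.sf(abs(beta) / se)) if se > 0 else (1.0 if beta == 0 else 0.0)
    return MrResult(
        method=method,
        beta=beta,
        se=se,
        ci_low=beta - Z95 * se,
        ci_high=beta + Z95 * se,
        pvalue=p,
        n_snp=n_snp,
        **extra,
    )


class IVWEstimator(BaseEstimator):
    """Inverse-variance-weighted estimator.

    Parameters
    ----------
    effects_model : {"fe", "mre"}
        Fixed effect, or multiplicative random effects (the standard error
        is multiplied by max(1, sqrt(Q/(n-1)))).
    """

    def __init__(self, effects_model: str = "fe"):
        self.effects_model = effects_model

    def fit(self, X, y=None):
        instruments = _as_instruments(X)
        if not instruments:
            raise ValueError("IVW requires at least one instrument")
        ratios = wald_ratios(instruments)
        b, se, _ = _ratio_arrays(ratios)
        beta, se_out, q = ivw_from_ratios(b, se, self.effects_model)
        self.q_ = q
        self.result_ = _normal_result(
            f"ivw_{self.effects_model}", beta, se_out, len(instruments)
        )
        self.beta_, self.se_, self.pvalue_ = beta, se_out, self.result_.pvalue
        return self

    def predict(self, beta_exposure):
        """Predicted outcome effect for given exposure effects (through-origin)."""
        return np.asarray(beta_exposure, dtype=float) * self.beta_


class EggerRegression(BaseEstimator):
    """MR-Egger: weighted regression Γ = α + βγ with weights 1/se(Γ)².

    Instruments are first oriented so every exposure effect is positive
    (jointly negating γ and Γ leaves the Wald ratio unchanged). The
    intercept α estimates the average directional pleiotropic effect and
    its t(n-2) test is the horizontal-pleiotropy test. Inference on both
    coefficients uses t(n-2) with the residual-variance scale estimated
    from the fit (so overdispersion widens the intervals).
    """

    min_instruments = 3

    def fit(self, X, y=None):
        instruments = _as_instruments(X)
        n = len(instruments)
        if n < self.min_instruments:
            raise ValueError(f"MR-Egger requires >= {self.min_instruments} instruments")
        g, sg, G, sG = _instrument_arrays(instruments)
        sign = np.where(g < 0, -1.0, 1.0)
        g, G = g * sign, G * sign
        w = 1.0 / sG**2
        design = sm.add_constant(g)
        fit = sm.WLS(G, design, weights=w).fit()
        alpha, beta = float(fit.params[0]), float(fit.params[1])
        se_alpha, se_beta = float(fit.bse[0]), float(fit.bse[1])
        # raw weighted residual sum of squares about the fitted line
        self.q_prime_ = float(np.sum(w * (G - alpha - beta * g) ** 2))
        df = n - 2
        tq = float(stats.t.ppf(0.975, df))
        # exact fit: residuals at floating-point noise make the t statistic
        # a ratio of rounding errors, so call the test degenerate instead
        scale = max(1.0, float(np.sum(w * G**2)))
        exact_fit = self.q_prime_ <= 1e-12 * scale

        def t_pvalue(est: float, se: float) -> float:
            if exact_fit or se == 0 or not np.isfinite(se):
                return 1.0 if abs(est) <= 1e-10 * np.sqrt(scale) else 0.0
            return float(2 * stats.t.sf(abs(est) / se, df))

        self.result_ = MrResult(
            method="egger",
            beta=beta,
            se=se_beta,
            ci_low=beta - tq * se_beta,
            ci_high=beta + tq * se_beta,
            pvalue=t_pvalue(beta, se_beta),
            n_snp=n,
            intercept=alpha,
            intercept_se=se_alpha,
            intercept_p=t_pvalue(alpha, se_alpha),
        )
        self.beta_, self.se_ = beta, se_beta
        self.intercept_, self.intercept_se_ = alpha, se_alpha
        self.pvalue_ = self.result_.pvalue
        return self

    def predict(self, beta_exposure):
        return self.intercept_ + np.asarray(beta_exposure, dtype=float) * self.beta_


def _bootstrap_se(
    estimate_fn, b: np.ndarray, se: np.ndarray, n_boot: int, seed: int
) -> float:
    """Parametric bootstrap: resample each ratio from N(bⱼ, seⱼ²)."""
    rng = np.random.default_rng(seed)
    draws = rng.normal(b, se, size=(n_boot, b.size))
    reps = np.array([estimate_fn(row) for row in draws])
    return float(reps.std(ddof=1))


def weighted_median_estimate(b: np.ndarray, w: np.ndarray) -> float:
    """Weighted median by linear interpolation of the standardized
    cumulative weights sⱼ = (cumsum(w) - w/2)/sum(w) at s = 0.5."""
    order = np.argsort(b)
    b, w = b[order], w[order]
    s = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    return float(np.interp(0.5, s, b))


class WeightedMedianEstimator(BaseEstimator):
    """Weighted-median estimator with parametric-bootstrap standard error."""

    min_instruments = 3

    def __init__(self, n_boot: int = 1000, seed: int = 0):
        self.n_boot = n_boot
        self.seed = seed

    def fit(self, X, y=None):
        instruments = _as_instruments(X)
        if len(instruments) < self.min_instruments:
            raise ValueError("weighted median requires >= 3 instruments")
        ratios = wald_ratios(instruments)
        b, se, w = _ratio_arrays(ratios)
        beta = weighted_median_estimate(b, w)
        se_boot = _bootstrap_se(
            lambda x: weighted_median_estimate(x, w), b, se, self.n_boot, self.seed
        )
        self.result_ = _normal_result("weighted_median", beta, se_boot, len(instruments))
        self.beta_, self.se_, self.pvalue_ = beta, se_boot, self.result_.pvalue
        return self


def mode_bandwidth(b: np.ndarray, bandwidth_factor: float = 1.0) -> float:
    """Modified Silverman bandwidth 0.9 min(sd, mad/0.6745) n^(-1/5)."""
    sd = float(np.std(b, ddof=1)) if b.size > 1 else 0.0
    mad = float(np.median(np.abs(b - np.median(b))))
    spread = min(sd, mad / 0.6745) if mad > 0 else sd
    return bandwidth_factor * 0.9 * spread * b.size ** (-0.2)


def weighted_mode_estimate(
    b: np.ndarray, w: np.ndarray, bandwidth_factor: float = 1.0, grid_size: int = 512
) -> float:
    """Argmax of the normal-kernel weighted density of the ratios.

    Ties on the density grid break toward the smallest value. A zero
    bandwidth (all ratios identical) returns the common value.
    """
    h = mode_bandwidth(b, bandwidth_factor)
    if h == 0:
        return float(b[0])
    wn = w / np.sum(w)
    grid = np.linspace(b.min() - 3 * h, b.max() + 3 * h, grid_size)
    dens = np.sum(wn[None, :] * stats.norm.pdf((grid[:, None] - b[None, :]) / h), axis=1)
    return float(grid[np.argmax(dens)])


class WeightedModeEstimator(BaseEstimator):
    """Weighted-mode estimator (kernel-density argmax of the Wald ratios)."""

    min_instruments = 3

    def __init__(self, bandwidth_factor: float = 1.0, n_boot: int = 1000, seed: int = 0):
        self.bandwidth_factor = bandwidth_factor
        self.n_boot = n_boot
        self.seed = seed

    def fit(self, X, y=None):
        instruments = _as_instruments(X)
        if len(instruments) < self.min_instruments:
            raise ValueError("weighted mode requires >= 3 instruments")
        ratios = wald_ratios(instruments)
        b, se, w = _ratio_arrays(ratios)
        h = mode_bandwidth(b, self.bandwidth_factor)
        if h == 0:
            # degenerate cluster: every ratio identical; fall back to the
            # fixed-effect IVW standard error
            beta, se_fe, _ = ivw_from_ratios(b, se, "fe")
            self.result_ = _normal_result("weighted_mode", float(b[0]), se_fe, b.size)
        else:
            beta = weighted_mode_estimate(b, w, self.bandwidth_factor)
            se_boot = _bootstrap_se(
                lambda x: weighted_mode_estimate(x, w, self.bandwidth_factor),
                b, se, self.n_boot, self.seed,
            )
            self.result_ = _normal_result("weighted_mode", beta, se_boot, b.size)
        self.beta_, self.se_ = self.result_.beta, self.result_.se
        self.pvalue_ = self.result_.pvalue
        return self


# ---------------------------------------------------------------------------
# functional wrappers

def ivw(ratios: Sequence[WaldEstimate], effects_model: str = "fe") -> MrResult:
    """IVW estimate from Wald ratios (fixed or multiplicative random effects)."""
    if not ratios:
        raise ValueError("IVW requires at least one ratio")
    b, se, _ = _ratio_arrays(ratios)
    beta, se_out, _ = ivw_from_ratios(b, se, effects_model)
    return _normal_result(f"ivw_{effects_model}", beta, se_out, len(ratios))


def egger(instruments: Sequence[HarmonizedInstrument]) -> MrResult:
    """MR-Egger slope and pleiotropy intercept."""
    return EggerRegression().fit(instruments).result_


def weighted_median(
    ratios: Sequence[WaldEstimate], n_boot: int = 1000, seed: int = 0
) -> MrResult:
    if len(ratios) < 3:
        raise ValueError("weighted median requires >= 3 instruments")
    b, se, w = _ratio_arrays(ratios)
    beta = weighted_median_estimate(b, w)
    se_boot = _bootstrap_se(lambda x: weighted_median_estimate(x, w), b, se, n_boot, seed)
    return _normal_result("weighted_median", beta, se_boot, len(ratios))


def weighted_mode(
    ratios: Sequence[WaldEstimate],
    bandwidth_factor: float = 1.0,
    n_boot: int = 1000,
    seed: int = 0,
) -> MrResult:
    if len(ratios) < 3:
        raise ValueError("weighted mode requires >= 3 instruments")
    b, se, w = _ratio_arrays(ratios)
    h = mode_bandwidth(b, bandwidth_factor)
    if h == 0:
        beta, se_fe, _ = ivw_from_ratios(b, se, "fe")
        return _normal_result("weighted_mode", float(b[0]), se_fe, len(ratios))
    beta = weighted_mode_estimate(b, w, bandwidth_factor)
    se_boot = _bootstrap_se(
        lambda x: weighted_mode_estimate(x, w, bandwidth_factor), b, se, n_boot, seed
    )
    return _normal_result("weighted_mode", beta, se_boot, len(ratios))
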