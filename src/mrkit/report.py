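"""Odds-ratio scaling, binary-outcome power, multiple testing, report output.

Estimates come out of the estimators on the log scale (log-odds of the
outcome per unit of log exposure). For reporting they are rescaled to the
odds ratio per a smaller, more interpretable exposure increment and the
family-wise significance threshold is Bonferroni-adjusted across outcomes.
Power for a binary outcome uses the standard non-centrality approximation
for the two-stage (Wald-type) MR test.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import MrResult


@dataclass(frozen=True)
class PowerParams:
    """Inputs of the binary-outcome MR power approximation.

    n_total: outcome GWAS sample size (cases + controls); case_fraction:
    proportion of cases K; r2_xz: exposure variance explained by the
    instruments; or_alt: odds ratio per SD of exposure under the
    alternative; alpha: test size.
    """

    n_total: int
    case_fraction: float
    r2_xz: float
    or_alt: float
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.case_fraction < 1:
            raise ValueError("case_fraction must lie in (0,1)")
        if not 0 < self.r2_xz < 1:
            raise ValueError("r2_xz must lie in (0,1)")
        if self.or_alt <= 0:
            raise ValueError("or_alt must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0,1)")


@dataclass(frozen=True)
class ScaledResult:
    """An MR estimate rescaled to an odds ratio per chosen exposure step."""

    raw_beta: float
    scale_multiplier: float
    or_scaled: float
    ci_low: float
    ci_high: float
    pvalue: float


def scale_to_or(result: MrResult, multiplier: float = 1.1) -> ScaledResult:
    """Rescale a log-scale estimate and convert to an odds ratio.

    The estimate and its CI bounds are multiplied by ``multiplier`` and
    exponentiated; the p-value is unchanged by this monotone transform.
    """
    if multiplier <= 0:
        raise ValueError("scale multiplier must be positive")
    return ScaledResult(
        raw_beta=result.beta,
        scale_multiplier=multiplier,
        or_scaled=float(np.exp(result.beta * multiplier)),
        ci_low=float(np.exp(result.ci_low * multiplier)),
        ci_high=float(np.exp(result.ci_high * multiplier)),
        pvalue=result.pvalue,
    )


def mr_power_binary(params: PowerParams) -> float:
    """Power of the MR Wald test for a binary outcome.

    Uses the non-centrality approximation: with case fraction K and
    alternative odds ratio OR, the attenuated effect on the probability
    scale is b = K(OR/(1+K(OR-1)) - 1), its variance
    v = (K(1-K) - b²)/(N r²), and power is the upper-tail mass of a
    non-central chi-square(1, b²/v) beyond the central critical value.
    """
    K, OR = params.case_fraction, params.or_alt
    b = K * (OR / (1 + K * (OR - 1)) - 1)
    var_num = K * (1 - K) - b * b
    if var_num <= 0:
        raise ValueError("degenerate variance: K(1-K) <= b^2")
    v = var_num / (params.n_total * params.r2_xz)
    ncp = b * b / v
    crit = stats.chi2.ppf(1 - params.alpha, df=1)
    if ncp == 0:
        return params.alpha
    return float(stats.ncx2.sf(crit, df=1, nc=ncp))


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test significance threshold controlling the family-wise error."""
    if m < 1:
        raise ValueError("number of tests must be >= 1")
    return alpha / m


def make_report(per_outcome: Mapping[str, "OutcomeAnalysis"], out_dir: str | Path) -> dict:
    """Write the full analysis report for a set of outcomes.

    Emits a summary table (one row per outcome: heterogeneity, pleiotropy,
    primary OR with CI and p, power at two alternatives), a four-method
    table, per-outcome scatter data and leave-one-out tables, and a JSON
    run manifest. Returns the manifest dict.
    """
    from .pipeline import OutcomeAnalysis  # local import: avoid cycle

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not per_outcome:
        raise ValueError("make_report requires at least one analysed outcome")

    m = len(per_outcome)
    first = next(iter(per_outcome.values()))
    alpha = first.config.alpha
    bonf = bonferroni_threshold(alpha, m)

    fmt = "%.10g"
    summary_rows, methods_rows = [], []
    for name, res in per_outcome.items():
        scaled = res.primary_scaled
        summary_rows.append(
            {
                "outcome": name,
                "n_snp": len(res.instruments),
                "q": res.heterogeneity.q,
                "q_pvalue": res.heterogeneity.pvalue,
                "egger_intercept": res.pleiotropy.egger_intercept,
                "intercept_pvalue": res.pleiotropy.pvalue,
                "primary_method": res.decision.primary_method,
                "or_scaled": scaled.or_scaled,
                "or_ci_low": scaled.ci_low,
                "or_ci_high": scaled.ci_high,
                "pvalue": scaled.pvalue,
                "significant_nominal": scaled.pvalue < alpha,
                "significant_bonferroni": scaled.pvalue < bonf,
                "power_or_small": res.power_small,
                "power_or_large": res.power_large,
            }
        )
        for mr in res.results.values():
            s = scale_to_or(mr, res.config.scale_multiplier_value)
            methods_rows.append(
                {
                    "outcome": name,
                    "method": mr.method,
                    "n_snp": mr.n_snp,
                    "beta": mr.beta,
                    "se": mr.se,
                    "ci_low": mr.ci_low,
                    "ci_high": mr.ci_high,
                    "pvalue": mr.pvalue,
                    "or_scaled": s.or_scaled,
                    "or_ci_low": s.ci_low,
                    "or_ci_high": s.ci_high,
                }
            )
        scatter = pd.DataFrame(
            {
                "rsid": [i.rsid for i in res.instruments],
                "beta_exposure": [i.beta_exposure for i in res.instruments],
                "se_exposure": [i.se_exposure for i in res.instruments],
                "beta_outcome": [i.beta_outcome for i in res.instruments],
                "se_outcome": [i.se_outcome for i in res.instruments],
            }
        )
        scatter.to_csv(out / f"scatter_{name}.tsv", sep="\t", index=False, float_format=fmt)
        loo = pd.DataFrame(
            {
                "excluded_rsid": [rsid for rsid, _ in res.leave_one_out],
                "beta": [r.beta for _, r in res.leave_one_out],
                "ci_low": [r.ci_low for _, r in res.leave_one_out],
                "ci_high": [r.ci_high for _, r in res.leave_one_out],
                "influential_flag": [
                    rsid in res.influential for rsid, _ in res.leave_one_out
                ],
            }
        )
        loo.to_csv(out / f"leave_one_out_{name}.tsv", sep="\t", index=False, float_format=fmt)
        res.audit.to_csv(out / f"harmonization_{name}.tsv", sep="\t", index=False)

    pd.DataFrame(summary_rows).to_csv(out / "summary.tsv", sep="\t", index=False, float_format=fmt)
    pd.DataFrame(methods_rows).to_csv(out / "methods.tsv", sep="\t", index=False, float_format=fmt)

    manifest = {
        "n_outcomes": m,
        "alpha": alpha,
        "bonferroni_threshold": bonf,
        "config": first.config.to_dict(),
        "outcomes": sorted(per_outcome),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
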