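"""End-to-end two-sample MR pipeline over summary-statistics files.

Per outcome: select instruments from the exposure GWAS (p-value filter,
LD clumping, MAF filter), substitute LD proxies for instruments absent
from the outcome study, harmonize effect alleles, run the pleiotropy and
heterogeneity tests, pick the primary estimator by the flowchart, compute
all estimators plus outlier and leave-one-out sensitivity analyses, and
scale the primary estimate to a reportable odds ratio with its power.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from . import diagnostics as dx
from . import estimators as est
from . import instruments as iv
from . import report as rp
from . import sumstats as ss

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable thresholds of the analysis.

    ``scale_mode`` selects how estimates are rescaled for reporting:
    "multiplier" multiplies the log-scale estimate by ``scale_multiplier``
    (default 1.1); "log" uses ln(scale_multiplier) ≈ 0.0953, the
    conventional per-10%-increase conversion for a log-transformed
    exposure.
    """

    p_threshold: float = 5e-8
    clump_r2: float = 0.1
    clump_window_kb: float = 10_000
    maf_min: float = 0.05
    proxy_r2: float = 0.9
    palindrome_eaf_window: float = 0.08
    alpha: float = 0.05
    scale_multiplier: float = 1.1
    scale_mode: str = "multiplier"
    n_boot: int = 1000
    presso_sims: int = 1000
    seed: int = 0
    r2_exposure: float = 0.0265
    n_exposure: int | None = None
    power_or_small: float = 1.1
    power_or_large: float = 1.3

    def __post_init__(self) -> None:
        if self.scale_mode not in ("multiplier", "log"):
            raise ValueError(f"unknown scale_mode {self.scale_mode!r}")

    @property
    def scale_multiplier_value(self) -> float:
        if self.scale_mode == "log":
            return float(np.log(self.scale_multiplier))
        return self.scale_multiplier

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class OutcomeAnalysis:
    """Everything computed for one exposure/outcome pair."""

    config: PipelineConfig
    instruments: list[ss.HarmonizedInstrument]
    audit: "object"
    strength: iv.InstrumentStrength
    heterogeneity: dx.HeterogeneityResult
    heterogeneity_egger: dx.HeterogeneityResult
    pleiotropy: dx.PleiotropyResult
    decision: dx.MethodDecision
    results: dict[str, est.MrResult]
    primary: est.MrResult
    primary_scaled: rp.ScaledResult
    presso: dx.PressoResult | None
    leave_one_out: list[tuple[str, est.MrResult]]
    influential: list[str]
    power_small: float | None
    power_large: float | None
    proxies_used: dict[str, str] = field(default_factory=dict)


def select_instruments(
    exposure: Sequence[ss.SnpAssociation],
    ld: iv.LdReference,
    config: PipelineConfig,
) -> list[ss.SnpAssociation]:
    """Significance filter, LD clumping, MAF filter — in that order."""
    sel = iv.filter_pvalue(exposure, config.p_threshold)
    sel = iv.clump(sel, ld, config.clump_r2, config.clump_window_kb)
    return iv.filter_maf(sel, config.maf_min)


def _apply_proxies(
    selected: list[ss.SnpAssociation],
    exposure_by_rsid: Mapping[str, ss.SnpAssociation],
    outcome_rsids: set[str],
    ld: iv.LdReference,
    r2_min: float,
) -> tuple[list[ss.SnpAssociation], dict[str, str]]:
    """Replace instruments absent from the outcome study with an LD proxy.

    A proxy must be present in both studies (its exposure effect replaces
    the target's, so both sides stay on the same variant) and not already
    selected.
    """
    chosen = {s.rsid for s in selected}
    out, proxies = [], {}
    for snp in selected:
        if snp.rsid in outcome_rsids:
            out.append(snp)
            continue
        candidates = (outcome_rsids & set(exposure_by_rsid)) - chosen
        proxy = iv.find_proxy(snp.rsid, candidates, ld, r2_min)
        if proxy is None:
            logger.warning("no outcome data or proxy for %s; dropped", snp.rsid)
            continue
        logger.info("using proxy %s for %s", proxy, snp.rsid)
        proxies[snp.rsid] = proxy
        chosen.add(proxy)
        out.append(exposure_by_rsid[proxy])
    return out, proxies


def analyze_outcome(
    exposure: Sequence[ss.SnpAssociation],
    outcome: Sequence[ss.SnpAssociation],
    ld: iv.LdReference,
    config: PipelineConfig = PipelineConfig(),
    n_cases: int | None = None,
    n_controls: int | None = None,
) -> OutcomeAnalysis:
    selected = select_instruments(exposure, ld, config)
    if not selected:
        raise ValueError("no instruments survive selection")
    exposure_by_rsid = {s.rsid: s for s in exposure}
    outcome_rsids = {s.rsid for s in outcome}
    selected, proxies = _apply_proxies(
        selected, exposure_by_rsid, outcome_rsids, ld, config.proxy_r2
    )
    instruments, audit = ss.harmonize(selected, outcome, config.palindrome_eaf_window)
    if len(instruments) < 3:
        raise ValueError(
            f"only {len(instruments)} instrument(s) after harmonization; "
            "the estimator suite needs at least 3"
        )

    n_exp = config.n_exposure
    if n_exp is None:
        ns = [s.n for s in selected if s.n is not None]
        n_exp = int(np.median(ns)) if ns else None
    if n_exp is None:
        raise ValueError("exposure sample size unavailable: set n_exposure in config")
    strength = iv.instrument_strength(instruments, config.r2_exposure, n_exp)

    ratios = est.wald_ratios(instruments)
    het_ivw = dx.cochran_q(ratios)
    het_egger = dx.rucker_q(instruments)
    pleio = dx.egger_intercept_test(instruments)
    decision = dx.select_method(pleio, het_ivw, config.alpha)

    results = {
        "ivw_fe": est.ivw(ratios, "fe"),
        "ivw_mre": est.ivw(ratios, "mre"),
        "egger": est.egger(instruments),
        "weighted_median": est.weighted_median(ratios, config.n_boot, config.seed),
        "weighted_mode": est.weighted_mode(ratios, 1.0, config.n_boot, config.seed),
    }

    presso = None
    primary = results[decision.primary_method]
    if decision.heterogeneity_detected and not decision.pleiotropy_detected:
        if len(instruments) >= 4:
            presso = dx.mr_presso(
                instruments, config.presso_sims, config.seed, config.alpha
            )
            if presso.corrected_estimate is not None:
                # outliers found: report the outlier-corrected IVW as primary
                corrected = dataclasses.replace(
                    presso.corrected_estimate, method="ivw_fe_outlier_corrected"
                )
                results["ivw_fe_outlier_corrected"] = corrected
                primary = corrected
        else:
            logger.warning("outlier test skipped: fewer than 4 instruments")

    loo = dx.leave_one_out(instruments)
    influential = dx.influential_snps(instruments)

    power_small = power_large = None
    if n_cases is not None and n_controls is not None:
        n_total = n_cases + n_controls
        K = n_cases / n_total
        protective = primary.beta < 0
        for attr, or_alt in (("small", config.power_or_small), ("large", config.power_or_large)):
            alt = 1.0 / or_alt if protective else or_alt
            p = rp.mr_power_binary(
                rp.PowerParams(n_total, K, config.r2_exposure, alt, config.alpha)
            )
            if attr == "small":
                power_small = p
            else:
                power_large = p

    return OutcomeAnalysis(
        config=config,
        instruments=instruments,
        audit=audit,
        strength=strength,
        heterogeneity=het_ivw,
        heterogeneity_egger=het_egger,
        pleiotropy=pleio,
        decision=decision,
        results=results,
        primary=primary,
        primary_scaled=rp.scale_to_or(primary, config.scale_multiplier_value),
        presso=presso,
        leave_one_out=loo,
        influential=influential,
        power_small=power_small,
        power_large=power_large,
        proxies_used=proxies,
    )


def run_pipeline(
    exposure_path: str | Path,
    outcome_paths: Mapping[str, str | Path],
    ld_path: str | Path | None,
    config: PipelineConfig = PipelineConfig(),
    out_dir: str | Path | None = None,
    case_counts: Mapping[str, tuple[int, int]] | None = None,
) -> dict[str, OutcomeAnalysis]:
    """Run the full analysis for one exposure against several outcomes.

    ``case_counts`` maps outcome name to (n_cases, n_controls) for the
    power calculation; outcomes without counts get no power estimate.
    """
    exposure = ss.read_sumstats(exposure_path)
    ld = iv.LdReference.from_tsv(ld_path) if ld_path else iv.LdReference()
    analyses: dict[str, OutcomeAnalysis] = {}
    for name, path in outcome_paths.items():
        outcome = ss.read_sumstats(path)
        cc = (case_counts or {}).get(name, (None, None))
        analyses[name] = analyze_outcome(exposure, outcome, ld, config, *cc)
    if out_dir is not None:
        rp.make_report(analyses, out_dir)
    return analyses
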