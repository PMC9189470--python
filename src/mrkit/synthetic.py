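"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generator works at the summary level: it draws per-SNP allele
frequencies and true exposure effects, rescales them to a chosen total
variance explained, and produces observed exposure and outcome effect
estimates with the large-sample standard errors of a standardized
quantitative trait (exposure) and a log-odds-scale case/control GWAS
(outcome, via the effective sample size 4/(1/cases + 1/controls)).
True outcome effects are Γⱼ = β γⱼ + αⱼ, where αⱼ is a per-SNP direct
(pleiotropic) effect that can be absent, balanced (mean zero) or
directional, optionally correlated with instrument strength (an InSIDE
violation); individual instruments can additionally be displaced by a
fixed multiple of their standard error to plant outliers.

Defaults emulate the adiponectin exposure study this package is built
around: 8 independent instruments explaining 2.65% of the variance of the
log-scale trait in 7,827 individuals, with biobank-magnitude case/control
counts for the outcome.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import SnpAssociation

_NONPALINDROMIC = (("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"))
_PALINDROMIC = (("A", "T"), ("C", "G"))


@dataclass(frozen=True)
class PleiotropySpec:
    """Direct (non-mediated) per-SNP effect distribution.

    kind: "none", "balanced" (mean 0) or "directional"; mean/sd are the
    moments of the normal the per-SNP effects are drawn from.
    """

    kind: str = "none"
    mean: float = 0.0
    sd: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "balanced", "directional"):
            raise ValueError(f"unknown pleiotropy kind {self.kind!r}")
        if self.kind == "balanced" and self.mean != 0:
            raise ValueError("balanced pleiotropy has mean 0")


@dataclass(frozen=True)
class OutlierSpec:
    """Plant ``count`` outliers by displacing the observed outcome effect of
    the first ``count`` SNPs by ``displacement_se`` standard errors."""

    count: int = 0
    displacement_se: float = 0.0


@dataclass(frozen=True)
class SimulationConfig:
    n_snps: int = 8
    n_exposure: int = 7827
    n_outcome_cases: int = 6000
    n_outcome_controls: int = 195000
    beta_causal: float = 0.0
    target_r2: float = 0.0265
    pleiotropy: PleiotropySpec = field(default_factory=PleiotropySpec)
    inside_violation: bool = False
    outliers: OutlierSpec = field(default_factory=OutlierSpec)
    maf_range: tuple[float, float] = (0.1, 0.5)
    palindromic_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps < 1 or self.n_exposure < 2:
            raise ValueError("counts must be positive")
        if self.n_outcome_cases < 1 or self.n_outcome_controls < 1:
            raise ValueError("case/control counts must be positive")
        if not 0 < self.target_r2 < 1:
            raise ValueError("target_r2 must lie in (0,1)")
        lo, hi = self.maf_range
        if not 0 < lo <= hi <= 0.5:
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not 0 <= self.palindromic_fraction <= 1:
            raise ValueError("palindromic_fraction must lie in [0,1]")
        if self.outliers.count > self.n_snps:
            raise ValueError("more outliers than SNPs")


@dataclass
class SimulatedStudy:
    """Paired exposure/outcome summary statistics with their ground truth."""

    config: SimulationConfig
    exposure: pd.DataFrame
    outcome: pd.DataFrame
    ld: pd.DataFrame
    truth: dict
    exposure_file: Path | None = None
    outcome_file: Path | None = None
    ld_file: Path | None = None
    truth_file: Path | None = None

    def write(self, out_dir: str | Path) -> "SimulatedStudy":
        """Write the study as the TSV dialect the pipeline reads."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        fmt = "%.12g"
        self.exposure_file = out / "exposure.tsv"
        self.outcome_file = out / "outcome.tsv"
        self.ld_file = out / "ld.tsv"
        self.truth_file = out / "truth.json"
        self.exposure.to_csv(self.exposure_file, sep="\t", index=False, float_format=fmt)
        self.outcome.to_csv(self.outcome_file, sep="\t", index=False, float_format=fmt)
        self.ld.to_csv(self.ld_file, sep="\t", index=False, float_format=fmt)
        self.truth_file.write_text(json.dumps(self.truth, indent=2, sort_keys=True) + "\n")
        return self

    def exposure_records(self) -> list[SnpAssociation]:
        return _df_to_records(self.exposure)

    def outcome_records(self) -> list[SnpAssociation]:
        return _df_to_records(self.outcome)


def _df_to_records(df: pd.DataFrame) -> list[SnpAssociation]:
    return [
        SnpAssociation(
            rsid=row.SNP,
            effect_allele=row.effect_allele,
            other_allele=row.other_allele,
            beta=row.beta,
            se=row.se,
            pvalue=row.pval,
            eaf=row.eaf,
            n=int(row.samplesize),
        )
        for row in df.itertuples()
    ]


def effective_sample_size(cases: int, controls: int) -> float:
    """Effective n of a case/control GWAS, 4/(1/cases + 1/controls)."""
    return 4.0 / (1.0 / cases + 1.0 / controls)


def _wald_p(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(beta) / se)
    return np.clip(p, np.finfo(float).tiny, 1.0)


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Draw one synthetic two-sample study under ``config``.

    The realized true exposure effects are rescaled so that
    sum 2 p(1-p) γ² equals ``target_r2`` exactly (the exposure is treated
    as a variance-1 log-scale trait, so γ is in SD units per allele).
    """
    rng = np.random.default_rng(config.seed)
    k = config.n_snps

    maf = rng.uniform(*config.maf_range, size=k)
    het = 2.0 * maf * (1.0 - maf)  # per-SNP genotype variance
    raw = rng.normal(size=k)
    denom = float(np.sum(het * raw**2))
    if denom <= 0:
        raise ValueError("infeasible target_r2: degenerate raw effects")
    gamma = raw * np.sqrt(config.target_r2 / denom)

    se_gamma = np.sqrt(1.0 / (het * config.n_exposure))
    beta_exp_obs = rng.normal(gamma, se_gamma)

    pl = config.pleiotropy
    if pl.kind == "none":
        alpha = np.zeros(k)
    else:
        mean = 0.0 if pl.kind == "balanced" else pl.mean
        noise = rng.normal(size=k)
        if config.inside_violation and pl.sd > 0:
            ag = np.abs(gamma)
            gs = (ag - ag.mean()) / (ag.std() if ag.std() > 0 else 1.0)
            rho = 0.8
            noise = rho * gs + np.sqrt(1 - rho**2) * noise
        # the direct effect is defined relative to the exposure-increasing
        # allele, so a directional mean pushes every oriented instrument
        # the same way (sign(γ)=0 never occurs: γ is continuous)
        alpha = np.sign(gamma) * (mean + pl.sd * noise)
    alpha_oriented = alpha * np.sign(gamma) if pl.kind != "none" else alpha

    Gamma = config.beta_causal * gamma + alpha
    n_eff = effective_sample_size(config.n_outcome_cases, config.n_outcome_controls)
    se_Gamma = np.sqrt(1.0 / (het * n_eff))
    beta_out_obs = rng.normal(Gamma, se_Gamma)
    if config.outliers.count:
        idx = np.arange(config.outliers.count)
        beta_out_obs[idx] += config.outliers.displacement_se * se_Gamma[idx]

    n_pal = int(round(config.palindromic_fraction * k))
    pairs = [
        _PALINDROMIC[i % len(_PALINDROMIC)] if i < n_pal
        else _NONPALINDROMIC[i % len(_NONPALINDROMIC)]
        for i in range(k)
    ]
    rsids = [f"rs{i + 1:07d}" for i in range(k)]
    a1 = [p[0] for p in pairs]
    a2 = [p[1] for p in pairs]

    n_out_total = config.n_outcome_cases + config.n_outcome_controls
    exposure = pd.DataFrame(
        {
            "SNP": rsids,
            "effect_allele": a1,
            "other_allele": a2,
            "eaf": maf,
            "beta": beta_exp_obs,
            "se": se_gamma,
            "pval": _wald_p(beta_exp_obs, se_gamma),
            "samplesize": config.n_exposure,
        }
    )
    outcome = exposure.copy()
    outcome["beta"] = beta_out_obs
    outcome["se"] = se_Gamma
    outcome["pval"] = _wald_p(beta_out_obs, se_Gamma)
    outcome["samplesize"] = n_out_total
    ld = pd.DataFrame(columns=["rsid_a", "rsid_b", "r2"])  # independent SNPs

    truth = {
        "config": _config_dict(config),
        "gamma": gamma.tolist(),
        "alpha": alpha.tolist(),
        "alpha_oriented": alpha_oriented.tolist(),
        "Gamma_true": Gamma.tolist(),
        "maf": maf.tolist(),
        "n_eff_outcome": n_eff,
        "realized_r2": float(np.sum(het * gamma**2)),
    }
    return SimulatedStudy(config=config, exposure=exposure, outcome=outcome, ld=ld, truth=truth)


def _config_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["maf_range"] = list(config.maf_range)
    return d


def simulate_block_ld_study(config: SimulationConfig, block_size: int = 3, r2: float = 0.5) -> SimulatedStudy:
    """Variant of :func:`simulate_study` whose LD table declares consecutive
    blocks of ``block_size`` SNPs as mutually correlated at ``r2``; exists
    to exercise clumping, the effect draws are unchanged."""
    study = simulate_study(config)
    rows = []
    rsids = list(study.exposure["SNP"])
    for start in range(0, len(rsids), block_size):
        block = rsids[start : start + block_size]
        for i in range(len(block)):
            for j in range(i + 1, len(block)):
                rows.append({"rsid_a": block[i], "rsid_b": block[j], "r2": r2})
    study.ld = pd.DataFrame(rows, columns=["rsid_a", "rsid_b", "r2"])
    return study


#: fixed seed of the shipped end-to-end fixture
PAPER_FIXTURE_SEED = 20220405


def make_paper_fixture() -> SimulatedStudy:
    """The deterministic 8-instrument study used as the default end-to-end
    input: log-scale exposure with total r² = 2.65% in n = 7,827, a
    biobank-magnitude case/control outcome, and a protective causal effect
    of gastric-cancer size (OR ≈ 0.88 per 10% exposure increase)."""
    config = SimulationConfig(
        n_snps=8,
        n_exposure=7827,
        n_outcome_cases=6000,
        n_outcome_controls=195000,
        beta_causal=-0.116,
        target_r2=0.0265,
        seed=PAPER_FIXTURE_SEED,
    )
    return simulate_study(config)
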