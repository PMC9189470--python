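"""Instrument selection from an exposure GWAS and instrument-strength metrics.

Selection follows the usual summary-level workflow: keep genome-wide
significant SNPs, prune them to approximate linkage equilibrium by greedy
LD clumping against a reference panel, and drop rare variants. Collective
instrument strength is summarised by the F-statistic (both the
variance-explained form and the mean per-SNP Wald form) and by the I²-GX
regression-dilution statistic used to judge the reliability of the MR-Egger
slope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .sumstats import HarmonizedInstrument, SnpAssociation

logger = logging.getLogger(__name__)


@dataclass
class LdReference:
    """Pairwise LD (r²) lookup table with optional genomic positions.

    ``pairs`` maps an unordered rsid pair to r²; r²(i,i)=1 is implied and
    absent pairs are treated as unlinked (r²=0). ``positions`` maps rsid to
    (chromosome, base-pair) and enables the clumping distance window.
    """

    pairs: dict[frozenset, float] = field(default_factory=dict)
    positions: dict[str, tuple[str, int]] = field(default_factory=dict)

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        val = self.pairs.get(frozenset((a, b)))
        if val is None:
            logger.debug("LD pair (%s, %s) absent from reference; assuming r²=0", a, b)
            return 0.0
        return val

    def add(self, a: str, b: str, r2: float) -> None:
        if not 0 <= r2 <= 1:
            raise ValueError(f"r² must lie in [0,1], got {r2}")
        self.pairs[frozenset((a, b))] = r2

    def within_window(self, a: str, b: str, window_kb: float) -> bool:
        """True when the pair should be LD-tested given the distance window.

        Pairs with unknown positions are always tested (the reference may be
        a plain r² table with no coordinates).
        """
        pa, pb = self.positions.get(a), self.positions.get(b)
        if pa is None or pb is None:
            return True
        if pa[0] != pb[0]:
            return False
        return abs(pa[1] - pb[1]) <= window_kb * 1000

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LdReference":
        """Read a TSV with columns rsid_a, rsid_b, r2 and optional
        chrom_a, pos_a, chrom_b, pos_b."""
        df = pd.read_csv(path, sep=None, engine="python")
        ref = cls()
        for col in ("rsid_a", "rsid_b", "r2"):
            if col not in df.columns:
                raise ValueError(f"{path}: missing LD column {col!r}")
        has_pos = {"chrom_a", "pos_a", "chrom_b", "pos_b"}.issubset(df.columns)
        for _, row in df.iterrows():
            ref.add(str(row["rsid_a"]), str(row["rsid_b"]), float(row["r2"]))
            if has_pos:
                ref.positions[str(row["rsid_a"])] = (str(row["chrom_a"]), int(row["pos_a"]))
                ref.positions[str(row["rsid_b"])] = (str(row["chrom_b"]), int(row["pos_b"]))
        return ref


@dataclass(frozen=True)
class InstrumentStrength:
    """Collective strength of an instrument set.

    ``f_overall`` is the variance-explained form
    F = (R²/k) / ((1-R²)/(n-k-1)); ``per_snp_f`` are the per-SNP Wald
    statistics (beta/se)², whose mean is the other F convention in common
    use. ``i2_gx`` quantifies the expected regression dilution of the
    MR-Egger slope due to measurement error in the SNP-exposure effects.
    """

    f_overall: float
    per_snp_f: tuple[float, ...]
    mean_per_snp_f: float
    i2_gx: float
    r2_exposure: float
    n_snp: int


def filter_pvalue(
    snps: Sequence[SnpAssociation], threshold: float = 5e-8
) -> list[SnpAssociation]:
    """Keep SNPs whose association p-value is strictly below ``threshold``.

    The extremes are allowed: 0 keeps nothing, 1 keeps everything with p<1.
    """
    if not 0 <= threshold <= 1:
        raise ValueError(f"p-value threshold must lie in [0,1], got {threshold}")
    return [s for s in snps if s.pvalue < threshold]


def filter_maf(
    snps: Sequence[SnpAssociation], maf_min: float = 0.05
) -> list[SnpAssociation]:
    """Remove SNPs with minor-allele frequency below ``maf_min``.

    The boundary is inclusive (maf exactly at the threshold is retained).
    SNPs with missing eaf cannot be assessed and are kept with a warning.
    """
    kept: list[SnpAssociation] = []
    n_missing = 0
    for s in snps:
        maf = s.maf
        if maf is None:
            n_missing += 1
            kept.append(s)
        elif maf >= maf_min:
            kept.append(s)
    if n_missing:
        logger.warning("filter_maf: %d SNP(s) with missing eaf retained unchecked", n_missing)
    return kept


def clump(
    snps: Sequence[SnpAssociation],
    ld: LdReference,
    r2_max: float = 0.1,
    window_kb: float = 10_000,
) -> list[SnpAssociation]:
    """Greedy LD clumping: keep the most significant SNP of each LD clump.

    Candidates are visited in ascending p-value order (ties broken by rsid,
    so the result does not depend on input order) and accepted unless they
    have r² >= ``r2_max`` with an already-accepted SNP within ``window_kb``.
    Of two linked SNPs, only the one with the lower p-value is retained.
    """
    ordered = sorted(snps, key=lambda s: (s.pvalue, s.rsid))
    accepted: list[SnpAssociation] = []
    for cand in ordered:
        linked = any(
            ld.within_window(cand.rsid, a.rsid, window_kb)
            and ld.r2(cand.rsid, a.rsid) >= r2_max
            for a in accepted
        )
        if not linked:
            accepted.append(cand)
    return accepted


def find_proxy(
    target: str,
    available: Iterable[str],
    ld: LdReference,
    r2_min: float = 0.9,
) -> str | None:
    """Best available proxy for ``target``: highest r² strictly above
    ``r2_min``; ties broken toward the lexicographically smallest rsid.
    Returns the target itself when it is available (r²=1)."""
    best: tuple[float, str] | None = None
    for rsid in available:
        r2 = ld.r2(target, rsid)
        if r2 <= r2_min:
            continue
        if best is None or r2 > best[0] or (r2 == best[0] and rsid < best[1]):
            best = (r2, rsid)
    return None if best is None else best[1]


def i2_gx(beta_exposure: np.ndarray, se_exposure: np.ndarray) -> float:
    """I²-GX regression-dilution statistic for the MR-Egger slope.

    Computed from the heterogeneity of the SNP-exposure effects oriented to
    positive sign (the orientation Egger regression uses), with inverse-
    variance weights: I² = (Q - (k-1))/Q, floored at 0.
    """
    g = np.abs(np.asarray(beta_exposure, dtype=float))
    w = 1.0 / np.asarray(se_exposure, dtype=float) ** 2
    k = g.size
    if k < 2:
        return 0.0
    gbar = np.sum(w * g) / np.sum(w)
    q = float(np.sum(w * (g - gbar) ** 2))
    if q <= 0:
        return 0.0
    return max(0.0, (q - (k - 1)) / q)


def instrument_strength(
    instruments: Sequence[HarmonizedInstrument],
    r2_exposure: float,
    n_exposure: int,
) -> InstrumentStrength:
    """Instrument-strength diagnostics for a harmonized instrument set.

    ``r2_exposure`` is the proportion of exposure variance the instruments
    explain; ``n_exposure`` the exposure GWAS sample size.
    """
    k = len(instruments)
    if k == 0:
        raise ValueError("instrument_strength requires at least one instrument")
    if not 0 < r2_exposure < 1:
        raise ValueError(f"r2_exposure must lie in (0,1), got {r2_exposure}")
    if n_exposure <= k + 1:
        raise ValueError("n_exposure must exceed k+1")
    g = np.array([i.beta_exposure for i in instruments], dtype=float)
    se = np.array([i.se_exposure for i in instruments], dtype=float)
    f_overall = (r2_exposure / k) / ((1.0 - r2_exposure) / (n_exposure - k - 1))
    per_snp = (g / se) ** 2
    return InstrumentStrength(
        f_overall=float(f_overall),
        per_snp_f=tuple(float(x) for x in per_snp),
        mean_per_snp_f=float(per_snp.mean()),
        i2_gx=i2_gx(g, se),
        r2_exposure=r2_exposure,
        n_snp=k,
    )
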