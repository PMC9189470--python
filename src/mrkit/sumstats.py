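"""Reading, validating and harmonizing GWAS summary statistics.

A summary-statistics file is delimited text (tab or comma) with one row per
SNP carrying the per-allele association estimate for a single trait. The
only join key between the exposure and outcome studies is the rsID; genomic
coordinates are not required. Harmonization expresses the exposure and
outcome effects of each SNP on a shared effect allele, resolving allele
swaps and strand flips and dropping palindromic SNPs whose orientation
cannot be established from allele frequencies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset({"A", "C", "G", "T"})
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: default file column names; remappable via ``column_map``
DEFAULT_COLUMNS: dict[str, str] = {
    "rsid": "SNP",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "eaf": "eaf",
    "beta": "beta",
    "se": "se",
    "pvalue": "pval",
    "n": "samplesize",
}

MANDATORY_FIELDS = ("rsid", "effect_allele", "other_allele", "beta", "se", "pvalue")


@dataclass(frozen=True)
class SnpAssociation:
    """One SNP's summary association with one trait.

    ``beta`` is the additive per-effect-allele estimate: log-units for a
    quantitative exposure, log-odds for a binary outcome. ``eaf`` is the
    effect-allele frequency; it may be missing (``None``).
    """

    rsid: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pvalue: float
    eaf: float | None = None
    n: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "effect_allele", str(self.effect_allele).upper())
        object.__setattr__(self, "other_allele", str(self.other_allele).upper())
        if self.effect_allele not in VALID_ALLELES:
            raise ValueError(f"{self.rsid}: invalid effect allele {self.effect_allele!r}")
        if self.other_allele not in VALID_ALLELES:
            raise ValueError(f"{self.rsid}: invalid other allele {self.other_allele!r}")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.rsid}: effect and other allele are identical")
        if not np.isfinite(self.beta):
            raise ValueError(f"{self.rsid}: non-finite beta")
        if not (np.isfinite(self.se) and self.se > 0):
            raise ValueError(f"{self.rsid}: se must be positive, got {self.se}")
        if not (0 < self.pvalue <= 1):
            raise ValueError(f"{self.rsid}: p-value must lie in (0, 1], got {self.pvalue}")
        if self.eaf is not None and not (0 <= self.eaf <= 1):
            raise ValueError(f"{self.rsid}: eaf must lie in [0, 1], got {self.eaf}")
        if self.n is not None and self.n <= 0:
            raise ValueError(f"{self.rsid}: sample size must be positive")

    @property
    def maf(self) -> float | None:
        """Minor-allele frequency, ``None`` when eaf is missing."""
        if self.eaf is None:
            return None
        return min(self.eaf, 1.0 - self.eaf)

    def is_palindromic(self) -> bool:
        return is_palindromic(self.effect_allele, self.other_allele)

    def flipped(self) -> "SnpAssociation":
        """The same association reported for the other allele."""
        return replace(
            self,
            effect_allele=self.other_allele,
            other_allele=self.effect_allele,
            beta=-self.beta,
            eaf=None if self.eaf is None else 1.0 - self.eaf,
        )


@dataclass(frozen=True)
class HarmonizedInstrument:
    """Exposure and outcome effects of one SNP on a shared effect allele."""

    rsid: str
    beta_exposure: float
    se_exposure: float
    beta_outcome: float
    se_outcome: float
    eaf_exposure: float | None = None
    eaf_outcome: float | None = None
    action_taken: str = "none"

    _ACTIONS = ("none", "outcome_flipped", "dropped_palindromic", "dropped_incompatible")

    def __post_init__(self) -> None:
        if self.action_taken not in self._ACTIONS:
            raise ValueError(f"unknown harmonization action {self.action_taken!r}")
        if self.se_exposure <= 0 or self.se_outcome <= 0:
            raise ValueError(f"{self.rsid}: standard errors must be positive")

    @property
    def kept(self) -> bool:
        return not self.action_taken.startswith("dropped")


def is_palindromic(a1: str, a2: str) -> bool:
    """True iff the allele pair is strand-ambiguous ({A,T} or {C,G})."""
    a1, a2 = str(a1).upper(), str(a2).upper()
    if a1 not in VALID_ALLELES or a2 not in VALID_ALLELES:
        raise ValueError(f"invalid allele pair ({a1!r}, {a2!r})")
    return {a1, a2} in ({"A", "T"}, {"C", "G"})


def _read_table(path: str | Path) -> pd.DataFrame:
    # sniff the delimiter: tab- or comma-separated are both accepted
    return pd.read_csv(path, sep=None, engine="python")


def read_sumstats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> list[SnpAssociation]:
    """Read and validate a summary-statistics file.

    Parameters
    ----------
    path
        Delimited text file with a header row.
    column_map
        Mapping from field names (``rsid``, ``effect_allele``, ...) to the
        column names used in the file; defaults to :data:`DEFAULT_COLUMNS`.

    Rows violating the record invariants (non-positive se, identical or
    non-ACGT alleles, p outside (0,1], ...) are skipped with a logged count.
    A missing mandatory column or zero valid rows is fatal.
    """
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    df = _read_table(path)
    missing = [cols[f] for f in MANDATORY_FIELDS if cols[f] not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s) {missing}")

    has_eaf = cols["eaf"] in df.columns
    has_n = cols["n"] in df.columns
    records: list[SnpAssociation] = []
    n_skipped = 0
    for _, row in df.iterrows():
        eaf = row[cols["eaf"]] if has_eaf else None
        if eaf is not None and pd.isna(eaf):
            eaf = None
        n = row[cols["n"]] if has_n else None
        if n is not None and pd.isna(n):
            n = None
        try:
            records.append(
                SnpAssociation(
                    rsid=str(row[cols["rsid"]]),
                    effect_allele=row[cols["effect_allele"]],
                    other_allele=row[cols["other_allele"]],
                    beta=float(row[cols["beta"]]),
                    se=float(row[cols["se"]]),
                    pvalue=float(row[cols["pvalue"]]),
                    eaf=None if eaf is None else float(eaf),
                    n=None if n is None else int(n),
                )
            )
        except (ValueError, TypeError) as exc:
            n_skipped += 1
            logger.warning("%s: skipping row (%s)", path, exc)
    if n_skipped:
        logger.warning("%s: skipped %d invalid row(s)", path, n_skipped)
    if not records:
        raise ValueError(f"{path}: no valid summary-statistics rows")
    return records


def write_sumstats(
    records: Iterable[SnpAssociation],
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> None:
    """Write records as a TSV in the same dialect :func:`read_sumstats` reads."""
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    rows = [
        {
            cols["rsid"]: r.rsid,
            cols["effect_allele"]: r.effect_allele,
            cols["other_allele"]: r.other_allele,
            cols["eaf"]: r.eaf,
            cols["beta"]: r.beta,
            cols["se"]: r.se,
            cols["pvalue"]: r.pvalue,
            cols["n"]: r.n,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.10g")


def _strand_flip(snp: SnpAssociation) -> SnpAssociation:
    return replace(
        snp,
        effect_allele=COMPLEMENT[snp.effect_allele],
        other_allele=COMPLEMENT[snp.other_allele],
    )


def harmonize_pair(
    exposure: SnpAssociation,
    outcome: SnpAssociation,
    palindrome_eaf_window: float = 0.08,
) -> HarmonizedInstrument:
    """Express exposure and outcome effects on the exposure's effect allele.

    Resolution order for non-palindromic SNPs: direct allele match (no
    change), swapped alleles (negate outcome beta, complement eaf), then the
    same two rules after complementing the outcome's strand; irreconcilable
    allele sets are dropped. Palindromic SNPs cannot be strand-resolved from
    allele labels, so they are kept only when both allele frequencies exist,
    both are farther than ``palindrome_eaf_window`` from 0.5, and they point
    to the same allele; otherwise they are dropped as ambiguous.

    ``palindrome_eaf_window = inf`` reproduces the strict "always exclude
    palindromic SNPs" policy.
    """
    if exposure.rsid != outcome.rsid:
        raise ValueError(f"rsid mismatch: {exposure.rsid} vs {outcome.rsid}")

    def build(out: SnpAssociation, action: str) -> HarmonizedInstrument:
        return HarmonizedInstrument(
            rsid=exposure.rsid,
            beta_exposure=exposure.beta,
            se_exposure=exposure.se,
            beta_outcome=out.beta,
            se_outcome=out.se,
            eaf_exposure=exposure.eaf,
            eaf_outcome=out.eaf,
            action_taken=action,
        )

    exp_pair = (exposure.effect_allele, exposure.other_allele)

    if exposure.is_palindromic():
        if {outcome.effect_allele, outcome.other_allele} != set(exp_pair):
            return build(outcome, "dropped_incompatible")
        # align by label first; the frequency check below decides if the
        # alignment is trustworthy
        if (outcome.effect_allele, outcome.other_allele) == exp_pair:
            aligned, action = outcome, "none"
        else:
            aligned, action = outcome.flipped(), "outcome_flipped"
        w = palindrome_eaf_window
        if exposure.eaf is None or aligned.eaf is None:
            return build(outcome, "dropped_palindromic")
        if abs(exposure.eaf - 0.5) <= w or abs(aligned.eaf - 0.5) <= w:
            return build(outcome, "dropped_palindromic")
        if (exposure.eaf - 0.5) * (aligned.eaf - 0.5) <= 0:
            # frequencies disagree on which allele is the common one:
            # strand orientation cannot be trusted
            return build(outcome, "dropped_palindromic")
        return build(aligned, action)

    for candidate in (outcome, _strand_flip(outcome)):
        pair = (candidate.effect_allele, candidate.other_allele)
        if pair == exp_pair:
            return build(candidate, "none")
        if pair == exp_pair[::-1]:
            return build(candidate.flipped(), "outcome_flipped")
    return build(outcome, "dropped_incompatible")


def harmonize(
    exposures: Sequence[SnpAssociation],
    outcomes: Sequence[SnpAssociation],
    palindrome_eaf_window: float = 0.08,
) -> tuple[list[HarmonizedInstrument], pd.DataFrame]:
    """Harmonize all exposure SNPs present in the outcome study.

    Returns the retained instruments and an audit table (one row per
    exposure SNP: rsid, action_taken) covering dropped SNPs too, including
    those absent from the outcome study (action ``missing_in_outcome``).
    """
    by_rsid = {o.rsid: o for o in outcomes}
    kept: list[HarmonizedInstrument] = []
    audit_rows = []
    for exp in exposures:
        out = by_rsid.get(exp.rsid)
        if out is None:
            audit_rows.append({"rsid": exp.rsid, "action_taken": "missing_in_outcome"})
            continue
        inst = harmonize_pair(exp, out, palindrome_eaf_window)
        audit_rows.append({"rsid": inst.rsid, "action_taken": inst.action_taken})
        if inst.kept:
            kept.append(inst)
    return kept, pd.DataFrame(audit_rows, columns=["rsid", "action_taken"])
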