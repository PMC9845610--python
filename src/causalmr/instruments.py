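"""Instrument selection: significance filter, LD clumping, confounder screen,
and per-SNP instrument strength.

A valid Mendelian-randomization instrument must be robustly associated with
the exposure (relevance), independent of other retained instruments (no LD),
not associated with exposure–outcome confounders, and strong (F > 10 by the
conventional weak-instrument rule).  :func:`select_instruments` composes the
full procedure in the fixed order

    genome-wide significance → LD clumping → harmonization (palindrome
    policy) → confounder-annotation exclusion → F-statistic filter

and reports the count surviving each stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .sumstats import harmonize, kept_instruments

__all__ = [
    "LDSource",
    "SelectionConfig",
    "SelectionReport",
    "filter_significant",
    "clump",
    "f_statistic",
    "exclude_confounded",
    "select_instruments",
]


class InsufficientInstrumentsError(RuntimeError):
    """Raised when selection leaves no usable instrument."""


@dataclass
class LDSource:
    """Pairwise linkage-disequilibrium lookup.

    Stores r² for rsid pairs; absent pairs mean r² = 0 and r²(a, a) = 1.
    ``window_kb`` is the maximum distance at which nonzero LD is considered
    by clumping.
    """

    pairs: dict[frozenset, float] = field(default_factory=dict)
    window_kb: float = 10_000.0

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self.pairs.get(frozenset((a, b)), 0.0)

    def set_r2(self, a: str, b: str, value: float) -> None:
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"r2 must be in [0, 1], got {value}")
        if a != b:
            self.pairs[frozenset((a, b))] = float(value)

    @classmethod
    def from_table(cls, table: pd.DataFrame, window_kb: float = 10_000.0) -> "LDSource":
        """Build from a three-column frame (rsid_a, rsid_b, r2)."""
        src = cls(window_kb=window_kb)
        cols = list(table.columns[:3])
        for a, b, r2 in table[cols].itertuples(index=False):
            src.set_r2(str(a), str(b), float(r2))
        return src

    @classmethod
    def from_file(cls, path: str | Path, window_kb: float = 10_000.0) -> "LDSource":
        return cls.from_table(pd.read_csv(path, sep="\t"), window_kb=window_kb)

    @classmethod
    def from_genotypes(
        cls, dosages: pd.DataFrame, window_kb: float = 10_000.0
    ) -> "LDSource":
        """Compute r² as squared Pearson correlation of allele-dosage columns.

        ``dosages`` has one column per rsid and one row per individual.
        Monomorphic variants (zero variance) get r² = 0 with everything.
        """
        src = cls(window_kb=window_kb)
        rsids = list(dosages.columns)
        mat = dosages.to_numpy(dtype=float)
        sd = mat.std(axis=0)
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(mat, rowvar=False)
        for i in range(len(rsids)):
            for j in range(i + 1, len(rsids)):
                if sd[i] == 0 or sd[j] == 0:
                    continue
                src.set_r2(rsids[i], rsids[j], min(1.0, float(corr[i, j] ** 2)))
        return src


def filter_significant(records: pd.DataFrame, p_threshold: float = 5e-8) -> pd.DataFrame:
    """Keep records with exposure p-value strictly below the genome-wide
    significance threshold (default 5×10⁻⁸), order preserved."""
    return records[records["pval"] < p_threshold].reset_index(drop=True)


def clump(
    records: pd.DataFrame,
    ld: LDSource,
    r2_threshold: float = 0.001,
    window_kb: float = 10_000.0,
) -> pd.DataFrame:
    """Greedy LD clumping.

    Sort by p-value ascending (ties broken by rsid for determinism); keep the
    most significant remaining SNP and discard every remaining SNP on the
    same chromosome within ``window_kb`` whose r² with it is ≥
    ``r2_threshold``.  The returned set is mutually independent under the
    (r², window) criterion, in original input order.
    """
    if records.empty:
        return records.reset_index(drop=True)
    order = records.sort_values(
        ["pval", "rsid"], kind="mergesort"
    )  # stable; rsid breaks p ties
    remaining = list(order.index)
    kept: list[int] = []
    by_idx = records
    while remaining:
        top = remaining.pop(0)
        kept.append(top)
        t = by_idx.loc[top]
        survivors = []
        for idx in remaining:
            s = by_idx.loc[idx]
            same_chrom = str(s["chrom"]) == str(t["chrom"])
            within = (
                same_chrom
                and abs(float(s["pos"]) - float(t["pos"])) <= window_kb * 1000.0
            )
            if within and ld.r2(s["rsid"], t["rsid"]) >= r2_threshold:
                continue
            survivors.append(idx)
        remaining = survivors
    kept_set = set(kept)
    return records[records.index.isin(kept_set)].reset_index(drop=True)


def f_statistic(beta_exp: float, se_exp: float) -> float:
    """Per-SNP instrument strength F ≈ (β/se)².

    The squared Wald statistic of the SNP–exposure association; the full
    R²·(n−2)/(1−R²) form needs per-SNP R², which summary data lack.
    """
    if se_exp <= 0:
        raise ValueError(f"se_exp must be positive, got {se_exp}")
    return (beta_exp / se_exp) ** 2


def exclude_confounded(
    records: pd.DataFrame,
    annotations: pd.DataFrame | None,
    confounder_traits: Iterable[str],
    p_threshold: float = 5e-8,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop SNPs annotated to a configured confounder trait.

    A SNP is excluded iff some annotation row (rsid, trait, pval) names it
    with a trait in ``confounder_traits`` at ``pval < p_threshold`` — a local
    stand-in for a PhenoScanner confounder lookup.  Trait matching is exact
    string.  Returns ``(kept, excluded)`` with the excluded frame carrying a
    ``reason`` column naming the triggering trait.
    """
    traits = set(confounder_traits)
    if annotations is None or annotations.empty or not traits:
        return records.reset_index(drop=True), pd.DataFrame(
            columns=list(records.columns) + ["reason"]
        )
    hits = annotations[
        annotations["trait"].isin(traits) & (annotations["pval"] < p_threshold)
    ]
    reason_by_rsid = {
        r.rsid: f"associated with confounder {r.trait!r} (p={r.pval:.3g})"
        for r in hits.itertuples()
    }
    mask = records["rsid"].isin(reason_by_rsid)
    excluded = records[mask].copy()
    excluded["reason"] = excluded["rsid"].map(reason_by_rsid)
    return records[~mask].reset_index(drop=True), excluded.reset_index(drop=True)


@dataclass
class SelectionConfig:
    """Tunable thresholds of the instrument-selection procedure."""

    p_threshold: float = 5e-8
    clump_r2: float = 0.001
    clump_kb: float = 10_000.0
    f_min: float = 10.0
    palindrome_policy: str = "drop"
    maf_threshold: float = 0.3
    confounder_traits: tuple[str, ...] = ()
    confounder_p_threshold: float = 5e-8


@dataclass
class SelectionReport:
    """Survivor counts at each stage of :func:`select_instruments`."""

    n_input: int = 0
    n_significant: int = 0
    n_clumped: int = 0
    n_harmonized: int = 0
    n_after_confounder: int = 0
    n_final: int = 0
    excluded_confounded: pd.DataFrame | None = None
    harmonized_full: pd.DataFrame | None = None
    warnings: list[str] = field(default_factory=list)

    def stage_counts(self) -> dict[str, int]:
        return {
            "input": self.n_input,
            "significant": self.n_significant,
            "clumped": self.n_clumped,
            "harmonized": self.n_harmonized,
            "confounder_screened": self.n_after_confounder,
            "f_filtered": self.n_final,
        }


def select_instruments(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    ld: LDSource | None = None,
    annotations: pd.DataFrame | None = None,
    config: SelectionConfig | None = None,
) -> tuple[pd.DataFrame, SelectionReport]:
    """Run the full selection procedure and return harmonized instruments.

    Stages, in order: genome-wide significance on the exposure p-value; LD
    clumping; exposure/outcome harmonization under the configured palindrome
    policy; confounder-annotation exclusion; per-SNP F > ``f_min`` filter.

    Raises
    ------
    InsufficientInstrumentsError
        If no instrument survives.  Fewer than 3 survivors (Egger's minimum)
        produces a warning in the report instead.
    """
    config = config or SelectionConfig()
    report = SelectionReport(n_input=len(exposure))

    sig = filter_significant(exposure, config.p_threshold)
    report.n_significant = len(sig)

    if ld is not None:
        sig = clump(sig, ld, config.clump_r2, config.clump_kb)
    report.n_clumped = len(sig)

    harmonized = harmonize(
        sig,
        outcome,
        palindrome_policy=config.palindrome_policy,
        maf_threshold=config.maf_threshold,
    )
    report.harmonized_full = harmonized
    insts = kept_instruments(harmonized)
    report.n_harmonized = len(insts)

    insts, excluded = exclude_confounded(
        insts,
        annotations,
        config.confounder_traits,
        config.confounder_p_threshold,
    )
    report.excluded_confounded = excluded
    report.n_after_confounder = len(insts)

    insts = insts[insts["f_stat"] > config.f_min].reset_index(drop=True)
    report.n_final = len(insts)

    if report.n_final < 1:
        raise InsufficientInstrumentsError(
            "no instrument survived selection; stage counts: "
            f"{report.stage_counts()}"
        )
    if report.n_final < 3:
        report.warnings.append(
            f"only {report.n_final} instruments survived; MR-Egger and "
            "mode/median estimators require >= 3"
        )
    return insts, report
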