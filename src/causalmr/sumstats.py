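"""Reading, validation and allele harmonization of GWAS summary statistics.

Two-sample Mendelian randomization consumes per-SNP association records from
an exposure GWAS and an outcome GWAS.  Before any estimation, the two tables
must be *harmonized* so that, for every shared SNP, the exposure and outcome
effect sizes refer to the same effect allele.  This module provides:

* :func:`read_sumstats` — parse a delimited text table into the canonical
  summary-statistics frame, rejecting malformed rows with reasons;
* :func:`harmonize` — align outcome records to the exposure's effect allele,
  flipping signs and frequencies where alleles are swapped and applying a
  configurable policy to strand-ambiguous (palindromic) SNPs.

The canonical frame carries one row per variant with columns ``rsid``,
``chrom``, ``pos``, ``effect_allele``, ``other_allele``, ``eaf``, ``beta``,
``se``, ``pval`` and ``n``.  Effects for binary traits are per-allele
log-odds; ``se`` must be positive and ``pval`` in (0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SUMSTATS_COLUMNS",
    "INSTRUMENT_COLUMNS",
    "ReadResult",
    "read_sumstats",
    "validate_sumstats",
    "harmonize",
    "kept_instruments",
    "is_palindromic",
]

#: Canonical column order for a summary-statistics frame.
SUMSTATS_COLUMNS = [
    "rsid",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
]

#: Columns of a harmonized-instrument frame (the unit of all estimators).
INSTRUMENT_COLUMNS = [
    "rsid",
    "chrom",
    "pos",
    "beta_exp",
    "se_exp",
    "pval_exp",
    "eaf_exp",
    "n_exp",
    "beta_out",
    "se_out",
    "pval_out",
    "eaf_out",
    "n_out",
    "palindromic",
    "action_taken",
    "f_stat",
]

_VALID_BASES = frozenset("ACGT")
_PALINDROME_PAIRS = frozenset({("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")})

#: Actions that exclude a record from estimation.
DROP_ACTIONS = frozenset({"dropped_palindrome", "dropped_incompatible"})


class SumstatsError(ValueError):
    """Configuration or structural error in a summary-statistics input."""


@dataclass
class ReadResult:
    """Outcome of parsing one summary-statistics file.

    Attributes
    ----------
    data : pandas.DataFrame
        Valid rows in canonical column order, original row order preserved.
    rejections : list of (int, str, str)
        ``(row_index, rsid, reason)`` for every rejected input row.
    """

    data: pd.DataFrame
    rejections: list[tuple[int, str, str]] = field(default_factory=list)

    @property
    def n_rejected(self) -> int:
        return len(self.rejections)

    def rejection_log(self) -> str:
        """Plain-text rejection log, one line per rejected row."""
        lines = [f"row {i}\t{rsid}\t{reason}" for i, rsid, reason in self.rejections]
        return "\n".join(lines)


def _check_row(row: pd.Series) -> str | None:
    """Return a rejection reason for one raw row, or None if valid."""
    rsid = row.get("rsid")
    if not isinstance(rsid, str) or not rsid.strip():
        return "missing rsid"
    ea = str(row.get("effect_allele", "")).strip().upper()
    oa = str(row.get("other_allele", "")).strip().upper()
    if len(ea) != 1 or ea not in _VALID_BASES:
        return f"invalid effect allele {ea!r} (SNPs only; indels rejected)"
    if len(oa) != 1 or oa not in _VALID_BASES:
        return f"invalid other allele {oa!r} (SNPs only; indels rejected)"
    if ea == oa:
        return "effect allele equals other allele"
    for col in ("beta", "se", "pval"):
        v = row.get(col)
        if v is None or (isinstance(v, float) and np.isnan(v)):
            return f"missing {col}"
        if not np.isfinite(v):
            return f"non-finite {col}"
    if row["se"] <= 0:
        return "nonpositive se"
    if not (0 < row["pval"] <= 1):
        return "pval outside (0, 1]"
    eaf = row.get("eaf")
    if eaf is not None and not np.isnan(eaf) and not (0 <= eaf <= 1):
        return "eaf outside [0, 1]"
    n = row.get("n")
    if n is not None and not np.isnan(n) and n <= 0:
        return "nonpositive sample size"
    return None


def validate_sumstats(df: pd.DataFrame) -> ReadResult:
    """Validate an in-memory raw frame, splitting valid rows from rejects.

    Alleles are upper-cased; numeric columns are coerced, with unparsable
    values causing row rejection rather than failure.
    """
    work = df.copy()
    for col in ("rsid", "chrom", "effect_allele", "other_allele"):
        if col in work.columns:
            work[col] = work[col].astype(str).str.strip()
    for col in ("pos", "eaf", "beta", "se", "pval", "n"):
        if col in work.columns:
            work[col] = pd.to_numeric(work[col], errors="coerce")
        else:
            work[col] = np.nan

    rejections: list[tuple[int, str, str]] = []
    keep_rows = []
    for i, (_, row) in enumerate(work.iterrows()):
        reason = _check_row(row)
        if reason is None:
            keep_rows.append(i)
        else:
            rejections.append((i, str(row.get("rsid", "?")), reason))

    out = work.iloc[keep_rows].copy()
    out["effect_allele"] = out["effect_allele"].str.upper()
    out["other_allele"] = out["other_allele"].str.upper()
    out["chrom"] = out.get("chrom", pd.Series(dtype=str)).astype(str)
    out = out.reindex(columns=SUMSTATS_COLUMNS)
    out = out.reset_index(drop=True)
    return ReadResult(data=out, rejections=rejections)


def read_sumstats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> ReadResult:
    """Read a delimited summary-statistics file.

    Parameters
    ----------
    path
        Delimited text file with one header row (TSV by default).
    column_map
        Mapping from canonical names (``rsid``, ``beta`` ...) to the file's
        column names; identity for canonical columns already present.
    sep
        Field delimiter; ``None`` infers tab vs comma from the header line.

    Raises
    ------
    SumstatsError
        If the file is missing or a mandatory mapped column is absent.
    """
    path = Path(path)
    if not path.exists():
        raise SumstatsError(f"summary-statistics file not found: {path}")
    if sep is None:
        header = path.open().readline()
        sep = "\t" if "\t" in header else ","
    raw = pd.read_csv(path, sep=sep, dtype=str)

    column_map = dict(column_map or {})
    rename = {}
    for canonical in SUMSTATS_COLUMNS:
        src = column_map.get(canonical, canonical)
        if src in raw.columns:
            rename[src] = canonical
        elif canonical in ("rsid", "effect_allele", "other_allele", "beta", "se", "pval"):
            raise SumstatsError(
                f"mandatory column {canonical!r} (file column {src!r}) not found in {path.name}"
            )
    raw = raw.rename(columns=rename)
    return validate_sumstats(raw)


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True for strand-ambiguous A/T and C/G allele pairs."""
    return (effect_allele, other_allele) in _PALINDROME_PAIRS


def _maf(eaf: float) -> float:
    return min(eaf, 1.0 - eaf)


def _check_unique(df: pd.DataFrame, label: str) -> None:
    dup = df["rsid"][df["rsid"].duplicated()]
    if len(dup):
        raise SumstatsError(f"duplicate rsid in {label} collection: {dup.iloc[0]}")


def harmonize(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    palindrome_policy: str = "drop",
    maf_threshold: float = 0.3,
) -> pd.DataFrame:
    """Align outcome effects to the exposure's effect allele per SNP.

    For each SNP present in both tables (matched on rsid):

    * identical allele orientation → kept ``as_is``;
    * swapped alleles (outcome effect allele equals exposure other allele
      and vice versa) → outcome beta sign flipped, ``eaf_out`` replaced by
      ``1 − eaf_out``, action ``flipped``;
    * palindromic pairs (A/T or C/G) → under policy ``"drop"`` excluded as
      ``dropped_palindrome``; under ``"infer_if_maf_below_threshold"`` kept
      and aligned by allele frequency only when the minor-allele frequency
      is below ``maf_threshold`` on *both* sides (and both frequencies are
      present), else dropped;
    * any other allele combination → ``dropped_incompatible``.

    Exposure-side values are never altered, and the function is idempotent:
    re-harmonizing an already aligned pair changes nothing.

    Returns the full harmonized frame including dropped records (flagged via
    ``action_taken``); use :func:`kept_instruments` for the estimation set.
    """
    if palindrome_policy not in ("drop", "infer_if_maf_below_threshold"):
        raise SumstatsError(f"unknown palindrome policy {palindrome_policy!r}")
    _check_unique(exposure, "exposure")
    _check_unique(outcome, "outcome")

    out_by_rsid = outcome.set_index("rsid")
    rows = []
    for _, exp in exposure.iterrows():
        rsid = exp["rsid"]
        if rsid not in out_by_rsid.index:
            continue
        out = out_by_rsid.loc[rsid]
        ea_x, oa_x = exp["effect_allele"], exp["other_allele"]
        ea_y, oa_y = out["effect_allele"], out["other_allele"]
        palindromic = is_palindromic(ea_x, oa_x)

        beta_out, eaf_out = out["beta"], out["eaf"]
        if palindromic:
            if (ea_y, oa_y) not in ((ea_x, oa_x), (oa_x, ea_x)):
                action = "dropped_incompatible"
            elif palindrome_policy == "drop":
                action = "dropped_palindrome"
            else:
                eaf_x = exp["eaf"]
                if (
                    pd.isna(eaf_x)
                    or pd.isna(eaf_out)
                    or _maf(eaf_x) >= maf_threshold
                    or _maf(eaf_out) >= maf_threshold
                ):
                    action = "dropped_palindrome"
                else:
                    # Frequencies on the same side of 0.5 imply the same
                    # allele; opposite sides imply a strand/report flip.
                    same_side = (eaf_x < 0.5) == (eaf_out < 0.5)
                    if same_side:
                        action = "as_is"
                    else:
                        action = "flipped"
                        beta_out = -beta_out
                        eaf_out = 1.0 - eaf_out
        elif (ea_y, oa_y) == (ea_x, oa_x):
            action = "as_is"
        elif (ea_y, oa_y) == (oa_x, ea_x):
            action = "flipped"
            beta_out = -beta_out
            eaf_out = 1.0 - eaf_out if not pd.isna(eaf_out) else eaf_out
        else:
            action = "dropped_incompatible"

        rows.append(
            {
                "rsid": rsid,
                "chrom": exp["chrom"],
                "pos": exp["pos"],
                "beta_exp": exp["beta"],
                "se_exp": exp["se"],
                "pval_exp": exp["pval"],
                "eaf_exp": exp["eaf"],
                "n_exp": exp["n"],
                "beta_out": beta_out,
                "se_out": out["se"],
                "pval_out": out["pval"],
                "eaf_out": eaf_out,
                "n_out": out["n"],
                "palindromic": palindromic,
                "action_taken": action,
                "f_stat": (exp["beta"] / exp["se"]) ** 2,
            }
        )

    return pd.DataFrame(rows, columns=INSTRUMENT_COLUMNS)


def kept_instruments(harmonized: pd.DataFrame) -> pd.DataFrame:
    """Rows of a harmonized frame that may enter estimation."""
    mask = ~harmonized["action_taken"].isin(DROP_ACTIONS)
    return harmonized[mask].reset_index(drop=True)
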