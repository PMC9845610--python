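"""Synthetic two-sample GWAS summary statistics with known ground truth.

Emulates the structure of the real exposure/outcome GWAS pairs the pipeline
consumes: tens of independent genome-wide-significant instruments with
per-allele log-odds effects and standard errors, strand-ambiguous
(palindromic) allele pairs, non-significant background SNPs, optional LD
blocks, confounder annotations, pleiotropy regimes and gross outliers.

Data model per instrument j:

* true SNP→exposure effect γⱼ ~ N(gamma_mean, gamma_sd);
* direct (pleiotropic) SNP→outcome effect αⱼ per ``pleiotropy_mode``:
  0 (*none*), N(0, alpha_sd) (*balanced*), N(alpha_mean, alpha_sd)
  (*directional*), or proportional to γⱼ plus noise (*inside_violating*);
* allele frequency mafⱼ ~ U(maf_range); standard errors from the binary-
  trait approximation se = (2·n·maf(1−maf))^(−1/2);
* observed effects β̂_Xj ~ N(γⱼ, se_Xj) and β̂_Yj ~ N(θγⱼ + αⱼ, se_Yj),
  with an extra ``outlier_shift`` added to β_Y for contaminated SNPs.

Effects are simulated directly on the log-odds scale rather than through
individual-level logistic models: summary-level MR consumes only (β, se).
Identical seeds give identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from .sumstats import SUMSTATS_COLUMNS

__all__ = ["SyntheticConfig", "SyntheticPair", "generate_pair",
           "generate_bidirectional", "write_pair"]

_NONPALINDROMIC = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                   ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]
_PALINDROMIC = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; defaults describe a clean, well-powered study.

    ``n_exp``/``n_out`` of 50,000 and ~30 instruments with γ ≈ 0.1 mirror
    the scale of the consortium GWAS pairs this generator stands in for.
    """

    j_snps: int = 30
    theta: float = 0.15
    gamma_mean: float = 0.1
    gamma_sd: float = 0.02
    pleiotropy_mode: str = "none"  # none | balanced | directional | inside_violating
    alpha_mean: float = 0.0
    alpha_sd: float = 0.0
    outlier_fraction: float = 0.0
    outlier_shift: float = 0.0
    n_exp: int = 50_000
    n_out: int = 50_000
    maf_range: tuple[float, float] = (0.1, 0.5)
    palindrome_fraction: float = 0.1
    n_null_snps: int = 50
    ld_block_size: int = 1
    ld_r2: float = 0.0
    confounder_fraction: float = 0.0
    seed: int = 0
    rsid_prefix: str = "rs"

    def validate(self) -> None:
        fracs = {
            "outlier_fraction": self.outlier_fraction,
            "palindrome_fraction": self.palindrome_fraction,
            "confounder_fraction": self.confounder_fraction,
        }
        for name, v in fracs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_exp <= 0 or self.n_out <= 0:
            raise ValueError("sample sizes must be positive")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie inside (0, 0.5], got {self.maf_range}")
        if self.pleiotropy_mode not in ("none", "balanced", "directional", "inside_violating"):
            raise ValueError(f"unknown pleiotropy_mode {self.pleiotropy_mode!r}")
        if self.j_snps < 1:
            raise ValueError("j_snps must be >= 1")
        if self.ld_block_size < 1:
            raise ValueError("ld_block_size must be >= 1")


class SyntheticPair(NamedTuple):
    exposure: pd.DataFrame
    outcome: pd.DataFrame
    ld: pd.DataFrame
    annotations: pd.DataFrame
    truth: dict


def _se(n: int, maf: np.ndarray) -> np.ndarray:
    return (2.0 * n * maf * (1.0 - maf)) ** -0.5


def _pval(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    from scipy import stats

    p = 2.0 * stats.norm.sf(np.abs(beta) / se)
    return np.clip(p, 1e-300, 1.0)


def generate_pair(config: SyntheticConfig) -> SyntheticPair:
    """Generate one exposure/outcome summary-statistics pair.

    Returns exposure and outcome frames in the canonical column order, an
    LD pair table, a confounder-annotation table, and a truth record with
    every latent value (γ, α, maf, outlier and palindrome flags, θ).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    j = config.j_snps

    gamma = rng.normal(config.gamma_mean, config.gamma_sd, size=j)
    if config.pleiotropy_mode == "none":
        alpha = np.zeros(j)
    elif config.pleiotropy_mode == "balanced":
        alpha = rng.normal(0.0, config.alpha_sd, size=j)
    elif config.pleiotropy_mode == "directional":
        alpha = rng.normal(config.alpha_mean, config.alpha_sd, size=j)
    else:  # inside_violating: pleiotropy correlated with instrument strength
        alpha = config.alpha_mean + 0.5 * (gamma - config.gamma_mean) + rng.normal(
            0.0, config.alpha_sd, size=j
        )

    maf = rng.uniform(config.maf_range[0], config.maf_range[1], size=j)
    se_x = _se(config.n_exp, maf)
    se_y = _se(config.n_out, maf)
    beta_x = rng.normal(gamma, se_x)
    mu_y = config.theta * gamma + alpha
    n_out_snps = int(round(config.outlier_fraction * j))
    outlier_idx = rng.choice(j, size=n_out_snps, replace=False) if n_out_snps else np.array([], int)
    outlier_flag = np.zeros(j, dtype=bool)
    outlier_flag[outlier_idx] = True
    mu_y = mu_y + np.where(outlier_flag, config.outlier_shift, 0.0)
    beta_y = rng.normal(mu_y, se_y)

    # Alleles: the stated fraction palindromic, the rest resolvable pairs.
    n_pal = int(round(config.palindrome_fraction * j))
    pal_flag = np.zeros(j, dtype=bool)
    pal_flag[rng.choice(j, size=n_pal, replace=False) if n_pal else []] = True
    alleles = [
        _PALINDROMIC[rng.integers(len(_PALINDROMIC))]
        if pal_flag[i]
        else _NONPALINDROMIC[rng.integers(len(_NONPALINDROMIC))]
        for i in range(j)
    ]

    # Genomic placement: LD blocks share a chromosome and sit within the
    # clumping window; distinct blocks are unlinked and far apart.
    block = config.ld_block_size
    n_blocks = int(np.ceil(j / block))
    chrom = [str(b % 22 + 1) for b in range(n_blocks) for _ in range(block)][:j]
    pos = [
        50_000_000 * (b // 22 + 1) + 10_000 * k
        for b in range(n_blocks)
        for k in range(block)
    ][:j]

    rsids = [f"{config.rsid_prefix}{i + 1}" for i in range(j)]
    exposure = pd.DataFrame(
        {
            "rsid": rsids,
            "chrom": chrom,
            "pos": pos,
            "effect_allele": [a for a, _ in alleles],
            "other_allele": [b for _, b in alleles],
            "eaf": maf,
            "beta": beta_x,
            "se": se_x,
            "pval": _pval(beta_x, se_x),
            "n": config.n_exp,
        }
    )

    # A third of outcome records are reported for the opposite allele, so
    # harmonization's sign/frequency flip is exercised on realistic input.
    swap = rng.random(j) < (1 / 3)
    outcome = exposure.copy()
    outcome["beta"] = np.where(swap, -beta_y, beta_y)
    outcome["eaf"] = np.where(swap, 1.0 - maf, maf)
    outcome["effect_allele"] = np.where(swap, [b for _, b in alleles], [a for a, _ in alleles])
    outcome["other_allele"] = np.where(swap, [a for a, _ in alleles], [b for _, b in alleles])
    outcome["se"] = se_y
    outcome["pval"] = _pval(beta_y, se_y)
    outcome["n"] = config.n_out

    # Null background SNPs (γ = 0) present in both GWAS.
    if config.n_null_snps:
        nn = config.n_null_snps
        maf_n = rng.uniform(config.maf_range[0], config.maf_range[1], size=nn)
        se_xn, se_yn = _se(config.n_exp, maf_n), _se(config.n_out, maf_n)
        bxn, byn = rng.normal(0, se_xn), rng.normal(0, se_yn)
        al = [_NONPALINDROMIC[rng.integers(len(_NONPALINDROMIC))] for _ in range(nn)]
        null_exp = pd.DataFrame(
            {
                "rsid": [f"{config.rsid_prefix}_null{i + 1}" for i in range(nn)],
                "chrom": [str(i % 22 + 1) for i in range(nn)],
                "pos": [900_000_000 + 10_000 * i for i in range(nn)],
                "effect_allele": [a for a, _ in al],
                "other_allele": [b for _, b in al],
                "eaf": maf_n,
                "beta": bxn,
                "se": se_xn,
                "pval": _pval(bxn, se_xn),
                "n": config.n_exp,
            }
        )
        null_out = null_exp.copy()
        null_out["beta"], null_out["se"] = byn, se_yn
        null_out["pval"], null_out["n"] = _pval(byn, se_yn), config.n_out
        exposure = pd.concat([exposure, null_exp], ignore_index=True)
        outcome = pd.concat([outcome, null_out], ignore_index=True)

    # LD table: constant r² within each instrument block.
    ld_rows = []
    if block > 1 and config.ld_r2 > 0:
        for b in range(n_blocks):
            members = rsids[b * block : (b + 1) * block]
            for i in range(len(members)):
                for k in range(i + 1, len(members)):
                    ld_rows.append((members[i], members[k], config.ld_r2))
    ld = pd.DataFrame(ld_rows, columns=["rsid_a", "rsid_b", "r2"])

    n_conf = int(round(config.confounder_fraction * j))
    conf_idx = rng.choice(j, size=n_conf, replace=False) if n_conf else np.array([], int)
    annotations = pd.DataFrame(
        {
            "rsid": [rsids[i] for i in conf_idx],
            "trait": ["confounder_trait"] * n_conf,
            "pval": [1e-12] * n_conf,
        }
    )

    truth = {
        "theta": config.theta,
        "config": asdict(config),
        "snps": {
            rsids[i]: {
                "gamma": float(gamma[i]),
                "alpha": float(alpha[i]),
                "maf": float(maf[i]),
                "outlier": bool(outlier_flag[i]),
                "palindromic": bool(pal_flag[i]),
                "swapped_in_outcome": bool(swap[i]),
            }
            for i in range(j)
        },
        "confounded": [rsids[i] for i in conf_idx],
    }
    exposure = exposure[SUMSTATS_COLUMNS]
    outcome = outcome[SUMSTATS_COLUMNS]
    return SyntheticPair(exposure, outcome, ld, annotations, truth)


def generate_bidirectional(
    config_fwd: SyntheticConfig, config_rev: SyntheticConfig
) -> tuple[SyntheticPair, SyntheticPair]:
    """Generate forward (X→Y) and reverse (Y→X) pairs with disjoint
    instrument namespaces, supporting asymmetric truths such as
    θ_fwd > 0 with θ_rev = 0."""
    fwd = generate_pair(
        SyntheticConfig(**{**asdict(config_fwd), "rsid_prefix": "rsF"})
    )
    rev = generate_pair(
        SyntheticConfig(**{**asdict(config_rev), "rsid_prefix": "rsR"})
    )
    return fwd, rev


def write_pair(pair: SyntheticPair, outdir: str | Path, prefix: str = "sim") -> dict[str, Path]:
    """Write the pair as the TSV dialects the pipeline reads plus a truth
    JSON; byte-identical across runs with the same config."""
    import json

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "exposure": outdir / f"{prefix}_exposure.tsv",
        "outcome": outdir / f"{prefix}_outcome.tsv",
        "ld": outdir / f"{prefix}_ld.tsv",
        "annotations": outdir / f"{prefix}_annotations.tsv",
        "truth": outdir / f"{prefix}_truth.json",
    }
    pair.exposure.to_csv(paths["exposure"], sep="\t", index=False)
    pair.outcome.to_csv(paths["outcome"], sep="\t", index=False)
    pair.ld.to_csv(paths["ld"], sep="\t", index=False)
    pair.annotations.to_csv(paths["annotations"], sep="\t", index=False)
    paths["truth"].write_text(json.dumps(pair.truth, indent=1, sort_keys=True))
    return paths
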