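"""MR-PRESSO: residual-sum-of-squares global heterogeneity test, per-SNP
outlier detection, and outlier-corrected estimation.

The global test asks whether the observed residual sum of squares (RSS) of
the instruments around leave-one-out IVW fits is larger than expected under
the null model in which every instrument is valid.  The null distribution is
built by parametric simulation: effect sizes are redrawn from their reported
sampling distributions with outcome effects centred on the leave-one-out
predictions, and the RSS recomputed identically.  Per-SNP empirical
p-values (Bonferroni-adjusted) flag individual outliers; removing them and
re-estimating yields the outlier-corrected causal effect.  Validity requires
at least 50% genuine instruments, balanced pleiotropy among the rest, and
the InSIDE condition — when more than half the instruments are flagged the
correction is refused.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .estimators import MREstimate, ivw

__all__ = ["PressoGlobal", "PressoResult", "presso_global", "presso_outlier_test",
           "presso_corrected", "run_presso"]


def _loo_theta(bx: np.ndarray, by: np.ndarray, sy: np.ndarray) -> np.ndarray:
    """Leave-one-out fixed-effects IVW estimates, vectorized over rows.

    Accepts 1-D (J,) or 2-D (k, J) effect arrays; ``sy`` is (J,).
    """
    w = bx**2 / sy**2
    xy = bx * by / sy**2
    sxx = w.sum(axis=-1, keepdims=True)
    sxy = xy.sum(axis=-1, keepdims=True)
    return (sxy - xy) / (sxx - w)


def _rss_terms(bx: np.ndarray, by: np.ndarray, sy: np.ndarray) -> np.ndarray:
    """Standardized squared residuals (β_Yj − θ̂₍₋ⱼ₎ β_Xj)² / se_Yj²."""
    theta_loo = _loo_theta(bx, by, sy)
    return ((by - theta_loo * bx) / sy) ** 2


@dataclass
class PressoGlobal:
    """Stored output of the global simulation, reused by the outlier test."""

    rss_obs: float
    global_pval: float
    sim_rss: np.ndarray            # (k_sim,) simulated global RSS
    obs_terms: np.ndarray          # (J,) observed squared residuals
    sim_terms: np.ndarray          # (k_sim, J) simulated squared residuals
    k_sim: int


@dataclass
class PressoResult:
    """Full MR-PRESSO report."""

    rss_obs: float
    global_pval: float
    outlier_pvals: pd.Series       # per-rsid Bonferroni-adjusted empirical p
    outliers: list[str]
    theta_raw: MREstimate
    theta_corrected: MREstimate
    distortion_pval: float | None = None
    correction_refused: bool = False
    k_sim: int = 0
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "rss_obs": self.rss_obs,
            "global_pval": self.global_pval,
            "n_outliers": len(self.outliers),
            "outliers": ",".join(self.outliers),
            "theta_raw": self.theta_raw.theta,
            "theta_corrected": self.theta_corrected.theta,
            "distortion_pval": self.distortion_pval,
            "correction_refused": self.correction_refused,
        }


def presso_global(
    insts: pd.DataFrame, k_sim: int = 1000, seed: int | None = None
) -> PressoGlobal:
    """Global heterogeneity test.

    RSS_obs is deterministic (no randomness before simulation).  Each of the
    ``k_sim`` replicates draws β*_X ~ N(β_X, se_X) and β*_Y ~ N(θ̂₍₋ⱼ₎β_X,
    se_Y) and recomputes the RSS with its own leave-one-out fits; the
    empirical p-value uses the +1 correction so it is never zero and never
    below 1/(k_sim+1).
    """
    j = len(insts)
    if j < 4:
        raise ValueError("MR-PRESSO requires >= 4 instruments")
    bx = insts["beta_exp"].to_numpy(dtype=float)
    sx = insts["se_exp"].to_numpy(dtype=float)
    by = insts["beta_out"].to_numpy(dtype=float)
    sy = insts["se_out"].to_numpy(dtype=float)

    obs_terms = _rss_terms(bx, by, sy)
    rss_obs = float(obs_terms.sum())

    theta_loo = _loo_theta(bx, by, sy)
    rng = np.random.default_rng(seed)
    bx_sim = rng.normal(bx, sx, size=(k_sim, j))
    by_sim = rng.normal(theta_loo * bx, sy, size=(k_sim, j))
    sim_terms = _rss_terms(bx_sim, by_sim, sy)
    sim_rss = sim_terms.sum(axis=1)

    pval = (1 + int((sim_rss >= rss_obs).sum())) / (k_sim + 1)
    return PressoGlobal(
        rss_obs=rss_obs,
        global_pval=pval,
        sim_rss=sim_rss,
        obs_terms=obs_terms,
        sim_terms=sim_terms,
        k_sim=k_sim,
    )


def presso_outlier_test(
    insts: pd.DataFrame, global_run: PressoGlobal, alpha: float = 0.05
) -> tuple[list[str], pd.Series, bool]:
    """Per-SNP outlier test from the stored simulated residuals.

    Each SNP's empirical p-value compares its observed squared residual with
    its own simulated distribution, Bonferroni-multiplied by J and capped at
    1; SNPs with adjusted p < ``alpha`` are flagged.  If more than half the
    instruments are flagged the 50%-genuine-instruments condition fails and
    correction is refused (with a warning).

    Returns ``(outlier rsids, adjusted p-values by rsid, refused)``.
    """
    j = len(insts)
    raw = (1 + (global_run.sim_terms >= global_run.obs_terms).sum(axis=0)) / (
        global_run.k_sim + 1
    )
    adjusted = np.minimum(1.0, raw * j)
    pvals = pd.Series(adjusted, index=insts["rsid"].to_numpy(), name="outlier_pval")
    flagged = list(pvals.index[adjusted < alpha])
    refused = len(flagged) > j / 2
    if refused:
        warnings.warn(
            f"{len(flagged)}/{j} instruments flagged as outliers; fewer than "
            "50% genuine instruments — outlier correction refused"
        )
    return flagged, pvals, refused


def presso_corrected(
    insts: pd.DataFrame,
    outliers: list[str],
    effects_model: str = "auto",
    distortion: bool = True,
    n_distortion: int = 1000,
    seed: int | None = None,
) -> tuple[MREstimate, MREstimate, float | None]:
    """Raw and outlier-corrected IVW estimates, plus the distortion test.

    The distortion p-value compares the observed shift
    (θ_raw − θ_corrected) with shifts obtained by removing random subsets of
    the same size; it is computed only when at least one outlier is flagged.
    """
    theta_raw = ivw(insts, effects_model=effects_model)
    clean = insts[~insts["rsid"].isin(outliers)]
    if len(clean) < 1:
        raise ValueError("removing outliers leaves no instrument")
    if not outliers:
        return theta_raw, theta_raw, None
    theta_corr = ivw(clean, effects_model=effects_model)

    distortion_pval: float | None = None
    if distortion:
        rng = np.random.default_rng(seed)
        j = len(insts)
        k = len(outliers)
        obs_shift = abs(theta_raw.theta - theta_corr.theta)
        shifts = np.empty(n_distortion)
        idx = np.arange(j)
        for b in range(n_distortion):
            drop = rng.choice(idx, size=k, replace=False)
            sub = insts.iloc[np.setdiff1d(idx, drop)]
            shifts[b] = abs(theta_raw.theta - ivw(sub, effects_model=effects_model).theta)
        distortion_pval = (1 + int((shifts >= obs_shift).sum())) / (n_distortion + 1)
    return theta_raw, theta_corr, distortion_pval


def run_presso(
    insts: pd.DataFrame,
    k_sim: int = 1000,
    alpha: float = 0.05,
    effects_model: str = "auto",
    distortion: bool = True,
    seed: int | None = None,
) -> PressoResult:
    """Global test → outlier test → corrected estimates, in one call."""
    g = presso_global(insts, k_sim=k_sim, seed=seed)
    outliers, pvals, refused = presso_outlier_test(insts, g, alpha=alpha)
    notes: list[str] = []
    if refused:
        notes.append("more than 50% of instruments flagged; correction refused")
        theta_raw = ivw(insts, effects_model=effects_model)
        return PressoResult(
            rss_obs=g.rss_obs,
            global_pval=g.global_pval,
            outlier_pvals=pvals,
            outliers=outliers,
            theta_raw=theta_raw,
            theta_corrected=theta_raw,
            distortion_pval=None,
            correction_refused=True,
            k_sim=k_sim,
            warnings=notes,
        )
    theta_raw, theta_corr, distortion_pval = presso_corrected(
        insts,
        outliers,
        effects_model=effects_model,
        distortion=distortion and len(outliers) >= 1,
        seed=seed,
    )
    return PressoResult(
        rss_obs=g.rss_obs,
        global_pval=g.global_pval,
        outlier_pvals=pvals,
        outliers=outliers,
        theta_raw=theta_raw,
        theta_corrected=theta_corr,
        distortion_pval=distortion_pval,
        correction_refused=False,
        k_sim=k_sim,
        warnings=notes,
    )
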