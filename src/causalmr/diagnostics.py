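"""Heterogeneity and pleiotropy diagnostics.

Cochran's Q measures whether the per-SNP Wald ratios scatter around the
pooled IVW estimate more than their standard errors explain; excess
heterogeneity signals invalid instruments or pleiotropy.  The analysis-level
decision rule is: fixed-effects IVW when the Q test p-value is ≥ 0.05,
multiplicative random-effects IVW otherwise.  The MR-Egger intercept test
screens for *directional* pleiotropy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import MREstimate, egger, ivw

__all__ = [
    "HeterogeneityReport",
    "cochran_q",
    "choose_effects_model",
    "egger_intercept_test",
    "leave_one_out",
]


@dataclass(frozen=True)
class HeterogeneityReport:
    """Cochran Q with its chi-square test and the fixed/random decision.

    ``i2`` = max(0, (Q − df)/Q) is the fraction of ratio variance beyond
    sampling noise.
    """

    q_stat: float
    df: int
    pval: float
    i2: float
    chosen_model: str

    def to_dict(self) -> dict:
        return {
            "q": self.q_stat,
            "df": self.df,
            "p": self.pval,
            "i2": self.i2,
            "chosen_model": self.chosen_model,
        }


def cochran_q(insts: pd.DataFrame, alpha: float = 0.05) -> HeterogeneityReport:
    """Q = Σ w_j (r_j − θ̂_IVW)² with w_j = β_Xj²/se_Yj², df = J−1.

    ``r_j`` are the Wald ratios and θ̂ the fixed-effects IVW estimate; the
    p-value is the upper tail of χ²(J−1).
    """
    j = len(insts)
    if j < 2:
        raise ValueError("Cochran Q requires >= 2 instruments")
    bx = insts["beta_exp"].to_numpy(dtype=float)
    by = insts["beta_out"].to_numpy(dtype=float)
    sy = insts["se_out"].to_numpy(dtype=float)
    w = bx**2 / sy**2
    theta = ivw(insts, effects_model="fixed").theta
    q = float((w * (by / bx - theta) ** 2).sum())
    df = j - 1
    p = float(stats.chi2.sf(q, df))
    i2 = max(0.0, (q - df) / q) if q > 0 else 0.0
    return HeterogeneityReport(
        q_stat=q,
        df=df,
        pval=p,
        i2=i2,
        chosen_model=choose_effects_model_from_p(p, alpha),
    )


def choose_effects_model_from_p(pval: float, alpha: float = 0.05) -> str:
    """Random effects iff heterogeneity p < alpha (strict)."""
    return "random" if pval < alpha else "fixed"


def choose_effects_model(report: HeterogeneityReport, alpha: float = 0.05) -> str:
    """Fixed-vs-random IVW decision from a heterogeneity report.

    Returns ``"random"`` iff the Q-test p-value is strictly below ``alpha``
    (default 0.05); the boundary p = alpha gives ``"fixed"``.
    """
    return choose_effects_model_from_p(report.pval, alpha)


def egger_intercept_test(
    insts: pd.DataFrame, alpha: float = 0.05
) -> tuple[MREstimate, bool]:
    """MR-Egger intercept with its t test; a nonzero intercept indicates
    average directional pleiotropy.

    Returns ``(intercept estimate, pleiotropy_suspected)`` where the flag is
    raised iff the intercept p-value is below ``alpha``.
    """
    _, intercept = egger(insts)
    return intercept, intercept.pval < alpha


def leave_one_out(insts: pd.DataFrame, effects_model: str = "auto") -> pd.DataFrame:
    """IVW estimate with each instrument excluded in turn.

    One row per excluded rsid with the re-estimated theta, se and 95% CI;
    used to spot single influential SNPs.
    """
    if len(insts) < 2:
        raise ValueError("leave-one-out requires >= 2 instruments")
    rows = []
    for i in range(len(insts)):
        rest = insts.drop(insts.index[i])
        est = ivw(rest, effects_model=effects_model)
        rows.append(
            {
                "excluded_rsid": insts.iloc[i]["rsid"],
                "theta": est.theta,
                "se": est.se,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "pval": est.pval,
                "effects_model": est.effects_model,
            }
        )
    return pd.DataFrame(rows)
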