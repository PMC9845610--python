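"""Causal-effect estimators for two-sample Mendelian randomization.

All estimators consume a harmonized-instrument frame with columns
``beta_exp``, ``se_exp``, ``beta_out``, ``se_out`` (per-SNP exposure and
outcome effects on the log-odds scale with their standard errors) and return
an :class:`MREstimate`.

The per-SNP building block is the Wald ratio r_j = β_Yj / β_Xj.  The four
pooled estimators trade robustness against pleiotropy for efficiency:

* **IVW** — inverse-variance-weighted pooling of Wald ratios, equivalent to
  weighted least squares of β_Y on β_X through the origin with weights
  β_X²/se_Y² (first-order); unbiased only when *every* instrument is valid.
  The multiplicative random-effects variant inflates the standard error by
  √(Q/(J−1)) when Cochran's Q exceeds its degrees of freedom.
* **MR-Egger** — the same regression with a free intercept; the intercept
  estimates average directional pleiotropy and the slope remains consistent
  under the InSIDE assumption (pleiotropy uncorrelated with instrument
  strength).
* **Weighted median** — consistent when instruments carrying ≥ 50% of the
  weight are valid.
* **Weighted mode** — consistent when the largest homogeneous cluster of
  ratio estimates is valid (zero-modal-pleiotropy assumption).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Z95",
    "MREstimate",
    "wald_ratio",
    "ivw",
    "egger",
    "weighted_median",
    "weighted_mode",
    "or_scale",
    "all_estimates",
    "estimates_frame",
]

#: Two-sided 95% normal quantile used for all non-Egger confidence intervals.
Z95 = 1.959964

MODE_GRID_POINTS = 512


@dataclass(frozen=True)
class MREstimate:
    """One method's causal estimate on the log-odds scale.

    ``effects_model`` records whether a fixed or multiplicative
    random-effects variance was used (``"not_applicable"`` for methods
    without that choice).
    """

    method: str
    theta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snps: int
    effects_model: str = "not_applicable"

    def or_scale(self) -> "ORScale":
        return or_scale(self)

    def to_dict(self) -> dict:
        d = {
            "method": self.method,
            "n_snps": self.n_snps,
            "theta": self.theta,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "pval": self.pval,
            "effects_model": self.effects_model,
        }
        orr = self.or_scale()
        d.update({"or": orr.or_, "or_ci_low": orr.ci_low, "or_ci_high": orr.ci_high})
        return d


class ORScale(NamedTuple):
    or_: float
    ci_low: float
    ci_high: float


def or_scale(est: MREstimate) -> ORScale:
    """Exponentiate a log-odds estimate and its CI to the odds-ratio scale."""
    return ORScale(np.exp(est.theta), np.exp(est.ci_low), np.exp(est.ci_high))


def _normal_p(theta: float, se: float) -> float:
    if se == 0:
        return 1.0 if theta == 0 else np.nextafter(0, 1)
    return float(2.0 * stats.norm.sf(abs(theta) / se))


def _columns(insts: pd.DataFrame) -> tuple[np.ndarray, ...]:
    bx = insts["beta_exp"].to_numpy(dtype=float)
    sx = insts["se_exp"].to_numpy(dtype=float)
    by = insts["beta_out"].to_numpy(dtype=float)
    sy = insts["se_out"].to_numpy(dtype=float)
    return bx, sx, by, sy


def wald_ratio(inst: pd.Series | pd.DataFrame) -> MREstimate:
    """Single-SNP causal estimate: θ = β_Y/β_X, se = se_Y/|β_X|.

    First-order delta method; exposure-side uncertainty is handled upstream
    by the F filter rather than propagated here.
    """
    if isinstance(inst, pd.DataFrame):
        if len(inst) != 1:
            raise ValueError("wald_ratio takes exactly one instrument")
        inst = inst.iloc[0]
    bx, by, sy = float(inst["beta_exp"]), float(inst["beta_out"]), float(inst["se_out"])
    if bx == 0:
        raise ValueError("Wald ratio undefined for beta_exp = 0")
    theta = by / bx
    se = sy / abs(bx)
    return MREstimate(
        method="wald",
        theta=theta,
        se=se,
        ci_low=theta - Z95 * se,
        ci_high=theta + Z95 * se,
        pval=_normal_p(theta, se),
        n_snps=1,
    )


def _ivw_point(bx: np.ndarray, by: np.ndarray, sy: np.ndarray) -> tuple[float, float, float]:
    """Return (theta, fixed se, Q) for the origin-constrained weighted fit."""
    w = bx**2 / sy**2
    sw = w.sum()
    theta = float((bx * by / sy**2).sum() / sw)
    se_fixed = float(sw**-0.5)
    ratios = by / bx
    q = float((w * (ratios - theta) ** 2).sum())
    return theta, se_fixed, q


def ivw(insts: pd.DataFrame, effects_model: str = "fixed") -> MREstimate:
    """Inverse-variance-weighted estimate.

    θ̂ = Σ β_X β_Y/se_Y² / Σ β_X²/se_Y², the weighted regression through the
    origin.  ``effects_model``:

    * ``"fixed"`` — se = (Σ β_X²/se_Y²)^(−1/2);
    * ``"random"`` — multiplicative overdispersion: fixed se ×
      max(1, √(Q/(J−1))), so the random-effects se never undercuts fixed;
    * ``"auto"`` — random iff the Cochran-Q p-value is below 0.05, following
      the heterogeneity decision rule.
    """
    if len(insts) == 0:
        raise ValueError("IVW requires at least one instrument")
    if effects_model not in ("fixed", "random", "auto"):
        raise ValueError(f"unknown effects model {effects_model!r}")
    if len(insts) == 1:
        # Exact identity: one instrument's IVW estimate is its Wald ratio.
        w = wald_ratio(insts.iloc[0])
        return replace(w, method="ivw", effects_model="fixed")
    bx, _, by, sy = _columns(insts)
    theta, se_fixed, q = _ivw_point(bx, by, sy)
    j = len(insts)

    chosen = effects_model
    if effects_model == "auto":
        if j >= 2:
            q_p = float(stats.chi2.sf(q, j - 1))
            chosen = "random" if q_p < 0.05 else "fixed"
        else:
            chosen = "fixed"

    if chosen == "random" and j >= 2:
        se = se_fixed * max(1.0, np.sqrt(q / (j - 1)))
    else:
        se = se_fixed
    return MREstimate(
        method="ivw",
        theta=theta,
        se=se,
        ci_low=theta - Z95 * se,
        ci_high=theta + Z95 * se,
        pval=_normal_p(theta, se),
        n_snps=j,
        effects_model=chosen,
    )


def egger(insts: pd.DataFrame) -> tuple[MREstimate, MREstimate]:
    """MR-Egger regression: weighted least squares of β_Y on β_X with a free
    intercept, weights se_Y⁻².

    Instruments are first oriented so β_X ≥ 0 (both betas flipped where
    needed), making the fit invariant to arbitrary allele orientation.
    Standard errors carry a multiplicative residual-heterogeneity scale
    max(1, √(RSS_w/(J−2))); inference uses the t distribution with J−2
    degrees of freedom.  Returns ``(slope, intercept)`` estimates.
    """
    j = len(insts)
    if j < 3:
        raise ValueError("Egger requires >= 3 SNPs")
    bx, _, by, sy = _columns(insts)
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    x = bx * flip
    y = by * flip
    w = sy**-2.0

    # Weighted normal equations for [intercept, slope].
    X = np.column_stack([np.ones(j), x])
    xtwx = X.T @ (w[:, None] * X)
    xtwy = X.T @ (w * y)
    cov_unscaled = np.linalg.inv(xtwx)
    coef = cov_unscaled @ xtwy
    resid = y - X @ coef
    rss_w = float((w * resid**2).sum())
    scale = max(1.0, np.sqrt(rss_w / (j - 2)))
    se = scale * np.sqrt(np.diag(cov_unscaled))

    df = j - 2
    tcrit = float(stats.t.ppf(0.975, df))

    def _mk(method: str, b: float, s: float) -> MREstimate:
        p = float(2.0 * stats.t.sf(abs(b) / s, df)) if s > 0 else (1.0 if b == 0 else 0.0)
        return MREstimate(
            method=method,
            theta=float(b),
            se=float(s),
            ci_low=float(b - tcrit * s),
            ci_high=float(b + tcrit * s),
            pval=p,
            n_snps=j,
        )

    slope = _mk("egger_slope", coef[1], se[1])
    intercept = _mk("egger_intercept", coef[0], se[0])
    return slope, intercept


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios, kind="stable")
    r = ratios[order]
    w = weights[order] / weights.sum()
    s = np.cumsum(w) - 0.5 * w  # midpoint positions
    return float(np.interp(0.5, s, r))


def _bootstrap_se(
    insts: pd.DataFrame,
    point_fn,
    n_boot: int,
    rng: np.random.Generator,
) -> float:
    """Parametric bootstrap: redraw β_X*, β_Y* ~ N(β, se) and re-estimate."""
    bx, sx, by, sy = _columns(insts)
    bxs = rng.normal(bx, sx, size=(n_boot, len(bx)))
    bys = rng.normal(by, sy, size=(n_boot, len(by)))
    ests = np.empty(n_boot)
    for b in range(n_boot):
        ests[b] = point_fn(bys[b] / bxs[b], bxs[b] ** 2 / sy**2)
    return float(ests.std(ddof=1))


def weighted_median(
    insts: pd.DataFrame, n_boot: int = 1000, seed: int | None = None
) -> MREstimate:
    """Weighted-median estimator (50% breakdown point).

    Wald ratios are sorted with normalized weights w_j = (β_Xj²/se_Yj²)/Σw;
    the estimate linearly interpolates between the ratios whose cumulative
    midpoint positions bracket 0.5.  The standard error comes from a
    parametric bootstrap over instrument effect sizes.
    """
    import warnings as _warnings

    j = len(insts)
    if j < 3:
        raise ValueError("weighted median requires >= 3 instruments")
    if n_boot < 100:
        _warnings.warn("n_boot < 100 gives unstable bootstrap standard errors")
    bx, _, by, sy = _columns(insts)
    theta = _weighted_median_point(by / bx, bx**2 / sy**2)
    rng = np.random.default_rng(seed)
    se = _bootstrap_se(insts, _weighted_median_point, n_boot, rng)
    return MREstimate(
        method="weighted_median",
        theta=theta,
        se=se,
        ci_low=theta - Z95 * se,
        ci_high=theta + Z95 * se,
        pval=_normal_p(theta, se),
        n_snps=j,
    )


def _mode_bandwidth(ratios: np.ndarray, phi: float) -> float:
    j = len(ratios)
    sd = ratios.std(ddof=1)
    mad = np.median(np.abs(ratios - np.median(ratios))) / 0.6745
    spread = min(sd, mad) if mad > 0 else sd
    return phi * 0.9 * spread * j ** (-1 / 5)


def _weighted_mode_point(
    ratios: np.ndarray, weights: np.ndarray, phi: float = 1.0
) -> float:
    h = _mode_bandwidth(ratios, phi)
    if h == 0 or not np.isfinite(h):
        return float(ratios[0])  # all ratios identical
    lo, hi = ratios.min() - 3 * h, ratios.max() + 3 * h
    grid = np.linspace(lo, hi, MODE_GRID_POINTS)
    dens = (weights[None, :] * np.exp(-0.5 * ((grid[:, None] - ratios[None, :]) / h) ** 2)).sum(
        axis=1
    )
    # argmax returns the first (smallest-value) maximizer: documented tie-break.
    return float(grid[int(np.argmax(dens))])


def weighted_mode(
    insts: pd.DataFrame,
    phi: float = 1.0,
    n_boot: int = 1000,
    seed: int | None = None,
) -> MREstimate:
    """Weighted-mode estimator.

    The estimate is the argmax over a 512-point grid of a weighted
    normal-kernel density of the Wald ratios, bandwidth
    h = φ · 0.9 · min(sd, MAD/0.6745) · J^(−1/5).  Ties in the density take
    the smaller grid value.  Bootstrap standard error as in the weighted
    median.
    """
    j = len(insts)
    if j < 3:
        raise ValueError("weighted mode requires >= 3 instruments")
    bx, _, by, sy = _columns(insts)
    theta = _weighted_mode_point(by / bx, bx**2 / sy**2, phi)
    rng = np.random.default_rng(seed)
    se = _bootstrap_se(
        insts, lambda r, w: _weighted_mode_point(r, w, phi), n_boot, rng
    )
    return MREstimate(
        method="weighted_mode",
        theta=theta,
        se=se,
        ci_low=theta - Z95 * se,
        ci_high=theta + Z95 * se,
        pval=_normal_p(theta, se),
        n_snps=j,
    )


def all_estimates(
    insts: pd.DataFrame,
    effects_model: str = "auto",
    n_boot: int = 1000,
    seed: int | None = None,
    methods: tuple[str, ...] = ("ivw", "egger", "weighted_median", "weighted_mode"),
) -> list[MREstimate]:
    """Run the requested estimators, silently skipping those whose minimum
    instrument count is not met (IVW is always attempted)."""
    out: list[MREstimate] = []
    j = len(insts)
    if "ivw" in methods:
        out.append(ivw(insts, effects_model=effects_model))
    if "egger" in methods and j >= 3:
        slope, intercept = egger(insts)
        out.extend([slope, intercept])
    if "weighted_median" in methods and j >= 3:
        out.append(weighted_median(insts, n_boot=n_boot, seed=seed))
    if "weighted_mode" in methods and j >= 3:
        out.append(weighted_mode(insts, n_boot=n_boot, seed=seed))
    return out


def estimates_frame(estimates: list[MREstimate]) -> pd.DataFrame:
    """Tidy frame of estimates (one row per method) with OR-scale columns."""
    return pd.DataFrame([e.to_dict() for e in estimates])
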