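"""Standard MR diagnostic plots: scatter, forest, funnel, leave-one-out."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .estimators import Z95, wald_ratio

__all__ = ["plot_scatter", "plot_forest", "plot_funnel", "plot_leave_one_out", "make_plots"]


def _ratios(insts):
    bx = insts["beta_exp"].to_numpy(float)
    by = insts["beta_out"].to_numpy(float)
    sy = insts["se_out"].to_numpy(float)
    return by / bx, sy / np.abs(bx)


def plot_scatter(results, path: str | Path) -> Path:
    """β_X vs β_Y with one fitted line per method (Egger keeps its
    intercept; the others pass through the origin)."""
    insts = results.model.instruments
    bx = insts["beta_exp"].to_numpy(float)
    by = insts["beta_out"].to_numpy(float)
    sx = insts["se_exp"].to_numpy(float)
    sy = insts["se_out"].to_numpy(float)
    sign = np.sign(bx)
    sign[sign == 0] = 1
    bx, by = bx * sign, by * sign

    fig, ax = plt.subplots(figsize=(6, 5))
    ax.errorbar(bx, by, xerr=Z95 * sx, yerr=Z95 * sy, fmt="o", ms=4,
                color="0.3", ecolor="0.7", lw=0.8, zorder=2)
    grid = np.linspace(0, bx.max() * 1.05, 50)
    for e in results.estimates:
        if e.method == "egger_intercept":
            continue
        intercept = 0.0
        if e.method == "egger_slope" and results.egger_intercept is not None:
            intercept = results.egger_intercept.theta
        ax.plot(grid, intercept + e.theta * grid, label=e.method, lw=1.2)
    for rsid in (results.presso.outliers if results.presso else []):
        row = insts[insts["rsid"] == rsid].iloc[0]
        s = 1 if row["beta_exp"] >= 0 else -1
        ax.plot(s * row["beta_exp"], s * row["beta_out"], "rx", ms=10, zorder=3)
    ax.set_xlabel(f"SNP effect on {results.model.exposure_name}")
    ax.set_ylabel(f"SNP effect on {results.model.outcome_name}")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_forest(results, path: str | Path) -> Path:
    """Per-SNP Wald ratios with 95% CIs and the pooled estimates below;
    MR-PRESSO-flagged SNPs are marked."""
    insts = results.model.instruments
    r, se = _ratios(insts)
    order = np.argsort(r)
    labels = insts["rsid"].to_numpy()[order]
    outliers = set(results.presso.outliers) if results.presso else set()

    fig, ax = plt.subplots(figsize=(6, 0.22 * len(insts) + 2))
    y = np.arange(len(insts))
    ax.errorbar(r[order], y, xerr=Z95 * se[order], fmt="o", ms=3,
                color="0.2", ecolor="0.6", lw=0.8)
    for yi, lab in zip(y, labels):
        if lab in outliers:
            ax.plot(r[order][yi], yi, "rx", ms=9)
    pooled = [e for e in results.estimates if e.method != "egger_intercept"]
    for k, e in enumerate(pooled):
        yy = -1.5 - k
        ax.errorbar([e.theta], [yy], xerr=[[e.theta - e.ci_low], [e.ci_high - e.theta]],
                    fmt="D", ms=4, color="C0")
        ax.text(ax.get_xlim()[1], yy, f" {e.method}", fontsize=7, va="center")
    ax.axvline(0, color="0.8", lw=0.8)
    ax.set_yticks(y)
    ax.set_yticklabels(labels, fontsize=6)
    ax.set_xlabel("Wald ratio (log OR)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_funnel(results, path: str | Path) -> Path:
    """Funnel plot: per-SNP ratio against its precision 1/se, with the
    pooled IVW estimate as a vertical line."""
    r, se = _ratios(results.model.instruments)
    fig, ax = plt.subplots(figsize=(5, 4.5))
    ax.plot(r, 1.0 / se, "o", ms=4, color="0.3")
    ax.axvline(results.headline.theta, color="C0", lw=1.2, label="IVW")
    ax.set_xlabel("Wald ratio (log OR)")
    ax.set_ylabel("precision (1/se)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_leave_one_out(results, path: str | Path) -> Path:
    """Leave-one-out IVW estimates with the full-set estimate for contrast."""
    loo = results.loo
    fig, ax = plt.subplots(figsize=(6, 0.22 * len(loo) + 1.5))
    y = np.arange(len(loo))
    ax.errorbar(loo["theta"], y,
                xerr=[loo["theta"] - loo["ci_low"], loo["ci_high"] - loo["theta"]],
                fmt="o", ms=3, color="0.2", ecolor="0.6", lw=0.8)
    ax.axvline(results.headline.theta, color="C0", lw=1.0)
    ax.set_yticks(y)
    ax.set_yticklabels(loo["excluded_rsid"], fontsize=6)
    ax.set_xlabel("IVW estimate excluding one SNP (log OR)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def make_plots(results, outdir: str | Path, prefix: str = "mr") -> dict[str, Path]:
    """Write the four standard plots; skipped (with a notice) when fewer
    than two instruments are available."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if results.model.n_instruments < 2 or results.loo is None:
        print("fewer than 2 instruments: plots skipped")
        return {}
    return {
        "scatter": plot_scatter(results, outdir / f"{prefix}_scatter.png"),
        "forest": plot_forest(results, outdir / f"{prefix}_forest.png"),
        "funnel": plot_funnel(results, outdir / f"{prefix}_funnel.png"),
        "leave_one_out": plot_leave_one_out(results, outdir / f"{prefix}_loo.png"),
    }
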