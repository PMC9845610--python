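"""End-to-end orchestration of the bidirectional analysis.

:func:`run_direction` takes one exposure/outcome pair of summary-statistics
files (plus optional LD and confounder-annotation tables), runs instrument
selection, all estimators, the heterogeneity diagnostics and MR-PRESSO, and
writes every intermediate table to an output directory.  The headline
estimate is IVW under the heterogeneity-chosen effects model on the
outlier-corrected instrument set, reported as an odds ratio with its 95% CI.

:func:`run_bidirectional` runs both causal directions with direction-specific
instrument selection and classifies the trait pair by which directions'
CIs exclude OR = 1.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from .instruments import SelectionConfig
from .model import BidirectionalResults, FitConfig, MRModel, MRResults
from .plots import make_plots

__all__ = ["PipelineConfig", "DirectionReport", "run_direction", "run_bidirectional"]


@dataclass(frozen=True)
class PipelineConfig:
    """Bundled selection + estimation settings, loadable from YAML."""

    selection: SelectionConfig = field(default_factory=SelectionConfig)
    fit: FitConfig = field(default_factory=FitConfig)
    make_plots: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        sel = raw.get("selection", {})
        if "confounder_traits" in sel:
            sel["confounder_traits"] = tuple(sel["confounder_traits"])
        fit = raw.get("fit", {})
        if "methods" in fit:
            fit["methods"] = tuple(fit["methods"])
        return cls(
            selection=SelectionConfig(**sel),
            fit=FitConfig(**fit),
            make_plots=raw.get("make_plots", True),
        )


@dataclass
class DirectionReport:
    """Everything one direction produces, plus where it was written."""

    exposure_name: str
    outcome_name: str
    stage_counts: dict
    results: MRResults
    outdir: Path | None = None
    plot_paths: dict = field(default_factory=dict)

    @property
    def headline_or(self):
        return self.results.odds_ratio


def _write_tables(report: DirectionReport, outdir: Path, config: PipelineConfig) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    res = report.results
    model = res.model

    model.instruments.to_csv(outdir / "instruments.tsv", sep="\t", index=False)
    if model.selection_report is not None and model.selection_report.harmonized_full is not None:
        model.selection_report.harmonized_full.to_csv(
            outdir / "harmonized_full.tsv", sep="\t", index=False
        )
    res.estimates_df.to_csv(outdir / "estimates.tsv", sep="\t", index=False)

    diag = {}
    if res.heterogeneity:
        diag.update(res.heterogeneity.to_dict())
    if res.egger_intercept:
        diag["egger_intercept"] = res.egger_intercept.theta
        diag["intercept_p"] = res.egger_intercept.pval
    pd.DataFrame([diag]).to_csv(outdir / "diagnostics.tsv", sep="\t", index=False)

    if res.loo is not None:
        res.loo.to_csv(outdir / "leave_one_out.tsv", sep="\t", index=False)
    if res.presso is not None:
        pd.DataFrame([res.presso.to_dict()]).to_csv(outdir / "presso.tsv", sep="\t", index=False)
        res.presso.outlier_pvals.rename_axis("rsid").reset_index().to_csv(
            outdir / "presso_outlier_pvals.tsv", sep="\t", index=False
        )

    log = {
        "exposure": report.exposure_name,
        "outcome": report.outcome_name,
        "stage_counts": report.stage_counts,
        "seed": config.fit.seed,
        "selection_config": asdict(config.selection),
        "fit_config": asdict(config.fit),
        "headline": res.headline.to_dict(),
        "classification_significant": res.significant,
        "notes": res.notes,
    }
    (outdir / "run_log.json").write_text(json.dumps(log, indent=1, sort_keys=True, default=str))


def run_direction(
    exposure_path,
    outcome_path,
    ld_path=None,
    annotation_path=None,
    config: PipelineConfig | None = None,
    outdir: str | Path | None = None,
    exposure_name: str = "exposure",
    outcome_name: str = "outcome",
) -> DirectionReport:
    """Run one causal direction end to end; see module docstring.

    A failed stage raises with the stage name prefixed.
    """
    config = config or PipelineConfig()

    def _stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise type(exc)(f"[stage {name}] {exc}") from exc

    model = _stage(
        "selection",
        lambda: MRModel.from_files(
            exposure_path,
            outcome_path,
            ld_path=ld_path,
            annotation_path=annotation_path,
            selection=config.selection,
            exposure_name=exposure_name,
            outcome_name=outcome_name,
        ),
    )
    results = _stage("estimation", lambda: model.fit(config.fit))
    counts = (
        model.selection_report.stage_counts() if model.selection_report else {}
    )
    report = DirectionReport(
        exposure_name=exposure_name,
        outcome_name=outcome_name,
        stage_counts=counts,
        results=results,
    )
    if outdir is not None:
        outdir = Path(outdir)
        report.outdir = outdir
        _stage("report", lambda: _write_tables(report, outdir, config))
        if config.make_plots and model.n_instruments >= 2:
            report.plot_paths = _stage("plots", lambda: make_plots(results, outdir))
    return report


def run_bidirectional(
    forward_paths: dict,
    reverse_paths: dict,
    config: PipelineConfig | None = None,
    outdir: str | Path | None = None,
    trait_x: str = "exposure",
    trait_y: str = "outcome",
) -> tuple[DirectionReport, DirectionReport, dict]:
    """Run both causal directions and classify the trait pair.

    ``forward_paths``/``reverse_paths`` map ``exposure``, ``outcome`` and
    optionally ``ld``/``annotations`` to file paths; instruments are
    re-selected independently per direction.  Returns the two reports plus a
    concordance summary (classification and headline ORs).
    """
    config = config or PipelineConfig()
    outdir = Path(outdir) if outdir is not None else None
    fwd = run_direction(
        forward_paths["exposure"],
        forward_paths["outcome"],
        ld_path=forward_paths.get("ld"),
        annotation_path=forward_paths.get("annotations"),
        config=config,
        outdir=(outdir / "forward") if outdir else None,
        exposure_name=trait_x,
        outcome_name=trait_y,
    )
    rev = run_direction(
        reverse_paths["exposure"],
        reverse_paths["outcome"],
        ld_path=reverse_paths.get("ld"),
        annotation_path=reverse_paths.get("annotations"),
        config=config,
        outdir=(outdir / "reverse") if outdir else None,
        exposure_name=trait_y,
        outcome_name=trait_x,
    )
    classification = BidirectionalResults(fwd.results, rev.results).classification
    summary = {
        "classification": classification,
        "forward": fwd.results.headline.to_dict(),
        "reverse": rev.results.headline.to_dict(),
    }
    if outdir is not None:
        (outdir / "concordance.json").write_text(
            json.dumps(summary, indent=1, sort_keys=True, default=str)
        )
    return fwd, rev, summary
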