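"""Model/Results interface for a two-sample Mendelian randomization analysis.

:class:`MRModel` is built from harmonized instruments (or directly from a
pair of GWAS summary-statistics tables via :meth:`MRModel.from_sumstats`,
which runs the full instrument-selection procedure).  Its :meth:`~MRModel.fit`
returns an :class:`MRResults` carrying every estimator's estimate with its
uncertainty, the heterogeneity and pleiotropy diagnostics, the MR-PRESSO
outlier analysis, leave-one-out influence table, and a ``summary()`` table.

:class:`BidirectionalMR` fits two directions (instruments re-selected per
direction) and classifies the exposure/outcome pair as *bidirectional*,
*forward_only*, *reverse_only* or *null* by whether each direction's 95% CI
excludes an odds ratio of 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import estimators as est
from .diagnostics import (
    HeterogeneityReport,
    choose_effects_model,
    cochran_q,
    egger_intercept_test,
    leave_one_out,
)
from .instruments import SelectionConfig, SelectionReport, LDSource, select_instruments
from .presso import PressoResult, run_presso
from .sumstats import read_sumstats

__all__ = ["FitConfig", "MRModel", "MRResults", "BidirectionalMR", "BidirectionalResults"]

ALL_METHODS = ("ivw", "egger", "weighted_median", "weighted_mode")


@dataclass(frozen=True)
class FitConfig:
    """Settings of the estimation stage (selection settings live in
    :class:`~causalmr.instruments.SelectionConfig`)."""

    methods: tuple[str, ...] = ALL_METHODS
    effects_model: str = "auto"      # fixed | random | auto (heterogeneity rule)
    heterogeneity_alpha: float = 0.05
    n_boot: int = 1000               # parametric bootstrap for median/mode
    run_presso: bool = True
    presso_k_sim: int = 1000
    presso_alpha: float = 0.05
    presso_distortion: bool = True
    seed: int = 0


class MRModel:
    """Two-sample MR model over a harmonized-instrument frame."""

    def __init__(
        self,
        instruments: pd.DataFrame,
        exposure_name: str = "exposure",
        outcome_name: str = "outcome",
        selection_report: SelectionReport | None = None,
    ):
        required = {"rsid", "beta_exp", "se_exp", "beta_out", "se_out"}
        missing = required - set(instruments.columns)
        if missing:
            raise ValueError(f"instrument frame missing columns: {sorted(missing)}")
        if (instruments["se_exp"] <= 0).any() or (instruments["se_out"] <= 0).any():
            raise ValueError("instrument standard errors must be positive")
        self.instruments = instruments.reset_index(drop=True)
        self.exposure_name = exposure_name
        self.outcome_name = outcome_name
        self.selection_report = selection_report

    @classmethod
    def from_sumstats(
        cls,
        exposure: pd.DataFrame,
        outcome: pd.DataFrame,
        ld: LDSource | None = None,
        annotations: pd.DataFrame | None = None,
        selection: SelectionConfig | None = None,
        exposure_name: str = "exposure",
        outcome_name: str = "outcome",
    ) -> "MRModel":
        """Build a model by running instrument selection on two GWAS tables."""
        insts, report = select_instruments(
            exposure, outcome, ld=ld, annotations=annotations, config=selection
        )
        return cls(insts, exposure_name, outcome_name, selection_report=report)

    @classmethod
    def from_files(
        cls,
        exposure_path,
        outcome_path,
        ld_path=None,
        annotation_path=None,
        selection: SelectionConfig | None = None,
        column_map=None,
        exposure_name: str = "exposure",
        outcome_name: str = "outcome",
    ) -> "MRModel":
        """Build a model from delimited summary-statistics files."""
        selection = selection or SelectionConfig()
        exp = read_sumstats(exposure_path, column_map=column_map).data
        out = read_sumstats(outcome_path, column_map=column_map).data
        ld = LDSource.from_file(ld_path, window_kb=selection.clump_kb) if ld_path else None
        ann = pd.read_csv(annotation_path, sep="\t") if annotation_path else None
        return cls.from_sumstats(
            exp, out, ld=ld, annotations=ann, selection=selection,
            exposure_name=exposure_name, outcome_name=outcome_name,
        )

    @property
    def n_instruments(self) -> int:
        return len(self.instruments)

    def fit(self, config: FitConfig | None = None, **overrides) -> "MRResults":
        """Estimate the causal effect and all diagnostics.

        Workflow: Cochran Q on the selected instruments → fixed/random
        decision → all requested estimators on the raw set → MR-PRESSO
        (global, per-SNP outlier, distortion) → re-estimation on the
        outlier-corrected set.  The headline estimate is IVW under the
        effects model chosen by the heterogeneity rule on the corrected set.
        """
        config = replace(config or FitConfig(), **overrides) if overrides else (config or FitConfig())
        insts = self.instruments
        j = len(insts)
        notes: list[str] = []

        het_raw = cochran_q(insts, alpha=config.heterogeneity_alpha) if j >= 2 else None

        raw_estimates = est.all_estimates(
            insts,
            effects_model=config.effects_model,
            n_boot=config.n_boot,
            seed=config.seed,
            methods=config.methods,
        )
        if j < 3:
            notes.append("insufficient instruments (<3) for Egger, median and mode")

        presso: PressoResult | None = None
        if config.run_presso and j >= 4:
            presso = run_presso(
                insts,
                k_sim=config.presso_k_sim,
                alpha=config.presso_alpha,
                effects_model=config.effects_model,
                distortion=config.presso_distortion,
                seed=config.seed,
            )
            notes.extend(presso.warnings)
        elif config.run_presso:
            notes.append("insufficient instruments (<4) for MR-PRESSO")

        if presso is not None and presso.outliers and not presso.correction_refused:
            corrected = insts[~insts["rsid"].isin(presso.outliers)].reset_index(drop=True)
        else:
            corrected = insts

        if len(corrected) < len(insts):
            corrected_estimates = est.all_estimates(
                corrected,
                effects_model=config.effects_model,
                n_boot=config.n_boot,
                seed=config.seed,
                methods=config.methods,
            )
        else:
            corrected_estimates = raw_estimates
        het = cochran_q(corrected, alpha=config.heterogeneity_alpha) if len(corrected) >= 2 else het_raw

        # Headline: IVW under the heterogeneity-chosen model, post-correction.
        if het is not None and config.effects_model == "auto":
            headline_model = choose_effects_model(het, config.heterogeneity_alpha)
        elif config.effects_model == "auto":
            headline_model = "fixed"
        else:
            headline_model = config.effects_model
        headline = est.ivw(corrected, effects_model=headline_model)

        egger_int, pleio_flag = (None, False)
        if j >= 3 and "egger" in config.methods:
            egger_int, pleio_flag = egger_intercept_test(insts)

        loo = leave_one_out(corrected, effects_model=config.effects_model) if len(corrected) >= 2 else None

        return MRResults(
            model=self,
            config=config,
            estimates=raw_estimates,
            corrected_estimates=corrected_estimates,
            heterogeneity=het,
            heterogeneity_raw=het_raw,
            egger_intercept=egger_int,
            pleiotropy_suspected=pleio_flag,
            presso=presso,
            corrected_instruments=corrected,
            headline=headline,
            loo=loo,
            notes=notes,
        )


@dataclass
class MRResults:
    """Fitted results of one MR direction."""

    model: MRModel
    config: FitConfig
    estimates: list[est.MREstimate]
    corrected_estimates: list[est.MREstimate]
    heterogeneity: HeterogeneityReport | None
    heterogeneity_raw: HeterogeneityReport | None
    egger_intercept: est.MREstimate | None
    pleiotropy_suspected: bool
    presso: PressoResult | None
    corrected_instruments: pd.DataFrame
    headline: est.MREstimate
    loo: pd.DataFrame | None
    notes: list[str] = field(default_factory=list)

    @property
    def estimates_df(self) -> pd.DataFrame:
        raw = est.estimates_frame(self.estimates).assign(instrument_set="raw")
        corr = est.estimates_frame(self.corrected_estimates).assign(
            instrument_set="outlier_corrected"
        )
        return pd.concat([raw, corr], ignore_index=True)

    @property
    def odds_ratio(self) -> est.ORScale:
        return self.headline.or_scale()

    @property
    def significant(self) -> bool:
        """95% CI excludes OR = 1 (equivalently, two-sided p < 0.05)."""
        orr = self.odds_ratio
        return orr.ci_low > 1.0 or orr.ci_high < 1.0

    def summary(self) -> str:
        m = self.model
        orr = self.odds_ratio
        lines = [
            "Two-sample Mendelian randomization",
            "=" * 66,
            f"Exposure: {m.exposure_name}    Outcome: {m.outcome_name}",
            f"Instruments: {m.n_instruments} selected"
            + (
                f", {len(self.corrected_instruments)} after outlier removal"
                if len(self.corrected_instruments) != m.n_instruments
                else ""
            ),
            "",
            f"{'method':<18}{'set':<10}{'nSNP':>5}{'theta':>9}{'se':>8}"
            f"{'OR':>8}{'95% CI':>17}{'p':>11}",
            "-" * 86,
        ]
        for label, ests in (("raw", self.estimates), ("corrected", self.corrected_estimates)):
            if label == "corrected" and ests is self.estimates:
                continue
            for e in ests:
                o = e.or_scale()
                lines.append(
                    f"{e.method:<18}{label:<10}{e.n_snps:>5}{e.theta:>9.4f}{e.se:>8.4f}"
                    f"{o.or_:>8.4f}  {o.ci_low:>6.4f}-{o.ci_high:<6.4f}{e.pval:>11.3g}"
                )
        lines.append("-" * 86)
        lines.append(
            f"Headline (IVW, {self.headline.effects_model} effects, corrected set): "
            f"OR {orr.or_:.4f} (95% CI {orr.ci_low:.4f}-{orr.ci_high:.4f}), "
            f"p = {self.headline.pval:.4g}"
        )
        if self.heterogeneity:
            h = self.heterogeneity
            lines.append(
                f"Cochran Q = {h.q_stat:.4f} (df {h.df}), p = {h.pval:.4g}, "
                f"I2 = {h.i2:.1%} -> {h.chosen_model} effects"
            )
        if self.egger_intercept:
            lines.append(
                f"Egger intercept = {self.egger_intercept.theta:.4g} "
                f"(p = {self.egger_intercept.pval:.4g})"
                + ("  ** directional pleiotropy suspected" if self.pleiotropy_suspected else "")
            )
        if self.presso:
            p = self.presso
            lines.append(
                f"MR-PRESSO RSSobs = {p.rss_obs:.4f}, global p = {p.global_pval:.4g}, "
                f"outliers: {', '.join(p.outliers) if p.outliers else 'none'}"
            )
        for n in self.notes:
            lines.append(f"note: {n}")
        return "\n".join(lines)


class BidirectionalMR:
    """Paired forward (X→Y) and reverse (Y→X) MR models."""

    def __init__(self, forward: MRModel, reverse: MRModel):
        self.forward = forward
        self.reverse = reverse

    def fit(self, config: FitConfig | None = None) -> "BidirectionalResults":
        fwd = self.forward.fit(config)
        rev = self.reverse.fit(config)
        return BidirectionalResults(fwd, rev)


@dataclass
class BidirectionalResults:
    forward: MRResults
    reverse: MRResults

    @property
    def classification(self) -> str:
        """bidirectional / forward_only / reverse_only / null, judged by
        each direction's 95% CI excluding OR = 1."""
        f, r = self.forward.significant, self.reverse.significant
        if f and r:
            return "bidirectional"
        if f:
            return "forward_only"
        if r:
            return "reverse_only"
        return "null"

    def summary(self) -> str:
        return "\n\n".join(
            [
                "[Forward direction]",
                self.forward.summary(),
                "[Reverse direction]",
                self.reverse.summary(),
                f"Concordance classification: {self.classification}",
            ]
        )
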