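# Methods

## Scope and model

`causalmr` performs two-sample Mendelian randomization: causal-effect
estimation for an exposure→outcome trait pair from two independent GWAS
summary-statistics tables, with instruments re-selected per direction for
bidirectional analyses.  Everything operates on per-SNP per-allele log-odds
effects β̂ with standard errors; no individual-level data are touched.

The instrumental-variable assumptions are documented contracts, not tested
hypotheses: each instrument must be (1) associated with the exposure,
(2) independent of exposure–outcome confounders, and (3) associated with the
outcome only through the exposure.  The pipeline enforces (1) directly
(genome-wide significance, F > 10), approximates (2) by excluding SNPs
annotated to user-named confounder traits, and probes (3) with the Egger
intercept, Cochran's Q and MR-PRESSO.

## Instrument selection

Stages run in a fixed order, each only removing SNPs:

1. **Significance**: keep exposure associations with p < `p_threshold`
   (default 5×10⁻⁸, the genome-wide convention).
2. **LD clumping**: greedy — repeatedly keep the most significant remaining
   SNP and remove same-chromosome SNPs within `clump_kb` (default
   10,000 kb) whose r² with it is ≥ `clump_r2` (default 0.001).  Equal
   p-values tie-break on lexicographic rsid so the output is deterministic.
   LD comes from a pair table or is computed as squared Pearson correlation
   of dosage columns; absent pairs mean r² = 0.
3. **Harmonization**: outcome records aligned to the exposure's effect
   allele — identical orientation kept as-is; swapped alleles flip the beta
   sign and replace eaf by 1−eaf; anything else is dropped as incompatible.
   Strand-complement rescue of non-palindromic SNPs (e.g. matching A/G
   against T/C) is deliberately not attempted: rsid-keyed modern summary
   statistics rarely need it, and a silent wrong rescue is worse than a
   dropped SNP.  Palindromic SNPs (A/T, C/G) cannot be oriented from
   alleles alone; the default policy drops them (the strict reading —
   strictness cannot create false positives), while
   `infer_if_maf_below_threshold` keeps those whose minor-allele frequency
   is below 0.3 on both sides and aligns them by frequency (same side of
   0.5 ⇒ same allele).  Missing frequency under the infer policy drops the
   SNP.  Harmonization is idempotent and never alters exposure-side values.
4. **Confounder screen**: a SNP is excluded iff a local annotation table
   (the stand-in for a PhenoScanner query) links it to a configured
   confounder trait at p < 5×10⁻⁸.  The trait list is user configuration
   with no default — which traits count as confounders is a scientific
   choice the software cannot make.
5. **Instrument strength**: per-SNP F ≈ (β̂_X/se_X)², kept when F > `f_min`
   (default 10).  The (β/se)² form is used because per-SNP R² is not
   available in summary data; the R²(n−2)/(1−R²) form would need both eaf
   and n.

Selection emits per-stage survivor counts.  Zero survivors is an error;
fewer than three triggers a warning since MR-Egger, the weighted median and
the weighted mode need ≥ 3 instruments.

## Estimators and inference

All 95% CIs use z = 1.959964 except MR-Egger, which uses t with J−2 df.

- **Wald ratio**: θ̂_j = β̂_Yj/β̂_Xj, se = se_Yj/|β̂_Xj| (first-order delta
  method).  Exposure-side uncertainty is deliberately not propagated here:
  it is controlled upstream by the F filter and enters MR-PRESSO through
  its simulation draws, matching the β²_X/se²_Y weighting the IVW uses.
- **IVW**: weighted regression through the origin; fixed, multiplicative
  random (se × max(1, √(Q/(J−1))) — floored so random effects never claim
  more precision than fixed), or `auto`, which applies the heterogeneity
  rule below.  A single instrument reduces to its Wald ratio exactly.
- **MR-Egger**: instruments first oriented so β̂_X ≥ 0 (the fit is otherwise
  not invariant to arbitrary allele orientation), then weighted least
  squares with intercept, weights se⁻²_Y, standard errors scaled by
  max(1, √(RSS_w/(J−2))).
- **Weighted median**: ratios sorted; with normalized weights w_j the
  midpoint positions are s_j = cum(w)_j − w_j/2 and θ̂ linearly interpolates
  at s = 0.5.
- **Weighted mode**: normal-kernel weighted density of the ratios with
  bandwidth h = φ·0.9·min(sd, MAD/0.6745)·J^(−1/5) (φ = 1 by default),
  maximized over a 512-point grid spanning range ± 3h; exact density ties
  resolve to the smaller grid value (first maximum).  All ratios identical
  (h = 0) returns the common ratio.
- Median and mode standard errors come from a parametric bootstrap —
  β̂*_X ~ N(β̂_X, se_X), β̂*_Y ~ N(β̂_Y, se_Y), `n_boot` = 1000 by default
  (< 100 warns) — with an explicit seed; identical seeds give identical
  output everywhere in the package.

**Heterogeneity and model choice.** Cochran's Q in ratio form
(Σ w_j(r_j − θ̂_IVW)², equivalent to the regression-residual form under
first-order weights), df = J−1, I² = max(0, (Q−df)/Q).  The decision rule is
*random effects iff the Q-test p < 0.05* (strict inequality: p = 0.05
exactly selects fixed).  The rule is applied to the post-outlier-correction
instrument set for the headline estimate.

**MR-PRESSO.** RSS_obs = Σ_j (β̂_Yj − θ̂₍₋ⱼ₎β̂_Xj)²/se²_Yj with leave-one-out
fixed-effects IVW predictions — deterministic given the instruments.  The
null distribution redraws β*_X ~ N(β̂_X, se_X) and β*_Y ~ N(θ̂₍₋ⱼ₎β̂_X, se_Y)
`k_sim` times (default 1000) and recomputes RSS identically, with its own
leave-one-out fits per replicate; residuals are standardized by se_Y so SNPs
compare on one scale (an unstandardized variant is a config option).
Empirical p-values use the +1 correction, so the global p is never below
1/(k_sim+1).  Per-SNP outlier p-values are Bonferroni-multiplied by J and
flagged below 0.05; if more than half the instruments are flagged the
50%-genuine-instruments condition fails and correction is refused with a
warning.  The distortion test compares the raw-vs-corrected shift against
shifts from removing random subsets of the same size (on by default when
outliers are found; off by config).  Outlier-corrected estimates are
recomputed for all methods, with raw estimates always reported alongside —
whether correction should apply to all estimators or IVW alone is genuinely
open, and reporting both costs nothing.

## Synthetic data generator

`generate_pair` emulates the structure of a well-powered consortium GWAS
pair: J instruments (default 30) with true exposure effects
γ_j ~ N(0.1, 0.02) on the log-odds scale, allele frequencies uniform on
[0.1, 0.5], standard errors from the binary-trait approximation
se = (2·n·maf(1−maf))^(−1/2) at n = 50,000 per GWAS, observed effects
β̂_X ~ N(γ, se_X) and β̂_Y ~ N(θγ + α, se_Y).  Direct (pleiotropic) effects
α follow the configured regime: none, balanced (mean zero), directional
(nonzero mean), or InSIDE-violating (correlated with γ).  Contamination
adds `outlier_shift` to β_Y for a fraction of SNPs.  A configurable
fraction of instruments (default 10%) gets palindromic alleles, a third of
outcome records are reported for the opposite allele (exercising the
harmonization flip), null background SNPs with γ = 0 populate the
non-significant tail, and optional LD blocks share constant r² within a
clumping window.  Truth records store every latent value.

What it does **not** emulate: individual-level genotypes, realistic LD from
reference panels, sample overlap between the two GWAS, allele-frequency
differences between cohorts, or case-control imbalance in the se formula.
Passing tests therefore demonstrate correctness of the estimators and the
pipeline logic under the stated sampling model, not robustness to those
real-data complications.

## Verification design and problem sizes

The verification suite checks properties, not the numbers of any published
analysis (which would require the original GWAS downloads, LD reference and
annotation queries).  Problem sizes are chosen to finish on a desk machine:
IVW-vs-oracle on 100 random sets; 500-replicate recovery at J = 30,
θ = 0.15, n = 50,000; 1000-replicate Q calibration; 200-replicate MR-PRESSO
null calibration (k_sim = 400–500 inside replicate loops, 1000 for single
analyses); 200-replicate bidirectional classification with the
bootstrap-based estimators disabled, since classification depends only on
the IVW CI.

Two finite-sample effects matter when reading the recovery results.  First,
with exposure effects measured with error, MR-Egger's slope attenuates by
I²_GX = var(γ)/(var(γ)+se²_X) and its intercept is displaced by roughly
θ(1−I²_GX)·mean(γ) — about 0.0016 at the default conditions (I²_GX ≈ 0.89),
which is resolvable at 500-replicate Monte-Carlo precision and vanishes as
n_exp → ∞; the intercept-recovery check is therefore made against this
analytic floor rather than exact zero.  Second, the weighted median carries
an O(1/F) bias of order −0.001 here, from the correlation between a ratio
and its own weight through the shared β̂_X.  Neither effect is an
implementation artifact (both vanish in the noise-free-exposure limit) —
they are the standard weak-instrument behaviour of these estimators.
Relatedly, the Q-calibration null is simulated with n_exp = 10⁶ so the
rejection rate measures the statistic's calibration rather than the ~2%/df
Q inflation that exposure noise at n = 50,000 adds under first-order
weights.

## Known limitations

- First-order Wald se ignores the β_Y·se_X/β²_X term; acceptable at F ≫ 10,
  conservative screening keeps it there.
- Confounder screening is exact-string trait matching on a local table — no
  ontology expansion, no live database.
- No proxy-SNP lookup, genome-build liftover, Steiger filtering,
  multivariable MR or MR-RAPS.
- MR-PRESSO p-values are simulation-based; only their distribution, not any
  third-party implementation's random stream, is reproducible.
- Multiple testing across outcome traits is not adjusted by default
  (per-trait reporting); a Bonferroni flag is available in config.
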