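# Methods

## Data model and preprocessing

A `ConcentrationBlock` is one samples × metabolites matrix of targeted
concentrations (µM) with sample metadata (group, tissue, aorta wet weight)
and a boolean validity mask marking cells inside the assay's dynamic range.
The on-disk dialect is a Biocrates-style wide delimited table; the
below-LOD sentinels `<LOD`, `< LOD`, `NA` and empty cells all mark a cell
out-of-range, since vendor exports vary.

Preprocessing follows targeted-metabolomics convention:

1. **Dynamic-range filter.** A metabolite is retained only if *strictly
   more than* 70% of its values are in-range (7/10 valid is dropped,
   8/10 kept). The rule is idempotent and never alters retained values.
2. **Weight normalization** (aorta only). Every concentration in a row is
   divided by that animal's aorta wet weight (mg), giving µM per mg; the
   methanol extraction volume is constant across samples and is not
   corrected for.
3. **Imputation.** Remaining censored cells are filled with half the
   per-metabolite minimum of the valid values (`half_min`, the usual
   left-censoring convention; `zero` is available). Imputation runs after
   filtering, so every column has valid values to take a minimum over.
4. **Scaling.** Each column is mean-centered and scaled to unit variance
   with the sample standard deviation (m − 1 denominator).

Metabolite names are parsed into a taxonomy (class + acyl carbons + double
bonds from the `C X:Y` code) that drives all class sums and ratios:
long-chain acylcarnitines are those with *strictly more than* 12 acyl
carbons; a lysoPC is "saturated" iff its acyl moiety has zero double bonds.

## Two-block decomposition

The multiblock model splits each scaled block into joint, unique and
residual parts, `X_b = T_j P_b' + U_b Q_b' + E_b`. The construction is the
two-block member of the O2PLS/OnPLS family, pinned to a deterministic,
oracle-checkable algorithm:

1. SVD of the cross-product `X_pl' X_ao`; the leading pair `(w_pl, w_ao)`
   gives per-block candidate scores `t_pl = X_pl w_pl`, `t_ao = X_ao w_ao`.
2. After sign-aligning `t_ao` to `t_pl`, the consensus joint score `t_j`
   is the unit-norm leading left singular vector of `[t_pl | t_ao]` — one
   score vector shared by both blocks.
3. Each block is deflated by least-squares projection onto `t_j`
   (`p_b = X_b' t_j`), and steps 1–3 repeat for `n_joint` components
   (default 2). Successive joint scores are mutually orthogonal because
   each candidate score lives in the column space of an already-deflated
   block.
4. Unique components per block are leading principal components of the
   deflated residual, re-orthogonalized against all joint scores;
   components with negligible singular value are dropped, so a noiseless
   joint-only block reports zero unique variance.
5. R² bookkeeping is captured sum-of-squares over the block's total
   sum-of-squares; joint + unique + residual sums to 1 within 1e-8, and
   the three parts reconstruct the scaled input exactly.

The number of unique components defaults to a permutation-null eigenvalue
rule: keep as many residual PCs as have singular values above the 95th
percentile of the leading singular value after independently permuting
each residual column (99 permutations).

The singular-vector sign is arbitrary, so the fitted model is oriented by
the group labels: t_j,1 (and both blocks' first-component loadings) are
flipped if needed so the ANG group mean exceeds the SHAM group mean.
Orientation is a pure sign change; it never alters variance fractions,
|τ|, p-values or significance.

Numerical tolerances: orthogonality and reconstruction at 1e-8 on
unit-variance data; degenerate unique components cut off at 1e-10 relative
to the residual norm; constant columns are rejected by name at scaling.

## Variable importance and error control

For each metabolite the Kendall τ-b rank correlation (tie-corrected,
because LOD imputation creates ties) between its concentration vector and
the t_j,1 score vector across mice is computed, with a two-sided p-value:
exact enumeration for n ≤ 9 without ties, otherwise the normal
approximation with tie-corrected variance (an m = 31 cohort always uses
the approximation). τ is invariant under strictly monotone transforms, so
raw and UV-scaled concentrations give identical importance tables.
Benjamini–Hochberg step-up selection runs at q = 0.05 separately per
block; the α-threshold reported is the largest admissible sorted p-value
(0 when nothing passes). Volcano coordinates are
`(loading on t_j,1, τ, −log₁₀ p)` with a class-based color key.

**A calibration caveat that applies to real data too:** t_j,1 is fitted on
the same data it is then correlated against. Under the global null (no
systematic structure at all) the τ test is calibrated — the flagged
fraction over null cohorts stays below q plus Monte-Carlo slack. But when
a block carries *unique* systematic structure and no joint structure, the
fitted joint score partially captures the unique factor, and metabolites
loading on it are *genuinely* correlated with the realized score: the
importance list then reflects within-block structure rather than
blood–aorta coupling. Interpreting the list as "shared risk" metabolites
implicitly assumes the joint component dominates — which the variance
bookkeeping should be used to verify.

## Group statistics and biomarkers

Pairwise group differences use the two-sided Mann–Whitney–Wilcoxon test
(exact when min(n₁, n₂) ≤ 8 without ties, otherwise tie-corrected normal
approximation), with BH correction over the metabolite × pair family.

Candidate biomarkers are per-sample features: class sums and ratios
(numerator sum over denominator sum, computed per sample — never a ratio
of medians). Each feature is scored on three contrasts (ANG vs pooled
SHAM+HCD, HCD vs ANG, SHAM vs HCD) by the AUC with ties counted ½ —
identically U/(n₊·n₋) — and DeLong's placement-value variance estimator
giving a normal-theory 95% CI clipped to [0, 1]. The AUC is reported for
the orientation making it ≥ 0.5 (recorded in a `flipped` column), since
discriminative performance, not direction, is evaluated; a
`good_classifier` flag applies the AUC ≥ 0.80 convention and a separate
flag marks intervals whose lower bound does not clear 0.80. The DeLong
implementation is cross-checked in the test suite against R's pROC.

The Friedewald helper computes LDL cholesterol as CT − HDL − TG/2.2
(mmol/L) with a warning above 4.5 mmol/L triglycerides where the formula
is unreliable. Note a bookkeeping subtlety: applying the formula to
*column means* of a lipid table does not reproduce the *mean of
per-animal* LDL values; the two disagree whenever the animals' values
vary, and only per-animal inputs give the latter.

## Synthetic cohorts

The generator emulates the study design so every pipeline stage can be
checked against ground truth. Defaults:

| parameter | default | meaning |
| --- | --- | --- |
| group sizes | 11 / 10 / 10 | SHAM / HCD / ANG mice |
| panel | 188 analytes | 40 AC, 21 AA, 21 amines, 76 PC, 14 lysoPC, 15 SM, 1 hexose |
| joint effect | (−1, 0, +1) | latent risk group means |
| variance split | 0.4 / 0.3 / 0.3 | joint / unique / noise per log-column |
| within-group sd | 0.5 | risk-factor spread inside a group |
| log_sigma | 0.25 | log-scale concentration sd |
| lod_quantile | 0.02 | lowest tail censored per analyte |
| aorta weight | 5 mg, log-sd 0.1 | lognormal wet weights |

On the log scale each standardized column is
`z = √f_j·s·risk + √f_u·u + √f_n·ε` with the realized factors
standardized in-sample; concentrations are `baseline · exp(log_sigma·z)`
with class-specific baselines spanning the orders of magnitude of a real
panel (hexose ≫ amino acids ≫ biogenic amines), so UV scaling is
exercised meaningfully. Censoring marks the `round(q·m)` smallest entries
of each column out-of-range (one cell per column at defaults), before
filtering, so the 70% rule is exercised; heavier censoring pushes
analytes below retention.

Three design choices matter for what the generator does and does not
emulate:

- **Measurement-scale attenuation.** Exponentiation attenuates a planted
  log-scale variance fraction f to ≈ f·σ²/(e^σ²−1) on the concentration
  scale the UV-scaled model consumes; at log_sigma = 0.25 the attenuation
  is ≈ 3.5%, so the planted 40% joint fraction is recoverable from the
  fitted R². log_sigma also sets effect sizes: a bulk signature column
  shifts ≈ 1.4-fold between SHAM and ANG, a strong hit ≈ 3.7-fold —
  within the range a targeted panel reports for top discriminators.
- **Common-mode unique factor.** The block-unique factor loads the polar
  LC panel (amino acids + biogenic amines) common-mode — emulating the
  shared per-sample derivatization/dilution efficiency of a targeted
  kit — and the other analytes with random sign. Ratios of polar analytes
  (BCAA/Gly, BCAA/Gln) cancel the common-mode part, which is precisely
  why they outperform single analytes; keeping the common mode confined
  to the polar panel leaves the unique loading direction near-orthogonal
  to the planted risk loadings, so the joint score is not contaminated.
- **Two-tier signature.** Named signature metabolites carry signed
  joint-loading multipliers: strong hits (plasma protectives Gly, Gln,
  taurine, C0, C2, C3 falling; aortic ADMA, putrescine, ornithine rising;
  aortic polar decreases) at magnitude 4, secondary hits — including the
  branched-chain amino acids — at 1.5, and class-level lipid entries
  (plasma PC/SM/lysoPC up, aortic PC/SM down) at 1 with pinned direction
  only. This reproduces the qualitative pattern of the modelled study:
  a marginal standalone BCAA classifier whose confidence interval touches
  0.80, against near-perfect BCAA/Gly and BCAA/Gln ratios. The aorta's
  structure is planted on the weight-normalized scale and the raw export
  back-computed by multiplying the weights in, so the pipeline's
  normalization step recovers the planted structure exactly.

`null_cohort` generates the global null — both joint and unique fractions
reassigned to noise — which is the reference for FDR and null-AUC
calibration (see the caveat above for why a null with unique structure
would not calibrate the data-driven importance test).

What the generator does **not** emulate: batch effects and QC drift,
longitudinal sampling, inter-metabolite correlation beyond the two planted
factors, heteroscedastic assay error, and missingness mechanisms other
than left-censoring. Passing recovery tests therefore demonstrate
correctness of the estimation machinery under the assumed factor
structure, not robustness to real-world nuisance structure.

## Problem sizes and runtime

The test suite and the acceptance script scale their simulations to run
on one CPU in minutes: recovery and signature rates use 100–200 cohorts
of m = 31; the variance-bookkeeping check uses one m = 2000 cohort;
error control uses 50–100 global-null cohorts; oracle checks use 50
random instances at n ≤ 8 (τ), full permutation enumeration at n = 5–6,
and 1000 random p-vectors (BH). Monte-Carlo slack on rate assertions
follows q + 2√(q/m) for FDR and binomial noise elsewhere.

## Known limitations

- The decomposition assumes complete data after imputation; there is no
  missing-data-aware NIPALS, and n > 2 blocks are out of scope.
- DeLong intervals are computed on the untransformed AUC scale and
  clipped; logit-scale intervals can behave better near AUC = 1 with tiny
  groups.
- The permutation rule for unique-component counts is a heuristic; SIMCA's
  selection rule for the modelled analysis is not public.
- With m = 31 the importance test's power and the AUC's granularity
  (1/210 for 10 vs 21) are limiting; rates quoted for the synthetic
  cohorts should not be read as power statements about other designs.
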