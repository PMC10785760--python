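# Methods

This note documents the models implemented in `dioxome`, the defaults
and why they were chosen, what the synthetic cohort does and does not
emulate, and the numerical decisions a maintainer should know about.

## Study design being emulated

The analysis targets a two-factory occupational cohort: 137 male
workers, 76 from a factory with a historical TCDD release (factory A,
mean age 69.0 y, with occupational lag periods of decades since last
exposure) and 61 from a comparison factory (B, mean age 58.8 y, no lag).
The targeted exposure panel holds 29 lipid-adjusted congener
concentrations in ppt: 7 PCDDs, 10 dioxin-like PCDFs, 12 dioxin-like
PCBs. Untargeted chemistry comes from GC-HRMS (m/z 85–850) and two
LC-HRMS metabolomics modes (C18-negative and HILIC-positive, m/z
85–1275, triplicate injections); 54 immune markers span four categories
(21 cytokines/growth factors, 23 hematologic, 7 humoral, 3 lymphoma
markers).

## TCDD back-extrapolation

One-compartment first-order elimination with half-life t½ = 7.1 years.
Only the excess above the population background is extrapolated:

    TCDDmax = bg + max(c − bg, 0) · 2^(lag / t½)

with `bg` defaulting to the mean measured TCDD among factory-B subjects
and lag = 0 for factory B. The source model's equation is not printed in
full anywhere we could rely on, so the background-excess form was fixed
as the package's definition: it is the unique form that (i) is
first-order in the excess, (ii) leaves the background a fixed point, and
(iii) reduces to the measured value at zero lag (for c ≥ bg). Whether
background should instead be subtracted after exponentiation is not
decidable from the available description; `subtract_background=False`
exposes the no-background variant `c · 2^(lag/t½)`. Note the clamped
form returns max(c, bg) at lag 0 when c < bg.

The transform satisfies a semigroup law (extrapolating by lag₁ then lag₂
equals one step of lag₁+lag₂) and is monotone in measured level, lag and
elimination rate; both are tested.

## Chlorine envelope screen

GC-EI fragments and isotopologues of one compound co-elute and co-vary,
so features are grouped by the similarity

    s_ij = exp(−(1−r_ij)²/(2σ_r²)) · exp(−(rt_i−rt_j)²/(2σ_rt²))

(r = Pearson on ln intensities; defaults σ_r = 0.5, σ_rt = 2 s) with
average-linkage hierarchical clustering on 1−s cut at 0.5. Cluster
abundance per subject is the member-feature mean weighted by mean
feature intensity; peak lists are normalized to max = 1.

A spectrum is chlorinated when some peak with no partner 1.99705 Da
below it is followed by peaks at +k·1.99705 Da (k ≤ 4, i.e. up to M+8;
±5 mDa) including at least M+2, and the observed relative intensities
fit the binomial ³⁵Cl/³⁷Cl envelope (p₃₇ = 0.2423) of some n ∈ 1..10
with mean per-peak relative residual ≤ 30%. Ties in the least-squares
fit go to smaller n. Choices worth restating:

- **±5 mDa absolute** mass tolerance (ppm tolerances misbehave at low
  m/z for Orbitrap-GC resolution); configurable.
- **30% relative intensity tolerance** per matched peak — a free
  parameter of the screen, deliberately loose because per-feature
  intensities are noisy.
- The envelope is fitted on the **cross-subject mean spectrum**;
  per-subject fits are noisier and add nothing at this stage.
- k_max = 4 and n ≤ 10 bound the search to plausible congeners below
  m/z 850.
- The ¹³C M+1 spacing (1.00336 Da) differs from half a Cl spacing by far
  more than the tolerance, so ¹³C distractors are rejected by mass
  arithmetic alone.

On the exact theoretical envelopes the detector recovers every n in
1..10; under 5% multiplicative noise its sensitivity is ≥ 0.90 at a
decoy false-positive rate ≤ 0.02 (both tested).

## Related-compound selection

For each (suspect, congener) pair, Spearman rho with midrank ties and
the two-sided p from t = r√((n−2)/(1−r²)) on n−2 df; selected iff rho > 0
and p < 0.002. Two-sidedness is the conservative reading of the
threshold; a one-sided variant is a trivial parameter change. At n = 137
the t approximation is ample — the suite checks it against a
10⁴-permutation oracle at n = 20, and the null selection rate against
its nominal 0.1%. Subclass sets are unions over the subclass's
congeners, so one compound may be PCDD- and PCB-related at once.

The exposure network connects any pair among {29 congeners} ∪ {related
compounds} meeting the same rho > 0, p < 0.002 rule (weight = rho);
related–related edges are included so communities can mix targeted and
related chemistry. Communities come from seeded Louvain modularity
maximization (networkx), with labels renumbered deterministically.

## Preprocessing

- **Filtering**: a feature is dropped when the median across subjects of
  its replicate CV (SD/mean, raw scale) is ≥ 100%, or when it is
  detected (≥ 1 replicate non-missing) in < 60% of subjects. The
  subject-median CV and the permissive "detected" definition are package
  decisions where the procedure is otherwise underdetermined.
- **Batch correction**: per feature, each analytical batch's ln
  intensities are standardized and rescaled to the pooled mean/SD. This
  location/scale standardization replaces empirical-Bayes ComBat
  shrinkage: with the generator's per-feature additive batch shifts the
  two coincide in expectation, and the simplification keeps the stage
  dependency-free and transparent. Batch-constant features pass through
  with a warning; batches need ≥ 3 subjects.
- **Left-censored imputation**: per feature, a normal law is fitted to
  observed ln intensities and missing cells are drawn from the fitted
  law truncated above at the observed minimum — the same censoring
  geometry as quantile-regression imputation (QRILC) but with a
  complete-case fit; far simpler and adequate at the ≤ 10% missingness
  the filters leave behind.
- **Targeted panel**: per congener, a censored log-normal MLE (observed
  density + censored-mass term at the LOD) and single imputation by
  E[X | X < LOD] under the fitted law. Recovery of (μ, σ) within 10% at
  n = 500 with 20% censoring is tested.

All downstream analyses use natural-log intensities and exposures.

## MWAS

OLS of each ln feature on ln exposure + age + factory + BMI (model 1),
adding smoking (2 indicators) and alcohol (model 2). Model 1 is the
default; model 2 is retained as a sensitivity flag. The factory (or
smoking) indicator is dropped automatically with a warning in
single-level subsets, which makes per-factory subgroup runs safe. The
scan is vectorized over features through one normal-equations solve per
exposure; coefficients and SEs match an explicit per-feature oracle to
1e-8 (tested) and null p-values are KS-uniform.

BH q-values are computed within each exposure × mode family
(statsmodels step-up), flags at q < 0.20. Aggregation mirrors the
summary-table semantics: per congener and mode, counts of features
significant for the congener itself, for ≥ 1 of its related compounds
(NA when it has none), and their union; subclass rows are unions across
congeners. The three per-subclass significant-feature lists (overlap
allowed) feed enrichment.

## Pathway enrichment

Features are annotated to putative metabolites when the observed m/z
matches an adduct transform of a neutral monoisotopic mass within
±5 ppm. Adduct sets are the standard positive-mode list (M+H, M+2H,
M+ACN+2H, M+Na, M+ACN+H, M+ACN+Na, 2M+H, M+H+H₂O) and negative-mode
list (M−H, M−H₂O−H, M+Na−2H, M+Cl, M+Hac−H, 2M−H) with monoisotopic
constants (proton 1.007276, Na 22.989770, ³⁵Cl 34.968853, ACN 41.026549,
acetic acid 60.021129, H₂O 18.010565).

The enrichment statistic is the one-sided hypergeometric tail of the
overlap between the significant-metabolite set and each pathway's
detected metabolites, within the detected-metabolite universe ("pathway
size" counts detected metabolites, matching the summary-table footnote
reading). Because the feature → metabolite map is many-to-many, the
null is calibrated by resampling feature lists of the same size
(n_perm = 1000 by default) and comparing hypergeometric scores:
perm_p = (1 + #{perm ≤ obs}) / (n_perm + 1). This empirical permutation
p replaces the gamma-fit null adjustment of the original m/z-level
enrichment tool — transparent and essentially exact at this scale. A
pathway passes at perm_p < 0.05 with ≥ 4 significant metabolites; the
minimum-overlap rule is absolute (a 3-metabolite overlap never passes).

## Integration

Enriched pathways are summarized per subject by PC1 of their significant
features' z-scored ln intensities (both modes pooled per pathway). The
PCA sign is fixed so the loading of largest magnitude is positive —
necessary for reproducible downstream networks. Integration runs on the
factory-A subset by default, where the immune markers are informative.

Pathway scores X and markers Y (both standardized) enter a PLS2 fit with
n_comp = 3 components (exposed as a parameter); the association score is
the model-reconstructed cross-correlation S = XᵀXB/(n−1) with B the
truncated-model coefficients, clipped to [−1, 1]. This definition is
anchored by two exact properties, both tested: with a single X and Y
column it equals the Pearson correlation, and at full rank S equals the
sample cross-correlation matrix. The p-value treats S as a correlation
on n−2 df; edges are kept at |S| > 0.3 and p < 0.05 and the bipartite
network is partitioned by the same seeded Louvain step.

## Synthetic cohort: what it emulates, and what it does not

Defaults (the conditions every test runs under): 137 subjects (76 A /
61 B) with factory-specific age/BMI distributions, log-normal congener
marginals under an equicorrelated Gaussian copula per subclass
(ρ = 0.5 PCDD / 0.2 PCDF / 0.92 PCB, reproducing "PCBs highly rank-
correlated, PCDFs weakly"), a ~50-fold factory contrast in median TCDD,
LODs at the 10th background percentile with flagged (not zeroed)
censoring; 800 GC features containing 60 chlorinated compounds (1–8 Cl,
binomial envelopes, 5% multiplicative noise, RT jitter 0.2 s) of which
30 correlate at r = 0.8 (ln scale) with randomly chosen congeners, plus
200 decoy compounds (half with a ¹³C M+1 distractor); 1,500 metabolome
features per mode in triplicate across 2 batches (technical noise 0.08,
per-feature batch shifts SD 0.3), with one designated pathway per
congener subclass receiving 12 affected metabolites whose features carry
β = 0.5 per unit ln exposure (driver exposures: TCDD, 23478F, PCB126)
plus small age/BMI effects; 8% left-censored missingness; 2% deliberately
high-CV and 2% low-detection features to exercise the filters; and 54
immune markers of which 5 per planted pathway load at 0.8 on that
pathway's latent factor (the standardized ln driver exposure). The
reduced scale (vs ~11,000 chemical and ~17,000 metabolome features in
the emulated study) keeps a full pipeline run at seconds; a full-scale
configuration is provided.

Planted latent factors use the driver exposure itself as the shared
signal, so the "true" pathway–marker correlation at loading λ = 0.8 is
≈ λ·corr(PC1, exposure), comfortably above the 0.3 edge threshold.

Not emulated: profile-mode spectra and chromatographic peak shapes;
isotopologues other than chlorine (the ¹³C M+1 distractor is a fixed
intensity ratio, not a carbon-count model); RT drift; correlated
metabolite–metabolite biology beyond the planted exposure effects;
non-ignorable missingness other than left censoring; measurement units
for immune markers (generated as z-scores). Passing tests therefore
demonstrate the machinery recovers planted structure of the assumed
form — they do not certify behavior under matrix effects, annotation
ambiguity, or confounding structures the generator does not contain.

## Numerical notes and edge cases

- Determinism: every stochastic stage takes an explicit seed; the
  pipeline fans one global seed into per-stage seeds. Regeneration from
  an identical configuration is byte-identical (tested).
- Spearman and association p-values are exactly 0 only at |r| = 1, where
  the t statistic is infinite; these are mapped to p = 0 explicitly.
- Zero-variance features are excluded from clustering and selection with
  warnings, never silently.
- Degenerate imputation (feature SD = 0) falls back to observed-min − ε.
- Louvain community labels are renumbered by smallest member node so
  outputs are order-invariant at a fixed seed.
- Empty cases (no suspects, no significant features, no retained edges)
  propagate as empty tables/networks with warnings, not errors; the
  pipeline aborts with the failing stage named for genuine errors.

## Problem sizes used in the checks

Test and acceptance computations run at the generator defaults above;
calibration checks use 10⁵ null Spearman pairs at n = 137, 10⁴ null MWAS
features, 500-feature effect-recovery scans, 500 simulated noisy
envelopes, 100 seeded enrichment runs, and 20 end-to-end pipeline seeds
for chain recovery (the acceptance script reports a 5-seed rate).

## Known limitations

- The batch model is location/scale only; strongly outlying batches with
  feature-specific variance inflation would be better served by
  empirical-Bayes shrinkage.
- Single imputation (panel E[X|X<LOD], left-tail draws for features)
  understates imputation uncertainty in downstream SEs.
- The enrichment permutation resamples features uniformly, ignoring any
  intensity-dependent detectability structure.
- The PLS association p-value treats the truncated-model score as a
  plain correlation; a label-permutation p is the rigorous alternative
  and is straightforward to add where it matters.
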