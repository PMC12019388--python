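# Methods

This note documents the models behind each pipeline stage, the synthetic
study the package ships, the numerical choices, and what the tests do and
do not establish about real data.

## Bulk differential expression

Counts are modeled per gene as negative binomial across samples.  The
stage follows the standard count workflow for a two-group cohort design:

1. **Sample QC** — strict bounds on alignment metrics (total mapped reads
   > 30e6, non-scaled library reads > 3e6, unique mapped reads > 3e6,
   mitochondrial ratio < 10%).  All four inequalities are strict; a sample
   exactly at a bound is removed.
2. **TMM normalization.**  The reference sample is the one whose
   upper-quartile count proportion is closest to the across-sample mean
   (lowest index on ties, for determinism).  For each sample, M- and
   A-values are computed over genes with positive counts in both sample
   and reference; ranks outside the central 40% of M (30% trim per side)
   or the central 90% of A (5% per side) are discarded; the factor is 2 to
   the precision-weighted mean of the surviving M-values, with weights the
   inverse delta-method variances (lib − n)/(lib·n) summed over sample and
   reference.  Factors are rescaled to geometric mean 1, so effective
   library size = library size × factor.  Genes with zero counts in every
   sample are dropped first (their M-values are undefined); the count is
   logged.
3. **Log-CPM.**  Two documented variants: the reporting transform
   log2(CPM + 1) for expression summaries, and the modeling transform
   log2((count + 0.5)/(effective library + 1) × 1e6).
4. **Precision weights.**  A per-gene two-group-means fit on the modeling
   transform yields residual SDs; lowess (span 0.5, 3 robustness
   iterations) of sqrt residual SD against average log-count gives the
   mean-variance trend, interpolated linearly between lowess points and
   held constant outside their range.  Each observation's weight is the
   trend value at its fitted log-count raised to −4.  The trend needs at
   least 10 genes and 2 samples per group.
5. **Moderated inference.**  Per-gene weighted least squares for the
   disease − control contrast.  Residual variances are shrunk toward a
   scaled-inverse-chi-square prior fitted by method of moments on log
   variances: with e_g = log s_g² − ψ(d/2) + log(d/2), the prior df d0
   solves ψ′(d0/2) = Var(e) − ψ′(d/2) (Newton iteration on the trigamma
   inverse, relative tolerance 1e-12); non-positive moment estimates give
   d0 = ∞, i.e. complete shrinkage, handled with the normal reference
   distribution.  Moderated t uses the posterior variance and d + d0
   degrees of freedom; adjustment is Benjamini–Hochberg step-up.
   The sign convention — positive log2FC = higher in disease — is used in
   every module.

## Single-cell stage

Cells are kept when 200 ≤ features ≤ 4000, total molecules ≥ 1000, and
mitochondrial fraction ≤ 15% (removal bounds strict, retention bounds
inclusive).  Normalization is depth-scaled log1p with scale 1e4, stored as
a separate layer.  Variance-stabilizing transforms, batch integration and
embedding/clustering are intentionally out of scope: lineage identity
comes from a hierarchical marker gating model applied cell by cell, which
is what the downstream statistics consume, and the synthetic data carry no
batch structure.

A gate passes when at least `min_positive_detected` of its positive
markers are detected (raw count > 0) and no negative marker is detected;
assignment is the deepest gate whose entire ancestor chain passes.  If two
terminal gates pass simultaneously the cell is left unassigned (logged).
The default model encodes Lin−CD34+ HSPC with CD38− HSC and CD38+ GMP
children, and CD14+ monocytes.

Within a gated population, genes detected in at least 10% of cells in
either group are tested by Wilcoxon rank-sum on the normalized layer.  The
exact null distribution (dynamic-programming enumeration of rank subsets)
is used when the combined n ≤ 16 with no ties; otherwise the normal
approximation with tie and continuity corrections.  log2FC is the
difference of group means of log-normalized expression divided by ln 2 —
declared explicitly because marker-finding conventions differ between
tools.

## Proteomics stage

The pipeline order is fixed and asserted: filter → impute → normalize →
test.  Filtering removes contaminant-flagged proteins, proteins without a
unique peptide, and proteins missing in ≥ 50% of samples (the boundary is
removed), plus — for surfaceome work — proteins without membrane
annotation.  Imputation is feature-wise KNN: neighbors are the k = min(10,
n−1) nearest proteins by Euclidean distance on row-standardized log2
abundances over mutually observed samples (scaled by the number of shared
samples); a missing entry is filled with the distance-weighted mean of the
neighbors' values at that sample, each neighbor re-centered by the
difference of means over the mutually observed samples.  The re-centering
makes an exact-copy neighbor impute its own value and prevents abundance-
level offsets between correlated proteins from leaking into the
imputation; observed cells are never modified, and entries with no
eligible neighbor stay missing with a warning.  Median normalization then
shifts each sample in log2 space so its median equals the grand median of
the pre-shift sample medians — which absorbs any per-sample additive shift
exactly — and differential abundance is the shared Wilcoxon implementation
with BH.  The default significance level is adj. p < 0.05, with 0.2
available as the permissive alternative.  The unpaired rank-sum is the
only variant implemented: group sizes like 9 vs 3 cannot be paired.

At 9 vs 3 the exact two-sided Wilcoxon p cannot go below 2/C(12,3) ≈
0.00909; significance after BH therefore requires complete separation and
a sufficiently small tested panel — an inherent property of the design,
not of the implementation.

## Triage funnel and intersection

"Expressed" is operationalized as median CPM across disease samples ≥ 1
(configurable and recorded in the report).  The funnel applies, in fixed
order: expressed ∧ surface (membership in ≥ 1 of the three annotation
resources) → enriched (adj. p < 0.05 and log2FC > 0; an optional log2FC
floor is exposed because enrichment definitions sometimes add one) →
tissue-safe (removed iff median TPM > 20 in any non-exempt tissue; Whole
Blood, Spleen and EBV-transformed lymphocytes are exempt; genes absent
from the reference are excluded with a warning) → stringent (log2FC >
6.5, strict).  All thresholds live in `TriageConfig`; tightening any of
them can only shrink downstream sets.

The cross-modal intersection computes six cardinalities: single-cell hits
(adj. p < 0.05, log2FC > 0), protein hits mapped to symbols through the
explicit ID map (unmapped accessions logged and excluded; symbols matched
after uppercasing, no alias resolution), their overlap, the
tissue-safety-filtered version of each hit set, and the final common set.
RNA-protein correlation is Spearman's rho between mean log2(CPM+1) and
mean log2 abundance over mapped pairs (≥ 10 required).

## Flow quantitation

MFI is the median by default (geometric mean available for bead peaks).
Positivity is MFI(stained)/MFI(FMO) strictly above 1.5.  Percent positive
counts stained events above the FMO 99th percentile.  The staining index
is (median_pos − median_neg)/(2 × robust SD_neg) with robust SD the
84.13th-percentile-minus-median spread; the formula is the field's
standard since instrument vendors differ.  Bead calibration is least
squares of log10(molecules) on log10(MFI); antigens per cell is the
fitted line evaluated at the cell MFI, reported as antigen density under
the Quantibrite convention of one PE per antibody.  Cytotoxicity is 100 ×
treated/UTD signal, uncapped, with values above 100 flagged.

## The synthetic study

The generator emulates the study conditions end to end with planted
ground truth; every quantity is fully determined by the seed (independent
numbered streams per generator, so calling order does not matter).

* **Bulk**: 600 genes × (20 disease + 10 control) samples, negative
  binomial with dispersion 0.1, baseline means 2^U(3,9) counts, log-normal
  library-size factors (σ = 0.2).  The 45-gene surface panel: 3
  cross-modal targets (bulk log2FC 8, single-cell 3, protein 3,
  tissue-safe, all three annotation sources), 6 high-fold-change but
  tissue-unsafe genes (bulk 7.5; two of them also single-cell + protein
  hits), 12 moderately enriched safe genes (bulk 3.5), 2 single-cell-only
  and 2 protein-only hits, 15 surface nulls, and 5 unexpressed surface
  genes.  Ground-truth funnel counts (40, 21, 15, 3) and intersection
  cardinalities (7, 7, 5, 5, 5, 3) follow from these parameters alone.
* **Single cell**: 8 donors × 150 cells, lineage mixture HSC 35% / GMP
  25% / monocyte 40%, Poisson counts with log-normal per-cell depth
  (σ = 0.05); markers at mean 8 when "high" and exactly 0 when "off", 250
  background genes (mean 4) giving every cell a realistic feature count,
  16 housekeeping genes (mean 60), 5 mitochondrial genes.  Planted QC
  failures (5% of cells by default) cycle through three modes — shallow
  depth, inflated mitochondrial content, few features — and are recorded
  exactly.  Two deliberate design features keep null genes null after
  depth normalization: expression shares are zero-sum, so the housekeeping
  block carries a computed compensating factor that balances the planted
  effects per lineage, and the background block carries a mild
  disease-down tilt (−0.085 log2) so the compensation stays on the
  negative side.  Real data have no such balance — compositional spillover
  is a genuine effect there — so passing the null-exactness tests says the
  statistics are correct, not that composition effects are absent in
  practice.
* **Proteomics**: the study-scale 9 vs 3 design; log2 abundances normal
  with σ = 0.5 around baselines that track the bulk means (so RNA-protein
  correlation is positive by construction), planted hit effects of 3 log2
  units (complete separation with near certainty at these sizes),
  missing-at-random at 10%, plus planted contaminants, zero-unique-peptide
  rows, high-missingness rows and unmapped accessions.  The tested panel
  size is even by design (28), because median normalization pins each
  sample's median protein to one exact value and an odd panel can create
  exact cross-sample ties that force the rank test off its exact path.
* **Tissue reference**: 15 tissues (3 exempt hematopoietic).  Safe genes
  stay ≤ 8 TPM in non-exempt tissues; unsafe genes carry explicit
  overrides above 20; surface genes run to hundreds of TPM in the exempt
  tissues, exercising the exemption.
* **Flow**: one stained/FMO pair of 10,000 events; background log-normal
  (median 50, σ = 0.4), positive fraction 60% at a median intensity placed
  on the bead calibration line so the planted density of 5000 antibodies
  per cell round-trips; four noiseless bead populations by default.

Because BH false positives among tested nulls occur at rate ≈ α(k+1)/m
per null regardless of sample size, exact agreement between realized hit
sets and parameter-level ground truth is guaranteed only because most
non-hit tested genes carry a small planted negative shift, leaving small
honest-null panels.  The residual probability of a single spurious hit
somewhere in the bundle is a few percent per seed; the shipped study uses
seed 1.

## Test-suite conditions and sizes

Oracle checks: exact Wilcoxon vs full enumeration for all group sizes up
to 8+8; BH vs the literal step-up formula on 1000 random vectors (1e-12);
TMM vs a scalar re-evaluation of the trim-and-weight formula on 200-gene
fixtures (1e-9); moderated t / adjusted p vs an explicit-matrix
re-implementation with an independent root finder on 50-gene slices
(1e-8).  Calibration: a 5000-gene null bulk study (type-I error within
[0.04, 0.06] at α = 0.05), single-cell null p-values pooled over four null
studies (KS uniformity at α = 0.01), protein null uniformity at 20 vs 20 —
the 9 vs 3 exact null is a coarse lattice for which a two-sided KS test
rejects any correct implementation, so at the study design super-uniformity
(P(p ≤ α) ≤ α) is asserted instead.  Recovery: mean bulk estimate of a
planted log2FC of 3 within ±0.3 at 20 vs 10 (the per-gene sampling SD is
≈ 0.15, so the mean over 12 planted genes is the stable quantity; a small
negative bias from the +0.5 modeling offset is visible at low counts);
protein power ≥ 80% at 9 vs 3 for log2FC 2; single-cell planted markers
recovered at FDR < 0.05 with ≈ 210 vs 210 HSCs.  Funnel: exact ground-truth
agreement on the seed-1 bundle and ≥ 95% recall with zero decoys over 20
seeds of a strong-target/weak-decoy study.

## Known limitations

* The generator's negative binomial has constant dispersion; no
  gene-specific dispersion trend, outlier samples, or batch structure.
* Single-cell counts are Poisson given the rate (no zero inflation or
  doublets), and the composition balance described above is a simulation
  device, not a property of real data.
* The lowess trend differs in smoothing details from other
  implementations of the same idea; weights agree qualitatively, not
  bitwise, with any particular external tool.
* Missingness in proteomics is missing-at-random by default; an
  intensity-dependent mode (logistic bias toward low-abundance values,
  overall rate preserved) exists because KNN imputation behaves
  differently under the two, but no mechanistic detection model is
  implied.
* The funnel nominates candidates; it makes no claim about clinical
  targetability, antibody availability, or antigen density sufficiency.
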