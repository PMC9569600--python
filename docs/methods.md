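# Methods

This note records the statistical models implemented in `saltscan`, the
parameter choices and their rationale, the synthetic-panel generator's design
and limits, and the numerical decisions that affect results.

## 1. Germination and seedling traits

Daily counts `N_i` (new germinations on day `i`, `i = 1..10`) from `S` sown
seeds per replicate give:

| Trait | Formula | Units |
|---|---|---|
| GP | 100 · ΣN_i / S | % |
| GRI (cumulative) | mean over days of the running cumulative % | %/day |
| GRI (daily) | Σ (daily % increments / day count) = GP / 10 | %/day |
| CVG | 100 · ΣN_i / Σ(N_i · i) | %/day |
| GI | Σ (11 − i) · N_i, counts as fractions of S by default | — |
| MGT | Σ(i · N_i) / ΣN_i | day |
| SVI | GP × SL | — |
| SL, RSR | ShL + RL, RL / ShL | cm, — |
| WCP | 100 · (SFW − SDW) / SFW | % |

CVG and MGT are exact reciprocals up to the factor 100 (CVG × MGT = 100), which
the tests exploit as an identity. Replicates with zero germination get GP = GRI
= GI = 0 and missing CVG/MGT (undefined, not zero); their seedling
measurements are missing by construction.

Two conventions are genuinely ambiguous in the screening literature and are
therefore configuration options rather than fixed choices:

- `gri_variant`: `"cumulative"` (default) averages the running cumulative
  germination percentage over days; `"daily"` averages the per-day increments
  and collapses to GP/10.
- `gi_count_scale`: `"fraction"` (default) weights day counts as fractions of
  seeds sown, giving GI ≤ 10; `"count"` uses raw counts.

## 2. Stress indices

For each of eight traits (GP, MGT, ShL, RL, SL, SFW, SDW, WCP) the Fernandez
stress-tolerance index is

STI = (Y_p · Y_s) / X̄_p²

with Y_p, Y_s the accession's control and salinity means and X̄_p the control
population mean over accessions present in both treatments. MGT is *not*
inverted: a large MGTTI reflects slow germination under both conditions, and
the index is reported as-is so its interpretation stays uniform across traits.
Panel-level response is R% = 100 · (mean_salt − mean_ctrl) / mean_ctrl.

## 3. Quantitative genetics

Per trait and treatment: one-way fixed-effects CRD ANOVA over accessions
(per-cell counts, so unbalanced data are handled exactly); combined two-way
ANOVA with accession, treatment and interaction via sequential (type-I) sums
of squares on cell means. Derived statistics: CV% = 100 · √MS_e / mean,
R² = SS_model / SS_total, and broad-sense heritability on the replicate-mean
basis:

σ_g² = max(0, (MS_accession − MS_e) / r),  σ_p² = σ_g² + σ_e²/r,
H_b = 100 · σ_g² / σ_p².

Negative variance-component estimates are truncated to zero and flagged.
LS-means come from least-squares on the accession indicator design; with
complete replication they equal arithmetic means. Correlations are Pearson with
pairwise deletion and a t-test p-value, starred at 0.1/0.05/0.01/0.001.

## 4. Multi-locus GWAS

Genotypes are inbred biallelic calls stored as a major-allele indicator
(1 = homozygous major), so every effect estimate is the effect of the major
allele. Preparation: intersect accessions (≥ 20 required), drop markers with
missing rate > 0.2, monomorphic markers, and markers below the MAF floor;
impute remaining missing calls to the observed major-allele frequency.

**Cofactor discovery.** 100 subsamples (default) of 80% of accessions; within
each, forward selection under SBC = n · ln(RSS/n) + k · ln(n) (k counts the
intercept; ties broken toward the smaller marker index), capped at
min(n/10, 50) terms and restricted to the top 500 markers by marginal F for
tractability (configurable off). The prefix of the forward path minimising
held-out mean squared error on the left-out 20% is kept. Markers kept in ≥ 2
subsamples are *potential cofactors*; a final forward-SBC pass over the
potential set on the full data fixes the cofactor set and its entry order.

**Scan.** Each marker is tested entered last after the cofactors: sequential
type-I F-test, partial R² = 100 · SeqSS / SS_total(corrected). A cofactor's own
test is the sequential test at its entry position — conditioning only on
cofactors entered before it. This matters: conditioning a cofactor on all
*other* cofactors (which were themselves selected on the same response)
deflates the residual and inflates the null family-wise error rate to ~0.2 at
panel scale; the sequential form is calibrated (measured FWER 0 over 100 null
panels). A non-cofactor that is numerically collinear with the cofactor set
drops its most-correlated cofactor before testing.

**Multiplicity.** Bonferroni over the m surviving markers, significance at
adjusted p < α (default 0.05).

## 5. QTL merging and annotation

Significant SNPs are merged per phenotype and chromosome by single linkage
within `qtl_merge_bp` (default 1 Mb); the lead marker is the smallest raw p.
The merge window is an explicit design choice, not an estimate of linkage
extent, and is configurable. Candidate genes are all gene models overlapping
±`flank_bp` (default 100 kb) around each significant SNP, with the relation
(contains_snp / upstream / downstream) and the distance to the nearer gene
edge; coordinates are 1-based inclusive (GFF3 convention).

## 6. Synthetic panel generator

- **Genotypes.** Markers in blocks of `ld_block_len` (default 10): an anchor
  column drawn at a frequency from `maf_range`, copies equal to the anchor with
  probability `within_block_corr` (default 0.9) and fresh draws otherwise.
  Expected r² is c² for anchor-copy pairs and c⁴ for copy-copy pairs; tests
  check the closed form. Calls are recoded after sampling so stored 1 is always
  the observed major allele. Positions are uniform over 7 chromosomes of
  700 Mb.
- **Latent tolerance.** Sum of planted QTL effects (default four loci with
  effects 0.8/0.7/0.6/0.6 at spread-out positions) plus a polygenic normal
  term (SD 1.0). Left unstandardised so that a single strong locus yields an
  exactly two-class latent variable, which the tests rely on.
- **Germination.** Per seed: germination with probability
  invlogit(2.5 − 1.2 · (salt − tolerance)), day of germination a clamped
  rounded normal, mean 3.0 + 0.6 · salt − 0.3 · tolerance, SD 0.8, days 1–10.
- **Seedling measurements.** value = mean · mult^salt + genetic term + noise,
  with control means ShL 10.2 cm, RL 11.1 cm, SFW 291 mg, SDW 30 mg and
  salinity multipliers 0.63/0.66/0.69/1.25 (dry weight *rises* under salt,
  reproducing the osmotic-adjustment pattern of real screens; WCP then falls).
  The noise SD is calibrated from a target heritability (`h2_target`, default
  0.85) on the replicate-mean basis, so H_b recovery is a generator contract.
  SDW is clipped below 0.99 · SFW; zero-germination replicates yield missing
  measurements.

**Known limits.** (i) Ratio traits inherit little planted genetic signal: the
genetic term scales shoot and root measurements proportionally, so WCP and RSR
heritability is low (~5%) regardless of `h2_target` — the calibration contract
covers the primary measurements, not ratios of them. (ii) Germination traits
carry binomial sampling noise on top of the latent model, so their realised
heritability is below `h2_target`. (iii) The block-copy LD model has no decay
with distance within a block and zero LD across blocks; it is designed for
power/calibration studies, not for realistic LD-decay curves.

## 7. Numerical choices

- Forward selection uses incremental Gram–Schmidt orthogonalisation (rank-1
  updates of projections and column norms), making a full subsample scan at
  192 × 2000 run in under a second; held-out MSE is computed by refitting each
  path prefix with `lstsq`.
- Collinearity threshold: a marker is treated as collinear with the cofactor
  design when its residual norm² falls below 1e−8 of its centred norm².
- p-values are floored at the smallest positive double to keep −log10(p)
  finite; selection stops when RSS falls below 1e−12 of the intercept-only RSS.
- Per-phenotype RNG streams are spawned from a single `SeedSequence`, so
  results for a given phenotype are independent of which other phenotypes are
  scanned.

## 8. Scope of the tests

The test suite asserts only quantities it computes itself: closed-form
identities, hand-worked examples, independent oracle implementations
(exhaustive all-subsets SBC search, textbook regression/ANOVA solutions) and
calibration properties of simulated panels (null family-wise error rate,
planted-locus recovery, heritability recovery). No empirical result from any
external dataset is asserted, because no such dataset ships with the package;
panel-scale numbers appearing in tests are inputs to arithmetic checks, not
reproduced findings.
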