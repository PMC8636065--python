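# Methods

`bxdtwas` implements a strain-panel transcriptome-wide association (TWAS)
analysis of the kind used with BXD recombinant-inbred mice: because every
mouse of a BXD strain is genetically identical, a trait measured in one
cohort (hearing acuity) can be joined at the strain level with a
transcriptome measured in another cohort (hippocampus microarrays), and each
transcript can be screened for correlation with the trait.

## Model and procedure

**Trait.** The auditory-evoked brainstem response (ABR) threshold is the
lowest stimulus level (dB SPL) evoking a reproducible response; higher means
worse hearing. Each mouse is tested at 8, 16 and 32 kHz. The strain-level
hearing acuity is a two-step mean: individuals are averaged within each
frequency, then the per-frequency strain means are averaged. The two-step
order matters when individual counts are unbalanced across frequencies and
is therefore a tested contract, not an implementation detail. When no
response occurs at the loudest tested level, the threshold is recorded at
that ceiling and enters the mean at face value (right-censoring is not
modeled; the recorded maximum is what the stepping protocol produces).
Individuals are pooled across sex. Single-frequency aggregation is available
for per-frequency analyses.

**Expression scale.** Arrays are assumed RMA-processed and log2-scaled
upstream (out of scope here). Each array (strain column) is re-normalized to
the *modified Z* scale: `2 * zscore(x) + 8`, giving every array mean 8 and
SD 2. The z-score uses the sample (n−1) SD — the convention is arbitrary at
array scale (thousands of genes) but is fixed so results reproduce
bit-for-bit. A zero-variance array is an error, not a NaN column.

**Screen.** For each gene, Pearson r between expression and trait over the
shared strains; the two-sided p comes from the exact transform
`t = r·sqrt(n−2)/sqrt(1−r²)` with n−2 df. The analytic significance
boundary on the correlation scale is `r* = t*/sqrt(t*² + n − 2)`; at n = 26
and α = 0.05, r* = 0.388. Genes can additionally be filtered by the
moderate-correlation rule |r| > 0.3; both filters are independent and
optional because screens of this design are reported under either
convention.

**Multiple testing.** Family-wise error is controlled by the Westfall–Young
single-step maxT procedure on |r|: the trait vector is permuted over strain
labels B times (default 1000), expression held fixed; per permutation the
maximum |r| over all genes is recorded; the adjusted p is
`(1 + #{b: M_b ≥ |r_obs|})/(B + 1)`. Permuting only the trait preserves the
gene–gene correlation structure, which is what makes maxT valid (and exact
under the global null) under arbitrary dependence. Ties use ≥
(conservative); the +1 keeps p > 0. Two repairs are applied and worth
stating: the finite-B estimator is not mathematically guaranteed to dominate
the analytic raw p, so `p_adjusted = max(p_maxT, p_raw)` is enforced; and
the step-down refinement (successive maxima with monotonicity enforcement)
is available behind a flag but is not the default. Note this procedure
controls FWER; screens of this kind sometimes label the threshold an "FDR",
which is a misnomer we do not adopt — the column is `p_adjusted`.

**Co-expression network.** Over a caller-supplied gene list (the pathway
module), all-pairs Pearson r across strains; an edge is kept iff |r| strictly
exceeds the threshold (default 0.3) and carries the signed r. Per node:
degree, connection weight (sum of |r| over incident edges), and average
weight. The *absolute* convention for connection weight is an interpretation
choice: a hub with mixed-sign edges still has large positive weight, which
matches how hub weights are reported in practice; signed sums are emitted
alongside. The hub maximizes degree, ties broken by absolute weight, then
lexicographic gene id (a deterministic, documented tie-break).

**Enrichment.** Hypergeometric upper tail (over-representation only) of the
query list against each GMT set, with expected overlap `n·K/N` and
enrichment ratio `k/expected`; Benjamini–Hochberg FDR across the sets of one
collection. The default background is the genes measured on the platform —
correlation candidates can only come from measured genes — and a
genome-wide background can be supplied explicitly; the two give different
p-values, which is why the choice is a visible parameter.

**PheWAS.** One gene's strain-level expression against each published
phenotype over the pairwise-complete strain overlap, using the same Pearson
code path as the screen. Phenotypes with overlap below `min_n = 6` are
reported as skipped, never silently dropped; below ~6 strains the t-based p
on r is uninformative. No multiple-testing correction by default (such scans
conventionally report unadjusted correlations); BH is available behind a
flag with a warning.

**Age confound.** OLS of a gene's expression on strain age (months), slope p
from t with n−2 df, as a check that a trait association is not an age
artifact in an aged panel.

## Synthetic panel generator

The generator (`bxdtwas.simulate`) emulates the statistical structure the
analysis assumes, with planted ground truth for recovery testing. Defaults
are the study conditions, not tuning knobs:

| parameter | default | meaning |
|---|---|---|
| `n_strains` | 26 | strains shared between cohorts |
| `n_genes` | 2000 | transcripts measured |
| `n_associated` | 50 | planted trait-associated genes |
| `target_r` | 0.6 | planted strain-level \|r\|, signs alternating |
| `module_size` / `hub_edge_r` / `hub_loading` | 9 / 0.6 / 0.95 | one-factor module; hub carries the largest loading |
| `module_trait_r` | 0.5 | module-factor coupling to the trait |
| `abr_mean_db` / `abr_sd_db` / `ceiling_db` | 71 / 18 / 100 | latent strain ABR distribution and censoring ceiling (dB SPL) |
| `individuals_per_strain` | 4 | mice per strain |
| `within_strain_sd_db` | 8 | within-strain ABR noise (free parameter; real within-strain variance is not published) |
| `frequency_offsets_db` | (0, +5, +10) | worse hearing at higher frequency |

A latent trait T ~ N(71, 18²) is drawn per strain; mouse × frequency
thresholds are T + offset + N(0, 8²), clipped to [0, 100] (ceiling
censoring). Associated genes are `±(r·z_T + sqrt(1−r²)·ε)` so the expected
*strain-level* correlation is ±`target_r` — effects are planted at the
strain level because that is the unit of analysis. Module genes load on one
shared factor that is itself correlated 0.5 with z_T (module genes in real
screens are trait-correlated); the hub's loading 0.95 versus members' 0.6
makes expected hub–member |r| ≈ 0.57 and member–member |r| ≈ 0.36, so at
n = 26 member–member edges drop below the 0.3 threshold far more often than
hub edges — that asymmetry, not a label, is what makes the hub recoverable.
Remaining genes are independent Gaussian noise, and every strain column is
finally rescaled to mean 8 / SD 2 exactly (the modified-Z array scale). The
phenotype table holds 20 phenotypes, 5 coupled to the module factor at
r ≈ 0.6 (emulating learning-related traits), the rest null, each missing a
random ~25% of strains. The gene-set collection holds the planted pathway
(the associated genes) plus nine size-matched random decoys. All randomness
flows through one `numpy.random.default_rng` (PCG64) seed; identical configs
give bit-identical panels.

`simulate_null_panel` keeps the module's gene–gene correlation (real
transcriptomes are dependent) but couples nothing to the trait and empties
the truth lists; it is the global null for error-rate calibration.

**What the generator does not emulate:** genotypes and QTL architecture
(the analysis never uses them), heavy-tailed or heteroskedastic expression
noise, batch structure, probe-level artifacts, and realistic gene–gene
correlation outside the one planted module. Passing recovery tests
therefore show the pipeline is correct under its own assumptions, not that
those assumptions hold for any real dataset.

## Numerical choices and degenerate inputs

- Zero-variance genes are excluded from the screen with their ids recorded;
  a zero-variance trait or array column is a hard error.
- |r| is clipped to [−1, 1] before the t transform; |r| = 1 maps to the
  smallest positive double rather than p = 0.
- Alignment uses sorted strain order and exact name matching (whitespace
  trim + BXD-prefix case normalization only); fewer than 6 shared strains
  is an error.
- Expression files must be complete; only phenotype tables may contain
  missing cells (`NA` or empty). Numbers parse in C locale; a decimal comma
  is a named load error.
- The pipeline report is JSON with sorted keys, so identical config + seed
  gives a byte-identical report.

## Problem sizes used in the checks

The calibration and recovery studies run at the panel's own scale: FWER is
estimated from 200 null panels of 200 genes × 26 strains with B = 200
permutations each; power/pathway/hub recovery from 100 panels at the default
2000 × 26 size; the planted-correlation calibration at 200 strains where
sampling noise on r is small. These sizes put Monte-Carlo error well inside
the 3-standard-error acceptance bands while keeping any single study under a
minute on one core.

## Known limitations

- The maxT adjustment controls FWER, not FDR; with thousands of genes and
  modest n it is conservative for discovery counts.
- Ceiling censoring biases the strain trait downward for the worst-hearing
  strains and attenuates correlations; the pipeline inherits this from the
  measurement protocol rather than modeling it.
- The enrichment module tests over-representation only (no depletion, no
  topology-aware pathway scoring).
- Network analysis is restricted to a supplied gene list; there is no
  module discovery (no WGCNA-style soft thresholding).
- `scripts/gn711_integration.py` reproduces the real-data headline numbers
  only when the GeneNetwork accession files are supplied manually; nothing
  in the package downloads data.
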