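# Methods

This note documents the models and procedures implemented in `somarvas`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical choices that matter.

## Somatic features

65 features are computed per tumor sample; 9 raw counts (total SNVs,
total indels, the seven substitution-class counts) are excluded before
component extraction because the signature exposures already carry that
information, leaving 56. Count-derived features are log2(x + 1); the
X-hypermutation ratio uses pseudocount 0.1 on both per-Mb rates; the WGD
count is floor(ploidy/2) with pseudocount 0.1; ploidy is log2 with no
pseudocount (ploidy > 0 always).

Minimum-count rules make a feature *missing*, never zero: the replicative
strand ratio needs ≥ 20 qualifying substitutions in the extreme
fork-polarity deciles, the CTCF ratio ≥ 10 SNVs in core + flank, the four
regional-density coefficients ≥ 30 SNVs, and the mitochondrial count
requires adequate mitochondrial coverage plus variant allele frequency
≥ 3%.

**Pseudocounts on ratio features.** The transcriptional strand ratios add
1 to both numerator and denominator. The replicative and CTCF ratios
adopt the same +1 convention for zero-safety; the minimum-count rules
make the effect negligible. The CTCF ratio uses raw counts, not per-bp
rates, although the flanking region is roughly 25× the core footprint —
the ratio is interpreted relative to its cohort distribution, not as an
absolute rate.

**Replicative strand bias.** Fork polarity is the signed derivative of
replication timing averaged per 10 kb; its deciles partition covered
windows. Only the two highest (reference strand predominantly leading)
and two lowest deciles enter. From the reference strand, T>C, T>G, G>A
and C>A are counted as leading or lagging; a substitution whose
complement is one of the four types counts on the opposite strand
(an A>G on the leading reference strand is a lagging T>C). The ≥ 20 rule
is read as ≥ 20 *total* across the four types.

**Signature fitting.** Exposures are non-negative least squares against
the signature catalog, with a bootstrap filter: a signature keeps its
exposure only if its fitted fraction exceeds 5% of the mutation burden in
at least 95% of multinomial channel-count bootstraps, otherwise it is set
to 0. Exposures are then mapped to the reference signature set by the
catalog's conversion matrix (identity for the synthetic catalogs) and
log2(x + 1)-transformed. This deliberately trades sensitivity for
resistance to signature mis-assignment at low mutation counts.

**Regional mutation density.** Four negative-binomial regressions of
binned mutation counts:

    count ~ RT + type + offset(ln bp)
    count ~ RT + DNase + type + offset
    count ~ RT + expression + type + offset
    count ~ RT + H3K36me3 + type + offset

with the latest-replicating / zero-signal bin as the reference level. The
feature is the top-bin coefficient (earliest RT, highest signal);
coefficients with standard error > 100 are discarded as non-converged.
The mutation-type covariate has 7 classes in exome-style mode (C>T split
at CpG) and 96 trinucleotide channels in genome-style mode; exome mode
also merges the small bins (RT 1∪2, H3K36me3 1∪2, expression 0∪1,
DNase 1∪2). Dispersion is estimated by maximum likelihood; when the NB
fit fails or diverges the model falls back to Poisson, which leaves the
rate coefficients consistent.

Coordinates are 0-based half-open internally; BED tracks are native,
MAF/VCF-style tables are converted at I/O.

## Components

Per cohort, features are median-imputed (samples missing > 20% of
features are dropped first) and z-scored before cohorts are concatenated;
a zero-variance feature within a cohort is an error rather than a silent
NaN factory.

**ICA with stability clustering.** FastICA (negentropy/logcosh, whitened,
tolerance 1e-4, ≤ 1000 iterations) is rerun `n_runs` times (default 200)
under distinct seeds; non-convergent runs are excluded, and more than 10%
of them is an error. Unit-norm loading vectors are pooled and clustered
by PAM-style k-medoids on correlation distance (1 − r); mean, lowest and
second-lowest per-cluster silhouettes are recorded over the cluster grid.
Because signs flip randomly between runs, each true component appears as
a mirrored cluster pair, so the informative cluster number is twice the
component number. The automated selection rule — the largest candidate
whose mean silhouette at k = 2×components exceeds 0.8 with second-lowest
cluster silhouette above 0.5, falling back to the best mean silhouette —
stands in for a visual broken-stick decision and is always overridable.
Mirror pairs are deduplicated by greedy disjoint matching on the most
negative correlations (so the retained count is always clusters/2); the
kept member is oriented so its largest-|loading| feature is positive.
Contributions are squared loadings normalized to 1 per component; scores
are the least-squares projection of the input on the loadings.

**VAE.** A minimal dense VAE in numpy with manual gradients: encoder
heads with batch normalization and ReLU (an optional extra hidden layer
of width 2×latent), a tanh decoder on inputs min-max scaled to [−1, 1],
Glorot-uniform initialization, Adam, and a 90/10 train/validation split
stratified by sex × cancer type. The loss is the feature-summed mean
squared error plus β·KL, with β warm-started at 0 and increased by κ per
epoch, capped at 1. Defaults: latent 14, κ = 0.001, 100 epochs, learning
rate 2e-3, batch 64. κ was chosen from a small in-package grid: with the
ReLU-constrained log-variance head the latent noise scale is at least 1,
so a full KL weight collapses the posterior at this feature
dimensionality; a modest final β preserves reconstruction while keeping
the regularizer active. Selection metrics are the mean validation
reconstruction correlation and, when reference components are supplied,
the mean over them of the maximum |r| against any latent dimension.

Tissue enrichment per component × cancer type: two-sided Welch t-test of
the type against the rest plus Cohen's d (pooled-SD), with types under 3
samples reported NA; a tissue map aggregates mean d per tissue.

## Rare pLoF sets and QC

Quality/rarity filters (in order): PASS or LowGQX with GQX ≥ 10; in
gnomAD-PASS with GQX ≥ 10 or absent with GQX ≥ 20; gnomAD AF < 0.1%
overall **and in every subpopulation**; within-cohort site frequency
< 1%; present in the matched tumor when tumor calls exist. Sets: I PTVs
only (frameshift indels, stopgain/stoploss/startloss, splicing — where
splicing includes SpliceAI donor/acceptor loss > 0.8); II/III add
missense at CADD ≥ 25 / ≥ 15; IV/V are missense-only by MTR ≤ 25th or
CCR ≥ 90th percentile. All sets then pass the PEXT filter (> 0.1 in the
matched tissue, mean PEXT when unmatched, skipped for splicing variants)
and the terminal-exon exclusion, excepted for CADD ≥ 15 or predicted
splicing effect. Sets I ⊆ II ⊆ III by construction; IV and V never
contain PTVs.

Cohort QC: variant-count outliers (mean ± 1.5 SD), MAF > 5% refilter,
heterozygosity (± 3 SD), Hardy–Weinberg exclusion (p < 1e-6), LD pruning
(window 50 *variants*, step 5, r² > 0.2 — a 50-bp window would be nearly
empty, so the window is read in variants, standard practice), pairwise
relatedness by a method-of-moments PI-hat (allele-frequency-standardized
genotype products estimating 2×kinship: ~1 duplicates, ~0.5 first-degree)
with removal of one of each pair above 0.185, PCA, trimmed k-means
(k = 10, 1% trim) with ancestry clusters selected by anchor labels
(clusters majority-composed of anchor samples are kept — a single
homogeneous population fragments across k = 10 centroids, so selection
is by cluster set, not a single cluster), and a final PCA giving 6 PCs.
Note the ± 1.5 SD count rule removes ≈ 13% of a clean Gaussian cohort by
construction; real cohorts' heavy-tailed count distributions make it far
less aggressive.

## Inheritance and LOH

LOH is assigned per gene–sample from copy-number segments (classes LOH,
DUP-LOH, LOHgain, cnLOH), excluded when the rare variant's tumor VAF is
below its normal VAF unless both exceed 0.8; without segments, the
fallback calls LOH when tumor − normal VAF > 0.25 **and** tumor VAF
> 0.8; a minor-allele-ploidy mode calls LOH below 0.4 with the same VAF
exclusion. Where alternative phrasings of the VAF conditions exist, the
unambiguous one is used for all modes, with the fallback's 0.8 bound
applied to the tumor. Two distinct qualifying variants in one gene count
as the biallelic state without phasing.

Encodings: dominant 1 for any carrier; additive 2 for carrier + LOH or
biallelic variants, else 1 for carriers; recessive 1 for the biallelic
state, with monoallelic carriers *excluded* from that gene's test rather
than scored 0. LOH without a carrier variant has no effect (logged).
Pointwise, additive ≥ dominant and recessive = 1 implies additive = 2.

## SKAT-O

For a gene's variant matrix G (samples × variants, encoded, excluded
samples removed) and the OLS null model with residuals r and variance
σ̂², the weighted, covariate-projected genotypes A give the score vector
s = Aᵀr, the burden statistic Q_B = (Σsⱼ)²/σ̂² and the SKAT statistic
Q_S = Σsⱼ²/σ̂², combined as Q_ρ = ρQ_B + (1−ρ)Q_S over 10 evenly spaced
ρ ∈ {0, 1/9, …, 1}. Default weights are flat — variants are already
prioritized to pLoF, so no Beta(MAF; 1, 25) up-weighting is imposed,
though it is available. Per-ρ p-values use Liu-type moment matching on
the eigenvalues of R_ρ^{1/2}AᵀA R_ρ^{1/2}; the omnibus p integrates the
minimum-p statistic over the 1-df mixing variable (the ρ = 1 endpoint is
capped at 0.999 inside the integral; substituting x = u² removes the
density singularity, and an 800-point trapezoid suffices to ~1e-6). The
final p is clamped to [min_ρ p, 10·min_ρ p], the Bonferroni sandwich the
construction guarantees. For a single variant column the test reduces
exactly to the 1-df score test.

Permutation mode is the model-free oracle: residuals are permuted
(Freedman–Lane, since A is already projected), per-ρ empirical p-values
are ranks within the pooled draws, and the omnibus p is the
+1-corrected fraction of permutations whose min-p beats the observed.
Analytic and permutation p agree with Spearman r > 0.99 at null and the
permutation type-I error at α = 0.05 is within binomial error of
nominal (acceptance suite).

Covariates: age (median-imputed), sex, cancer-type dummies (pan-cancer
strata only; reference level lexicographically first) and the first 6
ancestry PCs. Genes are testable with ≥ 2 carriers in the stratum
(recessive: ≥ 2 biallelic samples). Burden directions come from the OLS
coefficient of the binary carrier indicator with the same covariates.

Scenario QC computes λ = median(χ²₁(p))/0.4549 per stratum × component ×
model × set; a scenario is excluded when ≥ 100 genes were tested and
λ ≥ 1.5. Empirical FDR: score-matrix rows are shuffled within cancer
type (jointly across components, conserving their correlation), testing
is fully re-run, and the per-stratum threshold at level q is the
q-quantile of the randomized p distribution; fewer than 100 randomized
p-values flags the threshold unstable. The random-gene-set FDR is the
ratio of random-list to candidate-list hit counts at the same threshold,
as a percent. A hit replicates when its matching-stratum validation test
passes the validation thresholds (1% or 2%) with the same burden
direction; one-sided randomization p-values elsewhere use
(1 + #{null ≥ obs})/(1 + N).

Both testing modes use statistics quadratic in the residuals, so hit
calls are not invariant to nonlinear monotone transformations of the
phenotype in either mode; component scores are treated as linear-scale
quantities.

## Network and prevalence

The interaction graph is a simple weighted graph; enrichment tests use a
score floor (0.8 by convention), prioritization the unfloored graph.
Internal connectivity counts edges within the hit set against 1000
degree-matched draws: hit degrees are split into 10 equal-count bins
(ties broken by stable order), universe genes are assigned by the same
bin edges, and each draw preserves the per-bin counts exactly. The
cross-tier test counts lower-tier genes with ≥ 1 top-tier neighbor under
the same null. Prioritization reports, per gene, the maximum edge weight
to known dHR (BRCA1, BRCA2, PALB2, RAD51C) or dMMR (MLH1, MSH2, MSH6,
PMS2) proteins against degree-matched non-known genes, or the maximum
weight to a neighbor within the hit network against 10,000 degree-matched
redraws (0 when isolated). All permutation p-values carry the +1
pseudo-count and can never be 0.

Prevalence: the carrier frequency of a gene set is the fraction of
samples with ≥ 1 qualifying variant in any set gene; controls are drawn
10 times per gene matched on integer-kb covered exonic length
(nearest-kb fallback within 1 kb, logged; a set gene is never its own
control). Control-population frequencies sum the database allele
frequencies of cohort-observed variants (cohort-only singletons dropped),
assuming at most one rare pLoF per individual; a sum above 1 warns.

## Synthetic data: what it emulates, and what it does not

The generator encodes the causal picture the analysis assumes: latent
mutational processes (non-Gaussian, Laplace-distributed) mix linearly
into the 56 retained features with per-feature Gaussian noise
(default SD 0.5); rare deleterious variants in causal genes shift one
latent process by a configured effect (default 1–1.2 SD) in carriers;
LOH marks a configurable fraction of carriers with the matching
tumor-VAF pattern; age and sex act on the first process; causal genes
form a high-weight module in an Erdős–Rényi interaction network.
Carriers are spread over several variant sites per gene so each site
stays under the 1% cohort-frequency filter; subpopulation allele
frequencies are Dirichlet-style perturbations of the overall AF, so the
every-subpopulation rarity filter is exercised. Mixing weights default
to sparse O(1) entries per feature — the conventional linear-mixing
benchmark, under which ICA recovers sources at |r| > 0.9 at n = 2000;
row-normalized loadings would cap recovery near 0.89 at this noise
level. Event catalogs are generated with per-sample Dirichlet signature
mixtures, planted replication-timing rate multipliers, transcriptional
and replicative strand-bias factors, and microsatellite-concentrated
short indels, so the feature extractors can be checked against closed
forms. A single seeded generator drives every draw; fixed seed gives
bit-identical outputs.

Deliberately not emulated: real human genome coordinates or
trinucleotide frequencies, read-level error processes,
linkage-disequilibrium structure beyond random common variants,
population stratification confounding of rare variants, and the
correlation of feature missingness with mutation burden. Passing tests
therefore demonstrate that the machinery is correct and calibrated under
the stated generative model, not that real-cohort confounding is fully
handled.

## Problem sizes used in tests and the acceptance script

Chosen as the package's own defaults for a desk-scale demonstration:
null SKAT-O calibration at n = 500 samples × 2000 genes × 2000
permutations; planted-effect FDR recall at n = 2000 samples, 500 genes,
10 causal genes with 40 carriers each; ICA recovery at n = 2000 with 50
stability reruns and the cluster grid bracketing the truth; the
negative-binomial recovery at 5×10⁴ events on a 10-Mb toy genome; the
end-to-end pipeline at 400–600 samples per cohort with 60–120 genes.
ICA stability defaults to 200 reruns and the full k = 2…50 grid when run
as in the real study.

## Known limitations

- The analytic omnibus p relies on moment matching rather than exact
  Davies integration; the permutation mode is the reference when the two
  disagree in extreme tails.
- The VAE's ReLU-constrained latent heads limit how much source structure
  the latents can carry at full KL weight; the shipped warm-start
  schedule is tuned for reconstruction fidelity, and ICA remains the
  primary decomposition.
- k-medoids uses a PAM-style alternating heuristic, not exhaustive PAM;
  with 200 reruns the pooled clusters are well separated and the
  difference has not been observed to matter.
- The pipeline's caching is stage-level by configuration hash; it does
  not track fine-grained file dependencies.
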