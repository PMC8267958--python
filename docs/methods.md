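# Methods

## The burden-enrichment statistic

For a cohort of n tumor samples and a query gene set G of size k, the
statistic is the union count U(G): the number of samples with at least one
retained somatic mutation in any member of G. The null distribution is
empirical — N random gene sets of size k are drawn uniformly without
replacement from the cohort's gene universe, independently across
iterations (the same set may recur), and

    p-total = #{i : U(Rᵢ) ≥ U(G)} / N.

The ≥ rule (rather than strict >) is used deliberately: it is the
conservative convention for empirical tail probabilities and keeps p-total
strictly positive whenever the observed count is attainable by a random
set. p-total is monotone non-increasing in U(G) and lives on the lattice
{0, 1/N, …, 1}; with the default N = 1000 its resolution is 10⁻³, so
"p-total = 0" means "< 1/1000", not literally zero.

**Sampling universe.** The universe is the set of genes with ≥1 retained
mutation in the cohort — what a MAF actually lists. Genes never mutated in
the cohort contribute nothing to any union count, so including them would
only deflate every random set's count by a constant factor; drawing from
the mutated-gene universe makes the null a like-for-like comparison. The
query set is *not* excluded from the universe by default (an
`exclude` / `--exclude-query-set` switch exists; exclusion makes the test
slightly anti-conservative for large effects). A custom universe can be
obtained by supplying a different gene universe through the matrix.

**Why a within-cohort null.** Union counts are strongly inflated by
hypermutator samples (a single sample with thousands of mutations is hit by
almost every gene set). Because the random sets are scored on the same
incidence matrix, that inflation cancels between the query and the null —
the test asks whether the *genes* are unusual, not whether the samples are.
The null does not adjust for gene-level covariates (gene length, expression,
replication timing): a query set of unusually long genes will score high
for reasons unrelated to pathway biology. That is a known limitation of
the method, not of this implementation.

**Chi-squared follow-up.** The null average is rounded half-up to an
integer r and the table [[U(G), n−U(G)], [r, n−r]] is tested with the
Pearson χ² statistic at df = 1 *without* continuity correction — the
variant that reproduces the published example values for this construction
(0.006 and 0.08); with Yates correction neither reproduces. A table with a
zero margin is reported as p = 1 with a degeneracy flag rather than an
error. This follow-up treats the rounded average as if it were a second
observed group, which understates the null's spread; it is reported as the
companion statistic it is, with p-total as the primary inference.

**Determinism.** One integer master seed; each cohort derives its own
generator seed from (master seed, cohort label) via a SeedSequence and a
CRC-32 of the label, so multi-cohort runs are order-insensitive and every
report records the seed that produced its null.

## MAF handling

Records are parsed from tab-separated MAF with '#' pragma lines; required
columns are Hugo_Symbol, Chromosome, Start_Position, End_Position,
Reference_Allele, Tumor_Seq_Allele2, Variant_Classification,
Tumor_Sample_Barcode. The default classification filter retains 25 tokens
(Frame_Shift_Del … Stop_Codon_Del — effectively all called variants
including silent, UTR/flank, intronic and non-coding classes); typographic
apostrophe variants (3’UTR) are normalized to ASCII (3'UTR) on read, and
dropped-token counts are kept in a parse summary. Merging the per-caller
files takes the deduplicated union keyed on (sample, chromosome, start,
end, ref allele, tumor allele) — classification and caller-specific columns
deliberately excluded, so the same event called by four pipelines counts
once — keeping the first caller tag seen and sorting the output. Sample
identity defaults to the full tumor-sample barcode; the patient-level
switch truncates TCGA barcodes to the 12-character patient prefix before
counting denominators.

## Synthetic cohorts

The generator emulates the statistical structure of a pan-cancer somatic
cohort, with ground truth exposed for every draw:

| parameter | default | meaning |
|---|---|---|
| n_samples | 200 | cohort size |
| n_genes | 500 | gene universe |
| base_rate | 0.01 | baseline per-gene per-sample mutation probability |
| burden_dispersion | 1.0 | σ of log-normal per-sample burden multiplier |
| hypermutator_fraction | 0.05 | samples carrying the discrete multiplier |
| hypermutator_multiplier | 10 | their extra burden (POLE/MSI-like tail) |
| gene_mutability_shape | 1.0 | gamma shape of mean-1 per-gene weights |
| enrichment_factor | 1.0 | multiplier on a planted gene set |

Cell (g, s) is mutated independently with probability
min(1, base_rate · λ_s · w_g · enrichment), λ_s ~ LogNormal(0, σ) times the
hypermutator multiplier for a Bernoulli subset, w_g ~ Gamma(shape,
1/shape). Each mutated cell emits one MAF record with a classification
drawn uniformly from the 25-token list and a locus synthesized
deterministically from (gene index, sample index), so dedup keys are unique
and the same seed yields byte-identical MAF. The defaults describe a
mid-sized solid-tumor cohort with realistic overdispersion; per-sample
mutation counts are super-Poissonian whenever burden_dispersion > 0.

What the simulator does **not** model: sequence-context mutational
signatures, per-gene length/expression/replication-timing covariates,
multiplicity beyond one record per cell (a Poisson-multiplicity switch
would add MAF realism but not change the boolean matrix), clonality/VAF,
or copy number. Passing calibration on these cohorts therefore shows the
statistic is correct under burden and mutability heterogeneity — it does
not certify robustness to covariate structure that the null inherently
ignores.

**Calibration.** With no planted enrichment and the query set drawn by the
same mechanism as the random sets, p-total is approximately uniform
(slightly conservative because of the ≥ rule and count ties); the empirical
rejection rate at α = 0.05 over 200 replicate cohorts sits inside the 95%
binomial interval (observed 0.035–0.065 across seeds). With a planted
14-gene set at enrichment factor 10 the rejection rate is 1.0; at factor 5
a single default cohort already gives p-total < 1/1000. Two hundred
replicates run in a few seconds because the incidence matrix and the
without-replacement draws are vectorized (per-iteration gene sets via
row-wise argpartition of a uniform key matrix, chunked to bound memory).

## Bench-assay quantifications

*TLS extent*: 100 × (lesion-plasmid transformants / control-plasmid
transformants) × (fraction of sequenced repair events classified as TLS).
Linear in each factor; invariant under common scaling of the two colony
counts. The TLS fraction is an upstream input (sequencing classification is
out of scope).

*ΔΔCt*: fold change 2^(−ΔΔCt) with ΔΔCt = (Ct_target − Ct_ref)_treated −
(Ct_target − Ct_ref)_control; swapping treated and control inverts the fold
change exactly. No amplification-efficiency correction beyond the 2× per
cycle assumption.

*One-phase decay*: y(t) = plateau + (y0 − plateau)·e^(−kt), half-life =
ln 2 / k, fitted by bounded least squares (trust-region reflective via
scipy). The plateau is a free parameter constrained ≥ 0 — the named model
family fits a floor, and transcript series often level off at a stable
subpopulation — with a switch to pin it at 0. Initialization is
deterministic (y0 from the t = 0 value, plateau from the series minimum,
k from the log-linear slope of the plateau-subtracted values); no random
restarts. Optimizer tolerances are set to 1e-15: with the plateau resting
on its bound, looser tolerances stop visibly short of the exact solution
on noiseless data, and the fit is cheap enough that machine-precision
termination costs nothing. A fit reports converged = False — never an
exception — when the optimizer fails, the rate constant collapses to its
floor (1e-9/h), or the fitted amplitude y0 − plateau is negligible
(constant series); half-life is then NaN. Replicates enter as separate
unweighted points. Parameter recovery at the bench's own design — three
independent replicate series sampled at 0–8 h with Gaussian noise
σ = 0.05 and a true half-life of 6 h — has a median relative error of
~7–8%; a single 6-point series at that noise level does not pin down the
free plateau (median error ~16%), which is why stability experiments are
run in replicate.

## Problem sizes used in the shipped checks

Resampling-vs-exhaustive agreement uses toy matrices of ≤ 12 genes
(≤ 495 enumerable sets) against 10,000 resampling iterations; calibration
and power use 200 replicate cohorts at the generator defaults with
1000-iteration nulls; decay recovery uses 200 noisy triplicate series.
These sizes give 3σ-level statistical resolution for every check while the
whole suite runs in well under a minute.
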