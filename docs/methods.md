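# Methods

## Scope and data model

`edscan` starts from per-sample, per-site A/C/G/T pileup counts rather than
alignments: read mapping, base-quality recalibration and the base-quality
filter (BQ ≥ 25) are upstream tools' responsibility and enter the package as
a contract on the counts.  Coordinates are 1-based closed internally (so a
site is named the way editing sites are usually quoted, `GENE:contig:pos`);
BED input/output converts to 0-based half-open at the boundary.  Gene models
are single-transcript: ordered exons plus an optional CDS span, from which
UTRs, introns and codon positions are derived.

Read-position evidence is carried as one number per (sample, site): the
median relative position of alt-supporting reads within their reads.  This
is sufficient for the read-end artifact rule below and avoids per-read
storage; it is a site-level operationalization of a filter that per-read
pipelines implement with read trimming.

## Caller

A site/alt pair is a candidate when at least one sample passes depth ≥ 10,
alt depth ≥ 2 and AAF ≥ 0.01 (all inclusive).  AAF and editing level use the
same two-allele denominator, alt/(ref+alt); bases that are neither reference
nor the candidate alt (sequencing errors) are excluded, and a cell with no
ref+alt evidence is missing, not zero.

Strand is inferred from the gene model, the only strand information
available at the counts level.  Candidates overlapping genes on both strands
are dropped as `ambiguous_strand` — conservative and logged.  The removal
cascade then applies, in order: homopolymer run ≥ 5 (measured on the
reference around the site), simple-repeat interval, mitochondrial contig;
genomic distance ≤ 6 to a junction-adjacent exonic base (strand-agnostic);
indel proximity flag; cross-sample median alt read position ≤ 0.04 or
≥ 0.96; SNP-blacklist membership; and the germline AAF pattern — the
fraction of *callable* samples (depth ≥ 10; AAF is meaningless below that)
with AAF exactly 1.0 or in [0.40, 0.60] exceeding 0.90.  The first firing
rule is recorded per dropped candidate, and the filter log accounts for
every candidate exactly once.  Whitelisted sites bypass all four rules
(rescue precedes the rule list) — the flag is exposed so the rescue can be
disabled.

Consequences are annotated from the gene model: CDS events are translated
through the standard codon table on the coding strand (missense /
synonymous / stop-gained; note A→G on the coding strand cannot create a stop
codon, so stop-gained only ever appears if the caller is fed non-editing
substitutions), exonic non-CDS events become 5′/3′-UTR by strand-aware
position, intra-gene non-exonic events are intronic, and CDS-less genes
yield `non_coding`.

## Differential editing

Per event, the binomial GLM with logit link and group as the sole binary
covariate has a closed-form maximum likelihood: the fitted group
probabilities are the group-pooled edited fractions.  The LRT statistic is
therefore computed exactly,

    ll(E, U) = E·log(E/(E+U)) + U·log(U/(E+U)),   0·log 0 = 0
    stat = 2·[ ll(E₁,U₁) + ll(E₀,U₀) − ll(E₁+E₀, U₁+U₀) ] ~ χ²₁,

which is finite at separation boundaries (a group with zero edited or zero
unedited reads), so no special-casing or step-limited fitting is needed.
The tests cross-check this against statsmodels' IRLS GLM and a
golden-section likelihood-maximization oracle.  Events with fewer than two
usable samples (depth ≥ 10) in either group are flagged untestable — their
p is missing, never 1.  Significance is raw P < 0.05; BH q-values are
reported as an extra column but play no role in the default calls.  A
Gaussian-on-levels LRT is available (`family="gaussian"`) for sensitivity
analysis.

The test is exactly calibrated under its own sampling model (samples share
a group-level editing probability; verified at the nominal 5% over 1000
null simulations).  When per-sample levels vary around the group mean — the
generator's beta layer with κ = 50 — the pooled-count test is
overdispersed and anticonservative on such null sites (≈15–20% rejections
at nominal 5% in the default simulation).  This is a real property of
GLM-on-counts differential editing, not an implementation artifact; users
who need calibration under between-sample heterogeneity should use the
Gaussian-on-levels mode or interpret raw p accordingly.

Consensus across datasets joins events by (contig, pos) and keeps those
significant in ≥ k datasets (optionally requiring a consistent effect
direction); gene-level consensus counts a dataset when any event in the gene
is significant.  A differentially edited gene is a gene with ≥ 1 significant
event.  The expression screen is a two-sample Student's t-test on
log2(x+1) with BH FDR, flagging FDR ≤ 0.05 and |logFC| ≥ 1 (both
inclusive); zero-variance genes get p = 1 by convention.  PCA is
column-centered SVD of the (mean-imputed) samples × events matrix with a
deterministic sign convention.

## Co-editing network

The network is unsigned: a_ij = |r_ij|^β with pairwise-complete Pearson
correlations (events with > 50% missing cells or constant levels are
excluded and logged).  β is the smallest power in 1..20 whose scale-free
topology fit reaches R² ≥ 0.8 — connectivities binned into 10 equal-width
bins, log10 frequency regressed on log10 mean connectivity, R² signed by
the slope — else the best-fitting power with a warning.  A caveat worth
knowing: pure-noise matrices can also reach high signed R² at large powers,
so the fit index alone does not certify modular structure.

Topological overlap is TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j) + 1 −
a_ij), computed by matrix products and verified against a triple-loop
oracle.  Modules come from average-linkage clustering of 1 − TOM with a
static cut.  Because raising β compresses all TOM dissimilarities toward 1,
an absolute cut height is not transferable across powers; the cut is
therefore placed at a fixed fraction (default 0.9) of the dendrogram's
merge-height range, h_min + 0.9·(h_max − h_min).  Clusters smaller than
`min_size` (default 10) are unassigned (`grey`); surviving modules are
named by decreasing size with the conventional color sequence, so the
largest module is always `turquoise`.  Module eigengenes are the first
principal component of the per-event standardized module matrix, unit norm,
sign-oriented to correlate non-negatively with the module's mean profile.
Module–trait association is Pearson R with a two-sided t-based p; the key
module minimizes p against the group coding (control = 0, case = 1).

Hubs are the top-n (default 10) intramodular nodes by degree.  The edge set
is binarized on the |correlation| scale at 0.4 (configurable) rather than on
the β-powered adjacency: |r|^β rarely exceeds 0.4 at typical β, which would
empty the default edge set, while 0.4 is a meaningful score-scale cutoff for
an exported edge list.  Ties are broken by smaller differential-editing p,
then event id, making the hub list deterministic.

## Synthetic data generator

The generator emulates the study conditions the analysis assumes.  Defaults
(the package's study conditions): 12 cases vs 10 controls; two 30-kb contigs
each carrying a multi-exon coding gene (one per strand) plus a 2-kb
mitochondrial contig with a non-coding gene; planted poly-A/poly-T
homopolymer runs, AC/GT simple-repeat tracts and Alu-like intervals inside
the gene bodies; splice-junction-adjacent bases annotated from the gene
models.  Planted sites: 200 clean editing sites (100 differential at
Δ = 0.15, control means uniform on [0.02, 0.35]), 100 het SNPs (per-sample
allele fraction tightly beta-distributed around 0.5), 50 hom SNPs (fraction
1), 100 unedited null sites, and 200 context decoys split evenly across the
seven removal-rule contexts, each placed so that exactly its own rule fires
first.  Catalogue coverage: 50% of clean editing sites are whitelisted
(known-site catalogues are incomplete); 95% of planted SNPs are blacklisted,
reflecting that common germline variants are overwhelmingly catalogued —
the AAF-pattern rule is the backstop for the rest.

Counts follow a beta-binomial hierarchy: per-sample true levels are
beta-distributed around the group mean with concentration κ = 50 (between-
sample biological variation), depth is negative-binomial (mean 50,
dispersion 5 — about 7% of cells fall under the depth-10 floor, exercising
missingness), edited reads are binomial in the true level, and each read
errs to one of the other three bases at rate 0.001.  Reverse-strand sites
are emitted as T-reference sites with C alt counts.  The 20-site hub block
shares a standard-normal latent factor with loading 0.9 and scale σ = 0.08
on top of the group effect, giving true-level pairwise correlations ≈ 0.9
and observed correlations ≈ 0.7 at depth 50.  Hormone features are linear
in the latent factor and group (defaults chosen at realistic clinical
magnitudes, e.g. LH ≈ 7 IU/L + 3·factor + 2·case ± 1), with the LH/FSH
ratio derived; expression is per-gene negative-binomial with a weak
multiplicative cis coupling of hub host genes to the hub editing level.

What the generator does *not* emulate: alignment artifacts beyond the
read-end/indel summaries, reference bias, hyper-edited reads, overlapping
genes, multi-transcript isoforms, covariate structure (age/BMI), or
realistic LD between SNPs.  Passing tests therefore certify the pipeline's
logic and statistics under its stated model, not performance on real
cohorts.

## Benchmark study sizes

The bundled benchmarks run at desk scale, chosen so the full suite finishes
in seconds while keeping the statistical checks meaningful: caller metrics
on the 650-site default study; LRT calibration on 1000 null events and
power on 400 events per effect size; module/hub recovery on a 100-event
study with one 20-site hub block; clinical association replicated over 50
cohort draws of a 20-site study at n = 22.  The key-module–group
correlation fluctuates across seeds (the latent hub factor is independent
of group, and at n = 22 their sample correlation varies); the reported
seed-1 value is 0.70.

## Determinism and numerical choices

All randomness flows through numpy Generators seeded per stage via
`SeedSequence.spawn`; a fixed seed reproduces every output byte-for-byte,
and the pipeline manifest records a config hash plus SHA-256 checksums of
every output.  Ties in hub ranking and module naming are broken
deterministically; PCA and eigengene signs follow fixed conventions.  AUC
uses the Mann–Whitney convention (ties get half credit), which equals the
trapezoidal integral of the empirical ROC.  The logistic marker combination
standardizes markers (making the fit affine-invariant in exact arithmetic),
drops exact duplicate columns, and falls back to a ridge-stabilized fit
(flagged in the result) when the unpenalized likelihood shows separation;
in-sample AUC is reported and is optimistic at small n — a caveat printed
in the clinical example.
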