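# Methods

`escc_ith` reimplements a multi-region tumor-heterogeneity analysis as a
tested pipeline: somatic-variant post-filters, cancer-cell-fraction (CCF)
and clonality estimation, per-patient parsimony phylogenies with mutation
timing, mutational-signature deconvolution with an HRD (signature-3)
classifier, mirrored subclonal allelic imbalance (MSAI) detection,
neutral-evolution fitting, and TCR-repertoire heterogeneity metrics.
Because the motivating study's raw sequencing data are not required, every
stage is exercised end to end on a synthetic multi-region generator with
known ground truth.  This note records the models, the parameters that
matter, and the choices made where the design was genuinely open.

## Variant filtering

Only the numeric post-calling thresholds are implemented; upstream caller
internals and manual review steps are not reproducible and are out of
scope.  SNVs pass with tumor alt reads >= 4, matched-normal alt reads
<= 2, tumor coverage >= 14 and normal coverage >= 10 ("supported reads >=4
(<=2) and coverage >=14 (>=10)" is read as tumor (normal) thresholds by
sentence structure).  Indels pass with alt >= 6, coverage >= 20 and
VAF >= 0.1.  A patient is a hypermutator at >= 10x the cohort median
burden.  Germline variants in the 25-gene homologous-recombination panel
are deleterious when coverage >= 30, VAF > 8%, population MAF <= 1%
(absent MAF treated as 0, i.e. rare), and the variant is truncating or
ClinVar-pathogenic.  Driver annotation flags non-silent variants in the
driver-gene list with an exact catalog match or >= 3 recorded mutations
within 15 bp (genomic coordinates; the amino-acid alternative is not used
and the choice is flagged to users), or truncating variants in recessive
genes with SIFT < 0.05 or PolyPhen > 0.995.  Neoantigen candidates
require predicted MHC-I affinity strictly below 500 nM.  All filters are
pure functions: passed and rejected records partition the input and
rejections carry every violated rule.

## CCF and clonality

For a variant with VAF v in a sample of purity p, local tumor copy number
n_t, normal copy number n_n = 2, and multiplicity m:

    CCF = v (p n_t + (1-p) n_n) / (p m)

Multiplicity defaults to round(v (p n_t + (1-p) n_n) / p) clipped to
[1, n_major].  The original study used a full purity/ploidy model for
this step; re-deriving purity and ploidy is out of scope, so the closed
form above is used with externally supplied purity, and externally
computed CCFs can be substituted.  The 95% CI is Clopper-Pearson on v
pushed through the same linear map — conservative, and an approximation
since the upstream model's CI construction is unpublished.  A mutation is
subclonal iff the CI's upper bound is below 1.  Reported CCFs are capped
at 1.2 (not 1.0) so multiplicity misestimation stays visible.  LOH at a
gene locus means the minor allele is clonally lost with the major allele
retained; loss of the alternate allele additionally requires variant read
frequency > 0.7.

## Phylogenies and mutation timing

Each patient's mutations form a binary presence table over tumor samples:
present iff VAF >= 2% and >= 2 alt reads.  The two-read guard goes beyond
the published VAF rule to avoid single-read presence calls at depth ~300.
Trees are found by exhaustive search over all rooted binary leaf
topologies ((2n-3)!! for n samples; bounded at 9 samples), rooted at an
all-zero germline.  Characters are scored by Sankoff dynamic programming
under an asymmetric model: 0->1 gains cost 1, 1->0 reversals cost 10 —
effectively irreversible, since somatic point mutations are lost only by
deletion.  On perfect-phylogeny input the optimal score equals the
mutation count and each mutation has a unique gain edge; with homoplasy,
a mutation is assigned to its earliest (largest-clade) gain and flagged.
All co-optimal topologies are returned; the reported tree maximizes trunk
length, then lexicographic order — a deterministic stand-in for the
study's manual CNA-guided adjudication, whose criteria are unpublished
and are not guessed.  CNA-based rearrangement of trees is reduced to a
consistency check rather than automated edits.

Timing is defined by the presence pattern: trunk = present in every tumor
sample, private = exactly one, shared branch = the rest.  The
heterogeneous fraction is (shared + private) / total.

Clone intermixing is called from CCF evidence rather than tree topology
alone: for each non-trunk edge block (>= 3 mutations), a sample carrying
the block at median CCF in [0.1, 0.6) while another sample carries it
clonally (>= 0.6) is flagged as holding a minority population from that
clade's history.  This works whether or not the parsimony step absorbed
the intermixed sample into the clade.

Metastatic seeding: `monoclonal_precursor` when all lymph-node leaves
form one met-only clade attached at the first branching node with a
mutated stem; `linear` when that met-only clade is nested inside a
subclade containing primaries; `explosive` when two or more met lineages
attach independently at the first branching node; otherwise
`unclassified`.

## Mutational signatures

SNVs with trinucleotide context are counted into the 96
pyrimidine-standardized channels; indels carry no context and are
excluded (the 96-channel analysis is substitution-only).  Exposures are
fit against a 96 x 30 catalog by non-negative least squares with no
sparsity penalty, matching the referenced deconvolution strategy;
contributions are reported as proportions of mutations, the dominant
signature is the argmax (ties to the lowest index, logged).  Spectra can
be built per sample or pooled per patient; pooled is the default.
Early/late dynamics refit exposures separately on trunk and branch
mutation sets (a phase under 20 SNVs is flagged low-confidence), and the
cohort-level contrast of one signature uses a two-sided paired t-test.
The HRD classifier is the Mann-Whitney AUC (mid-ranks, ties count 1/2) of
signature-3 proportion against a configurable BRCA1/2-deficiency label
(germline-pathogenic only, germline + ubiquitous somatic, or biallelic).

The packaged catalog is a **synthetic stand-in** for the 30-signature
COSMIC v2 catalog (`data/signature_catalog_synthetic.tsv`), generated
deterministically: the signatures the analysis leans on are given their
published character (aging-like C>T at NpCpG, APOBEC-like C>T/C>G at
TpCpN, a near-flat HRD-like signature 3, broad MMR-like C>T, T>A for
aristolochic acid, C>A for tobacco chewing), the rest are sparse random
profiles.  Swap in the real catalog via `load_catalog(path)` for
production use.  A known identifiability limit carries over from the real
catalog: the flat signature 3 is weakly constrained by NNLS at a few
thousand SNVs (per-signature errors up to ~0.1 in mixtures that lean on
it), while mixtures of the structured signatures are recovered within
0.05 at 5000 SNVs.

## MSAI

Breakpoints from all of a patient's samples are pooled into consensus
segments, each carrying every sample's allele-specific copy state.  The
theoretical BAF when the B allele lies on the major haplotype is

    (p n_major + (1-p)) / (p (n_major + n_minor) + 2 (1-p)),

and major/minor BAFs sum to 1.  On a segment imbalanced in both samples
with >= 10 shared heterozygous SNPs, each SNP's BAF is scored under two
normal densities truncated to (0, 1), centered at the major and minor
theoretical BAFs ("log-truncated normal" is interpreted as this density
evaluated in log space; the original parameterization is unrecoverable
and the choice is isolated behind one function).  Sigma per
segment-sample is the MAD of BAFs folded about the nearer center, scaled
by 1.4826 and floored at 0.01.  The per-SNP log-likelihood ratio (LLR)
favors one haplotype; under mirroring the LLRs of the two samples
anti-correlate, so the reversal statistic r_i = -LLR_A(i) LLR_B(i) is
positive and is tested against zero with a one-tailed one-sample t-test.
The product form makes the test exactly symmetric in sample order.  A
segment is mirrored iff the test is significant (alpha = 0.05) and the
aggregate favored haplotype flips.  SNP phase labels, when present in
synthetic data, are used only to validate — never by the test.  Raw
p-values are reported; Benjamini-Hochberg adjustment across segments is
available as an option since the original multiple-testing treatment is
unstated.

## Neutral evolution

The cumulative mutation count is modeled as M(f) = (mu/beta)(1/f -
f/f_max).  As printed, this form has M(f_max) = (mu/beta)(1/f_max - 1) >
0, i.e. the clonal mutation mass sits at f_max; M(f) therefore counts
*all* mutations with VAF >= f — including the clonal peak above the
window — evaluated at the VAFs observed inside the open window
(0.12, 0.24), exactly as printed.  The slope is fit by least squares
through the origin (the model has no intercept) on x = 1/f - f/f_max;
R^2 is the conventional mean-centered one and can be negative.  R^2 >=
0.98 calls the sample neutral.  f_max defaults to purity/2, the expected
clonal heterozygous VAF in a diploid region (the source never states
f_max; it is configurable).  Eligibility: purity > 0.5 and >= 12 SNVs in
the window.

Samples failing the plain fit fall back to a contamination-corrected
model: observed VAFs are deflated by unrecognized normal contamination,
so the fit rescales f -> f (1 + eps) with eps >= 0 and refits (slope,
eps) by bounded least squares (the printed fallback gives only a rescaled
slope; this two-parameter realization reduces to the plain model at eps =
0).  eps is capped so no rescaled VAF reaches f_max — without the cap,
extreme eps compresses the window onto the curve's steep end and "fits"
arbitrary shapes — and an eps pinned at its bound is treated as
non-convergence (not neutral).  Limitation: a moderate subclonal cluster
(~15-20% of mutations) can still be absorbed by an interior eps and pass
the corrected fit; strongly subclonal samples (>= ~25% cluster mass) peg
eps and are rejected.  Selection inference and subclone deconvolution
are out of scope.

## TCR repertoires

Clone identity is (CDR3 amino-acid sequence, V gene, J gene) — the
amino-acid level matches CDR3-level reporting and is configurable.  After
dropping non-productive clones, sequences at <= 2 reads per million are
removed, and repertoires above one million reads are down-sampled to
exactly one million (multivariate hypergeometric, seeded) before
diversity is computed.  Shannon index is in bits; evenness (Pielou) =
Shannon / log2(unique clones), with a single-clone repertoire assigned
evenness 0; clonality = 1 - evenness (the standard definition consistent
with that normalization); CR4 = summed frequency of the top four clones.
The high-frequency clone threshold defaults to 0.01% with a documented
override to 0.1% — the source states both values in different places and
no intent is guessed.

Pairwise measures per chain: Jaccard index on clone-identity sets and
count overlap = sum of shared-clone reads over the two totals.  Both
distances average the chain terms with equal weight:
D = 0.5 (1/J_TRA - 1) + 0.5 (1/J_TRB - 1), and likewise with the count
overlap.  A zero Jaccard/overlap yields a capped distance (1e6) with a
flag; a chain missing in one sample is dropped with the remaining chain
reweighted.  Which of the two distances fed the published trees is
ambiguous; both are computed and the count-overlap distance is the NJ
default, as its defining section concerns tree construction.  Neighbor
joining is delegated to scikit-bio with negative branch lengths clamped
to zero.  Genetic/TCR tree concordance makes the qualitative criterion
explicit: a genetic clade among primary regions is concordant when its
members' mean pairwise TCR distance is smaller than the member-to-
non-member mean; the score is the fraction of concordant clades, with a
cophenetic Spearman correlation alongside.

## Synthetic data

The generator emulates the study design: five primary regions (plus
optional lymph-node mets) per patient, tumor depth 290x and normal 187x
(the cohort averages; configurable), purity 0.8 by default.  Coverage is
Poisson around the mean depth and alt reads binomial around the expected
VAF = purity x CCF x multiplicity / (copy-number-weighted denominator) —
the simplest model consistent with WES count data.  Each sample is by
default a pure population of one terminal clone, so presence patterns
form a perfect phylogeny and planted topology, edge assignments and
timing labels are exactly recoverable from noiseless output; `spill`
mixes a foreign clone into a sample for intermixing tests, and `seeding`
plants monoclonal-precursor / linear / explosive dissemination
structures.  Mutation contexts are multinomial draws from the catalog
under a chosen signature mixture.  Neutral VAF tails are inverse-CDF
draws making the expected M(f) exactly proportional to 1/f - f/f_max,
with the model's tail mass at f_max realized as a clonal point mass; the
implied slope for n draws above f_min is n / (1/f_min - f_min/f_max).
BAF segments share SNP phase across samples and flip the favored
haplotype under `mirrored`.  TCR cohorts realize a planted
sample-by-clone membership design exactly (one-read floor) with
Zipf-like abundances (exponent 2).  The BRCA cohort draws signature-3
scores from normal distributions shifted by `sep`, so the population AUC
is Phi(sep / sqrt(2)) in closed form.

What the generator does not emulate: sequencing artifacts and mapping
error, copy-number-driven VAF distortion (mutations sit on diploid
segments at multiplicity 1 unless BAF segments are simulated
separately), clustered mutational processes along the genome, and
repertoire sequencing error.  Passing tests therefore demonstrate the
correctness of the statistical machinery and its calibration under the
stated noise model — not robustness to artifacts real WES/TCR data can
contain.

## Problem sizes in the tests and acceptance run

The checks use the cohort-scale parameters where they are cheap (depths
200-300, 5000-mutation neutral spectra, 5000-SNV signature recovery, 50
replicates for slope recovery, 1000 replicates for both calibration
nulls) and a three-patient demo cohort with 4-7 tumor samples per
patient for the end-to-end pipeline, keeping the exhaustive topology
search (up to 10395 trees at 7 leaves) fast.  The neutral-evolution
headline number is recomputed by `scripts/acceptance.py` on a freshly
simulated eligible sample (purity 0.6, clonal peak at 0.3) with the fit
performed at f_max = 0.25 over the (0.12, 0.24) window; a clonal peak
placed exactly at 0.25 would belong to a purity-0.5 sample, which the
method's own eligibility rule excludes, and its read-noise spread into
the window would defeat the threshold for genuinely neutral data.
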