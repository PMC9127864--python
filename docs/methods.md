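# Methods

This note records the models, numerical conventions and design choices
behind `tcrep`, in the spirit of a statistical software methods appendix.

## Data model and preprocessing

The unit of analysis is the clonotype: a unique CDR3 amino-acid sequence
with representative V/J calls and an abundance (reads or templates). Raw
clone tables (AIRR rearrangement TSV or MiXCR export) arrive at nucleotide
resolution; `collapse_by_cdr3aa` merges nucleotide variants translating to
the same amino-acid CDR3, accumulating counts and taking the V/J alleles
of the highest-count variant as representative. Dominance ties break on
the lexicographically smallest nucleotide sequence so the operation is
deterministic; it is idempotent and conserves total counts exactly.
Non-productive rows (CDR3s containing stop `*` or frameshift `_`
characters) are dropped at read time with a logged count: diversity and
annotation are defined over productive receptors, and retaining
non-productive junctions would distort both. V/J calls are compared at
gene level (allele suffix `*NN` stripped) for annotation, where reference
databases record genes, but kept at allele level for usage profiles,
where the aligner's resolution is meaningful.

Frequencies are always counts divided by the repertoire total and are
recomputed rather than trusted from input files.

## Diversity

Hill numbers are evaluated directly from the closed form
`(sum p_i^alpha)^(1/(1-alpha))`; the order-1 case uses the exact Shannon
branch `exp(-sum p_i ln p_i)` inside a `|alpha-1| < 1e-9` window rather
than a numerical limit. Zero-frequency entries are removed before any
`p ln p` or `p**0` term is formed, so `0*ln(0)` is never evaluated. The
default profile grid is alpha 0 to 10 in steps of 0.1. Rényi entropy is
the natural log of the Hill number. Pielou's evenness J′ = H′/ln N is
undefined for N = 1 and raises rather than returning a sentinel.

Clone-size bins follow the hyper (> 1 %), high (0.1–1 %], medium
(0.01–0.1 %], low (≤ 0.01 %] convention; interior edges are half-open with
the lower edge exclusive and upper edge inclusive, consistent with the
outer edges. Top-rank cumulative abundance sorts clonotypes by descending
frequency, takes the frequency at rank ⌈qN⌉ as threshold and sums all
frequencies ≥ threshold, so threshold ties are included by construction.

## Similarity and gene usage

Morisita–Horn overlap is computed on amino-acid-collapsed frequency
vectors indexed over the union of the two clonotype sets (absent = 0);
computing on frequencies rather than counts is mathematically equivalent
after normalization. The RDI follows the subsample-and-average recipe:
per iteration, a fixed number of unique clonotypes (default: the smaller
repertoire's unique count) is drawn without replacement from each
repertoire, usage counts are assembled on the union category set,
transformed as 2·sqrt(count) (the variance-stabilizing transform for
Poisson-like counts), and the Euclidean distance is recorded; the mean
over iterations (default 100 in the library, fewer in the pipeline's
default configuration for speed) is reported. A seed is required, making
the estimate reproducible. No null-distance calibration is applied; the
raw mean distance is reported and compared only between pairs computed at
equal depth.

## Clustering

Two criteria approximate specificity grouping. Global similarity links
equal-length CDR3s that agree on the first three and last two residues
(the conserved junction framework) and differ at no more than one interior
position; connected components of size ≥ 2 are clusters. Pairs are found
by wildcard hashing (each sequence keyed once per interior position with
that position masked), which is exact for this relation and linear in
total sequence length. Motif enrichment counts interior k-mers (k = 3 and
4; interior = CDR3 minus first 3/last 2 residues) at clonotype-level
presence and applies a one-sided Fisher's exact test against a naive
background repertoire, retaining motifs with pseudocounted fold
enrichment ≥ 10 and p ≤ 1e-3. The background must be supplied (a
model-sampled naive repertoire in the pipeline) and is never the query
itself. Each retained motif defines one cluster of all clonotypes
containing it; a clonotype may belong to several motif clusters.
Clustering is per subject and fully deterministic; merging a global group
with every motif group sharing a member yields `mixed` clusters, the rest
stay `global` or `motif`, and anything outside all clusters is
non-clustered. Thresholds (interior convention, mismatch allowance, k,
fold, p) are exposed as parameters.

## Annotation

Strategy 1 annotates a clonotype whose V gene and CDR3 both equal a
reference entry. Strategy 2 first clusters the reference within each
epitope group using the machinery above; query clonotypes matching a
global-clustered entry on V gene, CDR3 length and Hamming distance ≤ 1
are annotated, as are all members of a query motif cluster whose enriched
motif string equals a reference-cluster motif. The "≤ 1 mismatch" rule is
interpreted as one substitution at equal length — no indels — matching
the default behaviour of sequence-match tools in this domain. A cluster
containing at least one annotated member is a common-antigen cluster and
all its members inherit common status. Every clonotype receives exactly
one record (specificity × cluster status); epitope multiplicity is
retained even though specificity is binary.

The compartment-diversity comparison subsamples unique clonotypes (not
reads): for a given size (by default, the size of the subject's common
compartment), 100 subsamples are drawn without replacement, counts are
renormalized within each subsample, and the mean Pielou J′ is reported.
The same size parameter is applied when subsampling the full repertoire,
giving a like-for-like comparison.

## Generation model

P_gen computation replaces a trained recombination model with an explicit
amino-acid-level process chosen to be exactly summable: draw a V prefix,
trim 0..T residues from its end; draw an insertion length 0..L and that
many i.i.d. residues; draw a J suffix, trim 0..T from its start;
concatenate. All component distributions are explicit categorical
distributions. The exact P_gen of a sequence is the finite sum of path
probabilities over all decompositions, implemented with precomputed
(trimmed-prefix → probability, path count) tables so each query costs
O(#prefixes × #suffixes). Defaults T = 2, L = 6 keep enumeration small;
the default human-TRB-flavoured model has 12 V and 8 J segments with
skewed usage and a glycine/serine-rich insertion composition. Sampling
and exact summation share the same parameters, so a Monte-Carlo estimate
(fraction of n draws equal to the query, SE = sqrt(p(1-p)/n)) is an
independent oracle for the summation; conservation (probabilities of all
reachable sequences summing to 1) holds by construction and is asserted
on a fully enumerable model in the tests. Sequences with P_gen = 0 are
excluded from log-scale correlation with a reported count. Precomputed
P_gen tables (e.g. from an external nucleotide-level model) can be
supplied and are consumed identically downstream.

## Statistics

Paired contrasts use the two-sided Wilcoxon signed-rank test with zero
differences dropped (Wilcoxon's original treatment, exposed as an
option); the exact conditional null distribution is used up to n = 25 and
the tie-corrected normal approximation beyond. Unpaired contrasts use the
two-sided Mann–Whitney test with midrank ties. The frequency/P_gen
coupling is Pearson's r on log10-transformed values. Clinical association
is simple linear regression of each feature on the per-subject coupling
coefficient; for simple regression the Pearson test and the slope t-test
coincide, so the reported r, slope and p are one test viewed two ways.
FDR correction is Benjamini–Hochberg, applied within an analysis family
(e.g. the three intra/inter similarity contrasts, or one clinical feature
set per scope), matching how such families are annotated on figures.

## Synthetic cohorts: what is emulated, and what is not

Each subject receives `n_clonotypes` (default 2,000) template clonotypes:
a small planted minority (default 1.5 %) copied verbatim from the
synthetic reference DB, the rest drawn from the generation model. Final
clone weights combine three log-scale terms: a Dirichlet base weight with
group-specific concentration (default 5 for the case-like group, 50 for
the control-like group — skewed vs even), a coupling term
beta·log10 P_gen with per-subject beta drawn around the group mean
(defaults 0.8 vs 0.2, SD 0.12), and lognormal noise (SD 0.5 log10 units).
Planted clonotypes additionally carry a lognormal memory-expansion factor
(mean 10^1.2 ≈ 16×, SD 0.2 log10): database-documented specificities are
antigen-experienced clones, and the boost keeps them above the detection
floor while leaving them on the same frequency/P_gen trend as everything
else. Sequencing is a multinomial draw at fixed depth (default 100,000);
clonotypes receiving zero reads drop out, so observed richness is lower
in skewed subjects, as in real data (planted clones keep a one-read
floor as a backstop). The synthetic reference DB builds one global
cluster per epitope — a seed CDR3 of full V prefix + one insertion
residue + full J suffix, plus Hamming-1 neighbors mutated only at
J-suffix positions that deeper J trimming can cover — so every entry has
positive, typical-magnitude P_gen under the model, and all group members
share an interior 4-mer motif spanning the V/insert/J junction.

Clinical covariates are linear in the subject's true beta with signs
fixed by the clinical picture being emulated (aldosterone-like,
ratio-like and sodium-like features rise with coupling strength, the
renin-like feature falls) plus Gaussian noise of 5 % of the slope
magnitude.

Per-subject beta variability (SD 0.12) was set so that beta is
identifiable across subjects at the default depth: markedly smaller
spreads leave within-group differences in the estimated coupling r below
its estimation noise, while much larger spreads push subjects into the
regime where the observable r saturates in beta. The planted fraction
(1.5 %) reflects that exact public-database hits are a small minority of
any repertoire.

The generator does **not** emulate: real human TRB segment frequencies or
nucleotide-level recombination (the model is amino-acid level with a
small segment set), HLA restriction, T-cell subset structure, longitudinal
dynamics, or sequencing error. Passing recovery tests therefore shows the
analysis correctly extracts the planted statistical structure — evenness
contrasts, abundance/generation coupling, clinical covariation — not that
the generator is a faithful forward model of human blood.

## Problem sizes and determinism

Default analysis runs use 8 + 8 subjects at 2,000 template clonotypes and
depth 10^5; a full simulated pipeline run completes in seconds, and the
replicate-recovery checks in the test suite use 50 cohorts. Every
stochastic component (simulation, RDI subsampling, evenness subsampling,
Monte-Carlo P_gen) takes an explicit seed or Generator; all cohort
streams derive from one master seed via seed-sequence spawning, so runs
are byte-reproducible. The pipeline manifest records the seed, parameters
and package version needed to reproduce a run.

## Known limitations

Cross-subject (pooled) clustering is simplified to per-subject
clustering. The RDI is reported without null calibration, so its absolute
scale depends on depth and category count. The generation model's
simplicity makes P_gen values comparable only within a model, not against
nucleotide-level tools. Motif enrichment uses clonotype-level presence,
ignoring abundance. The annotation monotonicity guarantee (more reference
entries never un-annotate a clonotype) holds per strategy but reference
clustering can reshape strategy-2 eligibility when entries are removed.
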