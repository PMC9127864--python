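# tcrep

Comparative analysis of T-cell receptor beta-chain (TCRβ) clonotype
repertoires between two matched patient groups — the analysis setting is a
paired case/control design such as aldosterone-producing adenoma (APA)
versus essential hypertension (EH), where the questions are: is the
repertoire less diverse in the case group, are repertoires less similar
between case subjects, which clonotypes carry known ("common") antigen
specificities, and is clonal abundance coupled to how easily a receptor is
generated by V(D)J recombination (a signature of bystander T-cell
activation)?

`tcrep` implements the full analysis as a tested, reusable library plus a
thin CLI, and ships a ground-truthed synthetic cohort generator so every
stage is verifiable without patient data.

## What it computes

**Diversity.** For a repertoire with clonotype frequencies *pᵢ*, the Hill
number of order α is

&nbsp;&nbsp;&nbsp;&nbsp;ᵅD = (Σᵢ pᵢᵅ)^(1/(1−α)),

with ⁰D the richness and ¹D = exp(H′) the exponential of Shannon entropy
(used exactly at α = 1). Profiles are reported over α ∈ [0, 10] together
with the Rényi entropy ᵅH = ln(ᵅD), Pielou's evenness J′ = H′/ln N,
clone-size spectra (hyper-expanded > 1 %, high 0.1–1 %, medium
0.01–0.1 %, low ≤ 0.01 %), and top-rank cumulative abundances.

**Similarity and usage.** Morisita–Horn overlap
MH = 2Σxᵢyᵢ / Σ(xᵢ² + yᵢ²) over the union of unique clonotypes (0 =
disjoint, 1 = identical), V/J/V–J/CDR3-length usage profiles, and the
repertoire dissimilarity index (RDI): subsampled usage vectors,
variance-stabilized as 2√count, Euclidean distance averaged over
iterations.

**Clustering and annotation.** Clonotypes are grouped into putative
shared-specificity clusters by global CDR3 similarity (equal length, ≤ 1
interior mismatch; the first 3 and last 2 residues must match) and by
enriched interior k-mers (k = 3, 4; Fisher's exact test against a naive
background). Clusters are typed global/motif/mixed. Annotation against a
VDJdb-style reference runs two strategies: exact V-gene + CDR3 matching,
and matching against per-epitope clustered reference entries (same V gene,
≤ 1 substitution) plus motif-to-motif matching; common status propagates
to whole clusters.

**Generation probability.** An explicit amino-acid-level V–insert–J model
assigns every CDR3 an exact generation probability P_gen by finite
summation over all (V, trim, insertion, trim, J) decompositions;
externally computed P_gen tables can be supplied instead. Per subject, the
package reports Pearson's r between log₁₀ frequency and log₁₀ P_gen — the
coupling that bystander activation is expected to strengthen.

**Statistics.** Two-sided Wilcoxon signed-rank tests for paired group
contrasts (exact small-sample distribution), rank-sum tests for
intra/inter-group similarity contrasts, linear regression of clinical
features (PAC, ARR, PRA, sodium, …) on the per-subject coupling
coefficient, and Benjamini–Hochberg FDR correction per analysis family.

**Synthetic cohorts.** `tcrep.simulate` generates paired cohorts with
group-controlled evenness (Dirichlet concentration), a tunable
frequency/P_gen coupling β per subject, planted reference-documented
clonotypes, matched clinical covariates driven by the true β, and a JSON
ground-truth ledger for recovery tests.

## Worked example

```sh
tcrep simulate --outdir demo --seed 4 --pairs 2 --clonotypes 300
tcrep diversity demo/APA00.tsv
```

prints, for the first simulated case subject:

```json
{
 "subject_id": "APA00",
 "richness": 205,
 "shannon_exp": 26.732767272636895,
 "pielou": 0.6172992469519611,
 "clone_size_cumfreq": {
  "hyper": 0.7852821471785283,
  "high": 0.19075809241907582,
  "medium": 0.021099789002109983,
  "low": 0.0028599714002859973
 }
}
```

205 unique clonotypes were observed, but their abundances are so skewed
that the effective diversity (exp Shannon) is only ~27 and evenness is
0.62; 79 % of all reads sit in hyper-expanded clones (> 1 % each) — the
expected picture for a strongly expanded case-group repertoire.

The full analysis (diversity → similarity → usage/RDI → clustering →
annotation → P_gen coupling → clinical association, one TSV per stage plus
a reproducibility manifest) runs from a YAML config:

```yaml
# config.yaml
outdir: out
seed: 1
simulation: {}        # or an `inputs:` block pointing at your own tables
```

```sh
tcrep run config.yaml
```

`tcrep.pipeline.run_pipeline` is the same entry point as a library call.
Real data enter as AIRR rearrangement TSVs or MiXCR clone tables, a
reference TSV (`v_gene`, `cdr3_aa`, `epitope`), and a clinical CSV.

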