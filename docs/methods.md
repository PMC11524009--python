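# Methods

This note records the models, rules and numerical choices behind each
stage of the package, what the synthetic generators do and do not
emulate, and the known limitations.

## Interactome model

The interactome is star-shaped around a curated list of disease seed
genes: every edge must touch at least one seed (seed–seed edges are
allowed; edges between two non-seed proteins are rejected with a
warning).  Known edges come from interaction-repository-style edge
lists; predicted edges carry a score in [0, 1] and are retained only
when the score is **strictly greater** than the calling threshold
(default 0.5) — a pair scoring exactly 0.5 is not called.  When a pair
is both known and predicted, known provenance wins and the event is
logged.  Non-seed nodes are classed *known interactor* if any incident
edge is known, else *novel interactor*; seeds with no edges remain as
isolated nodes so degree accounting never loses them.

Two counting conventions are reported side by side because published
per-gene tables list a seed–seed predicted pair under both endpoints:
`listed_pairs` counts per-row listings (the bundled MPeM table gives
417) and `unique_edges` counts canonical edges once (416).  Similarly,
"novel interactor" can mean a node with only predicted edges (the
node-class count) or any non-seed partner of a predicted edge
(`n_novel_partners`); both are reported.  The bundled table's MRE11 row
prints a novel-PPI count of 8 but lists 7 usable partner symbols; the
loader keeps both numbers and a test asserts the discrepancy is visible
rather than absorbed.

## Pairwise PPI prediction

The classifier reproduces the shape of pairwise interaction prediction:
symmetric features per unordered gene pair —

| feature | definition | default when unavailable |
|---|---|---|
| coexpr | Pearson r of expression rows over shared non-missing conditions (needs ≥ 3) | 0, n_missing+1 |
| mf/bp/loc_jaccard | \|X∩Y\|/\|X∪Y\| on annotation term sets | 0, n_missing+1 if a set is empty |
| same_chrom | same-chromosome indicator | 0, n_missing+1 if unknown |
| log_prox | log10(1 + \|pos_a − pos_b\|) on the same chromosome, else 0 | 0 |
| n_missing | number of imputed features | — |

— fed to a random forest (default 500 trees; training uses seeded 1:1
downsampling of the larger class and reports stratified 5-fold
cross-validated precision/recall/AUROC).  The score is the forest's
positive-class probability and candidate partners are called at score
strictly > 0.5.  The original high-precision model's training corpus
and exact encodings are not public, so the trained artifact here is
replaceable by design and is validated by recovery of planted signal on
synthetic truth, not by reproducing any published pair list; the 417
published predicted pairs enter the pipeline as packaged data.

## Enrichment statistics

All overlap tests are one-sided over-representation tests.  The
hypergeometric path computes P(X ≥ k) directly; the Fisher path uses
the exact test on the 2×2 table — the two are mathematically identical
and the test suite verifies agreement to ≤ 1e−10 relative error
exhaustively for every table with universe ≤ 60.  Odds ratios are
sample ORs (ad/bc) with 0.5 added to every cell only when some cell is
zero, keeping them finite without biasing non-degenerate tables.
Benjamini–Hochberg adjustment is applied within one collection per
call, never pooled across collections.  The background universe is an
explicit argument everywhere: published enrichment p-values in this
domain routinely omit their background, which is the single largest
obstacle to reproducing them, so no default universe is assumed.

## Tissue specificity

Classification runs on a gene × tissue matrix of mean TPM (an
`aggregate` step averages samples per tissue first).  Rules, applied
with precedence enriched > group-enriched > enhanced, all with the
> 1 TPM floor applied uniformly:

- *tissue-enriched*: top tissue ≥ fold × the **maximum** over all other
  tissues (fold default 5; a zero maximum counts as satisfied);
- *group-enriched*: the smallest descending-sorted prefix of 2–7
  tissues whose minimum is ≥ fold × the maximum outside the prefix;
- *tissue-enhanced*: top tissue ≥ fold × the **mean** over all tissues.

Max-of-others (not mean) is used for the first two rules, matching the
tissue-atlas semantics the categories come from; the enhanced rule uses
the all-tissue mean per its definition.  Ties in the descending sort
are broken by tissue name so group prefixes are reproducible.  The
specificity index si = mean over non-target tissues of
max(0, 1 − expr_t/expr_target) (si ∈ [0, 1]; > 0.8 called
tissue-specific; undefined at zero target expression) is this package's
explicit formula — the proprietary index it stands in for is
unpublished, so the 0.57 value reported for OVGP1 elsewhere is a
reference case, not a target.

## Functional modules

Similarity between genes is the Jaccard index of their direct network
neighbourhoods; each gene's k most similar genes (default k = 10, ties
by name) form its kNN set, and two genes are joined with weight
|kNN(u) ∩ kNN(v)| when they share at least one.  Louvain modularity
optimisation (networkx implementation, fixed seed, resolution γ = 1)
partitions the graph; modules of ≤ 4 genes are retained in the
partition but filtered from annotation reporting.  Each reported module
is annotated with the GO-BP term minimising the BH-adjusted p within
the module's own enrichment family; modules with nothing at q < 0.05
are reported unannotated.  The published 14-module decomposition was
produced on proprietary tissue-specific functional networks and is
documented as a reference case; this package runs the same algorithmic
recipe on the assembled interactome itself, validated by
adjusted-Rand-index recovery (≥ 0.9) of planted partitions.

## Prognostic screening

Per gene, patients are split at the median expression (ties to the low
stratum; strata with < 2 patients yield no call), and the two strata
are compared by the standard log-rank test: over distinct event times
j, χ² = (Σ_j (O_1j − E_1j))² / Σ_j V_j with hypergeometric variance
V_j = d_j (n_1j/n_j)(1 − n_1j/n_j)(n_j − d_j)/(n_j − 1), referred to
χ²(1).  With zero events the test is undefined and p = 1 is returned
with a warning.  Genes at raw p < 0.001 are called prognostic — no
multiplicity adjustment, faithfully emulating the registry criterion
this screen mirrors — with direction *unfavourable* when the
high-expression stratum has the smaller restricted mean survival (area
under the Kaplan–Meier curve to the last observed time); the
restricted-mean comparison avoids any proportional-hazards assumption.
The statistic is implemented directly (vectorised) and is checked in
the tests against lifelines (exact agreement) and against exhaustive
permutation enumeration on small cohorts.  At ≤ 8 patients the
asymptotic χ² p-value and the exact permutation p differ substantially
by nature (the tests verify the statistic and its permutation ranking
there, and p-agreement within Monte-Carlo error at n = 40).

## Drug repurposing

Signature reversal is Spearman rank correlation of log2-fold-change
profiles over shared genes (≥ 10 required; fewer yields no result,
with a warning).  A qualifying reversal is ρ < 0 with p ≤ 0.05.  A drug
is shortlisted when it reverses at least `min_datasets` (default 1)
disease contrasts *and* targets at least one interactome node; ranking
is by (number of reversed datasets descending, mean ρ ascending), and
the output is stratified into multi-dataset vs single-dataset groups.
Correlation p-values are not BH-adjusted across drugs by default
(shortlisting is per-dataset thresholding); a flag enables adjustment.
The published 39/23/16 drug counts derive from a proprietary
correlation engine whose statistic is unpublished and are documented
reference cases.

## Synthetic data: what it emulates and what it does not

All generators are pure functions of (parameters, seed).

- **World** (`generate_world`): Barabási–Albert truth network (m = 3
  edges per new node — heavy-tailed degrees like real PPI networks),
  random chromosome/position assignment, GO-like term sets shared along
  true edges with probability 0.3, and a 50-condition expression
  compendium with correlation ρ = 0.6 planted on a matching of true
  pairs.
- **Labelled pairs**: positives are a disjoint matching of truth edges,
  negatives disjoint non-edges; planted co-expression is
  N(0.5·signal, 0.2) for positives vs N(0, 0.2) for negatives, and
  annotation-term sharing is 0.1 + 0.4·signal vs 0.1.  Term sets are
  drawn fresh here (not taken from the world) so that at signal = 0 the
  classes are exactly exchangeable and classifier AUROC is ~0.5.
- **Disease study**: the overlap count between a DE set and the
  interactome is drawn from Fisher's noncentral hypergeometric
  distribution with the planted odds parameter, so the expected sample
  OR equals the planted OR.
- **Tissue matrix** (12 tissues, baseline 5 TPM, multiplicative noise
  with CV 0.1): enriched/group genes are raised 8× baseline in their
  tissue(s); enhanced genes 16× with one decoy tissue at 4.5× —
  analytically placed so the decoy blocks the enriched rule while the
  target still clears 5× the all-tissue mean with ≥ 95% probability at
  CV 0.1.
- **Survival cohort**: exponential event times (base hazard 0.02 per
  month, median ~35 months), hazard multiplied by the planted ratio for
  patients above the gene's median expression, independent exponential
  censoring tuned to the requested censoring fraction.
- **Drug library**: planted reversers carry the negated mean disease
  signature plus N(0, noise_sd) noise (0.3 in the recovery
  experiments) and always target the interactome; other drugs are
  random.

The generators reproduce the *statistical structure* each stage
assumes, not real biology: no literature-calibrated effect sizes, no
correlated annotation bias between related genes, no batch effects, no
informative censoring, no realistic drug polypharmacology.  Passing
recovery tests therefore demonstrates that the algorithms recover what
they are designed to recover under their stated assumptions — not that
real-data results would reach the same accuracy.

## Problem sizes used in tests and the acceptance script

Synthetic experiments run at sizes chosen to make the Monte-Carlo error
small relative to each tolerance while keeping runs quick: 2 000
labelled pairs on a 5 000-gene world for the classifier; 10 000
replicates for the null overlap calibration (universe 20 000, set sizes
2 000/1 000, chosen analytically so the discrete test's achieved size
is 0.049); 10 000 gene-level null survival tests across 40 independent
cohorts of 100 patients; 50 seeds per planted odds ratio; 80 planted
tissue genes; 20 seeds each for the hazard-gene and drug-reverser
recoveries; a 10-block × 20-node planted-partition graph for Louvain.

## Known limitations

- Gene identity is the uppercased symbol; no alias resolution or
  cross-species orthologue mapping (a two-column mapping file can be
  applied upstream by the caller).
- The published global counts (4 747 known PPIs, 2 747 known and 306
  novel interactors) depend on unprinted known-edge lists and cannot be
  recomputed from packaged data; the bundled per-gene table reproduces
  the novel-PPI accounting exactly (with the MRE11 caveat above).
- Enrichment results are only as meaningful as the chosen universe;
  the package forces that choice to be explicit rather than defaulting
  silently.
- The Louvain partition depends on its seed; determinism is guaranteed
  per seed, not across seeds.
- The drug-reversal statistic is a standard surrogate (Spearman on
  shared DE genes), not the proprietary score used in the original
  shortlists.
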