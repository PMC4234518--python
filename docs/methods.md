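# Methods

This note records the models the package implements, the parameters that
matter, what the synthetic generators do and do not emulate, and the
numerical choices made where the design was genuinely open.

## Interaction matrix

The unit of evidence is one (factor, target) pair, optionally tagged with the
detecting technique and a binding interval. Coordinates are stored 0-based
half-open (BED convention); 1-based inclusive dialects are converted at parse
time. Duplicate pairs are preserved at the record level and collapse to a
single 1 when the Boolean matrix is built, so the matrix never over-counts
repeated evidence. Rows (targets) and columns (factors) are sorted
lexicographically, which makes every downstream table deterministic.

Evidence tags are free strings matched case-insensitively after trimming.
Three named presets group the common techniques: `par-clip` ({PAR-CLIP}),
`other-clip` ({CLIP, CLIP-seq, HITS-CLIP, iCLIP}) and `rip` ({RIP}).
Targets may be UTR IDs or gene IDs — the matrix is agnostic; an optional
target→gene mapping is applied only when reporting gene-level sets.

## Greedy Boolean matrix factorization

Model: C ≈ S∘B with Boolean product (saturating addition), objective
|C − S∘B| (symmetric Hamming distance — uncovered ones and over-covered
zeros both count). Exact Boolean factorization is NP-hard; the miner is the
greedy association-based scheme:

1. **Association scores** between factor columns. Unbalanced:
   shared-target count over the seed's target count (asymmetric; lets
   widely-interacting factors join many seeds). Balanced: cosine similarity
   (symmetric; groups factors of comparable degree). All-zero columns score
   0 everywhere, including the diagonal.
2. **Candidate basis** A: A[i, j] = 1 iff score(i → j) ≥ τ. Row i is the
   cluster seeded by factor i. The comparison uses a 1e-12 slack so scores
   mathematically equal to τ are never lost to float round-off.
3. **Greedy selection**: for each unused candidate row, the best usage
   column sets s_i = 1 iff w₊·(newly covered ones of row i) − w₋·(newly
   covered zeros) > 0; the candidate with the largest total gain wins.
   Selection stops early when no candidate has positive gain, so fewer than
   k clusters may be returned.

Parameters and defaults: k = 25 clusters requested; τ = 0.6 for the first
pass and 0.4 for the sporadic pass (the working defaults of the published
human analysis); w₊ = w₋ = 1, matching the unweighted printed objective —
both configurable for asymmetric covering costs. "Priority to denser rows"
is realized implicitly by maximal-gain selection rather than a separate
ordering pass. Usage columns are not re-iterated after all rows are chosen
(single-pass greedy); re-selecting a verbatim-identical candidate row is
skipped as zero-gain.

Tie-breaking is fixed everywhere so runs are byte-reproducible: candidate
ties go to the lowest seed index; the final cluster ordering is by coverage
descending, then lexicographically smaller member set. Coverage is computed
per cluster on the final (B, S) as the number of ones of C inside the
cluster's rank-1 block; overlapping clusters may therefore both count a
shared 1, which is intended — coverage ranks clusters individually.

**Two-pass workflow.** Recurrent factors are those appearing in ≥ 2 pass-1
clusters (singleton clusters count as memberships). Their columns are
removed, targets left with no interaction are dropped, and the miner reruns
on the reduced matrix; pass-1 clusters carry R-prefixed IDs, pass-2
S-prefixed.

**τ selection.** The parameter surface reports the mean cluster size per
(k, τ) cell; the selected τ is the grid value whose mean size at the user's
k is closest to the mean number of factors bound per target (mean, not
median, per the stated heuristic), ties toward larger τ. The "stable
region" visual criterion is not automated — the surface is emitted as a TSV
for inspection.

## Cluster characterization

A cluster's target set is the intersection of its members' columns: the
targets bound by *every* member. Jaccard similarity |A∩B|/|A∪B| (defined 0
for two empty sets) compares clusters over target sets or member sets;
singletons are excluded from overlap matrices by caller choice, since a
one-factor cluster is not a combination.

**Enrichment.** One-sided Fisher exact (hypergeometric upper tail) per GO
term after propagating annotations to all is_a/part_of ancestors.
α = 0.05 on raw p-values with no multiple-testing correction — the topGO
convention for this analysis style; configurable. The *elim* variant
processes terms from the deepest DAG level (longest path to the namespace
root; ties by term ID) upward and, when a term tests at or below the
elimination threshold (default: α, configurable — reference implementations
differ and the choice is genuinely open), removes that term's study genes
from the annotation sets of all its ancestors before they are tested. The
enrichment background defaults to the genes with at least one interaction
in C (overridable); the alternative — all annotated genes — is equally
defensible, and the choice is surfaced rather than hidden.

*Emergent enrichments* are terms significant for the cluster's intersection
target set but for none of the individual members' target sets: annotations
that only the combination concentrates.

**Semantic similarity.** Wang's method: S-values propagate from the term
through its ancestor closure, S(term) = 1 and S(t) = max over children c of
w(edge)·S(c), with is_a weight 0.8 and part_of 0.6 (the method's standard
factors); other relations do not contribute. Term-list similarity is the
best-match average. Both are symmetric, bounded in [0, 1], and 1 on
identical inputs.

## Binding-site classifier

Sites are 20–70 nt sequences (bounds configurable; T silently read as U).
Pair tasks are class-balanced: when two RBPs' pools differ, the larger is
downsampled with the run seed.

**Folding.** The built-in backend is a Nussinov maximum-base-pairing DP
(canonical pairs AU/GC/GU, minimum hairpin loop 3) with stochastic traceback
sampling distinct co-optimal structures (duplicates re-drawn up to a retry
cap). This is a deliberately cheap stand-in for thermodynamic suboptimal-
structure samplers: it captures stem/loop architecture, not free energies.
Supplying dot-bracket strings per site gives exact parity with any external
folder. All structures of one sequence live in one disconnected graph, one
component per structure; vertices carry the nucleotide, edges are labeled
backbone or basepair.

**NSPDK features.** For every unordered vertex pair within a component at
shortest-path distance d ≤ D and every radius r ≤ R, the two radius-r
neighborhood subgraphs get quasi-canonical labels by iterative label
refinement (r rounds, seeded with distance-to-root and vertex label, folding
in edge labels), and the label pair with (d, r) is hashed into one of 2^b
bins of the (r, d) block. Defaults R = 2, D = 4, b = 20. Normalization is
per-(r, d)-block L2 followed by global L2, so self-similarity is exactly 1.
Hashing uses a fixed public mix (BLAKE2b-64 of the canonical tuple) — seeds
never affect the feature space, so encodings are comparable across runs.
Label refinement is a Weisfeiler–Leman-style approximation of subgraph
isomorphism: on the labeled, distance-annotated balls arising from RNA
graphs it is exact in practice (the test suite checks agreement with an
explicit rooted-isomorphism enumeration on small graphs), though
adversarial regular graphs could in principle collide.

**SVM and metrics.** Per stratified fold (default 10; configurable — the
averaging scheme is a free choice) an unbiased hinge-loss linear model is
trained by SGD (regularization 1e-4, epochs 100) on the hashed features.
AUROCC is the Mann–Whitney rank statistic with ties averaged, reported as
the mean over folds; F1, precision and sensitivity are computed at decision
threshold 0 on the pooled held-out predictions (threshold 0 is the natural
operating point of an unbiased hinge model). Site distances are
midpoint-to-midpoint by default (the natural choice when site lengths vary);
edge-to-edge gap is available, with overlapping sites at gap 0.

## Synthetic generators

`planted_matrix` draws C as a union of planted rank-1 blocks plus
independent bit flips (defaults: no noise; the acceptance scenarios use 2%,
a plausible per-entry error rate for curated interaction maps). It emulates
block co-regulation structure only — not the heavy-tailed factor degree
distribution of real compendia (where one factor can bind tens of thousands
of UTRs while the median is a dozen), so a green recovery test establishes
correctness of the miner, not robustness to extreme degree skew.

`synthetic_sites` embeds a class motif in uniform-random RNA backgrounds,
optionally wrapped in a 6 bp complementary hairpin so part of the signal is
structural. Per-site random streams derive from (seed, index), so extending
a set never perturbs existing sites. Real CLIP site sets have composition
bias, shared flanking context and cross-contamination that these sites do
not; classifier sanity checks here establish that the pipeline separates
separable classes and stays at chance on null splits, not field performance.

`toy_ontology` builds a balanced is_a tree with a few part_of cross-edges
and random leaf annotations, optionally concentrating one term on a gene
subset. Real GO is deeper, more irregular and multi-rooted per namespace.

## Degenerate inputs and edge cases

Empty record lists, empty study sets, single-class label vectors,
cross-namespace term pairs and dimension mismatches raise errors naming the
cause. All-zero factor columns are tolerated (scored 0, logged). Jaccard of
two empty sets is 0 by convention (logged). Folding retry exhaustion simply
returns fewer distinct structures. The AUROCC of a fold requires both
classes; stratified folds enforce this, and the fold count must not exceed
the smaller class size.

## Known limitations

- No optimal BMF solver beyond the exhaustive test oracle; the greedy result
  carries no approximation guarantee.
- No weighted/probabilistic interactions (binding scores, technique
  confidence) — the matrix is strictly Boolean.
- The built-in folder ignores thermodynamics; nested structures only.
- No multiple-testing correction in enrichment by design; interpret p-values
  as ranking scores, as is conventional for elim-decorrelated scans.
- Semantic similarity implements Wang/BMA only.
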