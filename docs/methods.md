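# Methods

## Model overview

`metnet` models the genetic commonality between a small molecule (for
us, a gut microbial metabolite) and complex diseases as proximity on a
weighted disease network.  Disease nodes carry the set of genes
associated with the trait; a metabolite node carries its
chemical–gene association set.  All similarity is set-based: for gene
sets *A* and *B* the cosine similarity of their binary indicator
vectors is

    w(A, B) = |A ∩ B| / sqrt(|A| · |B|)  ∈ [0, 1],

and every stored edge has weight strictly greater than zero.

Two network modes exist:

* **direct** (default): an edge exists iff the gene sets intersect.
* **indirect**: diseases whose genes do not overlap are additionally
  connected when at least one PPI links the two sets, or at least one
  pathway contains genes from both (criteria combined with OR by
  default, AND optionally).  Weights in indirect mode are cosines of
  *augmented* sets — the original genes plus their PPI neighbors
  and/or pathway co-members, restricted to genes that occur anywhere
  in the association table.  This is applied uniformly to all edges
  (not only the newly added ones), which is the one consistent rule
  that (a) keeps weights in [0, 1], (b) guarantees a positive weight
  whenever the connection criterion holds, and (c) reduces exactly to
  the direct weight when augmentation adds nothing.

GWAS-derived and OMIM-derived networks are built and analyzed
separately; each distinct trait label ("AD biomarkers", "AD (late
onset)", …) is its own node.

## Ranking by random walk with restart

Diseases are prioritized for a metabolite by a random walk with
restart seeded at the metabolite node.  With T the column-normalized
(weighted-degree) transition matrix and e the seed indicator, the
iteration

    p ← (1 − r) · T p + r · e

runs until the maximum absolute change drops below the tolerance.
Column normalization is used because it keeps the score vector a
probability distribution at every step (scores over all nodes sum
to 1), which the percentile bootstrap below relies on; a symmetric
normalization would not conserve mass.  Zero-degree columns redirect
to the seed, so isolated diseases are never visited: they score 0 and
rank last.

Defaults: restart probability r = 0.75, tolerance 1e-10, at most
10 000 iterations (with r = 0.75 the contraction factor is 0.25 and
convergence takes ~20 iterations).  Ranks are fractional with ties
sharing the average of the ranks they span; the percentile of a
disease is rank / n_diseases × 100, so "top 1.25 %" means the disease
sits at rank 11 of 881.  Display order breaks ties by label; the
statistics do not depend on it.

The restart walk is a standard choice for network-medicine
prioritization; the closed-form stationary solution
p = r (I − (1 − r) T)⁻¹ e serves as an independent oracle in the test
suite (agreement within 1e-10 on random small networks).

## Permutation null and statistics

The null model randomizes the real mGDN by **double-edge swaps** over
the combined edge set (disease–disease and metabolite–disease edges
together): two random edges (x,y), (p,q) are replaced by (x,p), (y,q)
unless a self-loop or duplicate would result.  10·|E| swap attempts
are made per replicate, degrees are preserved exactly, and the weight
multiset is preserved and reassigned to the shuffled edges uniformly
at random.  A naive endpoint shuffle (degrees free) is available as a
fallback for graphs too rigid to admit any swap; if that shuffle
disconnects the metabolite in a replicate, the disease of interest is
assigned the median rank for that replicate and the occurrence is
logged.

For a (metabolite, disease) pair with observed percentile *o* and null
percentiles {nᵢ} from `n_perm` replicates (default 1000):

* enrichment fold = mean(nᵢ) / o, also rendered as a percent
  (fold 3.534 ↔ "353.4 %");
* empirical p-value = (1 + #{nᵢ ≤ o}) / (1 + n_perm) — the add-one
  rule keeps it strictly positive and is the recommended headline
  statistic;
* t-test p-value: one-sample two-sided test of {nᵢ} against *o*.
  With ~1000 replicates this test is extremely powerful and its
  p-values are often astronomically small; it is reported for
  comparability, not as the primary criterion.

Per-trait profiles collect the metabolites passing a
Benjamini–Hochberg FDR of 0.05 on the empirical p-values (correction
and threshold configurable: `bonferroni`, `none`).  Profiles are
compared by Jaccard similarity |A∩B|/|A∪B|, against the random
expectation (n₁/N)(n₂/N) for independent subsets of the N metabolites
tested; for profiles of 56 and 62 metabolites out of 171 that
expectation is 0.1187 (≈ 11.9 %).

## Pathway co-regulation score

For a metabolite gene set and a disease gene set, shared pathways are
those containing at least one gene from each side.  Each shared
pathway scores

    R = (Σᵢ Gᵢ) · (Σⱼ Gⱼ),

the product of the per-side gene sums; with unit (indicator) weights
this is the product of the two gene counts, so pathways rich in both
metabolite- and disease-associated genes rank first.  Ties break
alphabetically.  A gene associated with both sides counts on both
sides — the two sums are independent.  An optional `evidence`
weighting substitutes per-gene association scores for the unit
weights; indicator weighting is the default.

## Input handling defaults

* Gene identifiers are plain uppercase symbols, whitespace-trimmed; no
  identifier-mapping service is used and cross-source joins are
  symbol-exact.
* Chemical–gene evidence scores: values on a 0–1000 integer scale are
  auto-detected (max > 1) and divided by 1000; default retention
  threshold 0.4 (mid confidence), configurable.
* PPI confidences: same rescaling; default threshold 0.7 (high
  confidence), configurable.  Both thresholds are exposed because no
  canonical cutoff exists for this analysis.
* Dialect column names (GWAS-catalog-, OMIM-, STITCH-, STRING-style)
  are resolved from alias lists; an explicit column map overrides
  them.

## Synthetic-data generator

The generator emulates the five input families with exactly countable
ground truth:

* Disease gene sets are uniform random subsets (default 5–15 genes) of
  an `n_genes` universe (default 200); their chance overlaps create
  the GDN edges.
* Metabolite gene sets combine decoy genes from a reserved pool
  disjoint from the disease universe, per-(metabolite, disease)
  background genes included independently with probability
  `background_overlap` (default 0.02), and, for planted pairs, exactly
  ⌈overlap_fraction × |disease genes|⌉ of that disease's genes
  (default one planted pair at fraction 0.5).  Keeping decoys outside
  the disease universe makes the realized background rate equal the
  configured dial and the planted overlap exact.
* Chemical–gene evidence scores are uniform on [0.4, 1.0] and PPI
  confidences uniform on [0.7, 1.0], so default loading thresholds
  retain all generated signal; PPI density defaults to 0.01 of all
  gene pairs, and 50 pathways of 10–30 genes are drawn from the full
  gene universe.
* The first disease labels are AD-like multi-trait names so
  cross-trait profile operations are exercised realistically.  The
  same seed yields a byte-identical bundle.

What the generator does **not** emulate: linkage disequilibrium and
GWAS effect sizes, hub structure and modularity of real PPI networks,
hierarchically nested pathway collections, correlated trait
definitions, and literature-biased gene annotation.  Passing tests
therefore demonstrate the correctness and calibration of the
*algorithms* under exchangeable nulls and planted signal — not that
any particular real metabolite–disease association is reproducible.

## Statistical study sizes

The statistical guarantees in the test suite use sizes chosen to make
the Monte-Carlo error small while keeping the studies desk-scale:

* **Calibration**: 500 independent background-only fixtures (40
  diseases drawing 5–10 genes from a 600-gene universe, 5 %
  background), 200 permutations each; the rejection rate of the
  empirical p-value at α = 0.05 must lie in [0.02, 0.08].  Forty
  diseases keep the percentile grid fine enough that the add-one
  p-value is not overly conservative under rank discreteness.
* **Recovery**: 20 fixtures at the default planted configuration (200
  genes, 40 diseases, 20 metabolites, one planted pair at overlap
  0.5, background 0.02), 500 permutations; the planted disease must
  reach the top 3 with p < 0.05 in ≥ 90 % of seeds.  With 40 diseases
  the best achievable observed percentile is 2.5 %, so empirical
  p-values sit near 0.03 even for a rank-1 hit — the criterion
  operates close to the resolution limit of a 40-disease percentile
  grid, which is why the recovery rate is ~0.9 rather than 1.0.

## Known limitations

* The exact prioritization algorithm used in the antecedent literature
  is not restated there; the restart walk with the defaults above is a
  documented substitution, standard for this problem class.
* Whether historical edge shuffles preserved degrees or weights is
  unknown; degree-preserving swaps with weight reassignment are the
  default, with the naive shuffle as an explicit alternative.
* Indirect-mode edge weighting (augmented-set cosine) is this
  package's construction; only the connection criterion itself is
  standard.
* The t-test treats null percentiles as approximately normal; for
  small n_perm or heavily tied ranks the empirical p-value should be
  used instead.
* Pathway scores are association counts, not enrichment statistics; no
  background correction for pathway size is applied (by design — the
  score is the product form above).
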