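# metnet

Network-medicine toolkit for linking small molecules — typically gut
microbial metabolites — to the genetics of complex diseases.  Given
disease–gene association tables (GWAS-catalog- or OMIM-style),
chemical–gene associations with evidence scores (STITCH-style),
protein–protein interactions (STRING-style), and pathway gene sets
(GMT), `metnet`:

1. builds a **genetic disease network (GDN)**: diseases are nodes, two
   diseases are connected when they share associated genes (or, in
   *indirect* mode, when their genes interact or co-occur in a
   pathway), with edge weight the cosine similarity of the gene sets,
   `w(A,B) = |A∩B| / √(|A|·|B|)`;
2. inserts a metabolite node (**mGDN**) connected to every disease
   whose genes overlap the metabolite's, weighted the same way;
3. ranks all diseases for that metabolite by **random walk with
   restart** from the metabolite node (restart probability `r`, column
   normalization; steady state `p = r·(I − (1−r)·T)⁻¹·e`), reporting
   rank percentiles (`rank / n_diseases × 100`);
4. assesses significance against a null of **degree-preserving
   edge-shuffled** networks: the enrichment fold
   `mean(null percentile) / observed percentile`, an add-one empirical
   p-value `(1 + #{null ≤ obs}) / (1 + n_perm)`, and a one-sample
   t-test of the null percentiles against the observed value;
5. compares per-trait **significant-metabolite profiles** by Jaccard
   similarity `|A∩B|/|A∪B|` against the random expectation
   `(n₁/N)·(n₂/N)`;
6. scores pathways **co-regulated** by a metabolite and a disease:
   for each pathway containing genes from both sides,
   `score = Σᵢ Gᵢ · Σⱼ Gⱼ` (with unit gene weights, the product of the
   two gene counts).

A synthetic-data generator emits all five input files with planted
metabolite–disease overlap, so the entire pipeline is testable without
any database download.

## Worked example

```python
from metnet import (FixtureConfig, simulate, build_gdn, insert_metabolite,
                    rank_diseases, permutation_test, format_enrichment_percent)

fx = simulate(FixtureConfig(seed=0))          # planted: M0001 <-> "AD biomarkers"
gdn = build_gdn(fx.disease_gene, mode="direct")
mgdn = insert_metabolite(gdn, "M0001", fx.chemical_gene.gene_sets()["M0001"])

ranked = rank_diseases(mgdn, restart_prob=0.75)
top = ranked.entries[0]
print(f"top disease for M0001: {top.disease!r} (rank {top.rank:.0f}, top {top.percentile:.2f} %)")

res = permutation_test(mgdn, "AD biomarkers", n_perm=1000, seed=42)
print(f"observed percentile : {res.observed_percentile:.2f} %")
print(f"null mean percentile: {res.null_mean:.1f} %")
print(f"enrichment          : {res.enrichment_fold:.2f}-fold "
      f"({format_enrichment_percent(res.enrichment_fold)})")
print(f"p_empirical = {res.p_empirical:.4f}, p_ttest = {res.p_ttest:.3g}")
```

prints

```
top disease for M0001: 'AD biomarkers' (rank 1, top 2.50 %)
observed percentile : 2.50 %
null mean percentile: 47.6 %
enrichment          : 19.04-fold (1904.0 %)
p_empirical = 0.0200, p_ttest = 6.31e-308
```

The generator planted a metabolite sharing half of the genes of the
"AD biomarkers" trait (2 % background overlap elsewhere).  The walk
ranks that trait first of 40 diseases (top 2.5 %), while on 1000
edge-shuffled networks the trait sits near the 48th percentile on
average — a 19-fold enrichment with an empirical p-value of 0.02.

The same steps are available from a shell: `metnet simulate`,
`metnet build`, `metnet rank`, `metnet test`, `metnet profiles`,
`metnet profile-sim`, `metnet pathways`, `metnet load-check`
(see `metnet --help`).

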