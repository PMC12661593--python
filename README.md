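# ppicohort

Multi-sample protein–protein interaction (PPI) network analysis for
patient stratification.

Most differential-expression workflows compare group means and lose the
per-patient structure of the signal. `ppicohort` instead builds one PPI
network **per sample** on a fixed background interactome, clusters the
samples by how similar their networks are, and asks which clusters are
enriched for a phenotype — then summarises each phenotype group's
networks into a consensus network whose most-connected ("hub") proteins
are candidate drivers or drug targets. It is aimed at researchers with
a gene × sample matrix of expression z-scores (e.g. a cBioPortal
export), a two-group phenotype assignment, and a STRING-style
interactome.

## Method

For each sample the top-*N* genes by expression z-score (most
upregulated, or most downregulated) are taken as *seed* proteins. The
sample's network contains every interactome edge between two seeds and,
with the maximum path length set to 2, single intermediary (*imputed*)
proteins connecting seed pairs that lack a direct interaction. Samples
are compared by the Jaccard distance between their network node sets,

> J(G₁, G₂) = 1 − |V₁ ∩ V₂| / |V₁ ∪ V₂|,

clustered with UPGMA (average linkage), and every dendrogram branch
below the meta-cluster height threshold is tested for phenotype
enrichment with the two-sided Fisher exact test on the in-cluster ×
group 2×2 table. The cophenetic correlation between the distance matrix
and the tree guides the choice of *N*. Within a significant cluster,
each group's member networks are merged into a consensus network
(keeping proteins that recur in at least half the members by default);
hubs are the highest-degree consensus proteins, community structure is
found by Louvain modularity optimisation, and the topological
separation of the two groups' unique protein sets in the interactome is
quantified by the separation score

> s_AB = ⟨d_AB⟩ − (⟨d_AA⟩ + ⟨d_BB⟩) / 2,

where ⟨d_AA⟩ is the mean shortest-path distance from each member of A
to its nearest other member, and ⟨d_AB⟩ the mean nearest cross-set
distance. s_AB > 0 means the two protein sets occupy separated
interactome neighbourhoods (distinct molecular entities); s_AB < 0
means they overlap.

A synthetic-cohort generator (scale-free interactome, two implanted
connected disease modules with controllable overlap, per-sample module
activation over a standard-normal z-score background) provides ground
truth for every stage.

## Worked example

```python
import ppicohort as pc

cfg = pc.SyntheticConfig(n_proteins=300, module_size_a=12, module_size_b=12,
                         n_group1=12, n_group2=12, rng_seed=11)
interactome, truth, expression = pc.generate_cohort(cfg)

model = pc.CohortNetworkModel(interactome, expression, truth.labels,
                              pc.RunConfig(seed_count=20))
results = model.fit()
print(results.summary())
```

```
Cohort PPI network analysis
============================================================
samples analysed:        24
seed genes per sample:   20 (upregulated)
max path length:         2 (connector mode: best)
cophenetic correlation:  0.8664
significant clusters:    2 (alpha=0.001, height<=0.8)
------------------------------------------------------------
cluster 1 [N21]: n=12 (group1=12, group2=0), p=7.4e-07
  group 1 consensus: 22 nodes / 43 edges; Q=0.2399, 5 modules
    hubs: G0004(11), G0016(11), G0003(8), G0001(7), G0005(6)
------------------------------------------------------------
cluster 2 [N22]: n=12 (group1=0, group2=12), p=7.4e-07
  group 2 consensus: 20 nodes / 30 edges; Q=0.2906, 5 modules
    hubs: G0086(11), G0002(6), G0004(5), G0003(4), G0006(4), G0038(4)
```

The two groups separate cleanly into two pure clusters (each Fisher
p ≈ 7×10⁻⁷: 12 of one group, 0 of the other). The group-1 hub list is
dominated by implanted module-A proteins — here G0004, G0016, G0003 and
G0005 are four of the twelve module-A genes — with degree in
parentheses; the cophenetic correlation of 0.87 says the dendrogram
represents the distance matrix faithfully. `results.save("outdir")`
writes the Newick dendrogram, distance matrix, cluster report,
per-group GraphML/edge/hub tables, separation scores, and a JSON
manifest that suffices to re-execute the identical run.

The same analysis runs from the shell against real data:

```sh
ppicohort run --config run.conf          # full pipeline
ppicohort sweep --config run.conf        # cophenetic sweep over seed counts
ppicohort separation --interactome links.txt --set-a A.txt --set-b B.txt
ppicohort synth --outdir demo --seed 1   # synthetic cohort with ground truth
```

`run.conf` holds `key = value` lines (or YAML) naming the interactome,
expression and phenotype files plus any non-default parameters
(`seed_count = 125`, `max_path_length = 2`, `meta_cluster_threshold =
0.8`, ...). Accepted interactome dialects: STRING `protein.links`
records (`protein1 protein2 combined_score`, scores 0–1000) and 2–3
column edge TSVs.

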