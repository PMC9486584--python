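# dimona

**Di**fferential **m**ulti-**o**mics **n**etwork **a**nalysis: rank drugs by
how strongly the molecular interaction network around their targets differs
between two sample groups (e.g. two disease subtypes), integrating several
omics layers — mRNA, protein, phosphosite, metabolite — into one
heterogeneous network per condition.

It is aimed at computational biologists who have per-layer abundance
matrices for two conditions, a prior-knowledge table linking features across
layers, and a drug→target table, and who want an explainable, edge-level
differential drug response prioritization rather than a black-box score.

## Method

1. **Single-layer networks.** For each layer and condition, a complete
   weighted graph over the features with Spearman (or Pearson) correlations
   as edge weights, computed over pairwise-complete observations. The dense
   graph is reduced to the edges with the largest |weight|, by target
   average degree, target density, or by maximizing the scale-freeness of
   the degree distribution (signed R² of the log–log fit of p(k) on k), with
   the scale-free cut harmonized across conditions so the two reduced
   networks are similar in size.
2. **Multi-layer assembly.** Per condition, layer networks are joined by
   connector edges from prior knowledge: identical feature names across two
   layers at a fixed weight (mRNA–protein, protein–phosphosite), or explicit
   weighted pairs (e.g. protein–metabolite interactions).
3. **Integrated interaction scores.** Each edge's weight is replaced by a
   semi-local score pooling the strength of alternative routes between its
   endpoints:

   s(u,v) = Σ_{l=1..L} (1/|path_l(u,v)|) Σ_{k ∈ path_l(u,v)} Π_{e ∈ k} w(e),

   where path_l(u,v) is the set of simple paths of length l between u and v
   and L (default 3) the maximum length considered. For weights in [−1, 1],
   s ∈ [−L, L]; with L = 1 the transform is the identity. By default, scores
   are computed only for edges incident to drug targets.
4. **Differential network.** The union graph of the two conditions with
   per-edge d = s_A − s_B, an edge missing from one condition contributing
   zero there.
5. **Differential drug response score.** Per drug, |mean| (or |median|) of d
   over all edges incident to its targets; drugs with no such edges are
   reported as unscored. Drugs are ranked by descending score.

Evaluation utilities build ground truth from cell-line sensitivity panels
(per-drug two-sided Mann–Whitney U between conditions), compute ROC AUC,
the unnormalized partial AUC over false positive rates in [0, 0.1] (0.005
for a random ranking, 0.1 for a perfect one), Spearman correlation between
prediction and ground truth, and a mean-PageRank-of-targets baseline.

A synthetic data generator (`dimona.simulate`) produces two-condition
multi-omics cohorts with block-structured correlations, perturbed blocks
whose co-regulation differs between conditions, and drugs with known
differential status — every stage of the pipeline is testable without any
external download.

## Worked example

`examples/02_integrate_and_rank.py` generates a three-layer, 90-feature
cohort (40 samples per condition, 9 correlation blocks of which 3 are
perturbed) and runs the full pipeline:

```
top of the drug ranking (score = |mean differential| over target-incident edges):
drug_id    score  n_edges  rank  unscored  planted_differential
drug006 1.081210       28   1.0     False                  True
drug004 1.017252       34   2.0     False                  True
drug000 0.957516       33   3.0     False                  True
...
per-target trace for drug006:
       target  in_network  n_edges  mean_abs_differential
protein:G0010        True       16               1.059339
protein:G0018        True       13               1.357670
```

All eight drugs whose targets sit inside perturbed correlation blocks rank
at the top, and the per-target trace shows which target's neighborhood
changed most. `examples/03_evaluate.py` scores the default-scale cohort
against its sensitivity-derived ground truth:

```
pipeline:  AUC = 0.950  pAUC = 0.0733  Spearman rho = -0.650 (p = 3.31e-07), n = 50
PageRank:  AUC = 0.463  pAUC = 0.0125  Spearman rho = 0.175
```

The ranking is far from the uninformative baselines (AUC 0.5, pAUC 0.005);
rho is negative because ground truth is p-value based (small p = strong
differential response).

A thin CLI mirrors the library: `dimona simulate`, `dimona run`,
`dimona evaluate`, `dimona explain` (see `dimona --help`).

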