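# Methods

## Model and assumptions

The package contrasts two sample groups ("conditions") through the
correlation structure of their molecular networks, not through mean
abundance differences. The underlying assumptions are: (i) co-regulation
within a condition is captured by pairwise correlation of abundance
profiles; (ii) prior-knowledge links between layers (name identity for
mRNA–protein–phosphosite, curated pairs elsewhere) are condition-agnostic
and can carry fixed weights; (iii) a biologically meaningful change between
conditions shows up as a change in the *neighborhood* of an edge, which is
why edge weights are replaced by path-integrated scores before the
differential is taken; and (iv) a drug's response difference between
conditions is driven by the differential interactions around its targets.

### Integrated interaction score

For an edge (u, v), s(u,v) = Σ_{l=1..L} mean over simple paths of length l
from u to v of the product of edge weights along the path. Design points
that the implementation commits to:

- **Paths are simple** (no repeated node) and each geometrically distinct
  undirected path counts once. Walks with node revisits would break the
  stated bound |s| ≤ L for weights in [−1, 1]; the bound only holds for the
  simple-path reading, which is therefore the correct one.
- The l = 1 term is the direct edge's own weight, so L = 1 is the identity
  transform — a useful degenerate case for testing and for bypassing
  integration entirely.
- A length with no paths contributes 0 (avoiding a 0/0 mean).
- Enumeration is a depth-first search with cutoff L started from the
  lower-degree endpoint; cost is O(deg^(L−1)) per edge, negligible at the
  default L = 3 on hard-thresholded networks.
- With restriction to drug-target-incident edges (default), unscored edges
  keep their raw weight and carry `computed=False`. Drug scoring reads only
  target-incident edges, which are scored by construction, so the choice of
  what the other edges carry does not affect the ranking.

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| correlation method | Spearman | robust to outliers, captures monotone non-linear relations; Pearson available |
| `min_pairs` | 5 | minimum pairwise-complete observations for a correlation; below it, no edge (avoids degenerate coefficients on tiny overlaps) |
| reduction | average degree / density / scale-free | all threshold on \|weight\|, keeping strong negative correlations; retained weights are unchanged |
| scale-free grid | cuts 0.1–0.9 step 0.02 | search grid for the hard threshold |
| scale-free R² target | 0.8 | fit quality demanded of the reduced degree distribution; relaxed in 0.05 steps with a warning when unattainable |
| `max_path_length` L | 3 | maximum detour length pooled into a score; s ∈ [−L, L] |
| aggregator | mean | \|mean\| of differential scores over target-incident edges; median available |
| ground-truth threshold | 0.01 | Mann–Whitney p below which a drug counts as a true positive in ROC evaluation |
| `min_reps` | 3 | minimum sensitivity replicates per condition for a drug to enter the ground truth |
| pAUC range | FPR ∈ [0, 0.1] | unnormalized, so random = 0.005 and perfect = 0.1 |

Zero- and missing-fraction feature filters implement "more than X%" as a
strict inequality (boundary features kept) and run per condition, each
condition's matrix filtered over its own samples; zeros and missing values
are distinct concepts with separate filters (>90% zeros, >20% missing by
default). Each condition's network is built on its own surviving features;
the differential union with zero-fill absorbs any resulting asymmetry.

## Numerical and tie-breaking choices

- Count-based reduction keeps `round(n·d/2)` (average degree d) or
  `round(ρ·n(n−1)/2)` (density ρ) top-|weight| edges; when the cut falls
  inside a block of tied |weight|, *all* tied edges are kept, making the
  result order-independent at the cost of slightly exceeding the target.
- Scale-free fit: linear regression of log10 p(k) on log10 k over raw
  occupied degree bins (no log-binning), R² sign-flipped when the slope is
  positive so that "anti-scale-free" networks score negatively. At least two
  occupied positive-degree bins are required; otherwise the fit is signalled
  undefined and the cut disqualified.
- Harmonized scale-free reduction: among grid cut pairs where both reduced
  networks reach the R² target, the pair minimizing |E_A − E_B| wins, ties
  broken by the lexicographically smallest cut pair.
- Zero-variance features and feature pairs with fewer than `min_pairs`
  complete observations produce no edge rather than a NaN weight.
- Mann–Whitney p-values: exact for small tie-free samples, normal
  approximation with tie correction otherwise (scipy's automatic policy).
  Fully tied data give p = 1, the no-evidence case.
- ROC with tied predicted scores follows the standard single-segment
  convention; the partial AUC interpolates the curve at FPR = 0.1 and
  integrates trapezoidally, unnormalized.
- Drug score ties are broken lexicographically by drug id, giving a
  deterministic ranking.
- Connector weights are used as given; |weight| > 1 triggers a warning
  because the integrated-score range assumes correlation-scale weights.
- PageRank baseline: power iteration to a 1e−13 tolerance on the undirected
  differential graph weighted by |raw differential edge weight| (raw, not
  integrated, differences), damping 0.85.

## Synthetic data generator

`dimona.simulate` draws features from a one-factor-per-block model:
x = √ρ·z_block + √(1−ρ)·ε with standard normal latent and noise, giving
exact within-block correlation ρ (default 0.8) and zero between-block
correlation. The block latent is shared across layers, so same-name
connectors join genuinely co-varying features. Perturbed blocks use ρ − δ
(default δ = 0.6) in condition B only — the planted differential signal.
Entries are masked completely at random (default 5%) to exercise
pairwise-complete correlation. Differential drugs target perturbed-block
features and their sensitivities shift by 3 SD between conditions (10
replicates per condition); null drugs target intact blocks with identical
sensitivity distributions. Default scale: three layers × 300 features, 40
samples per condition, 10 blocks (3 perturbed), 50 drugs with 2 targets
each; a full pipeline run at this scale takes ~20 s on one CPU. All
randomness flows from one seed through spawned child generators, so the
omics matrices and the drug tables are individually reproducible.

What the generator does **not** emulate: realistic marginal distributions
(counts, over-dispersion, heteroscedastic mass-spec noise), batch effects,
informative missingness, hub-dominated degree distributions, or weighted
prior-knowledge connectors with calibration issues. Passing the synthetic
recovery tests therefore shows the machinery is correct and that a strong
planted differential co-regulation signal is recoverable — not that real
cohorts of any particular size would yield comparable accuracy.

## Open choices made here

- Condition order (A − B) is the caller's listing order and is recorded in
  every output; drug scores are invariant to the swap because of the
  absolute value.
- An edge incident to two targets of the same drug enters the score once
  (union semantics) — idempotent and the natural reading of "all edges
  incident to the targets".
- Unscored drugs (no target-incident edges) are listed, not dropped, so
  evaluation can align drug sets explicitly.
- The harmonization rule (minimal edge-count gap subject to a shared R²
  target, with stepwise relaxation) is this package's own concrete
  criterion for "similar-sized, scale-free in both groups"; the R² target
  and grid are exposed in `ReductionSpec`.

## Limitations

- Simple-path enumeration is exponential in L; L beyond ~4 on dense
  networks is impractical, and the default target-incident restriction is
  the intended operating mode for large networks.
- Correlation networks conflate direct and indirect co-regulation;
  integrated scores mitigate single-edge noise but do not deconvolve
  regulation direction (graphs are undirected throughout).
- No statistical significance is attached to drug scores; the ranking is a
  prioritization, and the permutation reference implemented for the partial
  AUC applies to whole rankings, not individual drugs.
- Multigraphs are not supported: a connector that duplicates an existing
  edge is an error rather than a parallel edge.
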