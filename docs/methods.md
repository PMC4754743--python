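# Methods

## Model

The scorer treats miRNA–disease association prediction as similarity-based
link prediction on a bipartite network. Its single modelling assumption is
guilt by association: functionally similar miRNAs tend to associate with
phenotypically similar diseases, and vice versa. Nothing is "fitted" in the
parametric sense — the score of a candidate pair is a deterministic function
of the association matrix and the similarity matrices — so the Model/Results
split separates the *inputs and configuration* (`WBSMDA`) from the *derived
quantities* (`WBSMDAResults`: integrated similarities, score matrix,
rankings).

### Similarity layers

1. **Disease semantic similarity (SS).** A disease anchored at ontology term
   `t0` has term contributions `C(t) = Δ^k`, `k` = minimum number of
   child→parent edges from `t0` to `t`; equivalently the topological
   recursion `C(t) = Δ · max{C(c) : c child of t in the closure}` with
   `C(t0) = 1`. Terms in the same layer contribute equally. Similarity is
   shared contribution mass over total semantic value. Both formulations are
   implemented (the recursion in the library, the path enumeration as the
   test oracle) and agree exactly on random DAGs.
2. **Gaussian interaction-profile kernel (KD, KM).** Profiles are rows or
   columns of `A`; the squared Euclidean distance of binary vectors is
   computed as a Hamming distance in integer arithmetic, so kernels are
   exact to the last float. The bandwidth is `γ = γ′ / mean‖IP‖²`, the mean
   taken over *all* entities on the axis including those with empty profiles.
   An all-zero network leaves γ undefined and is an error.
3. **Integration (SM, SD).** The curated matrices carry an explicit
   availability mask; `fallback` mode (default) keeps a curated value
   wherever one exists and uses the kernel only for missing entries, so the
   kernel never overrides curation. `average` mode blends the two where both
   exist. Fallback is the default because it makes the integrated matrix
   reduce exactly to the curated one when coverage is complete; the choice
   is recorded in every output header and is the single biggest open design
   point of this model family.

### Scoring

Within- and between-scores are group maxima of integrated similarity
(see README for the formulas). Two conventions matter:

* **Self-exclusion.** The candidate is excluded from its own within and
  between groups. Without it, `SM(m,m) = 1` puts every unknown candidate's
  between-score at 1 and the miRNA-view contrast collapses to a constant;
  a regression test pins this.
* **Empty groups.** A maximum over an empty group is 0 (flagged), and a
  contrast `w/(w+b)` with `w+b = 0` is 0. With these limits the documented
  new-disease and new-miRNA single-view scores are exactly the general
  formula restricted to the informative view, and `score_new_mirna` equals
  `score_new_disease` on the transposed network by construction (tested
  exactly).

Combination default is the bounded `ratio` mode, giving probability-like
scores in [0, 1]; a `difference` mode (range [−1, 1]) is provided for
sensitivity analysis.

## Parameters

| parameter | meaning | default | why |
|---|---|---|---|
| Δ (`delta`) | per-edge decay of ancestor-term contributions, unitless in (0,1) | 0.5 | the standard value of the DAG-contribution semantic similarity this layer follows; halving per layer keeps deep ancestors from dominating |
| γ′_d, γ′_m (`gamma_prime_*`) | raw kernel bandwidth per axis, unitless > 0 | 1.0 | the convention of the interaction-profile-kernel literature; after normalization γ adapts to network density automatically |
| `integration_mode` | fallback / average | fallback | curation should not be diluted by topology-derived similarity where it exists |
| `combine_mode` | ratio / difference | ratio | bounded, probability-like, symmetric in the two views |
| `refresh_kernels` | fold / never | fold | see cross-validation below |

## Cross-validation

LOOCV removes each known association in turn; k-fold (default k = 5,
100 repeats) removes a random near-equal group at a time, with a single
integer seed expanded to per-repeat substreams (`default_rng([seed, rep])`).
The held-out miRNA is ranked among the disease's candidates — miRNAs with
no known association to that disease in the full dataset.

**Kernel refresh and leakage.** Interaction profiles depend on `A`, so the
kernels are recomputed on the reduced network for every fold (default
`refresh_kernels="fold"`); leaving them frozen (`"never"`) lets the held-out
edge leak its own profile signal into the similarity and measurably inflates
the AUC (a test demonstrates the inflation). The bandwidths γ are estimated
once on the full network and held fixed across folds: they are a global
scale, a scalar summary to which a single edge contributes negligibly, and
holding them fixed makes the refresh exactly local — removing edge (i, j)
changes only row/column i of KD and row/column j of KM, which both bounds
the recomputation cost and is pinned by a regression test. Functional and
semantic similarity do not depend on `A` and are computed once.

**ROC construction.** Candidate counts differ per disease, so tests are
pooled on the normalized-rank scale: a test with `b` candidates strictly
above it and `t` tied is retrieved as the threshold sweeps past `b/c`,
linearly across the tied block. The resulting curve is piecewise linear and
its trapezoidal area equals the pairwise statistic — the mean fraction of
test-vs-candidate comparisons won, ties counting half — to 1e-9 by
construction (property-tested on random rank sets). Ties in ranks use the
average-rank convention throughout.

## Synthetic data

The generator plants the exact structure the scorer assumes: latent clusters
shared by diseases and miRNAs, association probability `p_in` within a
cluster versus `p_out` across, functional similarity `Normal(s_in or s_out,
sim_noise)` clipped to [0, 1] and symmetrized, a fraction `1 − fs_coverage`
of miRNAs with no functional-similarity entry (exercising the fallback
path), and an ontology of one root with one subtree per cluster, diseases
anchored at leaves. The default study conditions are 30 diseases × 40
miRNAs, 4 clusters, `p_in = 0.6`, `p_out = 0.05`, `s_in = 0.9`,
`s_out = 0.1`, noise 0.05, coverage 0.8 — roughly 220 associations, a size
at which full LOOCV with per-fold kernel refresh runs in well under a
second. The null configuration keeps the geometry and sets
`p_in = p_out = 0.15`, `s_in = s_out = 0.5`: an exchangeable dataset on
which LOOCV AUC must sit near 0.5. Every disease and miRNA is guaranteed at
least one association (a degenerate all-zero draw gets one within-cluster
edge), so the kernel bandwidth is always defined.

What the generator does **not** emulate: the heavy-tailed degree
distribution of curated databases (hub diseases with hundreds of miRNAs),
literature bias (well-studied miRNAs accumulate associations), and
correlated noise between the functional-similarity resource and the
association list (in real data FS is itself derived from shared disease
associations, so the two inputs are not independent). Passing the synthetic
benchmarks therefore shows the pipeline recovers planted
similarity-cluster signal and is correctly anti-leakage; it does not certify
performance on a particular curated dataset.

## Numerical choices and degenerate inputs

* Similarity files must be symmetric to 1e-8 (triangles averaged below that,
  rejected above); values outside [0, 1] are rejected.
* Identifier normalization is trim + casefold; registries are sorted
  lexicographically so all matrices are deterministic functions of the input
  set, not its order.
* Prediction output orders ties by ascending miRNA identifier.
* Unanchored diseases and uncovered miRNAs are masked, not zeroed — masking
  routes them to the kernel at integration; zero would assert dissimilarity.
* Maxima over empty groups are 0 with an explicit flag on the component
  object, never NaN.

## Known limitations

* The within/between contrast uses a *maximum*, so a single spurious
  high-similarity neighbour can dominate a candidate's score; scores are
  biased toward miRNAs and diseases with many known associations.
* Scores are rankings, not calibrated probabilities, despite living in
  [0, 1].
* The evaluation recomputes kernels per fold but keeps FS fixed; if the
  functional-similarity resource was itself derived from the association
  data, LOOCV on real data retains that (unavoidable, upstream) circularity.
* Ontology terms are treated as an unweighted DAG; no information-content
  weighting of terms is implemented.
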