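# Methods

## The model

A cohort of bulk genomic measurements is arranged as a matrix
`M ∈ R^{s×g}` (s samples × g gene features: copy-number ratios, expression
counts, or a concatenation of both).  Each sample is treated as an
approximately convex combination of a small number of unknown pure
subpopulation profiles:

    M = F V + ε,     F ∈ R^{s×k},  V ∈ R^{k×g},
    F_ij ≥ 0,  Σ_j F_ij = 1.

Geometrically, samples are points inside a simplex whose vertices are the
pure profiles.  Real cohorts are rarely one uniform mixture: subgroups of
tumors share some cell states (normal contamination, a common ancestral
clone) but not others.  The model for that substructure is a *simplicial
complex*: a union of low-dimensional simplices glued along shared vertices.
A vertex shared by several sub-simplices (a *fulcrum*) is read as a cell
state common to those subgroups.

The package infers, fully automatically: the number of sub-simplices, each
one's vertex count, the vertex profiles, per-sample mixture fractions, and
the glued global complex, together with a model likelihood.

## Pipeline stages

1. **Normalization.** Log2 copy-number ratios are exponentiated back to
   linear ratios, then all features are Z-scored per column with the
   unbiased (n−1) standard deviation.  For mixed DNA+RNA input each data
   type gets one pooled mean/SD over all its entries, since the two types
   live on incomparable count scales.  Constant columns are zeroed (not
   dropped) to keep feature indexing stable.

2. **Embedding.** Economy PCA retains `k_upper` components (default 12, an
   upper bound on how many subpopulations a method of this class can hope
   to resolve).  Global dimension candidates come from a sliver scan: for
   each tolerance δ on a 0.05-spaced grid, the dimension estimate j grows
   until the greedy enclosing j-simplex of the top-j scores has volume
   `ν < δ^j·L^j/j!` (L its longest edge) — the enclosing body has become a
   sliver, so the j-th axis carries no real extent — and j−1 is recorded.
   Distinct recorded dimensions form the candidate set (one representative
   δ each); a full candidate model is built per dimension and the best
   likelihood wins.  The enclosing simplex is built by farthest-point
   vertex selection followed by uniform inflation about the centroid until
   every point passes a barycentric containment test; its volume comes from
   the Cayley–Menger determinant.  Scores of the selected dimensions are
   min-max scaled to [0,1] per component for the clustering stage, which
   assumes that range.

3. **Pre-clustering.** A two-stage medoidshift.  Stage 1 (gaussian kernel,
   Euclidean distance, bandwidth = the neighborhood-size parameter times
   the mean nearest-neighbor spacing) contracts the cloud onto local
   representative points; representatives must recur as fixed points in at
   least half of 1000 bootstrap resamples (counted over the resamples that
   contain them).  Stage 2 re-clusters the survivors with a *negative*
   exponential kernel on geodesic (k-nearest-neighbor shortest-path)
   distances, bandwidth = the median representative–representative
   geodesic: each representative hill-climbs away from dense regions, so
   arms/faces of the complex separate at their extremes.  Two non-obvious
   but load-bearing choices:

   * moves are restricted to representatives within **half the geodesic
     diameter**.  Unrestricted, the negative kernel maps every point to the
     globally farthest extreme and the pointer dynamics collapse into
     two-cycles between opposite tips, merging everything into one cluster;
     with the half-diameter radius, opposite extremes stay mutually
     unreachable while anything stranded partway along one submanifold can
     still reach the extreme beyond it.  Surviving attractors are then
     re-resolved against the same objective field until fixed.
   * samples join the cluster of their **geodesically nearest** stage-2
     representative rather than following their stage-1 pointer chain;
     chains passing through noise-dominated regions can hop between
     submanifolds, geodesic proximity to an extremal representative cannot.

   Soft membership uses a folded-normal density over geodesic distance to
   each cluster representative, with scale = that representative's geodesic
   distance to the (snapped-to-data) mean of all representatives; each
   sample's weight row is min-max rescaled (best cluster 1, worst 0) and
   then renormalized to sum 1, giving per-cluster assignment probabilities.

4. **Per-cluster component count.** For each cluster, the share of total
   per-PC standard deviation is compared against the same shares computed
   from 100 isotropic standard-normal clouds of matching shape; leading PCs
   whose share exceeds the null mean by κ = 3 null SDs (≈ p < 0.001) count
   as genuine axes, and a cluster with q genuine axes gets k_c = q + 1
   simplex vertices.  Shares rather than raw SDs make the test
   scale-invariant; the comparison runs on unnormalized PC scores, where
   pure-noise axes keep their true (small) magnitude.  The test is
   deliberately conservative for small clusters.

5. **Cluster-wise unmixing.** Each cluster is fitted with a k_c-vertex
   simplex by minimizing

        Σ_j W_j ‖x_j − F_j V‖₁  +  γ·β·ln MST(V, A)

   over vertices V and simplex-constrained fractions F, where W is the
   cluster's assignment-probability column, MST is the total Euclidean
   minimum-spanning-tree length of the vertex graph (a minimum-evolution
   penalty on how much divergence from a common source the vertices imply),
   β = k_c·d·ln(n_eff)/2 is a BIC complexity term (n_eff = ΣW, d = k_c−1),
   and γ trades reconstruction against parsimony.  The fit runs in the
   cluster's own (k_c−1)-dimensional weighted-PCA subspace.  Optimization
   alternates exact F-steps (fast nonnegative-least-squares path for
   interior points, one batched linear program for the rest) with L-BFGS-B
   V-steps, plus two moves the alternation cannot make on its own:

   * a **deflation proposal** — shrink the simplex about its centroid until
     the most extreme supported point touches the boundary (the closed-form
     inverse of the enclosing-simplex inflation).  At an exactly-covering
     position the weighted-L1 term is kinked: with fractions held fixed any
     vertex motion breaks the exact interior reconstructions, so the
     alternating V-step is pinned there;
   * a **per-vertex radial polish** — a short line search sliding each
     vertex along its centroid ray, judged by the fully re-projected
     objective, since uniform deflation stops at the first contact and
     leaves the remaining vertices inflated.

   Three deterministic starts are tried (greedy max-volume points, the same
   shrunk 5% toward the centroid, and the inflated enclosing simplex); the
   best final objective wins.  With k_c = 1 the L1-optimal vertex is the
   weighted coordinate-wise median, computed directly.

   γ defaults to `auto`: the ratio of mean discarded-PC to mean retained-PC
   variance (a noise-to-signal estimate — noisy data earns stronger
   regularization), floored at 1/β so the minimum-evolution term never
   degenerates below a plain ln MST.  The floor matters at high SNR: with
   γ ≈ 0 the objective is exactly flat across all data-covering simplices
   and vertices would stay wherever the optimizer entered the zero-residual
   region; at the floor the ln MST tie-break settles them within about one
   sample spacing of the data hull.

6. **Reconciliation.** Vertices fitted in different clusters may be the
   same cell state.  Every vertex takes its 15 nearest samples as a
   neighbor set; a cross-cluster vertex pair merges when the observed
   neighbor overlap strictly exceeds the independence expectation
   n₁n₂/N (the hypergeometric mean).  Merges are transitive (union–find)
   and a merged vertex sits at the mean of its members, with adjacency the
   union of member adjacencies.  If the vertex graph is still disconnected,
   cross-component pairs are greedily mean-merged, committing at each round
   the pair whose merged model attains the lowest total per-cluster
   objective, until one component remains.

7. **Assembly and selection.** Global fractions mix each cluster's
   (re-projected) fraction rows with the per-sample assignment
   probabilities; rows provably stay on the probability simplex.  Across
   δ-derived candidate dimensions, the selected model minimizes the
   assembled complex's own negative log-likelihood:

        Σ_i ‖x_i − F_i V‖₁  (full PC-score space)  +  Σ_c γ β_c ln MST_c

   i.e. the model equation evaluated with the fractions the model actually
   reports.  Two tempting alternatives fail: likelihoods computed in each
   candidate's min-max-normalized space are incomparable (that scaling
   inflates pure-noise PCs to signal scale, flattering high-dimensional
   candidates), and summing per-cluster objectives across clusters counts
   fuzzy cross-cluster residuals — a large penalty precisely on correct
   multi-cluster decompositions — while letting re-optimized fractions
   absorb noise.  Ties break toward fewer vertices, then lower dimension.

8. **Interpretation.** Vertices map back to gene Z-score space through the
   PCA loadings.  Per gene, a two-sided standard-normal tail p-value on the
   vertex Z-score, Bonferroni-corrected across genes (α = 0.01 default),
   yields the up/down gene lists a user would submit for term enrichment.
   Reproducibility between two inferred vertex sets is scored by matching
   each vertex to its nearest counterpart in the other set and dividing the
   mean matched distance by the pooled mean within-set pairwise distance
   (0 = identical; < 1 = matches tighter than within-set spread).

## Parameters

| key | default | meaning |
|---|---|---|
| `k_upper` | 12 | max PCs / upper bound on resolvable components |
| `kappa` | 3.0 | null-SD threshold for a genuine per-cluster axis |
| `delta_step` | 0.05 | sliver-tolerance grid spacing on (0,1) |
| `noise_reps` | 100 | Gaussian-null replicates for component counting |
| `n_boot` | 1000 | bootstrap replicates vetting stage-1 representatives |
| `stage1_bandwidth` | 1.0 | stage-1 kernel scale, in units of mean 1-NN spacing |
| `isomap_knn` | 15 | neighbor-graph degree for geodesics (auto-raised until connected) |
| `consensus_frac` | 0.5 | bootstrap fixed-point consensus threshold |
| `gamma` | `auto` | minimum-evolution regularizer (see stage 5) |
| `merge_knn` | 15 | neighbor-set size for the vertex-overlap merge test |
| `max_iter` | 1000 | cap on F/V alternations per simplex |
| `tol` | 1e-6 | relative objective change declaring convergence |
| `mst_log_floor` | 1e-6 | floor inside ln MST (coincident-vertex guard) |
| `alpha` | 0.01 | Bonferroni-corrected significance for gene lists |

## Synthetic data

`scunmix.synthetic` generates ground-truthed structured mixtures: component
profiles are disjoint blocks of elevated/depressed genes (amplitude 1 per
gene), each sub-simplex of a connected vertex tree receives a block of
samples with Dirichlet(α = 1) fractions over its vertices, and isotropic
Gaussian noise is added.  The DNA block can be written as log2 ratios of
baseline-2-shifted values so the exponentiate-then-Z-score input path is
exercised end to end.  Two presets match the validation experiments: a
single uniform simplex (3 vertices, 300 samples, 6 genes, noise SD 0.01)
and a three-arm fulcrum complex (a shared vertex plus three private tips,
100 samples per arm, 8 genes — two per vertex, mirroring the two-genes-per-
vertex layout of the single-simplex case — and noise SD 2% of the arm
length in gene space).

What the generator does *not* emulate: correlated gene–gene noise,
heavy-tailed count noise, batch effects, unequal per-arm sampling density,
and vertices defined by overlapping gene programs.  Passing the planted-
recovery tests therefore demonstrates the machinery is correct under the
model's own assumptions, not that real cohorts satisfy those assumptions.

Known statistical floor: with n Dirichlet(1) samples on a simplex, the
most extreme sample sits ~`√(π/4n)` short of each vertex, so fitted
vertices (which settle at the data hull) carry an irreducible error of a
few percent of the simplex scale at n = 300.  Recovery metrics are
accordingly measured in the [0,1]-normalized PC space, where the simplex
has unit scale.

## Numerical choices

* Sample SD (n−1) everywhere; constant columns zeroed with a log warning.
* PCA signs fixed by making each loading's largest-magnitude entry
  positive, for bitwise-reproducible runs.
* L1 projections: NNLS fast path accepted only at ≤1e-9 residual, exact
  closed form in one dimension, HiGHS LP otherwise; fractions renormalized
  and clipped at 0.
* The sliver scan computes (ν, L) once per j and reuses them across the δ
  grid; the assertion with ν = 0 (affinely degenerate scores) is true for
  any δ > 0, so exactly rank-deficient data terminates early.
* Degenerate guards: min-max spans at float-noise level map to 0.5; a
  cluster whose folded-normal scale is zero falls back to the mean pairwise
  geodesic; flat weight rows become 1/r; empty stage-2 clusters are
  dropped; an all-zero weight row falls back to its argmax cluster.
* One master seed fans out through `SeedSequence.spawn` to per-candidate
  generators; reruns are bit-identical.

## Limitations

* The pre-clustering separates substructures by their *extremes*; a
  uniform single simplex is typically first split into per-corner clusters
  whose fits are then re-unified by the vertex merge.  The final model is
  correct but cluster count r should not be read as the number of
  sub-simplices before reconciliation.
* Component counting is conservative: a genuine axis whose variance share
  sits within 3 null SDs of isotropic noise is dropped, so small or noisy
  clusters under-report vertices.
* Column Z-scoring measures each gene against the cohort's own mixing
  spread, so under near-uniform mixing a vertex's gene Z-scores stay
  moderate (≈ 2–3 for Dirichlet(1) mixtures regardless of profile
  amplitude) and Bonferroni-significant lists can be empty; the lists are
  informative for cohorts where per-gene variation is dominated by a
  minority of strongly altered samples, as in real copy-number data.
* Merging tests use each vertex's original neighbor set within a round;
  pathological chains of borderline overlaps could over-merge.
* Runtime is dominated by the bootstrap (O(n_boot · n³) medoidshift map
  construction, a few seconds at n = 300) and the per-cluster LP F-steps.
  Cohorts of a few thousand samples are practical; tens of thousands are
  not without subsampling.
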