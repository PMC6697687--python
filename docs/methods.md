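# Methods

## Ground truth: linear response at a stable steady state

A dynamical model is dx/dt = f(x) with Jacobian J = ∂f/∂x evaluated at a
steady state x\* (units 1/time). The orientation convention is
J[i, j] = ∂f_i/∂x_j throughout, so kinetic influence flows j → i; the
influence network is exactly the off-diagonal sparsity pattern of J with
sign(J[i, j]) and weight |J[i, j]| on each edge, self-loops excluded.

The sensitivity S[i, j] = dx_i/dx_j is computed by clamping the source:
hold x_j at a displaced value and let the remaining species re-equilibrate.
By the implicit function theorem the first-order response solves
J[−j, −j] δx = −J[−j, j], giving column j directly; S[j, j] = 1 by
convention for every method, so the (information-free) diagonal never
enters rank comparisons. A singular reduced Jacobian leaves that column
NaN with a warning rather than aborting — on heterogeneous corpora some
models are simply unusable and are dropped from means, with counts
reported.

The implementation is verified against an independent brute-force oracle
that integrates the clamped ODE system (LSODA, rtol 1e−12) until the
relative state change per window falls below 1e−10 and differences the
endpoints. For linear systems the two computations are analytically
identical, which the test suite exploits; the default perturbation is
1e−4·x\*_j with a 1e−6 floor, small enough that curvature is negligible
for the Hill-type models as well.

## Topology-only predictors

All three predictors consume only the influence network; none sees |J|.

- **First neighbor**: S[i, j] = 1 iff edge j → i exists (either direction
  in the undirected variant), else 0.
- **Distance**: S[i, j] = 1/(1 + d(j → i)) with d the unweighted
  shortest-path hop count. The 1/(1+d) kernel (rather than 1/d) gives a
  defined diagonal of 1 and preserves the inverse-distance ordering, which
  is all the rank-based score consumes. Unreachable pairs are exact zeros,
  ranked tied-lowest downstream.
- **Propagation**: S = (1−α)(I − αW)⁻¹ with
  W = D_out^{−1/2} A D_in^{−1/2} the symmetric-degree-normalized walk
  matrix of the *unweighted* adjacency (±1 entries in the signed variant;
  zero-degree nodes get normalizer 1), the standard random-walk-with-
  restart form. α (default 0.9) sets how far perturbation mass spreads
  before restart; columns are rescaled to unit diagonal afterwards. The
  restart form keeps (I − αW) well conditioned for α < 1; a singular
  system raises with a suggestion to lower α.

Undirected variants symmetrize the adjacency (edge if either direction is
present; a negative sign wins the tie, as suppression dominates).

## Scoring convention

Accuracy is the column-wise Spearman ρ on off-diagonal entries, averaged
over columns where it is defined; constant columns are skipped and
counted, never scored as 0, so degenerate tiny models cannot bias corpus
means. Nonnegative predictors (first neighbor, distance, unsigned
propagation, everything enhanced by a positive factor) carry no sign
information and are scored against |S_truth|; the signed propagation
variant is scored against the signed truth. Without this split a
sign-balanced corpus would push every unsigned predictor to ρ ≈ 0 by
construction regardless of how well it ranks influence strength.

## Enhancement factor

Three steps per model:

1. **Bio-impact matrix**: within each Jacobian column, competition ranks
   of |J[i, j]| in *ascending* order — rank N is the strongest impact,
   ties share the smallest applicable rank, and exact zeros therefore all
   share rank 1. Ascending order is what makes the construction an
   *enhancement*: the factor is monotone increasing in impact strength,
   so the elementwise product amplifies the interactions the kinetics say
   matter. (With the opposite order the same pipeline measurably
   *suppresses* them and scores below the bare distance model.) Magnitude
   ranking is the default; signed ranking is available by flag.
2. **Scaled impact matrix**: ⌈log₂(rank)⌉ + 1, computed with exact
   integer arithmetic via bit_length so powers of two never hit a
   floating-point boundary. This compresses a rank alphabet that grows
   with N (ranks can exceed 200 on large models) into a handful of
   classes a classifier can generalize over.
3. **Normalization**: divide each column by its diagonal element;
   E has unit diagonal and E[i, j]·E[j, i] structure preserved under the
   later per-node reconstruction.

`apply_enhancement` multiplies E elementwise into a base sensitivity
matrix and resets the diagonal to 1. Two upper bounds quantify what
perfect knowledge of the factor would buy: the full-rank factor
(rank[i, j]/rank[j, j], no log compression) and the scaled factor E, both
applied to the directed distance model. E is invariant to any positive
rescaling of the whole Jacobian, so the enhancement uses only the rank
structure of the kinetics, not their absolute scale.

## GCN enhancement-factor prediction

**Labels.** Each node's class is the median of its row of the scaled
impact matrix over the columns where it actually receives an interaction
(J[i, j] ≠ 0), rounded half-up and clipped to 1..C, with
C = ⌈log₂ N_max⌉ + 1 over the corpus; nodes with no incoming interaction
get class 1. Restricting the median to the interaction support matters on
sparse models: the unrestricted row median collapses to the shared
zero-rank value for nearly every node, leaving a degenerate
(near-single-class) task. When scaled rows are constant the ratio
reconstruction below reproduces E exactly.

**Features (D = 8).** In-degree, out-degree, log(1+N), local clustering
coefficient (undirected projection), fraction of negative incident edges,
mean inverse out-distance to all other nodes, an isolated-target indicator
(in-degree = 0), and the integer size scale ⌈log₂ N⌉. The last two are
deliberately redundant step/indicator encodings: graph convolution
averages features over neighborhoods, and these survive the smoothing
that otherwise blurs per-node degree information. Features are
standardized per batch; a one-hot identity encoding is not used by
default. Feature contents are a design choice of this package — nothing
upstream prescribes them.

**Batching.** Two regimes:

- *Full graph*: all influence networks united, plus one extra center node
  linked (weight 1, undirected) to each member network's hub — its
  highest total-degree node, ties to the lowest index. The center gets
  mean features and no label and is excluded from both masks.
- *Sparse graph*: block-diagonal adjacency, one block per network, plus a
  one-hot pooling matrix assigning each node to its network. The pooling
  matrix is used to append each node's graph-mean feature vector to its
  own features — the per-graph context that the full-graph regime routes
  through the center node instead.

Blocks are symmetrized and unsigned for the spectral normalization
(direction and sign enter through the features). Train/test masks split
*whole models*; the shuffle is keyed on model ids, so membership depends
only on identities and the seed, never on input order — this is what
makes batch assembly and (dropout-free) training permutation-equivariant.

**Architecture and training.** Two layers of
H′ = σ(D̂^{−1/2} Â D̂^{−1/2} H W), Â = A + I, ReLU then softmax over C
classes; hidden width 16 (smallest standard choice), bias terms included
in the trainer while the standalone layer keeps the pure bias-free rule.
Cross-entropy on the train mask, Adam at learning rate 0.01, dropout 0.5
on the hidden layer, up to 200 epochs, weight decay 5e−4 on the first
layer; classes absent from the training mask get weight 0 with a warning.
The forward pass, analytic backward pass and Adam update are implemented
directly in numpy/scipy — the model is small enough that a deep-learning
framework would add nothing but a dependency — and are bitwise
reproducible under the config seed. The final-epoch model is used for
prediction (no early stopping).

**Reconstruction.** Predicted classes ℓ̂(i) (argmax, ties to the lowest
class) give Ê[i, j] = ℓ̂(i)/ℓ̂(j), the direct per-node analogue of the
diagonal normalization; Ê·Êᵀ = 1 elementwise and the diagonal is 1 by
construction.

## Synthetic corpus

The generator emulates the salient statistics of curated biochemical model
repositories: small heterogeneous networks, sparse signed Jacobians,
stable steady states. Defaults, chosen once on realism grounds:

- sizes uniform on [5, 60] — desk-scale while spanning the heterogeneity
  that motivates learning across models;
- per-model edge density min(0.5, 3/(N−1)), i.e. a mean in-degree of
  about 3 interactions per species;
- signs balanced (half activating), magnitudes log-normal with σ = 1;
- diagonal set to −(|row sum| + 0.1): strict diagonal dominance
  guarantees stability (Gershgorin) and nonsingular reduced Jacobians for
  every ground-truth solve;
- steady states log-normal, strictly positive;
- per-model seeds spawned deterministically from one master seed.

Two rhs families: linear f(x) = J(x − x\*), and Hill-saturating pairwise
interactions (n = 2, K = x\*_j) with linear decay, whose coefficients are
chosen so the analytic Jacobian at x\* equals the sampled matrix exactly.

What the generator does **not** emulate: conservation laws and stoichiometric
coupling, wide time-scale separation, multistability, the specific
kinetic-law families of curated models, or their long-tailed size
distribution. Consequently the synthetic corpus shows *smaller* gaps
between the distance model and its enhanced variants than heterogeneous
real kinetics produce — the rank structure of a log-normal-weight Jacobian
is only mildly more informative than hop distance — so passing the
ordering checks here demonstrates correctness of the constructions and the
direction of their effects, not the effect sizes attainable on real
curated models.

## Problem sizes used in checks

The bundled verification runs use corpora of 50–60 models (sizes 5–60),
20 linear models (sizes 5–30) for the oracle-equivalence check, 3 training
seeds for the learning-recovery check with a 40/20 model split, and
5-model probes for I/O and harness shape — sizes at which every check is
exact or tightly converged while the whole suite stays interactive.

## Network property analysis

Per-model descriptors: node count, mean log₁₀ of the nonzero |J| entries,
number of strongly connected components (directed), mean Burt's constraint
(undirected unweighted projection; isolated nodes skipped), edge density,
and mean shortest path over reachable ordered pairs (NaN when none).
Property–accuracy association is the Spearman ρ of each property with each
method's per-model score. The random-expectation band half-width is twice
the standard deviation of the correlations obtained when the property is
replaced by uniform random draws (n_random repetitions, fixed seed) — an
approximate 95% span of what a meaningless property would produce at this
corpus size; a ±1σ band would cover only ~68% of null correlations.

## Known limitations

- Imported models carry Jacobians only; no symbolic extraction from SBML
  kinetic laws is performed (a bundle-producing hook is the documented
  ingestion path), and imported Jacobians are taken as given at their
  stated steady state.
- The propagation operator's exact form and α are declared choices: only
  the qualitative degree-weighted-neighbor-sum behaviour is fixed by the
  model family, so its scores should be compared across configurations,
  not treated as canonical constants.
- The per-node label function and the ratio reconstruction are one
  consistent reading of turning a matrix factor into a node classification
  problem; both are isolated behind small functions (`node_labels`,
  `labels_to_enhancement`) and can be swapped.
- Spearman scoring needs N ≥ 3 and skips constant columns; corpora of
  2-species models are not scoreable.
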