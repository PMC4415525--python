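# Methods

## The model

`ddsbm` infers cell types (or, generally, entity types) and their
microcircuitry jointly from one or more connectivity matrices over the
same N entities. The generative story is an infinite stochastic block
model extended with spatial structure:

- A partition of the N entities into K types is drawn from a Chinese
  restaurant process with concentration α; K is therefore inferred, not
  fixed.
- For every ordered (directed) or unordered (undirected) pair of types
  (m, n), link parameters η_mn govern how the probability (or rate) of
  a connection between a type-m and a type-n entity decays with the
  physical distance between them.
- Each observed edge R(i, j) is conditionally independent given the
  types, the pair's distance d(i, j), and η.

Three link-function families are implemented:

| family | edge model | η_mn | per-graph globals |
|---|---|---|---|
| logistic-distance Bernoulli | Bernoulli(p), p = p*·(p_max − p_min) + p_min, p* = 1/(1 + e^{(d − μ_mn)/λ_mn}) | threshold μ_mn, scale λ_mn | p_max, p_min |
| logistic-distance Poisson | Poisson(r), r = r*·(r_mn − r_min) + r_min | threshold μ_mn, ceiling r_mn | scale λ, floor r_min |
| per-component-ceiling Bernoulli | as Bernoulli but ceiling p_mn per type pair, p_mn ~ Beta(a, b) | ceiling p_mn, threshold μ_mn | λ = μ^hp/10, p_min, a, b |

Connection probability is always non-increasing in distance; the model
cannot express "more likely to connect when farther apart", which is a
deliberate assumption and a known limitation.

μ_mn and λ_mn (and r_mn) carry exponential priors whose *means* are
global hyperparameters (μ^hp, λ^hp). The mean parameterization keeps
the hyperprior grids on the same scale as the data's distances (e.g. a
grid from 1 to 80 μm for a retinal patch). All global hyperparameters,
including α, live on finite log10-spaced grids with uniform hyperpriors,
so their conditional updates are exact discrete Gibbs draws. Reference
grids: 40 points for the Bernoulli family, 20 for the Poisson family
(with rate ceiling grid 2.0–20.0 and r_min = 0.01), 50 for the
per-component-ceiling family; α defaults to {0.1, 0.3, 1, 3, 10}.

Two optional per-entity feature models share the partition:

- **Soma depth**: each type has a Gaussian depth with a conjugate
  normal–scaled-inverse-χ² (NIX) prior on its (mean, variance); the
  per-type parameters are collapsed analytically, so the assignment
  sweep only needs marginal-likelihood ratios. Defaults (depths
  normalized to [0, 1]): μ^(s) = 0.5, κ = 1, σ² = 0.04, ν = 1 — weakly
  informative, centered mid-depth with a prior depth s.d. of 0.2.
- **Synapse depth profile**: each type has a mixture of at most three
  Gaussians over its synapses' depths, with per-type means and weights
  and a global variance scale σ² gridded over {0.01, 0.1, 1.0}.

Multiple graphs (e.g. a directed chemical-synapse graph and an
undirected gap-junction graph) multiply their likelihoods under one
shared partition, each with its own η tables and hyperparameters.

Self-pairs (i, i) are excluded from every likelihood product; diagonal
entries have no defined semantics. Probabilities are clamped to
[1e−12, 1 − 1e−12] before logs so extreme user-supplied values cannot
produce infinite scores.

## Inference

Posterior inference composes three MCMC kernels per iteration:

1. **Assignments** — Gibbs sweep with the auxiliary-class method for
   non-conjugate likelihoods (Neal's algorithm 8). Each entity chooses
   among existing types (weight = type size) and 3 ephemeral types
   (weight α/3 each) whose η are drawn from the prior; when the entity
   was the last member of its type, that type's parameters are retained
   as one ephemeral candidate. Empty types are removed immediately, so
   labels remain contiguous (0-based internally).
2. **η** — univariate slice sampling (step-out and shrinkage) of every
   component parameter; components are conditionally independent given
   the assignment. The slice width is 0.1 of the corresponding
   hyperprior grid's range (falling back to the grid's magnitude for
   degenerate single-point grids). Synapse-profile means are slice
   sampled alongside η; profile weights use independence
   Metropolis–Hastings from their uniform-Dirichlet prior, which is
   exact though slow-mixing — adequate because weights are weakly
   identified at the data sizes involved.
3. **Hyperparameters** — exact Gibbs over the grids. The conditional
   over the Cartesian product factorizes: grids entering only the η
   prior (μ^hp, λ^hp) need no likelihood evaluations, while grids
   entering the likelihood (p_max, p_min; the Poisson λ) are scored by
   full relation log-likelihoods per grid point.

During burn-in the log-likelihood (never the priors) is divided by a
temperature cooled geometrically from T = 64 to T = 1, by default over
900 iterations, followed by 100 iterations at T = 1. The geometric
shape T(i) = 64^(1 − i/900) was chosen over linear cooling for uniform
multiplicative steps; the shape is configurable. At high temperature
the CRP prior dominates and chains transiently collapse to few types;
they re-split as T approaches 1, but single-site Gibbs cannot reliably
split merged types late in a run. The protocol therefore leans on
pooling: many short annealed chains from independent CRP-distributed
initializations, keeping each chain's final state as one posterior
sample. The highest-scoring sample is the MAP estimate; all numerical
summaries (link probabilities, coassignment) average over the pool.
Per-chain success on hard instances is well below 1, which is why the
default is 20 chains — the MAP over the pool is much more reliable than
any single chain.

Scores reported in traces are always the un-tempered (T = 1) joint log
score, so values are comparable across the annealing schedule.

## Validation studies and the synthetic generators

The generators emulate the study designs used to validate the method;
their defaults are the package's study conditions.

- `gen_dd_sbm`: positions uniform on a 100 × 100 square (or interval);
  balanced types; each type pair is either "connected" (μ = 45, λ = 2,
  so nearby members connect with probability near p_max = 0.9) or
  "background" (μ = 1, probability near p_min = 0.01). The random block
  pattern is redrawn until every pair of type rows differs in at least
  two blocks, which makes all types identifiable from connectivity
  alone — this is what "well-separated" means here. Overall edge
  density lands near 0.1–0.25.
- `gen_sbm`: same block patterns with distance playing no role
  (probabilities 0.4 / 0.02); positions are generated but independent
  of the graph, so the data can feed spatial diagnostics.
- `gen_mixed_membership`: Dirichlet(0.3) memberships; each pair's
  endpoints sample roles independently.
- `gen_latent_position_cluster`: Gaussian-mixture latent positions;
  edge probability logistic(intercept − latent distance).
- `gen_features`: per-type Gaussian soma depths and mixture-profile
  synapse depths at configurable parameters.

What these generators do **not** emulate: measurement noise in
distances, missing entities, degree heterogeneity within a type,
spatially varying density, or overdispersed counts. Passing the
recovery studies therefore shows correctness of the inference machinery
under the model's own assumptions, not robustness to real-data
violations of them.

The distance-blind ablation replaces every pairwise distance with the
mean distance. At a single common distance the logistic link reduces to
a free per-block probability spanning (p_min, p_max), i.e. an ordinary
(distance-free) infinite stochastic block model — using d = 0 instead
would floor every block's probability near half of p_max and make the
contrast trivial. On distance-dependent data this ablation fragments
spatial structure into many small types, reproducing the expected
overestimation of K.

The edge-effect study windows data to a circular region and measures
the connectivity-distance variance statistic: for each type pair,
off-diagonal pairs are binned by distance (8 equal-width bins over the
observed range; bins need a minimum pair count to vote), and the
statistic is the variance of per-bin connection frequencies averaged
over type pairs. Small windows on spatial data suppress it (all
surviving pairs are short-range); windows on non-spatial data leave it
at the binomial noise floor. Because the floor scales inversely with
pair counts, windowed non-spatial values are compared against the
spatial signal's magnitude, not against the full-data floor to machine
precision.

## Problem sizes used by the test suite and acceptance script

The studies are run at desk scale, chosen so the full suite completes
comfortably on one CPU: recovery uses N = 150 with K ∈ {2, 3, 4, 6, 8}
(one dataset each), 300 annealing + 50 post iterations, and 8–12
pooled chains per dataset; cross-validated link prediction uses N = 80,
10 folds, 3 chains per fold; kernel-validity enumeration uses N = 5
with 9000 sweeps against a quadrature oracle; the edge-effect study
uses N = 400 over 10–20 seeded replicates. The acceptance thresholds
(K within ±1 and ARI > 0.8 in ≥ 80% of datasets; pooled AUC > 0.9)
follow the validation design the package implements.

## Numerical choices

- MAP ties (equal log scores) resolve to the lowest chain id.
- ROC/AUC uses the Mann–Whitney convention: ties get half credit.
- Coassignment block sorting uses average-linkage hierarchical
  clustering of 1 − coassignment and returns the dendrogram leaf order
  (deterministic for fixed input).
- Contact-area thresholding is strict (area > 0.1 μm² ⇒ edge); the
  boundary case "exactly 0.1" is no edge.
- Synapse-count rescaling divides by 4.0 and rounds half-up, so a raw
  count of 2 becomes 1.
- Cross-validation folds partition ordered pairs for directed
  relations and unordered pairs for undirected ones; held-out pairs
  contribute nothing to training likelihoods (they are masked, not
  imputed).
- The per-graph λ of the Poisson family and the per-component λ_mn of
  the Bernoulli family are deliberately asymmetric — each family is
  implemented exactly as specified by its parameterization.

## Known limitations

- Single-site Gibbs mixes slowly across partition modes; inference
  quality depends on chain count and annealing length. Split–merge
  moves are out of scope because the inference protocol is fixed to the
  three kernels above.
- The monotone link family cannot represent non-monotone
  distance–connectivity relationships.
- Hyperparameter grids bound the representable scales; data whose
  distance scale falls outside the grid range needs custom grids
  (`priors.default_hyper` takes the scale as an argument).
- The mixed-membership and latent-position generators exist to test
  behavior under model mismatch; the model itself cannot represent
  partial membership or continuous types and is expected to
  overestimate K (mixed membership) or fit poorly (continuous types).
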