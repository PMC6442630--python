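# Methods

## The model

All analyses concern simple graphs — undirected, unweighted, loopless —
drawn from a stochastic block model (SBM).  An SBM with K blocks is
parameterized by a block membership probability vector π on the unit
simplex and a symmetric K×K connectivity matrix B with entries in [0, 1]:
memberships z_i are i.i.d. multinomial(π) and each dyad i < j is an
independent Bernoulli(B[z_i, z_j]) edge.

Two qualitative two-block regimes, for B = [a, b; b, c]:

* **affinity** — both within-block densities dominate the between
  density (a, c ≫ b);
* **core–periphery** — one block's within density dominates both other
  densities (a ≫ b, c).

Because "≫" needs a number to be testable, `classify_structure` uses a
dominance margin, default 2.0 (affinity iff min(a, c) ≥ 2b; core–periphery
iff max(a, c) ≥ 2·max(b, min(a, c)); affinity is checked first).  The
margin is a flag, not a fitted quantity.

## Spectral embedding

Adjacency spectral embedding (ASE) eigendecomposes A; Laplacian spectral
embedding (LSE) eigendecomposes the normalized Laplacian
L(A) = D^(−1/2) A D^(−1/2).  Both retain the d eigenpairs of largest
eigenvalue magnitude and map vertex i to row i of X = U_d |S_d|^(1/2).
Sparse Lanczos iteration (seeded start vector, so results are bit-stable)
is used for large graphs, a dense eigendecomposition below n = 200 or when
d approaches n.  Each eigenvector's largest-magnitude entry is made
positive (first index on ties) so X is reproducible across runs.

When d is not given, it is chosen from the scree of eigenvalue magnitudes
by profile-likelihood singular-value thresholding: each candidate split d
models the leading d and the remaining values as two Gaussians with
distinct means and one pooled variance; d̂ maximizes the profile
likelihood, ties toward smaller d.  A split with zero pooled variance fits
perfectly and wins outright.  `elbow > 1` recurses on the tail beyond the
previous elbow.  The default scree depth is min(100, n−2).

## Clustering

Embedded vertices are clustered by maximum-likelihood EM over Gaussian
mixtures with full covariances (the embedding limit theory yields
block-specific elliptical covariances, so constrained families are not
searched).  Defaults: 5 k-means++-seeded restarts, tolerance 1e−6, a
covariance floor of 1e−6·trace(cov(X))/d on the diagonals (embeddings can
be near-degenerate).  The number of components maximizes the penalized
likelihood 2·loglik − dim(θ_K)·ln n with
dim(θ_K) = (K−1) + K·d + K·d(d+1)/2 — a maximize-BIC convention — with
ties toward smaller K.  Hard labels are MAP assignments; ties go to the
lower component index and empty components are compacted.

## Assessment

**ARI.**  Pair-counting adjusted Rand index from the contingency table;
when both partitions are pairwise-trivial (M = E) the value is 1 if they
induce the same pair relations, else 0.  Significance uses a label
permutation test with the add-one estimator p = (1 + #{ARI* ≥ ARI})/(1+B),
so p is never zero.

**Chernoff information.**  For Gaussian limits F_1 = N(μ_1, Σ_1),
F_2 = N(μ_2, Σ_2), with Σ_t = tΣ_1 + (1−t)Σ_2,

    h(t) = t(1−t)/2 · (μ_1−μ_2)ᵀ Σ_t⁻¹ (μ_1−μ_2)
           + 1/2 · log( |Σ_t| / (|Σ_1|^t |Σ_2|^(1−t)) ),

and C(F_1, F_2) = sup_{t∈(0,1)} h(t), found by a grid scan (step 1e−3)
plus bounded local refinement to 1e−8.  For a K-block SBM, ρ_A is the
minimum pairwise Chernoff information among the blocks' ASE limit
components, ρ_L likewise for LSE, and the Chernoff ratio ρ = ρ_A/ρ_L
says which embedding separates the hardest block pair at the better
large-sample rate (ρ > 1: ASE; ρ < 1: LSE).

**Empirical limit parameters.**  Closed-form limit covariances are out of
scope; instead the per-block Gaussian limits are estimated by sampling
`n_graphs` graphs (default 5) at a large matched n (default 4000),
embedding each, aligning the replicates by the orthogonal Procrustes
rotation of their block means (the embedding is identified only up to an
orthogonal transform), pooling, and taking per-block sample means and
covariances.  ρ is computed at one matched n for both methods from the
same seed stream; its scale is n-dependent but cancels in the ratio.

**Mixture KL and the grouping analysis.**  KL between Gaussian mixtures
has no closed form; it is estimated by Monte Carlo (sample from P,
average log p − log q, standard error reported, clamped at 0), which is
dimension-agnostic where grid quadrature would not be.  The grouping
analysis asks which bipartition of the four block components into two
cluster mixtures is most divergent.  Unordered nonempty bipartitions of
four items number 7; the literature's count of "10 ways" is matched by
the ordered-KL mode, which evaluates the three 2-vs-2 splits in both KL
directions and the four 1-vs-3 splits once.  A symmetrized-KL mode over
the 7 partitions is also provided; which convention the original analysis
used is not stated anywhere we know of, so both are kept.

## The synthetic four-block two-truths model

The default generator emulates the a priori {LG, LW, RG, RW} projection
of a composite human connectome: hemisphere (Left/Right) crossed with
tissue (Gray/White), π = [0.28, 0.22, 0.28, 0.22], and

    B = [0.020  0.045  0.002  0.005]      (order LG, LW, RG, RW)
        [0.045  0.130  0.005  0.115]
        [0.002  0.005  0.020  0.045]
        [0.005  0.115  0.045  0.130]

The structure encodes two anatomical facts: gray matter connects almost
exclusively within its own hemisphere (0.020 within vs. 0.002 across),
while white matter is a dense core whose cross-hemisphere (callosal)
connectivity, 0.115, is nearly as strong as its within-hemisphere 0.130.
Consequently:

* the hemisphere collapse (exact π-weighted dyad aggregation) is
  an affinity model, (a, b, c) ≈ (0.0536, 0.0254, 0.0536);
* the tissue collapse is core–periphery, (a, b, c) ≈ (0.011, 0.025, 0.1225);
* at d = K = 2, GMM∘LSE recovers the hemisphere bipartition and GMM∘ASE
  the tissue bipartition, essentially perfectly at n = 4000.

The numeric entries were chosen by validating candidates from this
structural family against all of the above requirements simultaneously;
the regime is not knife-edge (50/50 independent seeds recover both truths
perfectly at n = 4000), but the design space is genuinely narrow: if
white-matter lateralization (within minus cross, here 0.015) grows much
beyond this, the adjacency embedding's second dimension becomes a
hemisphere contrast and ASE finds the hemisphere truth instead; if it
shrinks to zero the hemisphere collapse stops being affinity at margin 2.

What the generator does **not** emulate: degree heterogeneity within
blocks (real connectomes are far from block-constant), weighted edges,
finite-parcellation effects, or inter-subject variability.  Passing tests
therefore show that the pipeline exhibits the two-truths phenomenon in
its idealized regime, not that any particular real dataset does.

### A known negative result

The mixture-KL grouping analysis applied to the LSE limit components of
this default model selects the tissue split, not the hemisphere split,
even though GMM∘LSE robustly clusters by hemisphere.  The two criteria
measure different things: the GMM likelihood favors merging the pair of
blocks that forms the tightest two clusters, while the KL between cluster
mixtures is governed by the worst-separated pair across the divide.  In
any four-block model of this family whose tissue structure is
core–periphery, the Laplacian embedding's first coordinate carries an
irreducible degree-driven gray/white separation (≈ 2(√d̄_W − √d̄_G)
within-block standard deviations, with d̄ the expected block degrees)
that exceeds the white blocks' hemisphere separation whenever the
adjacency geometry is such that ASE clusters by tissue.  A parameter
search across the structural family found no configuration satisfying
both; the grouping test for LSE is left failing with this analysis rather
than weakened.  The ASE grouping analysis (tissue split) passes with a
large margin.

## Experiment and map defaults

The Monte-Carlo experiment uses n = 4000 and 50 replicates with
d = K = 2 fixed — sizes chosen so the whole study runs in minutes on one
CPU while staying in the regime where the embedding limit theory is
accurate — and reports, per replicate, ARI of each method's clustering
against each binary truth, plus the delta-ARI coordinates
x = ARI(LSE, hemi) − ARI(LSE, tissue), y = ARI(ASE, hemi) − ARI(ASE,
tissue) and their quadrant fractions.  Replicate seeds are spawned from
one master seed, so the experiment is exactly reproducible.

The Chernoff-ratio map fixes a scale s = max(a, c) (default 0.1, a flag:
ρ is not scale-free) and π = (0.5, 0.5), reconstructs
B = [s, sy; sy, sx] per grid cell, estimates ρ per cell (default n = 1000
with one graph per cell — the map is a sign/contour diagnostic over
hundreds of cells, not a precision estimate), and extracts the ρ = 1
contour by linear interpolation.  The y = x diagonal marks the rank-1
submodel separating positive-definite from indefinite B.

## Degenerate inputs and tie-breaks

Zero-degree vertices are rejected by LSE with a pointer to LCC
extraction; the pipeline always takes the largest connected component
first.  Blocks with fewer than two vertices yield NaN within-block
densities with a warning.  Empty multinomial blocks are resampled (≤ 100
tries).  Scree ties break toward smaller d, BIC ties toward smaller K,
MAP ties toward the lower component index, equal-size component ties in
the LCC toward the component containing the smallest vertex id.
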