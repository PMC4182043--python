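# Methods

## Problem setting

The package predicts drug–disease associations on a tripartite network:
drugs D, diseases S, protein targets T, with a binary association matrix
`A_ds`, drug–target interactions `A_dt` and target–target interactions
`A_tt`.  Biological similarity matrices — chemical structure between drugs,
phenotype between diseases — are *inputs*: computing them (substructure
alignment, text-mined phenotype profiles) is out of scope.  The prediction
problem is transductive: all drug–disease pairs are present from the start,
a few carry the positive label, and label spreading ranks the rest.

## Similarity model

Two topology similarities are derived from `A_ds`:

* **Sharing degree.** `SD = A·Aᵀ` counts shared diseases for two drugs
  (shared drugs for diseases).  Raw counts are unbounded while the other
  similarity is a correlation in [0,1]; fusing the two by a geometric mean
  is only meaningful on a common scale, so counts are cosine-normalized to
  `SD_ij/√(SD_ii·SD_jj)` (zero-degree nodes → 0, diagonal → 1).
* **Shortest-path profiles.** In the fully integrated graph M4, each drug
  is described by its vector of shortest-path lengths to every disease
  (diseases: to every drug); similarity is the Pearson correlation of two
  profiles.  Unreachable pairs get a finite sentinel equal to the node
  count — larger than any true path, but avoiding infinities that would
  destroy the correlation.  Negative correlations are clipped to 0 (a
  geometric mean cannot absorb negatives), and constant profiles —
  isolated nodes, or the degenerate single-disease case where every
  profile has length 1 — get similarity 0 by convention.

The two are combined entrywise as `SD^w · SP^(1−w)` (default `w = 0.5`),
then blended with biology: `Sim = λ·Sim_bio + (1−λ)·Sim_topo`, defaults
`λ = 0.5` for both node kinds.  None of these weights is documented in the
source material; equal weighting is the neutral choice and all are
configurable (`SimilarityFusionConfig`).

## Integrated graphs M1–M4

M1 = drug–disease edges; M2 adds drug–drug edges; M3 adds drug–target;
M4 adds target–target.  How the drug–drug layer is defined is genuinely
open; we threshold the drug similarity at `tau` (default 0.5).  Edge sets
are nested by construction, and isolated nodes are retained.

## Relevance vectors and GIP features

The pair vector of ⟨d, s⟩ has one entry per node, blocks ordered
drugs → diseases → targets: the drug block is d's similarity row, the
disease block s's similarity row, and each target entry is the maximum of
the drug's and the disease's interaction evidence (known interaction → 1,
else best similarity to an interacting drug; a disease contributes through
its associated drugs; empty maxima → 0).  How the drug's and disease's
per-node scores merge into *one* pair vector is not specified anywhere; the
block-wise layout with an elementwise-max target block is the only
combination consistent with the stated per-node rules and the documented
vector length (#drugs + #diseases + #targets, i.e. 447 at published scale).

Features are Gaussian-interaction-profile kernels against the n known
pairs, `K(p,i) = exp(−r‖v_p − v_i‖²)` with `r = n/Σ‖vᵢ‖²` (numerator
constant 1, the standard GIP convention), giving n-dimensional feature
vectors (609 at published scale).

## Label spreading

Pairwise Euclidean feature distances pass through `T(d) = σ₀(d/σ₀)^γ`
before the Gaussian `W_ij = exp(−T(d_ij)²/2σ²)` (diagonal zeroed).  The
transform's defining properties: fixed point at σ₀, contraction below,
amplification above (γ > 1); `T(d) = σ₀(d/σ₀)^γ` is the minimal form with
these properties and is adopted with γ = 2.  Defaults: α = 0.99 (very few
labels are known, so propagation is favored over clamping), σ = σ₀,
tol = 1e−9.

σ₀ is selected from the histogram of all pairwise feature distances: 50
equal-width bins, find the two highest local maxima, and take the longest
run of consecutive bins between them whose counts fall below 20% of the
median *occupied*-bin count; σ₀ is the band's midpoint.  The occupied-bin
median matters: for sharply bimodal distances most bins are empty, the
all-bin median is zero, and no bin could ever fall strictly below it.
Without two peaks or without such a run the selector falls back to the
median distance with a warning — on the synthetic test-bed the distance
distribution is broad and unimodal, so the fallback is the common path
there.

With `S = D^{−1/2} W D^{−1/2}` (isolated pairs keep zero rows, with a
warning), the iteration `F(t+1) = αSF(t) + (1−α)Y` from `F(0) = Y`
converges to `(1−α)(I−αS)^{−1}Y`; the implementation solves the linear
system directly (never inverts) and keeps the iterative solver for
verification.  The energy

    Q(F) = ½[ Σ_{i<j} W_ij ‖F_i/√D_ii − F_j/√D_jj‖² + ((1−α)/α) Σ ‖F_i−Y_i‖² ]

counts each edge once; under that convention the spreading limit is the
exact unconstrained minimizer (counting ordered pairs would instead make
the minimizer correspond to a different effective α, 2α/(1+α)).  Y is
one-hot n×2: known pairs (1,0), the rest (0,1) by default ("all-unknown";
a "none" mode leaving them (0,0) exists for sensitivity analysis).  A pair
is called associated iff `F[:,0] > F[:,1]`; ties go to the negative class
to avoid inflating positive calls.  `F[:,0] − F[:,1]` is the ranking
score.

## Topology statistics

Per integrated level: edge count; diameter (largest connected component on
disconnected graphs; ties by node count, then edge count, then node ids);
characteristic path length (mean over reachable unordered pairs only);
global efficiency (mean inverse distance, unreachable pairs contribute 0);
mean degree 2B/m; degree coefficient of variation (population sd/mean —
note the source material prints heterogeneity values orders of magnitude
above any sd/mean ratio, suggesting an unnormalized sum; we keep the
standard CV); clustering `2E_v/(k_v(k_v−1))` with degree<2 nodes scored 0
and averaged over *all* nodes; and structure entropy of the degree shares
`I_i = k_i/Σk`, `En = −ΣI_i ln I_i`, normalized as
`NE = (En − ½ln(4(m−1)))/(ln m − ½ln(4(m−1)))` between the star-graph
minimum and the uniform maximum, clipped to [0,1] because isolated nodes
can push a graph below the star bound.  Degree-0 nodes contribute nothing
to the entropy (x ln x → 0).

Shortest paths use Dijkstra on the sparse adjacency (equivalent to
Floyd–Warshall for unweighted graphs, linear-algebra-free and faster);
clustering and efficiency are cross-checked in the tests against exhaustive
triangle counting and hand-derived closed forms.

## Reliability analysis

Removal fractions 0–10% (configurable upper bound), node count
`round(f·m)`.  Random mode draws uniformly and averages 20 repeats (each
repeat a distinct child seed); targeted mode removes by descending degree,
ties broken by identifier, and is deterministic.  Post-removal metrics use
the reduced node count m′ and the same disconnected-graph conventions as
above; an edgeless residual graph is reported with entropy 0.

## Evaluation protocol

Repeated k-fold CV (default 10×10; the acceptance workload uses 10-fold ×
1 repeat × 5 independently drawn networks to stay desk-scale).  Per fold
the held-out positives are removed from `A_ds` *before* every stage —
sharing-degree and path-profile similarities, relevance vectors, GIP
bandwidth and features, and Y — so no label information leaks.  The test
pool is held-out positives plus all never-associated pairs (subsamplable
via `max_unknown`); AUC (Mann–Whitney, half credit for ties) and AUPR
(grouped step-curve sweep, area = Σ ΔR·P) are averaged over folds.

## Synthetic test-bed

The generator emulates therapeutic-area structure: round-robin assignment
of all three node kinds to `n_modules` blocks; `A_ds` ~ Bernoulli(p_in)
inside a block, Bernoulli(p_out) across; `A_dt` analogous with
`p_dt_in/p_dt_out`; `A_tt` Bernoulli(p_in) within blocks; similarities
`clip(sim_signal·[same block] + N(0, sim_noise), 0, 1)`, symmetrized, unit
diagonal.  Defaults: 30 drugs, 15 diseases, 20 targets, 3 modules,
p_in = 0.5, p_out = 0.02, p_dt_in = 0.3 (targets are hit by fewer drugs
than diseases are treated by), p_dt_out = 0.02, sim_signal = 0.6,
sim_noise = 0.1 (mild measurement noise that keeps within/cross-module
similarity separable, matching the planted-recoverability contract).  The
"published-shape" preset reproduces the published dataset dimensions exactly by
weighted sampling without replacement (within-block cells 10× as likely),
so the printed counts (609/668) hold for every seed.

What the generator does **not** emulate: degree heavy-tails of curated
pharmacology data (blocks are internally homogeneous), correlated noise
between chemical and phenotypic similarity, multi-module drugs, or any
real identifiers.  Passing tests therefore demonstrate correct mechanics
and recoverable planted signal, not clinical performance.

A consequence of block-homogeneous Bernoulli associations worth knowing:
conditional on the planted modules, every unobserved within-module cell is
exchangeable, so no method can rank a masked within-module positive above
a within-module negative better than chance.  The resulting
Bayes-optimal CV AUC under the default conditions is ≈0.86 (analytically
`P₊ᵢP₋ₒ + ½(P₊ᵢP₋ᵢ + P₊ₒP₋ₒ)` with the in/out posterior masses, confirmed
by a true-module oracle); the pipeline reaches ≈0.85, i.e. essentially the
information-theoretic ceiling of this test-bed, and clearly above the
max-kernel (0.82) and similarity-product (0.85) baselines.  A
structure-free null (p_in = p_out, no similarity signal) lands at chance
(AUC ≈ 0.48).

## Numerical and degenerate-input conventions

* Similarity matrices are symmetrized on read, clipped to [0,1] with a
  warning, diagonal forced to 1; symmetry tolerance 1e−12.
* Pearson correlation of any constant sequence is 0.
* Empty maxima in relevance rules are 0; all-zero known vectors make the
  GIP bandwidth undefined (error).
* `(I − αS)` is solved with a symmetric solver; singularity surfaces the
  condition number.
* Unknown identifiers are hard errors everywhere — silent intersection of
  id sets hides data bugs.
* All stochastic stages consume explicit seeds; repeat seeds are spawned
  from a `SeedSequence` so runs are reproducible bit-for-bit.

## Known limitations

* The drug–drug layer of M2 is a thresholding choice, not a curated
  interaction network.
* The degree-heterogeneity statistic is a standard CV; the unnormalized
  variant seen in some reports is not reproduced.
* Dense matrices throughout: the contract is desk scale (~10⁴ pairs);
  the full published-scale pair graph (~10⁴ nodes) fits in memory but a
  pairwise weight matrix beyond that would need a sparse treatment.
* AUPR uses the step-curve (average-precision) convention; interpolated
  variants give slightly different values.
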