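# Methods

## Connectivity modes

A mode is a symmetric region × region matrix of interregional similarity in
Fisher-z units. Construction paths:

* **Feature-profile similarity** — Pearson correlation between regional rows
  of a region × feature matrix. Zero-variance regions yield NaN edges, which
  are carried (symmetrically) and excluded from every statistic rather than
  imputed.
* **Partial feature similarity** — each region's profile is residualized
  (with intercept) on the across-region mean profile before correlating;
  used for laminar-intensity-style data where the global mean profile is a
  confound. The mean profile is the global one, not recomputed excluding the
  pair under test; with few regions this induces the usual −1/(n−1) residual
  correlation, which vanishes as regions grow.
* **Time-series connectivity** — Pearson correlation between regional time
  series.
* **PC1 composite** — several matrices (e.g., band-specific networks) are
  vectorized (upper triangle), stacked, column-centered, and reduced by SVD;
  PC1 scores are re-embedded as a symmetric matrix. PCA sign is arbitrary, so
  PC1 is oriented to correlate positively with the elementwise mean of the
  inputs; loadings and variance explained are reported.

Supporting normalizations: the robust sigmoid
`1/(1 + exp(−(x − median)/(IQR/1.35)))` followed by unit-interval rescaling
("normalized IQR" is read as IQR scaled to its normal-distribution
SD-equivalent, the convention of the feature-normalization lineage this
follows); per-feature z-scoring for receptor-style inputs; donor-wise
differential stability ΔS(p) = mean over donor pairs of the Spearman
correlation of feature p's regional profile, with features retained when
ΔS strictly exceeds 0.1 (the threshold is inclusive-exclusive ambiguous in
common usage; strict is documented and tested). Fisher z uses
arctanh with r = ±1 clipped to ±(1 − 1e−7).

Edge ranks (1 = most negative, E = most positive, ties averaged) make edge
strengths comparable across modes; the average-rank tie rule preserves the
rank-sum identity E(E+1)/2 exactly.

## Geometry and structural coupling

Distance decay is fit two ways on the upper-triangular edges — nonlinear
least squares for `y = a·exp(b·d) + c` (five starting rates b ∈ {−0.001,
−0.01, −0.05, −0.1, −0.5} to avoid local minima) and ordinary least squares
for the linear form — and the form with higher R² is selected; both are
reported. The exponential includes an offset c; the zero-offset
parameterization can be read off the fit but is not fit separately.
Residualizing a mode on its fit ("distance-regressed") re-embeds residuals
symmetrically and reports the residual–distance Spearman as a diagnostic.

Binned edge-rank curves sort edges by distance into equal-count bins
(remainder edges join the last, longest-distance bin) and report the median
rank per bin.

Structure–similarity coupling is the difference in mean mode weight between
structurally connected and unconnected pairs, with significance from
surrogate connectomes that preserve degree sequence, density, and the
10-bin edge-length histogram exactly (see Null models); p-values use the
(1 + count)/(1 + n) estimator throughout, which cannot return zero.

## Rich club and hubs

The rich-club coefficient φ(k) is the density of the subgraph of regions
with binary structural degree ≥ k (weighted variants are out of scope). The
ratio divides by the mean φ over plain degree-preserving surrogates;
per-threshold significance counts surrogates whose own ratio (against the
same ensemble mean) reaches the observed ratio. Rich links — structurally
supported edges whose endpoints both have degree ≥ k — are compared with the
remaining supported edges by median mode edge rank and a one-sided
two-sample Welch t-test (the unequal-variance two-sample form; a
"one-sample" reading appears in some descriptions of this analysis but has
no second class to compare against).

Hubness is the per-region sum of incident edge ranks; cross-modal hubness
the elementwise median over modes. Strongest-edge sets take the
ceil(pct% · E) highest-weight edges with lexicographic tie-breaks, so
results are deterministic. Intra-class fractions report the share of those
edges whose endpoints share a label; with two labelings the conjunction
(same intrinsic network AND same cytoarchitectonic class) is used.

## Disease exposure

`D_i = (1/N_i) Σ_{j≠i} d_j·c_ij` over the positive edges of region i
(N_i = their count); Spearman's ρ between D and d summarizes how well the
mode's wiring predicts the abnormality topography. Variants: negative edges
only; weighted structural connectivity restricted to connected pairs;
inverse Euclidean distance over all pairs (the minimal monotone choice of a
distance-to-weight map, exposed as the default of a configurable kernel);
all-edges (mask dropped, N_i = n−1); and distance-regressed inputs. Regions
with no qualifying edge get NaN exposure and are excluded pairwise. Note the
count normalization means exposure conserves a constant abnormality map only
for binary weights.

## Gradients and communities

Gradients are PCA scores of a mode's row profiles with the undefined
diagonal imputed as the off-diagonal row mean (keeps self-similarity from
dominating PC1) and component signs anchored to correlate positively with
mean row weight. Variance explained is reported per component.

Signed Louvain maximizes
`Q(γ) = 1/(2m⁺) Σ_ij [w⁺_ij − γ p⁺_ij] δ(σ_i,σ_j)
      − 1/(2(m⁺+m⁻)) Σ_ij [w⁻_ij − γ p⁻_ij] δ(σ_i,σ_j)`,
with p±_ij = s±_i s±_j/(2m±). Sums run over ordered pairs including i = j
(the null diagonal is partition-invariant), which pins Q(γ=1) = 0 for a
single community on an all-positive network. Whether γ also scales the
negative null term is genuinely underdetermined in the field's notation;
both conventions are implemented (`negative_gamma={"scaled","unscaled"}`,
default scaled). The optimizer is greedy node-moving plus aggregation on the
signed modularity matrix with seeded random node order. Consensus clustering
builds the run × run co-assignment matrix over n_reps randomized runs,
thresholds it at the 95th percentile of a label-permutation null, and
re-clusters iteratively until all runs agree (cap 50 meta-iterations, modal
partition with a flag otherwise). The resolution sweep covers γ = 0.1…6.0
in steps of 0.1 (60 values) by default.

## Similarity network fusion

Affinities use the scaled exponential kernel
`W(i,j) = exp(−ρ²(x_i,x_j)/(μ ε_ij))` where x_i is region i's row profile
with both regions' self-entries removed (keeps ρ a metric between comparable
vectors), and `ε_ij` averages each region's mean distance to its K nearest
neighbors with ρ(i,j). The neighborhood reading of ε follows the N_i
notation of the standard formulation (the prose alternative "all other
regions" is exposed nowhere because it contradicts that notation);
ε is floored at 1e−12 to guard the all-identical degenerate case.
Defaults: μ = 0.5, K = ⌊n/10⌋, 20 iterations. Each iteration updates all
modes synchronously (order-independence), renormalizes rows
(P(i,i) = 1/2, off-diagonal rows sum to 1/2), and symmetrizes; the fused
network is the elementwise mean of the m matrices, diagonal zeroed. No
convergence test is applied — the fixed 20 iterations always run and the
per-iteration Frobenius delta is recorded. The update is a smoothing
diffusion: even m identical inputs are not a literal fixed point, so the
consistency property tested is invariance to the number of copies plus
positive rank alignment with the input kernel, not equality. Robustness
checks: leave-one-out fusions and a (K, μ) grid, both summarized by Spearman
correlation with the reference fusion over upper-triangular edges.

## Null models

**Spin permutations.** One uniform random rotation (quaternion method) per
repetition is applied to the left hemisphere's unit-sphere parcel centroids;
the right hemisphere uses the same rotation conjugated by an x-reflection so
mirrored geometry stays mirrored. Each original parcel takes the value of
the nearest rotated parcel within its hemisphere; if a medial-wall proxy
point is nearest, the next most proximal parcel is used. Reassignments may
repeat values (they are not permutations in the strict sense). Spin
p-values are two-sided on |r| with the +1 estimator, so the minimal
attainable p is 1/(n_rotations + 1) — marginally more conservative than the
0/n convention some reports use. Calibration under independent spatially
smooth maps is uniform (tested by KS at 500 rotations × 200 replicates).

**Rewired surrogates.** Edges are binned by Euclidean distance into
equal-count bins (10 by default; 1 bin gives plain Maslov–Sneppen
rewiring). Degree-preserving double-edge swaps are drawn within bins, with
proposals rejected when they would create self-loops or multi-edges or when
either new edge's distance leaves the bin — this preserves the binned
edge-length histogram exactly, at the cost of a retry loop (cap 100 per
swap; shortfalls, typically <10% of the 20·n swap budget, are logged and
recorded). Swapped edges carry their weights, preserving the weight
multiset.

## Synthetic study conditions

The generator emulates the statistical structure the analyses assume, not
the biology. A bilateral parcellation places n/2 centroids per hemisphere on
a mirrored 2-D sheet in mm space with matching spherical projections and
medial-wall proxies; intrinsic (7-way) and cytoarchitectonic (4-way) labels
come from independent k-means partitions of the sheet, mirrored across
hemispheres. Feature matrices are spatial Gaussian-process draws
(covariance exp(−d/λ), sampled through the symmetric kernel square root with
eigenvalue clipping at 0) mixing a shared latent pool (weight α) with
mode-specific draws, homotopic mirror pairs sharing latents at weight 0.8,
plus white measurement noise. The structural connectome draws edges with
probability ∝ exp(−η d)·g_i g_j (g = 3 for a hub fraction of regions),
solves the proportionality constant for the requested density, and assigns
rank-uniform weights ordered by the underlying edge score. Abnormality maps
invert the exposure model: three z-scored iterations of d ← C⁺d/N⁺ from a
random start, plus Gaussian noise.

Defaults (n = 200 regions, 7 modes, 60 features/mode, λ = 15 mm, α = 0.2,
noise SD 0.9, density 0.15, η = 0.02/mm, hub fraction 0.1) were calibrated
once so the suite reproduces a median pairwise inter-mode edge correlation
near 0.25 — the regime where modes are related but non-redundant — while
keeping a clear distance decay (binned-rank Spearman ≈ −0.74) and elevated
homotopic similarity. One global seed expands into named substreams
(parcellation, shared latents, per-mode latents, feature noise, connectome,
time series, abnormality), so adding a component never perturbs another's
stream.

What the generator does *not* emulate: mode-specific decay shapes
(exponential vs. linear differences between modes), low-dimensional
dominant gradients (synthetic PC1 variance is 12–20%, far below what highly
gradient-like modes show), structure–similarity coupling beyond shared
geometry (the coupling delta is positive but not significant against
edge-length-preserving nulls — by construction, wiring adds nothing over
distance here; the planted-coupling calibration test covers detection
power), donor sampling geometry, and biophysical time-series realism.
Passing tests therefore demonstrate correctness of the computations and
calibration of the inference machinery, not that real cortical data behave
this way.

## Problem sizes and numerical choices

The packaged analyses run at n = 200 regions / 7 modes (the default study),
with unit and oracle tests at 3–100 regions; surrogate ensembles use 50–100
networks and consensus clustering 20–50 repetitions in the packaged runs
(250 repetitions and 1,000 surrogates remain the defaults of the respective
functions' signatures where the cited procedures specify them). Tolerances:
symmetry 1e−10; SNF row-stochasticity 1e−10; eigen-oracle agreement 1e−8;
Fisher clipping 1e−7; rank ties averaged; strongest-edge ties lexicographic;
degenerate inputs (constant maps, all-equal regions, empty edge classes)
raise or flag rather than silently returning numbers.
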