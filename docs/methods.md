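# Methods

This note documents the models and numerical conventions implemented in
`connectoprofile`, the choices made where several conventions exist, and
what the synthetic validation does and does not demonstrate.

## Input model

A subject is a symmetric, non-negative, zero-diagonal N×N weight matrix
over atlas regions; weights are treated as given (typically
SIFT2-filtered streamline counts — no volume normalization or
re-weighting is applied here). On ingestion, asymmetry up to a relative
1e−6 is attributed to round-off and repaired by averaging (A + Aᵀ)/2;
anything larger is an error, since tractography connectomes are symmetric
by construction. Fully disconnected rows are accepted with a warning:
anatomically disconnected regions legitimately remain in the matrix so
that dimensions stay comparable across subjects. The reference size is
the 84-region Desikan–Killiany parcellation, but any N ≥ 3 works.

## Graph metrics

All metrics operate on the reciprocal weight→length remap
L_ij = 1/w_ij (absent edges have infinite length), the standard
convention for streamline-weighted connectomes: stronger connections are
shorter communication paths.

- **Characteristic path length** L: mean Dijkstra shortest-path length
  over connected unordered pairs. Unreachable pairs are *excluded* from
  the mean and their count is reported; efficiency-type metrics instead
  count them as zero efficiency, which matches the inverse-path-length
  definitions and keeps both metrics finite on fragmented graphs.
- **Global efficiency** E_glob: mean of 1/d_ij over all unordered pairs.
- **Strength** s_i = Σ_j w_ij, reported per node and as the mean.
- **Clustering** C_i: geometric-mean (Onnela) triangle formula on weights
  normalized by the network-wide maximum,
  C_i = Σ_{j,h} (w̃_ij w̃_jh w̃_hi)^{1/3} / (k_i (k_i − 1)); degree < 2
  gives 0. This is the standard weighted-undirected variant; the
  max-normalization puts C in [0, 1] and makes it invariant to uniform
  weight scaling.
- **Local efficiency** E_loc(i): global efficiency of the subgraph induced
  by i's neighbours, computed on the same max-normalized weights, 0 for
  fewer than two neighbours.
- **Betweenness centrality** BC_i: weighted Brandes accumulation on the
  length matrix, *unnormalized* (unordered source–target pair counts,
  ties split fractionally). Raw counts are reported because hub
  magnitudes on 84 nodes are conventionally quoted in the hundreds to
  thousands.
- **Navigation efficiency** E_nav: decentralized greedy geometric
  routing. From s toward t the walk repeatedly hops to the connected
  neighbour with the smallest Euclidean distance to t (region centroids,
  mm). The walk *fails* when that neighbour has already been visited or
  the current node has no neighbours; ties break to the lowest node
  index, making the walk deterministic. A successful walk contributes
  1/(sum of remapped edge lengths along the walk); failures contribute 0;
  E_nav averages over all ordered pairs. A hop-count length variant is
  available (`length="hops"`); the remapped-length variant is the
  default because it is commensurable with E_glob (and navigation
  efficiency can then never exceed shortest-path efficiency, a property
  the tests assert).
- **Normalized clustering** C/C_rand: mean clustering divided by the mean
  clustering of degree-preserving surrogates. Each surrogate applies
  10 × E attempted double-edge swaps (two edges (a,b), (c,d) rewired to
  (a,d), (c,b), rejecting self-loops and duplicates), with weights
  travelling on the edge slots — degrees and the weight multiset are
  preserved exactly, strengths are not. Default 100 surrogates; the
  generator is seeded, so C_norm is bit-reproducible. These null-model
  parameters (100 nulls, 10 swaps/edge) are conventional choices exposed
  in `NullModelConfig`, not estimates.

## GraphMe profile

Three metrics are inverted (1/x) for display — characteristic path
length, normalized clustering, betweenness — so that larger always means
better-integrated on the radar plot. Head-size correction then scales
every metric by the subject's total intracranial volume; the default
`divide` mode (metric/ICV) is the conventional correction, a literal
`multiply` mode is available, and `none` skips it (the synthetic
presets carry ICVs so either mode runs). Correction is applied after
inversion.

The control band is, per metric, mean ± t_{0.975,n−1}·sd/√n by default —
the literal 95% confidence interval of the control *mean*. Because a CI
of the mean shrinks with n and is a narrow yardstick for classifying an
*individual*, a `prediction` option (mean ± t_{0.975,n−1}·sd·√(1+1/n))
is provided; with it, a held-out healthy subject is categorized "normal"
at the nominal ~95% rate, which the test suite verifies empirically over
500 simulated cohorts (16 nodes, 12 controls — coverage of a t
prediction interval does not depend on network size). Band boundaries
are inclusive: a value exactly at the limit is "normal". Categories are
invariant to affine increasing rescalings applied identically to patient
and controls (but not to arbitrary monotone transforms, since mean ± sd
bands do not commute with nonlinear maps).

## Deviation mapping

Edgewise z = (T_ij − μ_ij)/σ_ij with the control sample mean and SD
(ddof = 1). Two-sided p-values use the *standard normal* reference,
computed via erfc so far tails are exact (no 1 − CDF cancellation); no
small-sample t correction is applied, matching how such z maps are
conventionally read. BH-FDR (q = 0.05 default) runs over the unique
upper-triangle edges; for N = 84 that family is C(84,2) = 3486 edges.
Zero-variance edges where the patient matches the control mean get z = 0;
zero-variance edges where the patient differs carry no parametric
information and are excluded and flagged rather than tested. Node
strengths are handled identically over the N-node family (correction can
be disabled). Sign convention: z < 0 ⇒ "weaker" connection in the
patient, z > 0 ⇒ "stronger".

Hubs are the k = round-half-up(0.10·N) highest-betweenness nodes (8 on
84 nodes); threshold ties break by higher strength, then lower index.
The reference hub set defaults to the betweenness of the control
group-average connectome; a `consensus` option ranks nodes by how often
they are hubs in individual controls. Hub alterations are the set
differences (gained/lost).

**Known limitation — small-sample tails.** With n = 12 controls the
statistic (T − mean)/sd is approximately √(13/12)·t₁₁ under the null, so
the normal reference understates tail probabilities (nominal |z| = 2.95
has true two-sided probability ≈ 0.013, not 0.003). Under a global null
this barely matters — BH rejects almost nothing (measured rejected-edge
fraction ≈ 0.4%) — but when a strong lesion relaxes the BH threshold,
marginal |z| ≈ 3 edges pass at an inflated rate, visible as a modest
count of spurious "stronger" edges alongside a heavily-lesioned
recovery. Lesion recovery at study conditions remains high
(sensitivity ≈ 0.99, precision ≈ 0.97 for attenuation 0.3 on 4 nodes).

## Synthetic cohorts

The generator produces what the deviation model assumes: per-edge
approximately unimodal control distributions with stable mean and SD.

- **Geometry**: node centroids uniform in a brain-sized ellipsoid
  (semi-axes 65 × 85 × 60 mm) with exact left/right mirror pairs and a
  midline gap; mirror symmetry yields bilateral hub fixtures and gives
  navigation a meaningful embedding.
- **Template**: w_ij = w₀·exp(−d_ij/λ) with w₀ = 2000 and λ = 35 mm,
  thresholded to the strongest 60% of pairs. The distance decay, weight
  scale and density are set to resemble SIFT2 streamline-count matrices
  on an 84-region parcellation (dense graphs, strong short-range edges);
  they are fixture parameters, not estimates from data.
- **Subjects**: template × symmetric per-edge lognormal noise with
  median 1 and CV 0.15 (so μ_log = 0, σ² = ln(1 + CV²)). The median-1
  parameterization keeps weights positive and right-skewed; the per-edge
  sample mean consequently overshoots the template by √(1 + CV²) ≈ 1.011,
  which is irrelevant to z-scores (they compare patient to control
  *sample* statistics). ICVs are drawn at 1.5 × 10⁶ mm³ ± 8%.
- **Lesions**: all edges incident to chosen target nodes multiplied by
  a ∈ [0, 1] (or zeroed), symmetry preserved; the returned mask marks
  exactly the changed nonzero edges and serves as ground truth.

What passing the synthetic suites shows: the statistical machinery is
correctly implemented and calibrated *under its own assumptions*
(independent edges, multiplicative noise, homogeneous controls). What it
does not show: robustness to real-data features the generator omits —
inter-subject registration error, parcellation variability, heavy-tailed
or zero-inflated edge distributions, correlated edge noise, and
systematic acquisition differences between patient and controls.

## Determinism and problem sizes

Every stochastic component (null-model rewiring, synthetic sampling)
runs off explicit seeds; a fit derives per-subject null seeds from one
base seed via `numpy.random.SeedSequence`, and repeated runs are
byte-identical. The Monte-Carlo validation sizes — 200 null replicates
for false-positive control, 100 lesioned runs for recovery, 500 cohorts
for band coverage — were chosen so Monte-Carlo standard errors are small
relative to the margins being checked.
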