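# Methods

## Problem and model

Rigid-body protein–protein docking produces a table of solutions, each a
rotation triple (radians, internally wrapped to [0, 2π)), a translation
(Å) and an interaction score (internally oriented so larger = better;
engines that print "lower is better" are negated at parse time). The
package treats the solution set as a point cloud on the product space
(angle torus) × (translation box) and asks which regions of that space the
docking sampler visited densely and scored well.

### Angular metric

Per coordinate, dᵢ = min(|bᵢ−aᵢ|, |bᵢ−aᵢ+2π|, |bᵢ−aᵢ−2π|) ∈ [0, π]; the
triple distance is the Euclidean combination √(Σdᵢ²) ∈ [0, π√3]. This is
the flat torus metric: symmetric, wrap-invariant, triangle inequality
(property-tested). Quaternion or rotation-matrix geodesics are deliberate
non-goals: the method operates on the engine's raw angle columns.

### Embedding and feature construction

Torgerson scaling of the angular distance matrix: B = −½·J·D²·J with
J = I − 11ᵀ/n; eigendecompose; coordinates are eigenvectors scaled by
√eigenvalue. The torus metric is not Euclidean-embeddable, so negative
eigenvalues occur; they are dropped and their summed magnitude is logged
(`run_log.yaml`, `negative_eigenvalue_mass`) as a distortion diagnostic.
Retention: positive components, largest first, until 95% of the positive
eigenvalue mass, capped at 6 (both configurable). A typical run therefore
clusters in ≈ 5 + 3 dimensions. Numerical positivity uses the threshold
max|λ|·n·ε_machine, so an all-zero distance matrix cleanly yields zero
retained components and clustering falls back to translations alone.

The retained coordinates are concatenated with (tx, ty, tz) and each
column is standardized to mean 0, unit sample variance (ddof = 1).
Constant columns are zeroed and flagged instead of divided by ≈0. Column
standardization is the simplest reading of "equal weight per variable";
block-level variance equalization (equal total weight for the angular vs
the positional block) would be a reasonable alternative but is not
implemented.

Interaction energy is *not* part of the clustering distance; it enters
only through ranking (representatives, significance, outcome). Folding a
third unit into the metric would need an arbitrary angle/position/energy
exchange rate, whereas rank-based use of the score is scale-free.

## Density clustering

DBSCAN is implemented from the density-connectivity definition rather than
wrapped from a library, because every semantic detail is pinned for
reproducibility and is oracle-tested:

* neighborhood is closed (≤ ε) and counts the point itself; a core point
  has ≥ k neighbors (default k = 15, the package default for typical
  docking tables of hundreds to thousands of rows);
* clusters are connected components of the ε-graph over core points;
  border points join the first cluster whose expansion reaches them, with
  points processed in row order and FIFO expansion — so the labeling is a
  deterministic function of the input order;
* everything else is Cluster 0 (noise). n < k yields all-noise with a
  warning rather than an error.

Brute-force distance matrices are used throughout (no spatial index); the
intended scale is n ≲ 10⁴.

### Automatic ε

Candidates are the nearest-rank percentiles 5, 10, …, 95 of the positive
k-distance profile (distance of each point to its k-th nearest neighbor),
deduplicated — at most 19 DBSCAN runs. Each candidate labeling is scored
by four validity indexes oriented larger-is-better: Davies–Bouldin ×−1,
Calinski–Harabasz, Hubert–Levine C-index ×−1 ((S_w−S_min)/(S_max−S_min)
over within-cluster pair distances), and mean Silhouette. Candidates are
ranked per index (ties share the mean rank; candidates with < 2 clusters
get rank 0 on every index) and the mean of the four ranks decides; ties go
to the smaller ε (denser, more conservative clusters). If no candidate
produces two clusters, the fallback maximizes the non-noise fraction, with
a warning.

**Noise handling in the indexes.** The indexes are computed over *all*
points, with the noise set entering as one extra (diffuse) group; a
`noise_as_group=False` switch restricts them to clustered points. The
default matters: evaluated on clustered points only, Silhouette,
Davies–Bouldin and the C-index all improve monotonically as ε shrinks —
tighter cores, more noise — so the consensus would always pick the
smallest candidate and shed half the data. Scoring the noise as a group
penalizes exactly that regime; with it, the automatic selection recovers
well-separated planted modes with ARI ≥ 0.9 (acceptance suite). Labelings
without noise are unaffected by the switch. Eligibility always requires at
least two genuine clusters. Singleton-cluster members take Silhouette 0;
a zero C-index denominator (all pair distances equal) scores 0; a zero
within-cluster scatter makes Calinski–Harabasz +∞, which ranks top and
ties with other exact candidates.

### Finalization

Clusters with fewer than `min_cluster_size` members (default 15, the same
default as k but independently configurable) are discarded to Cluster 0 —
a docking region supported by a handful of poses is not worth human
inspection. Survivors are relabeled 1..G by decreasing size, ties broken
by the earlier first-member row.

## Cluster analysis

* **Representative** = member minimizing the mean of the centrality rank
  (ascending summed feature-space distance to co-members; rank 1 = medoid)
  and the energy rank (ascending −score). Ties: better score, then lower
  id. Rank averaging combines "central" and "high energy" without a units
  trade-off.
* **Significant cluster**: size ≥ max(min_cluster_size, 5% of n) AND mean
  member score ≥ the 75th percentile of all solution scores. Both
  constants are explicit `AnalysisThresholds` fields; no quantitative
  criterion exists in the field for these words, so the defaults are the
  package's own and are deliberately conservative.
* **Outcome flag**: `satisfactory` if any cluster is significant; else
  `static_candidate` if ≥ 3 of the 10 best-scored solutions are noise
  (a constrained, inflexible binding site shows up as strong isolated
  contacts that never densify); else `unsatisfactory` if clusters exist
  but every cluster mean is below the global median score; else
  `indeterminate`. With zero clusters every solution is noise, so the
  static rule fires before the vacuous "all clusters below median" branch
  can.
* **Markers**: user-supplied solution ids are looked up (cluster, score,
  representative status) and highlighted in the cluster plot.

## Pose export

Rotation matrices follow a named Euler convention (default `zyz`:
R = Rz(a₁)·Ry(a₂)·Rz(a₃); `zyx` and `xyz` are registered). Poses apply
x' = R·(x−c) + c + t with c the ligand centroid by default (`origin`
switches to the fixed origin). Docking engines disagree silently on both
conventions, so both are configurable and stamped into REMARK 250 records
of every written file. PDB I/O goes through biotite; trajectories are
MODEL/ENDMDL stacks. Rigidity (internal distances preserved to 1e-6 Å) and
the PDB 3-decimal round trip are tested.

## Synthetic data

The generator plants G binding modes: centers rejection-sampled so every
pair is ≥ 10 noise-sd apart in both the angular and the translational
component (factor configurable), members scattered with Gaussian noise
(angles wrapped mod 2π — an adequate wrapped-Gaussian approximation for
sd ≪ π), outliers uniform on the torus × box. Scores are Gaussian per
group; by default cluster means run 110–100+10·G so earlier-planted modes
score higher, and outliers sit at 60 ± 10, well below any cluster.
Defaults: 4 modes × 50 members, angular sd 0.1 rad, translational sd
0.5 Å, 30 Å box, 20% outliers (count = round(f/(1−f) × members), i.e. the
fraction refers to the final table), one center pinned at angles (0,0,0)
so its members straddle the wrap. Rows are shuffled and ids assigned in
shuffled order; identical spec + seed gives a byte-identical TSV.

What the generator does *not* emulate: correlated angle–translation
structure within a mode, energy funnels, anisotropic or multi-modal
cluster shapes, and receptor-dependent excluded volume. Passing the
planted-recovery tests therefore shows the machinery is correct under
well-separated Gaussian modes, not that every real docking landscape will
split as cleanly.

## Problem sizes and determinism

The test and acceptance workloads use tables of ~180–750 solutions (up to
5 modes × 120 members + 20% outliers), sizes at which the full pipeline
runs in seconds while exercising every code path; the implementation
itself is O(n²) memory in the distance matrices and comfortable to a few
thousand solutions. All randomness flows from explicit seeds
(`numpy.random.default_rng`); identical input + seed + config produces
byte-identical tabular outputs, which is asserted in the CLI tests.

## Known limitations

* Angle triples are compared coordinate-wise on the torus, not as
  rotations: gimbal-degenerate pairs (different triples, same rotation)
  are distant in the metric. This mirrors the raw-column convention of the
  docking tables the method consumes.
* The ε grid is percentile-quantized; a pathological density profile could
  place the optimum between candidates.
* Validity indexes assume roughly convex clusters; strongly elongated
  density-connected clusters can depress the consensus score even when
  DBSCAN finds them correctly.
* The outcome heuristics are qualitative classifications made explicit;
  their thresholds are defaults to be revisited per docking engine.
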