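# dockclust

Unsupervised clustering of rigid-body protein–protein docking solutions.

A rigid-body docking run samples thousands of candidate placements of a
ligand protein against a receptor. Each solution is a rotation-angle triple
(a₁, a₂, a₃), a translation (tx, ty, tz) in Å, and an interaction score.
Inspecting thousands of poses by hand is hopeless; what a structural
biologist wants is the handful of *recurrent binding configurations* the
sampler kept falling into, each summarized by one representative pose.
`dockclust` extracts exactly that, with no tuning required from the user.

## Method

1. **Wrap-aware angular distances.** Angles live on a circle, so each
   coordinate contributes dᵢ = min(|bᵢ−aᵢ|, |bᵢ−aᵢ+2π|, |bᵢ−aᵢ−2π|) and two
   solutions' rotations are compared with the torus metric
   d(A,B) = √(d₁²+d₂²+d₃²) ∈ [0, π√3]. A cluster whose rotations straddle
   0/2π stays one cluster; naive Euclidean treatment of the raw angle
   columns tears it apart.
2. **Principal coordinates.** Classical (Torgerson) MDS converts the angular
   distance matrix into Euclidean coordinates: eigendecompose
   B = −½·J·D²·J, keep the leading positive-eigenvalue components (95% of
   the positive eigenvalue mass, at most 6).
3. **Joint feature space.** The MDS coordinates are concatenated with the
   translations and every column is standardized to zero mean and unit
   sample variance, so rotation and position carry equal weight in the
   Euclidean distances that follow.
4. **DBSCAN with automatic ε.** DBSCAN (MinPts k = 15) is implemented from
   its density-connectivity definition. Candidate radii are percentiles of
   the k-distance profile; each candidate labeling is scored by four
   cluster-validity indexes — Davies–Bouldin (×−1), Calinski–Harabasz,
   Hubert–Levine C-index (×−1) and Silhouette — and the candidate with the
   best mean rank across the four wins. Clusters with fewer than 15 members
   are discarded to noise ("Cluster 0") and the survivors are relabeled
   1..G by decreasing size.
5. **Representatives.** Within each cluster, members are ranked by
   centrality (summed feature-space distance to co-members; rank 1 = medoid)
   and by score; the member with the best mean rank is the cluster's
   representative. Representatives can be exported as PDB poses and merged
   into a multi-MODEL pseudo-trajectory that animates the displacement of
   one protein over the other.

## Worked example

Generate a synthetic docking table with three planted binding modes and
cluster it:

```sh
$ dockclust simulate --out demo.tsv --n-clusters 3 --members 60,45,40 --seed 4
wrote 181 solutions to demo.tsv

$ dockclust run --input demo.tsv --outdir demo_out --mark 1
wrote outputs to demo_out
eps=0.787975 clusters=3 noise=36 outcome=satisfactory
```

The pipeline selected ε ≈ 0.788 automatically, recovered the three planted
modes, left 36 solutions (the planted outliers) in Cluster 0, and flagged
the run satisfactory because at least one cluster is both large and
well-scored. `demo_out/clusters.tsv` summarizes the clusters:

```
cluster	size	mean_score	median_score	representative_id	significant
1	60	128.7541134	128.9817846	38	1
2	45	120.5582922	121.1915609	49	0
3	40	109.4147315	109.4314913	14	0
```

and `demo_out/representatives.tsv` holds the reduced solution set — 181
poses condensed to three:

```
cluster	solution_id	score
1	38	138.2463126
2	49	124.5858842
3	14	122.8901859
```

The output directory also contains per-solution assignments
(`assignments.tsv`), the ε-selection scorecard (`eps_selection.tsv`, one
row per candidate with the four index values, their ranks and the chosen
flag), a PCA cluster plot, the all-pairs axis panels, the k-distance
profile, and a `run_log.yaml` recording the configuration and versions.
Passing `--ligand ligand.pdb` additionally writes per-cluster pose PDB
files and `trajectory.pdb` with one MODEL per representative.

Input tables use a plain TSV dialect (header
`solution_id rot1 rot2 rot3 tx ty tz score`, angles in degrees by default,
`#` comments skipped); other docking-engine layouts can be plugged in with
`dockclust.register_dialect`.

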