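"""Cluster DEG expression profiles into shared / organ-specific programs.

Standardized 6-condition profiles of the up- and down-regulated genes are
partitioned by k-means (k chosen by silhouette), features that correlate
poorly with their centroid are left unassigned, and each cluster is tagged
by the shape of its mean profile.
"""

from mirscreen import SimConfig, run_pipeline, simulate_dataset

ds = simulate_dataset(SimConfig(seed=1))
res = run_pipeline(ds.mrna, ds.mirna, ds.targets, skip_screen=True)

print(f"{res.clusters.n_clusters} clusters over "
      f"{int(res.mrna_de.feature_calls['is_de'].sum())} DEGs:")
for cid in res.clusters.cluster_means.index:
    size = len(res.clusters.members(cid))
    print(f"  {cid:8s} {size:4d} genes  -> {res.clusters.labels[cid]}")
print("(labels: trend per organ from T0 to T2; 'high-X' marks a >2-fold "
      "higher absolute CPM level in organ X)")
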