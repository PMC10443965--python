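"""The integrated anti-correlation screen for candidate regulator miRNAs.

A DE miRNA is nominated when its predicted targets are over-represented in
a DEG cluster (hypergeometric p < 0.01) and its standardized 6-condition
profile is negatively correlated (Pearson r < -0.4) with the mean profile
of those in-cluster targets — the expression signature of a repressor.
"""

from mirscreen import SimConfig, run_pipeline, simulate_dataset
from mirscreen.screen import passing_mirnas

ds = simulate_dataset(SimConfig(seed=1))
res = run_pipeline(ds.mrna, ds.mirna, ds.targets, ds.gene_sets)

c = res.candidates
print("top of the screen table (all tested miRNA x cluster pairs kept):")
cols = ["mirna", "cluster", "k", "n", "K", "EF", "pvalue", "r", "passes"]
print(c[cols].head(8).round(3).to_string(index=False))

passing = passing_mirnas(c)
truth = set(ds.truth.regulator_ids)
print(f"\npassing candidates: {passing}")
print(f"planted regulators: {sorted(truth)}")
print(f"recovered {len(set(passing) & truth)}/6 planted regulators, "
      f"{len(set(passing) - truth)} false positive(s)")
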