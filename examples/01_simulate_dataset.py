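"""Generate a synthetic paired mRNA/miRNA developmental dataset.

Builds the default two-organ (A/B), three-timepoint (T0/T1/T2) design with
three replicates per condition, planted expression archetypes, and six
planted repressor miRNAs, then writes the six fixture files.
"""

from pathlib import Path

from mirscreen import SimConfig, simulate_dataset, write_fixture

cfg = SimConfig(seed=1)
ds = simulate_dataset(cfg)

print(f"mRNA counts:  {ds.mrna.counts.shape[0]} genes x {ds.mrna.counts.shape[1]} samples")
print(f"miRNA counts: {ds.mirna.counts.shape[0]} miRNAs x {ds.mirna.counts.shape[1]} samples")
print(f"target map:   {len(ds.targets)} predicted (miRNA, gene) pairs")
print(f"planted regulators: {ds.truth.regulator_ids}")
print("  each targets", cfg.targets_per_regulator, "genes of one archetype;",
      cfg.decoy_targets_per_mirna, "decoy targets per miRNA mimic prediction noise")

outdir = Path("scratch/example_fixture")
paths = write_fixture(ds, outdir)
print(f"\nwrote {len(paths)} files to {outdir}/ (counts, sample sheet, targets, GMT, truth)")
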