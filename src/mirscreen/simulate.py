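"""Synthetic paired mRNA/miRNA datasets with planted expression programs.

The generator emulates a two-organ (A ~ cochlear sensory epithelium,
B ~ auditory brainstem) by three-timepoint (T0 embryonic baseline, T1, T2)
bulk RNA-seq design with a few replicates per condition. Gene mean
profiles follow a small set of archetypes — shared repression/induction
(optionally with a higher absolute level in one organ), organ-specific
induction, and a transient mid-development peak — on a log2 scale around
each gene's own baseline abundance; the remaining genes are flat. Counts
are negative binomial with mean mu and variance mu + alpha*mu^2 around
library-size-scaled expected fractions, with log-normal library sizes.

A handful of planted "repressor" miRNAs receive the sign-flipped profile
of the archetype whose genes they target, scaled to ``coupling_strength``
log2 units of amplitude, so that their expression anti-correlates with
their targets' mean pattern. The emitted target map mixes these true
targets with uniform random decoy pairs, mimicking the false-positive
structure of sequence-based target prediction. A "deafness-like" gene set
enriched in one shared archetype is emitted for set-enrichment testing.

Everything is reproducible from a single seed; each output matrix uses
its own RNG stream (derived from the seed by fixed offsets) so adding
miRNAs never perturbs the mRNA draws.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    CountMatrix,
    GeneSetCollection,
    SampleDesign,
    TargetMap,
    write_counts,
    write_gmt,
    write_sample_sheet,
    write_target_map,
)


@dataclass(frozen=True)
class Archetype:
    """A planted mean-profile shape over the 6 (organ, timepoint) conditions.

    ``mean_log2_profile`` is organ-major (A-T0, A-T1, A-T2, B-T0, B-T1,
    B-T2), in log2 units added to a gene's baseline abundance.
    """

    name: str
    mean_log2_profile: tuple[float, float, float, float, float, float]

    def __post_init__(self) -> None:
        if len(self.mean_log2_profile) != 6:
            raise ValueError("archetype profile must have 6 conditions")


#: the six default archetypes: shared repression (equal and organ-A-high
#: absolute levels), shared induction, organ-specific induction in each
#: organ, and a transient organ-A peak at the middle timepoint.
DEFAULT_ARCHETYPES: tuple[Archetype, ...] = (
    Archetype("shared-down", (2, 1, 0, 2, 1, 0)),
    Archetype("shared-down-high-A", (3.5, 2.5, 1.5, 2, 1, 0)),
    Archetype("shared-up", (0, 1, 2, 0, 1, 2)),
    Archetype("A-specific-up", (0, 1, 2, 0, 0, 0)),
    Archetype("B-specific-up", (0, 0, 0, 0, 1, 2)),
    Archetype("transient-A", (0, 2, 0, 0, 0, 0)),
)


@dataclass
class SimConfig:
    """Parameters of the synthetic paired dataset."""

    n_genes: int = 2000
    n_mirnas: int = 300
    n_replicates: int = 3
    organs: tuple[str, str] = ("A", "B")
    timepoints: tuple[str, str, str] = ("T0", "T1", "T2")
    archetypes: tuple[Archetype, ...] = DEFAULT_ARCHETYPES
    genes_per_archetype: int = 150
    n_regulators: int = 6
    targets_per_regulator: int = 100
    decoy_targets_per_mirna: int = 50
    coupling_strength: float = 1.5
    nb_dispersion: float = 0.1
    libsize_log_sd: float = 0.3
    mrna_libsize: float = 5e6
    mirna_libsize: float = 1e6
    mirna_archetype_fraction: float = 0.2
    deafness_set_size: int = 40
    deafness_in_archetype: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_mirnas, self.n_replicates) < 1:
            raise ValueError("all counts must be positive")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if self.n_regulators > self.n_mirnas:
            raise ValueError("n_regulators exceeds n_mirnas")
        if self.archetypes and self.targets_per_regulator > self.genes_per_archetype:
            raise ValueError(
                "targets_per_regulator exceeds genes assigned to the coupled archetype"
            )
        if self.archetypes and self.genes_per_archetype * len(self.archetypes) > self.n_genes:
            raise ValueError("archetype genes exceed n_genes")
        if self.n_regulators > 0 and not self.archetypes:
            if self.coupling_strength != 0:
                raise ValueError("regulators with nonzero coupling require archetypes")


@dataclass
class GroundTruth:
    """Planted structure: labels the downstream stages are expected to recover."""

    gene_archetype: dict[str, str]
    regulator_ids: list[str]
    regulator_archetype: dict[str, str]
    true_targets: dict[str, list[str]]
    library_sizes: dict[str, float]


@dataclass
class SimDataset:
    mrna: CountMatrix
    mirna: CountMatrix
    targets: TargetMap
    gene_sets: GeneSetCollection
    truth: GroundTruth
    config: SimConfig = field(repr=False, default=None)


def _design(config: SimConfig) -> list[SampleDesign]:
    design = []
    for organ in config.organs:
        for tp in config.timepoints:
            for rep in range(1, config.n_replicates + 1):
                design.append(SampleDesign(f"{organ}_{tp}_r{rep}", organ, tp, rep))
    return design


def _draw_counts(
    base_log2: np.ndarray,
    deltas: np.ndarray,
    design: list[SampleDesign],
    conditions: list[tuple[str, str]],
    libsizes: np.ndarray,
    alpha: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """NB counts around library-scaled expected fractions.

    deltas: features × 6 log2 offsets. With alpha == 0 the draws collapse
    to the rounded expected means (deterministic noise-free limit).
    """
    cond_index = {c: j for j, c in enumerate(conditions)}
    abundance = 2.0 ** (base_log2[:, None] + deltas)  # features × conditions
    fractions = abundance / abundance.sum(axis=0, keepdims=True)
    means = np.empty((len(base_log2), len(design)))
    for i, d in enumerate(design):
        means[:, i] = fractions[:, cond_index[(d.organ, d.timepoint)]] * libsizes[i]
    if alpha == 0:
        return np.rint(means).astype(np.int64)
    n = 1.0 / alpha
    p = n / (n + means)
    return rng.negative_binomial(n, p).astype(np.int64)


def simulate_dataset(config: SimConfig) -> SimDataset:
    """Generate the paired dataset, target map, gene set and ground truth.

    Byte-identical across runs for a fixed seed. Separate RNG streams:
    offset 0 drives planted structure (archetype membership, regulator and
    target choices), 1 the library sizes, 2 the mRNA counts, 3 the miRNA
    counts.
    """
    rng_structure = np.random.default_rng([config.seed, 0])
    rng_lib = np.random.default_rng([config.seed, 1])
    rng_mrna = np.random.default_rng([config.seed, 2])
    rng_mirna = np.random.default_rng([config.seed, 3])

    design = _design(config)
    organs = tuple(sorted(config.organs))
    conditions = [(o, t) for o in organs for t in config.timepoints]

    gene_ids = np.array([f"gene{i:05d}" for i in range(config.n_genes)])
    mirna_ids = np.array([f"mir{i:04d}" for i in range(config.n_mirnas)])

    # --- planted structure -------------------------------------------------
    shuffled_genes = rng_structure.permutation(config.n_genes)
    gene_archetype: dict[str, str] = {g: "flat" for g in gene_ids}
    archetype_members: dict[str, np.ndarray] = {}
    gene_deltas = np.zeros((config.n_genes, 6))
    for a_idx, archetype in enumerate(config.archetypes):
        lo = a_idx * config.genes_per_archetype
        members = shuffled_genes[lo : lo + config.genes_per_archetype]
        archetype_members[archetype.name] = members
        gene_deltas[members] = np.asarray(archetype.mean_log2_profile, dtype=float)
        for g in gene_ids[members]:
            gene_archetype[g] = archetype.name

    regulator_idx = rng_structure.choice(
        config.n_mirnas, size=config.n_regulators, replace=False
    )
    regulator_ids = [str(m) for m in mirna_ids[regulator_idx]]
    mirna_deltas = np.zeros((config.n_mirnas, 6))
    regulator_archetype: dict[str, str] = {}
    true_targets: dict[str, list[str]] = {}
    if config.archetypes:
        for j, m_idx in enumerate(regulator_idx):
            archetype = config.archetypes[j % len(config.archetypes)]
            centered = np.asarray(archetype.mean_log2_profile, dtype=float)
            centered = centered - centered.mean()
            scale = np.abs(centered).max()
            if scale > 0:
                mirna_deltas[m_idx] = -centered / scale * config.coupling_strength
            regulator_archetype[str(mirna_ids[m_idx])] = archetype.name
            targets = rng_structure.choice(
                archetype_members[archetype.name],
                size=config.targets_per_regulator,
                replace=False,
            )
            true_targets[str(mirna_ids[m_idx])] = sorted(gene_ids[targets])

    # bystander miRNAs: a fraction ride a random archetype (un-flipped), rest flat
    bystanders = np.setdiff1d(np.arange(config.n_mirnas), regulator_idx)
    if config.archetypes and config.mirna_archetype_fraction > 0:
        n_arch = int(round(len(bystanders) * config.mirna_archetype_fraction))
        chosen = rng_structure.choice(bystanders, size=n_arch, replace=False)
        arch_choice = rng_structure.integers(0, len(config.archetypes), size=n_arch)
        for m_idx, a_idx in zip(chosen, arch_choice):
            centered = np.asarray(
                config.archetypes[a_idx].mean_log2_profile, dtype=float
            )
            centered = centered - centered.mean()
            scale = np.abs(centered).max()
            if scale > 0:
                mirna_deltas[m_idx] = centered / scale * config.coupling_strength

    # --- target map: true targets + uniform decoys -------------------------
    pairs: list[tuple[str, str]] = []
    for m in mirna_ids:
        current = set(true_targets.get(str(m), []))
        pairs.extend((str(m), g) for g in sorted(current))
        non_targets = np.array(sorted(set(gene_ids) - current))
        n_decoys = min(config.decoy_targets_per_mirna, len(non_targets))
        decoys = rng_structure.choice(non_targets, size=n_decoys, replace=False)
        pairs.extend((str(m), str(g)) for g in sorted(decoys))
    target_map = TargetMap.from_pairs(pairs)

    # --- deafness-like gene set enriched in one shared archetype ------------
    gene_sets = GeneSetCollection({}, {})
    if config.archetypes and config.deafness_set_size > 0:
        host = config.archetypes[min(1, len(config.archetypes) - 1)].name
        n_in = min(config.deafness_in_archetype, config.deafness_set_size,
                   len(archetype_members[host]))
        inside = rng_structure.choice(
            archetype_members[host], size=n_in, replace=False
        )
        flat_pool = np.array(
            [i for i, g in enumerate(gene_ids) if gene_archetype[g] == "flat"]
        )
        outside = rng_structure.choice(
            flat_pool, size=config.deafness_set_size - n_in, replace=False
        )
        members = set(gene_ids[inside]) | set(gene_ids[outside])
        gene_sets = GeneSetCollection(
            {"deafness_like": members},
            {"deafness_like": f"synthetic set enriched in the {host} archetype"},
        )

    # --- library sizes and counts -------------------------------------------
    def libs(mean: float, n: int) -> np.ndarray:
        if config.libsize_log_sd == 0:
            return np.full(n, mean)
        return mean * np.exp(rng_lib.normal(0.0, config.libsize_log_sd, size=n))

    lib_mrna = libs(config.mrna_libsize, len(design))
    lib_mirna = libs(config.mirna_libsize, len(design))

    base_genes = rng_mrna.normal(5.0, 1.5, size=config.n_genes)
    counts_mrna = _draw_counts(
        base_genes, gene_deltas, design, conditions, lib_mrna,
        config.nb_dispersion, rng_mrna,
    )
    base_mirnas = rng_mirna.normal(7.0, 1.5, size=config.n_mirnas)
    counts_mirna = _draw_counts(
        base_mirnas, mirna_deltas, design, conditions, lib_mirna,
        config.nb_dispersion, rng_mirna,
    )

    sample_ids = [d.sample_id for d in design]
    mrna = CountMatrix(
        pd.DataFrame(counts_mrna, index=gene_ids, columns=sample_ids), design, "mRNA"
    )
    mirna = CountMatrix(
        pd.DataFrame(counts_mirna, index=mirna_ids, columns=sample_ids), design, "miRNA"
    )
    truth = GroundTruth(
        gene_archetype=gene_archetype,
        regulator_ids=sorted(regulator_ids),
        regulator_archetype=regulator_archetype,
        true_targets=true_targets,
        library_sizes={
            **{f"mRNA:{s}": float(v) for s, v in zip(sample_ids, lib_mrna)},
            **{f"miRNA:{s}": float(v) for s, v in zip(sample_ids, lib_mirna)},
        },
    )
    return SimDataset(mrna, mirna, target_map, gene_sets, truth, config)


def write_fixture(dataset: SimDataset, directory: str | Path) -> dict[str, Path]:
    """Write the six fixture files (counts ×2, sheet, targets, GMT, truth JSON)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "mrna_counts": directory / "mrna_counts.tsv",
        "mirna_counts": directory / "mirna_counts.tsv",
        "sample_sheet": directory / "sample_sheet.csv",
        "target_map": directory / "target_map.tsv",
        "gene_sets": directory / "gene_sets.gmt",
        "truth": directory / "truth.json",
    }
    write_counts(dataset.mrna, paths["mrna_counts"])
    write_counts(dataset.mirna, paths["mirna_counts"])
    write_sample_sheet(dataset.mrna.design, paths["sample_sheet"])
    write_target_map(dataset.targets, paths["target_map"])
    if len(dataset.gene_sets):
        write_gmt(dataset.gene_sets, paths["gene_sets"])
    else:
        paths["gene_sets"].write_text("")
    truth = dataset.truth
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        json.dump(
            {
                "gene_archetype": truth.gene_archetype,
                "regulator_ids": truth.regulator_ids,
                "regulator_archetype": truth.regulator_archetype,
                "true_targets": truth.true_targets,
                "library_sizes": truth.library_sizes,
            },
            fh, indent=1, sort_keys=True,
        )
    return paths
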