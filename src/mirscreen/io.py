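"""Core data model and readers/writers shared by all pipeline stages.

Counts are tab-separated feature × sample integer tables; the sample sheet
is a CSV mapping each sample to its (organ, timepoint, replicate) cell of
the two-organ, three-timepoint developmental design. miRNA→target maps are
two-column TSVs (one predicted pair per row, TargetScan-style) and gene
sets use the GMT convention (name, description, tab-separated members).

Feature ids are opaque strings throughout: no annotation lookup happens
anywhere in the pipeline.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("mirscreen")

#: timepoint orders recognised without an explicit declaration
_KNOWN_TIMEPOINT_ORDERS = (
    ("E16", "P0", "P16"),
    ("T0", "T1", "T2"),
)

DESIGN_COLUMNS = ("sample_id", "organ", "timepoint", "replicate")


class FormatError(ValueError):
    """A file failed to parse into a valid object; message locates the fault."""


def infer_timepoint_order(timepoints: Iterable[str]) -> tuple[str, ...]:
    """Return the developmental ordering of a set of timepoint labels.

    Recognises the embryonic→postnatal labels E16/P0/P16 and the generic
    T0/T1/T2; any other label set is ordered lexicographically (callers
    that need a different order should relabel).
    """
    tps = set(timepoints)
    for order in _KNOWN_TIMEPOINT_ORDERS:
        if tps == set(order):
            return order
    return tuple(sorted(tps))


@dataclass(frozen=True)
class SampleDesign:
    """One sample's position in the organ × timepoint × replicate design."""

    sample_id: str
    organ: str
    timepoint: str
    replicate: int

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValueError(f"replicate must be positive, got {self.replicate}")


@dataclass
class CountMatrix:
    """Integer feature × sample counts with a typed sample design.

    ``counts`` is a DataFrame indexed by feature id with one column per
    sample, in the same order as ``design``. ``feature_kind`` is "mRNA" or
    "miRNA" and controls which stage defaults apply downstream.
    """

    counts: pd.DataFrame
    design: list[SampleDesign]
    feature_kind: str = "mRNA"

    def __post_init__(self) -> None:
        if self.feature_kind not in ("mRNA", "miRNA"):
            raise ValueError(f"feature_kind must be mRNA or miRNA, got {self.feature_kind!r}")
        if self.counts.index.has_duplicates:
            dups = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dups[:5]}")
        sample_ids = [d.sample_id for d in self.design]
        if list(self.counts.columns) != sample_ids:
            raise ValueError("counts column order does not match design order")
        keys = [(d.organ, d.timepoint, d.replicate) for d in self.design]
        if len(set(keys)) != len(keys):
            raise ValueError("(organ, timepoint, replicate) combinations must be unique")
        arr = self.counts.to_numpy()
        if not np.isfinite(arr).all() or (arr < 0).any():
            raise ValueError("counts must be finite and non-negative")

    @property
    def feature_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> list[str]:
        return [d.sample_id for d in self.design]

    @property
    def organs(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for d in self.design:
            seen.setdefault(d.organ, None)
        return tuple(sorted(seen))

    @property
    def timepoints(self) -> tuple[str, ...]:
        return infer_timepoint_order(d.timepoint for d in self.design)

    @property
    def conditions(self) -> list[tuple[str, str]]:
        """The organ × timepoint cells in fixed order (organ-major)."""
        return [(o, t) for o in self.organs for t in self.timepoints]

    def condition_samples(self, organ: str, timepoint: str) -> list[str]:
        return [
            d.sample_id for d in self.design if d.organ == organ and d.timepoint == timepoint
        ]

    def subset_features(self, features: Sequence[str]) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(features)], self.design, self.feature_kind)


@dataclass
class TargetMap:
    """Predicted miRNA→gene pairs (deduplicated)."""

    pairs: pd.DataFrame  # columns: mirna_id, gene_id

    def __post_init__(self) -> None:
        if list(self.pairs.columns) != ["mirna_id", "gene_id"]:
            raise ValueError("TargetMap frame must have columns mirna_id, gene_id")
        if self.pairs.duplicated().any():
            raise ValueError("TargetMap contains duplicate pairs")

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "TargetMap":
        df = pd.DataFrame(list(pairs), columns=["mirna_id", "gene_id"])
        n0 = len(df)
        df = df.drop_duplicates(ignore_index=True)
        if len(df) < n0:
            logger.warning("dropped %d duplicate target pairs", n0 - len(df))
        return cls(df)

    def targets_of(self, mirna_id: str) -> set[str]:
        return set(self.pairs.loc[self.pairs["mirna_id"] == mirna_id, "gene_id"])

    def by_mirna(self) -> dict[str, set[str]]:
        return {
            m: set(g) for m, g in self.pairs.groupby("mirna_id", sort=True)["gene_id"]
        }

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. a deafness-gene list, GO-style categories)."""

    sets: dict[str, set[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_sample_sheet(path: str | Path) -> list[SampleDesign]:
    """Read the CSV sample sheet (columns sample_id, organ, timepoint, replicate)."""
    df = pd.read_csv(path, comment="#", dtype=str)
    missing = [c for c in DESIGN_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: sample sheet missing columns {missing}")
    designs = []
    for _, row in df.iterrows():
        try:
            rep = int(row["replicate"])
        except (TypeError, ValueError):
            raise FormatError(
                f"{path}: non-integer replicate {row['replicate']!r} for sample {row['sample_id']!r}"
            ) from None
        designs.append(
            SampleDesign(str(row["sample_id"]), str(row["organ"]), str(row["timepoint"]), rep)
        )
    return designs


def read_counts(
    path: str | Path, sample_sheet_path: str | Path, feature_kind: str = "mRNA"
) -> CountMatrix:
    """Read a counts TSV and its sample sheet into a validated CountMatrix.

    Samples are reordered to sample-sheet order. Errors are hard and name
    the offending sample, feature or cell; there is no silent coercion.
    """
    design = read_sample_sheet(sample_sheet_path)
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate feature id(s) {dup[:5]}")
    sheet_ids = [d.sample_id for d in design]
    for col in df.columns:
        if col not in sheet_ids:
            raise FormatError(f"{path}: counts column {col!r} has no sample-sheet row")
    for sid in sheet_ids:
        if sid not in df.columns:
            raise FormatError(f"{path}: sample {sid!r} from sheet absent from counts")
    df = df[sheet_ids]
    df.index.name = None
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise FormatError(f"{path}: non-numeric cell in counts")
    if not np.all(np.isfinite(arr)):
        raise FormatError(f"{path}: non-finite cell in counts")
    if np.any(arr != np.round(arr)):
        bad = np.argwhere(arr != np.round(arr))[0]
        raise FormatError(
            f"{path}: non-integer count at feature {df.index[bad[0]]!r}, sample {df.columns[bad[1]]!r}"
        )
    df = df.astype(np.int64)
    return CountMatrix(df, design, feature_kind)


def read_target_map(path: str | Path) -> TargetMap:
    """Read a two-column miRNA→gene TSV; duplicates dropped with a warning."""
    df = pd.read_csv(
        path, sep="\t", comment="#", dtype=str,
        names=["mirna_id", "gene_id"], header=0,
    )
    if df.empty:
        logger.warning("%s: empty target map", path)
        return TargetMap(pd.DataFrame(columns=["mirna_id", "gene_id"]))
    if df.isna().any().any():
        raise FormatError(f"{path}: target map row with missing field")
    return TargetMap.from_pairs(df.itertuples(index=False, name=None))


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT gene-set file (name, description, members...)."""
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has {len(fields)} fields (< 3)")
            name, desc, *members = fields
            members = [m for m in members if m]
            uniq = set(members)
            if len(uniq) < len(members):
                logger.warning("%s:%d: set %r has duplicate members", path, lineno, name)
            sets[name] = uniq
            descriptions[name] = desc
    if not sets:
        logger.warning("%s: empty GMT file", path)
    return GeneSetCollection(sets, descriptions)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_counts(cm: CountMatrix, path: str | Path) -> None:
    cm.counts.rename_axis("feature_id").to_csv(path, sep="\t")


def write_sample_sheet(design: Sequence[SampleDesign], path: str | Path) -> None:
    pd.DataFrame([d.__dict__ for d in design], columns=list(DESIGN_COLUMNS)).to_csv(
        path, index=False
    )


def write_target_map(tm: TargetMap, path: str | Path) -> None:
    tm.pairs.to_csv(path, sep="\t", index=False)


def write_gmt(gsc: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in gsc.sets.items():
            desc = gsc.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


def write_run_metadata(path: str | Path, **metadata) -> None:
    """Write the JSON sidecar (config echo, seed, thresholds) next to a stage output."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(metadata, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
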