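"""Reading, writing and aligning the on-disk formats used throughout the package.

Two kinds of per-protein inputs are handled: modality feature tables (TSV with a
header, one identifier column plus numeric feature columns) and gene-set
collections in the standard GMT dialect (one set per line: name, description,
tab-separated members). Edge lists for the network encoder are plain
source/target[/weight] TSV.

Identifier matching across files is exact, case-sensitive string equality; an
opt-in ``normalize`` flag upper-cases and strips whitespace. Silent fuzzy
matching is deliberately avoided so that data errors surface early.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ModalityMatrix",
    "PairedDataset",
    "GeneSetCollection",
    "Partition",
    "read_modality_table",
    "write_modality_table",
    "intersect_modalities",
    "read_gmt",
    "write_gmt",
    "read_edge_list",
]


def _normalize_id(s: str) -> str:
    return s.strip().upper()


@dataclass
class ModalityMatrix:
    """One modality's per-protein feature table: ``n`` ids and an n x d matrix."""

    ids: list[str]
    values: np.ndarray
    modality_name: str = "modality"

    def __post_init__(self) -> None:
        self.ids = [str(i) for i in self.ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError(f"values must be 2-D, got shape {self.values.shape}")
        n, d = self.values.shape
        if d < 1:
            raise ValueError("modality must have at least one feature column")
        if len(self.ids) != n:
            raise ValueError(
                f"{len(self.ids)} ids but {n} rows in {self.modality_name!r}"
            )
        if any(i == "" for i in self.ids):
            raise ValueError("empty-string identifier")
        seen: set[str] = set()
        for i in self.ids:
            if i in seen:
                raise ValueError(f"duplicate identifier {i!r} in {self.modality_name!r}")
            seen.add(i)
        if not np.all(np.isfinite(self.values)):
            bad = int(np.argwhere(~np.isfinite(self.values).all(axis=1))[0, 0])
            raise ValueError(
                f"non-finite value in row {bad} (id {self.ids[bad]!r}) of {self.modality_name!r}"
            )

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def d(self) -> int:
        return int(self.values.shape[1])

    def reindex(self, ids: Sequence[str]) -> "ModalityMatrix":
        """Return a copy restricted to `ids`, rows in that order."""
        pos = {p: i for i, p in enumerate(self.ids)}
        try:
            rows = [pos[i] for i in ids]
        except KeyError as e:
            raise KeyError(f"id {e.args[0]!r} not present in {self.modality_name!r}")
        return ModalityMatrix(list(ids), self.values[rows].copy(), self.modality_name)


@dataclass
class PairedDataset:
    """Two modalities aligned on a shared, identically ordered id list."""

    ids: list[str]
    modality_v: ModalityMatrix
    modality_x: ModalityMatrix

    def __post_init__(self) -> None:
        if not (self.modality_v.ids == self.modality_x.ids == self.ids):
            raise ValueError("paired modalities must share one ordered id list")
        if len(self.ids) < 2:
            raise ValueError("a paired dataset needs at least 2 proteins")

    @property
    def n(self) -> int:
        return len(self.ids)

    def subset(self, ids: Sequence[str]) -> "PairedDataset":
        return PairedDataset(
            list(ids), self.modality_v.reindex(ids), self.modality_x.reindex(ids)
        )


@dataclass
class GeneSetCollection:
    """Named protein sets (pathway / complex / compartment standards)."""

    sets: dict[str, frozenset[str]]
    background: frozenset[str] | None = None

    def __post_init__(self) -> None:
        self.sets = {str(k): frozenset(v) for k, v in self.sets.items()}
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
        if self.background is not None:
            self.background = frozenset(self.background)
            for name, members in self.sets.items():
                if not members <= self.background:
                    raise ValueError(f"set {name!r} is not a subset of the background")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneSetCollection):
            return NotImplemented
        return self.sets == other.sets and self.background == other.background

    @property
    def universe(self) -> frozenset[str]:
        out: set[str] = set()
        for m in self.sets.values():
            out |= m
        return frozenset(out)

    def flatten(self, restrict_to: Sequence[str] | None = None) -> dict[str, str]:
        """One label per protein: the lexicographically first set containing it.

        Overlapping standards (a protein annotated to several sets) are made into
        a partition deterministically; the rule is documented rather than hidden.
        """
        labels: dict[str, str] = {}
        keep = None if restrict_to is None else set(restrict_to)
        for name in sorted(self.sets):
            for pid in self.sets[name]:
                if keep is not None and pid not in keep:
                    continue
                labels.setdefault(pid, name)
        return labels


@dataclass
class Partition:
    """Hard clustering: protein id -> opaque cluster label."""

    assignment: dict[str, object] = field(default_factory=dict)

    @property
    def ids(self) -> list[str]:
        return list(self.assignment)

    def labels_for(self, ids: Sequence[str]) -> list[object]:
        return [self.assignment[i] for i in ids]

    @classmethod
    def from_arrays(cls, ids: Sequence[str], labels: Sequence[object]) -> "Partition":
        if len(ids) != len(labels):
            raise ValueError("ids and labels must have equal length")
        return cls(dict(zip(ids, labels)))


def read_modality_table(
    path: str | Path,
    id_column: str | None = None,
    modality_name: str | None = None,
    normalize: bool = False,
) -> ModalityMatrix:
    """Read a TSV feature table into a :class:`ModalityMatrix`.

    ``id_column`` defaults to the first column. All remaining columns must be
    numeric; duplicate ids are an error naming the offender.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such modality table: {path}")
    df = pd.read_csv(path, sep="\t", dtype={0: str} if id_column is None else None)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need an id column plus at least one feature column")
    if id_column is None:
        id_column = df.columns[0]
    if id_column not in df.columns:
        raise ValueError(f"{path}: id column {id_column!r} not found")
    ids = df[id_column].astype(str).tolist()
    if normalize:
        ids = [_normalize_id(i) for i in ids]
    feat = df.drop(columns=[id_column])
    try:
        values = feat.to_numpy(dtype=float)
    except (TypeError, ValueError):
        for col in feat.columns:
            coerced = pd.to_numeric(feat[col], errors="coerce")
            if coerced.isna().any() and not feat[col].isna().any():
                row = int(coerced.isna().idxmax())
                raise ValueError(
                    f"{path}: non-numeric cell in column {col!r}, row id {ids[row]!r}"
                )
        raise
    counts = pd.Series(ids).value_counts()
    dups = counts[counts > 1]
    if len(dups):
        raise ValueError(f"{path}: duplicate identifier {dups.index[0]!r}")
    name = modality_name if modality_name is not None else path.stem
    return ModalityMatrix(ids, values, name)


def write_modality_table(mm: ModalityMatrix, path: str | Path, id_column: str = "id") -> None:
    df = pd.DataFrame(mm.values, columns=[f"f{i}" for i in range(mm.d)])
    df.insert(0, id_column, mm.ids)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def intersect_modalities(a: ModalityMatrix, b: ModalityMatrix) -> PairedDataset:
    """Align two modalities on the sorted intersection of their id sets.

    Proteins absent from either modality are dropped (the count is logged).
    Output order is lexicographic so results do not depend on file ordering.
    """
    shared = sorted(set(a.ids) & set(b.ids))
    if not shared:
        raise ValueError(
            f"modalities {a.modality_name!r} and {b.modality_name!r} share no identifiers"
        )
    dropped_a = a.n - len(shared)
    dropped_b = b.n - len(shared)
    if dropped_a or dropped_b:
        logger.info(
            "intersect_modalities: kept %d shared proteins (dropped %d from %s, %d from %s)",
            len(shared), dropped_a, a.modality_name, dropped_b, b.modality_name,
        )
    return PairedDataset(shared, a.reindex(shared), b.reindex(shared))


def read_gmt(path: str | Path, normalize: bool = False) -> GeneSetCollection:
    """Read a GMT gene-set file (name, description, members...; tab-separated)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such GMT file: {path}")
    sets: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: malformed GMT line (need name, description, >=1 member)"
                )
            name, _desc, *members = fields
            members = [m for m in members if m]
            if normalize:
                members = [_normalize_id(m) for m in members]
            if not members:
                raise ValueError(f"{path}:{lineno}: set {name!r} has no members")
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = frozenset(members)
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(collection.sets):
            members = sorted(collection.sets[name])
            fh.write("\t".join([name, "na", *members]) + "\n")


def read_edge_list(path: str | Path) -> list[tuple[str, str, float]]:
    """Read a source/target[/weight] TSV edge list; weight defaults to 1."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such edge list: {path}")
    edges: list[tuple[str, str, float]] = []
    with open(path) as fh:
        first = True
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: need at least source and target")
            if first:
                first = False
                # tolerate an optional header row
                if fields[0].lower() in {"source", "src", "from"}:
                    continue
            w = float(fields[2]) if len(fields) > 2 and fields[2] else 1.0
            edges.append((fields[0], fields[1], w))
    if not edges:
        raise ValueError(f"{path}: empty edge list")
    return edges
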