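"""Readers and writers for landmark data, trees, partitions and trait tables.

On-disk conventions
-------------------
* Landmarks: wide CSV, one row per specimen — ``specimen_id,x1,y1,z1,x2,...``
  (canonical format); TPS records (``LM3=``/``LM=`` + ``ID=``) are supported
  for interoperability.
* Trees: Newick with branch lengths on every edge (the root edge may be
  absent or lengthless).
* Module partitions: CSV with 1-based ``landmark_index,module_name`` rows
  covering ``1..L`` exactly once.
* Trait tables: CSV with a ``species`` column followed by the category
  columns (resource-use percentages, or 30 foraging-behaviour scores).

Landmark indices in files are 1-based, matching anatomical-table
convention; all internal arrays are 0-based.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd


class FormatError(ValueError):
    """A file violates its declared on-disk format."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class LandmarkConfiguration:
    """A single specimen's ordered 3D landmark configuration."""

    specimen_id: str
    coords: np.ndarray                      # (L, 3), length units
    landmark_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise FormatError(
                f"specimen {self.specimen_id!r}: coordinates must be (L, 3), "
                f"got {self.coords.shape}"
            )
        if self.coords.shape[0] < 3:
            raise FormatError(
                f"specimen {self.specimen_id!r}: need at least 3 landmarks, "
                f"got {self.coords.shape[0]}"
            )
        if not np.all(np.isfinite(self.coords)):
            raise FormatError(f"specimen {self.specimen_id!r}: non-finite coordinate")
        if self.landmark_labels is not None and len(self.landmark_labels) != len(self.coords):
            raise FormatError(f"specimen {self.specimen_id!r}: label/landmark count mismatch")

    @property
    def n_landmarks(self) -> int:
        return self.coords.shape[0]


@dataclass(frozen=True)
class ModulePartition:
    """Assignment of every landmark (1-based index) to a named module."""

    mapping: dict[int, str]                 # landmark_index (1-based) -> module

    def __post_init__(self) -> None:
        if not self.mapping:
            raise FormatError("empty module partition")
        n = max(self.mapping)
        missing = sorted(set(range(1, n + 1)) - set(self.mapping))
        if missing:
            raise FormatError(f"partition has gaps; missing landmark indices: {missing}")

    @property
    def n_landmarks(self) -> int:
        return max(self.mapping)

    @property
    def module_names(self) -> tuple[str, ...]:
        """Module names in order of first appearance."""
        seen: dict[str, None] = {}
        for i in sorted(self.mapping):
            seen.setdefault(self.mapping[i], None)
        return tuple(seen)

    def indices(self, module: str) -> np.ndarray:
        """0-based landmark indices belonging to ``module``, ascending."""
        if module not in self.module_names:
            raise KeyError(
                f"unknown module {module!r}; valid modules: {list(self.module_names)}"
            )
        return np.array(sorted(i - 1 for i, m in self.mapping.items() if m == module))

    def validate_landmark_count(self, n_landmarks: int) -> None:
        if self.n_landmarks != n_landmarks:
            raise FormatError(
                f"partition covers {self.n_landmarks} landmarks but dataset has {n_landmarks}"
            )


# ---------------------------------------------------------------------------
# landmarks
# ---------------------------------------------------------------------------

def _parse_wide_csv(lines: list[str], path: str) -> list[LandmarkConfiguration]:
    configs: list[LandmarkConfiguration] = []
    n_coords: int | None = None
    rows = [ln for ln in lines if ln.strip()]
    if not rows:
        raise FormatError(f"{path}: empty landmark file")
    start = 0
    first = rows[0].split(",")
    # header row detected by a non-numeric second field
    if len(first) > 1:
        try:
            float(first[1])
        except ValueError:
            start = 1
    for rowno, line in enumerate(rows[start:], start=start + 1):
        fields = [f.strip() for f in line.split(",")]
        specimen_id, values = fields[0], fields[1:]
        if len(values) % 3 != 0:
            raise FormatError(
                f"{path}, row {rowno} ({specimen_id!r}): {len(values)} coordinates "
                "is not a multiple of 3"
            )
        if n_coords is None:
            n_coords = len(values)
        elif len(values) != n_coords:
            raise FormatError(
                f"{path}, row {rowno} ({specimen_id!r}): expected {n_coords} "
                f"coordinates, got {len(values)} (ragged rows)"
            )
        try:
            flat = np.array([float(v) for v in values])
        except ValueError as exc:
            raise FormatError(f"{path}, row {rowno} ({specimen_id!r}): {exc}") from None
        configs.append(LandmarkConfiguration(specimen_id, flat.reshape(-1, 3)))
    return configs


def _parse_tps(lines: list[str], path: str) -> list[LandmarkConfiguration]:
    configs: list[LandmarkConfiguration] = []
    coords: list[list[float]] = []
    expected: int | None = None
    specimen_id: str | None = None

    def flush(lineno: int) -> None:
        nonlocal coords, expected, specimen_id
        if expected is None:
            return
        if len(coords) != expected:
            raise FormatError(
                f"{path}, near line {lineno}: LM={expected} but {len(coords)} rows read"
            )
        sid = specimen_id if specimen_id is not None else f"specimen_{len(configs) + 1}"
        configs.append(LandmarkConfiguration(sid, np.array(coords)))
        coords, expected, specimen_id = [], None, None

    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        upper = line.upper()
        if upper.startswith(("LM3=", "LM=")):
            flush(lineno)
            try:
                expected = int(line.split("=", 1)[1])
            except ValueError:
                raise FormatError(f"{path}, line {lineno}: bad LM record {line!r}") from None
        elif upper.startswith("ID="):
            specimen_id = line.split("=", 1)[1].strip()
        elif "=" in line and not line[0].isdigit() and not line[0] in "+-.":
            continue                         # other TPS keywords (IMAGE=, SCALE=...)
        else:
            if expected is None:
                raise FormatError(f"{path}, line {lineno}: coordinates before any LM record")
            parts = line.split()
            if len(parts) != 3:
                raise FormatError(
                    f"{path}, line {lineno}: expected 3 coordinates, got {len(parts)}"
                )
            try:
                coords.append([float(p) for p in parts])
            except ValueError as exc:
                raise FormatError(f"{path}, line {lineno}: {exc}") from None
    flush(len(lines))
    if not configs:
        raise FormatError(f"{path}: no TPS records found")
    return configs


def read_landmarks(path: str | Path, format: str = "wide-csv") -> list[LandmarkConfiguration]:
    """Read an ordered collection of landmark configurations.

    All configurations must share the same landmark count; specimen order is
    preserved as read.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if format == "wide-csv":
        configs = _parse_wide_csv(lines, str(path))
    elif format == "tps":
        configs = _parse_tps(lines, str(path))
    else:
        raise ValueError(f"unknown landmark format {format!r}")
    counts = {c.n_landmarks for c in configs}
    if len(counts) > 1:
        raise FormatError(f"{path}: landmark counts differ across specimens: {sorted(counts)}")
    return configs


def write_landmarks(
    configs: Sequence[LandmarkConfiguration],
    path: str | Path,
    format: str = "wide-csv",
    decimals: int = 6,
) -> None:
    """Write configurations to wide CSV (canonical) or TPS, at fixed precision."""
    path = Path(path)
    fmt = f"%.{decimals}f"
    lines: list[str] = []
    if format == "wide-csv":
        n = configs[0].n_landmarks
        header = ["specimen_id"]
        for i in range(1, n + 1):
            header += [f"x{i}", f"y{i}", f"z{i}"]
        lines.append(",".join(header))
        for c in configs:
            lines.append(",".join([c.specimen_id] + [fmt % v for v in c.coords.ravel()]))
    elif format == "tps":
        for c in configs:
            lines.append(f"LM3={c.n_landmarks}")
            for p in c.coords:
                lines.append(" ".join(fmt % v for v in p))
            lines.append(f"ID={c.specimen_id}")
    else:
        raise ValueError(f"unknown landmark format {format!r}")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

def read_tree(path: str | Path) -> dendropy.Tree:
    """Read a rooted Newick tree, enforcing unique tips and branch lengths.

    Branch lengths are mandatory on every edge except the root edge
    (phylogenetic covariance is undefined without them); zero-length
    branches are allowed with a warning. Internal node labels are ignored.
    """
    path = Path(path)
    try:
        tree = dendropy.Tree.get(
            path=str(path),
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse-error types
        raise FormatError(f"{path}: could not parse Newick tree: {exc}") from None
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    dupes = sorted({lb for lb in labels if labels.count(lb) > 1})
    if dupes:
        raise FormatError(f"{path}: duplicate tip labels: {dupes}")
    zero = []
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue                         # root edge may be lengthless
        if edge.length is None:
            head = edge.head_node
            name = head.taxon.label if head.taxon else "<internal node>"
            raise FormatError(
                f"{path}: missing branch length on edge above {name!r}"
            )
        if edge.length < 0:
            raise FormatError(f"{path}: negative branch length {edge.length}")
        if edge.length == 0:
            zero.append(edge)
    if zero:
        warnings.warn(f"{path}: {len(zero)} zero-length branch(es)", stacklevel=2)
    return tree


def tip_labels(tree: dendropy.Tree) -> list[str]:
    """Tip labels in the tree's leaf-iteration order."""
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


# ---------------------------------------------------------------------------
# partitions and trait tables
# ---------------------------------------------------------------------------

def read_partition(path: str | Path, expected_n_landmarks: int | None = None) -> ModulePartition:
    """Read a 1-based ``landmark_index,module_name`` CSV into a partition."""
    path = Path(path)
    mapping: dict[int, str] = {}
    rows = [ln for ln in path.read_text().splitlines() if ln.strip()]
    start = 0
    if rows and not rows[0].split(",")[0].strip().isdigit():
        start = 1                            # header row
    for rowno, line in enumerate(rows[start:], start=start + 1):
        fields = [f.strip() for f in line.split(",")]
        if len(fields) < 2:
            raise FormatError(f"{path}, row {rowno}: expected landmark_index,module_name")
        try:
            idx = int(fields[0])
        except ValueError:
            raise FormatError(f"{path}, row {rowno}: bad landmark index {fields[0]!r}") from None
        if idx in mapping:
            raise FormatError(f"{path}, row {rowno}: duplicate landmark index {idx}")
        if idx < 1:
            raise FormatError(f"{path}, row {rowno}: landmark indices are 1-based, got {idx}")
        mapping[idx] = fields[1]
    part = ModulePartition(mapping)
    if expected_n_landmarks is not None:
        part.validate_landmark_count(expected_n_landmarks)
    return part


def write_partition(partition: ModulePartition, path: str | Path) -> None:
    lines = ["landmark_index,module_name"]
    lines += [f"{i},{partition.mapping[i]}" for i in sorted(partition.mapping)]
    Path(path).write_text("\n".join(lines) + "\n")


def _read_species_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    first = df.columns[0]
    df[first] = df[first].astype(str).str.strip()
    df = df.set_index(first)
    df.index.name = "species"
    return df


def read_resource_table(path: str | Path) -> pd.DataFrame:
    """Read per-species resource-use percentages over the raw food categories.

    Rows must sum to 100 (+/- 0.5) with no negative scores. Category-name
    validity is checked by :func:`aviamorph.trophic.merge_resource_categories`.
    """
    df = _read_species_table(path)
    if (df.values < 0).any():
        bad = df.index[(df.values < 0).any(axis=1)].tolist()
        raise FormatError(f"{path}: negative resource scores for {bad}")
    sums = df.sum(axis=1)
    bad = sums[(sums - 100).abs() > 0.5]
    if len(bad):
        raise FormatError(
            f"{path}: resource scores must sum to 100 +/- 0.5; offenders: "
            f"{dict(bad.round(3))}"
        )
    return df


def read_foraging_table(path: str | Path) -> pd.DataFrame:
    """Read per-species scores over the 30 foraging-behaviour categories."""
    from aviamorph.trophic import FORAGING_BEHAVIOURS

    df = _read_species_table(path)
    unknown = sorted(set(df.columns) - set(FORAGING_BEHAVIOURS))
    if unknown:
        raise FormatError(f"{path}: unknown foraging behaviours: {unknown}")
    if (df.values < 0).any():
        raise FormatError(f"{path}: negative foraging scores")
    sums = df.sum(axis=1)
    bad = sums[(sums - 10).abs() > 0.5]
    if len(bad):
        raise FormatError(
            f"{path}: foraging scores must sum to 10 +/- 0.5; offenders: {dict(bad.round(3))}"
        )
    return df


def check_taxa_consistency(reference: Sequence[str], **others: Sequence[str]) -> None:
    """Hard-error if any input's taxon set differs from ``reference``.

    Labels are compared by exact equality after whitespace trimming; every
    orphan (either direction) is listed. Silent intersection would hide
    data loss.
    """
    ref = {str(t).strip() for t in reference}
    problems = []
    for name, labels in others.items():
        lab = {str(t).strip() for t in labels}
        extra, missing = sorted(lab - ref), sorted(ref - lab)
        if extra or missing:
            problems.append(f"{name}: not in reference {extra}; absent from {name} {missing}")
    if problems:
        raise ValueError("taxon mismatch across inputs:\n  " + "\n  ".join(problems))
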