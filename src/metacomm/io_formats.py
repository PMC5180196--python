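"""Readers, writers, and the shared labeled-matrix contracts.

All tabular files are UTF-8 TSV ("\\t" separator, "." decimal). Trees are
newick with branch lengths. Distance matrices are written as full square
matrices with an id header row and an id first column.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "AlignmentError",
    "OtuTable",
    "SampleMetadata",
    "PhyloTree",
    "DistanceMatrix",
    "DEFAULT_MONTHS",
    "DEFAULT_ENV_VARIABLES",
    "read_otu_table",
    "write_otu_table",
    "read_sample_metadata",
    "write_sample_metadata",
    "read_tree",
    "read_distance_matrix",
    "write_distance_matrix",
    "read_results_table",
    "write_results_table",
    "check_sample_alignment",
]

DEFAULT_MONTHS = (
    "April",
    "May",
    "June",
    "July",
    "August",
    "September",
    "October",
)

DEFAULT_ENV_VARIABLES = (
    "salinity",
    "temperature",
    "chl_a",
    "nh4",
    "no3",
    "po4",
    "sio4",
)

_SYM_TOL = 1e-12


class FormatError(ValueError):
    """Malformed or contract-violating input file."""


class AlignmentError(ValueError):
    """Sample/taxon identifier sets disagree between inputs."""


def _find_duplicates(ids: Sequence[str]) -> list[str]:
    seen: set[str] = set()
    dups: list[str] = []
    for x in ids:
        if x in seen and x not in dups:
            dups.append(x)
        seen.add(x)
    return dups


@dataclasses.dataclass
class OtuTable:
    """Integer count matrix (samples x OTUs) with per-OTU taxonomy labels.

    Parameters
    ----------
    sample_ids : ordered unique sample identifiers (rows of ``counts``).
    otu_ids : ordered unique OTU identifiers (columns of ``counts``).
    counts : non-negative integer matrix, shape ``(n_samples, n_otus)``.
    taxonomy : mapping OTU id -> free-text taxonomy label. Every OTU must
        have an entry; "Unclassified" marks OTUs without an assignment.
    """

    sample_ids: list[str]
    otu_ids: list[str]
    counts: np.ndarray
    taxonomy: dict[str, str]

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.otu_ids = [str(o) for o in self.otu_ids]
        dups = _find_duplicates(self.sample_ids)
        if dups:
            raise FormatError(f"duplicate sample ids: {dups}")
        dups = _find_duplicates(self.otu_ids)
        if dups:
            raise FormatError(f"duplicate OTU ids: {dups}")
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape != (len(self.sample_ids), len(self.otu_ids)):
            raise FormatError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.otu_ids)} OTUs"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            rounded = np.rint(counts)
            if not np.all(np.isfinite(counts)) or np.any(rounded != counts):
                bad = np.argwhere(~np.isfinite(counts) | (np.rint(counts) != counts))
                i, j = bad[0]
                raise FormatError(
                    f"non-integer count {counts[i, j]!r} at sample "
                    f"{self.sample_ids[i]!r}, OTU {self.otu_ids[j]!r}"
                )
            counts = rounded.astype(np.int64)
        if np.any(counts < 0):
            bad = np.argwhere(counts < 0)
            i, j = bad[0]
            raise FormatError(
                f"negative count {counts[i, j]} at sample "
                f"{self.sample_ids[i]!r}, OTU {self.otu_ids[j]!r}"
            )
        self.counts = counts.astype(np.int64)
        missing_tax = [o for o in self.otu_ids if o not in self.taxonomy]
        if missing_tax:
            raise FormatError(f"OTUs without taxonomy entry: {missing_tax[:10]}")
        self.taxonomy = {o: str(self.taxonomy[o]) for o in self.otu_ids}

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    def sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def otu_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def sample_index(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.sample_ids)}

    def select_samples(self, ids: Sequence[str]) -> "OtuTable":
        idx = self.sample_index()
        missing = [s for s in ids if s not in idx]
        if missing:
            raise AlignmentError(f"samples not in table: {missing}")
        rows = [idx[s] for s in ids]
        return OtuTable(list(ids), list(self.otu_ids), self.counts[rows, :], dict(self.taxonomy))

    def select_otus(self, ids: Sequence[str]) -> "OtuTable":
        idx = {o: j for j, o in enumerate(self.otu_ids)}
        missing = [o for o in ids if o not in idx]
        if missing:
            raise AlignmentError(f"OTUs not in table: {missing}")
        cols = [idx[o] for o in ids]
        return OtuTable(
            list(self.sample_ids),
            list(ids),
            self.counts[:, cols],
            {o: self.taxonomy[o] for o in ids},
        )

    def drop_empty_otus(self) -> "OtuTable":
        keep = [o for o, tot in zip(self.otu_ids, self.otu_totals()) if tot > 0]
        return self.select_otus(keep)

    def drop_empty_samples(self) -> "OtuTable":
        keep = [s for s, tot in zip(self.sample_ids, self.sample_totals()) if tot > 0]
        return self.select_samples(keep)

    def to_frame(self) -> pd.DataFrame:
        """OTUs as rows, samples as columns, taxonomy as last column."""
        df = pd.DataFrame(self.counts.T, index=self.otu_ids, columns=self.sample_ids)
        df.index.name = "otu_id"
        df["taxonomy"] = [self.taxonomy[o] for o in self.otu_ids]
        return df


@dataclasses.dataclass
class SampleMetadata:
    """Per-sample month, coordinates and environmental variables.

    Wraps a DataFrame indexed by sample id with columns ``month``,
    ``latitude``, ``longitude`` and one numeric column per environmental
    variable. The environmental variable set is identical across samples.
    """

    data: pd.DataFrame
    env_variables: tuple[str, ...]
    months: tuple[str, ...] = DEFAULT_MONTHS

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].tolist()
            raise FormatError(f"duplicate sample ids in metadata: {dups}")
        required = ["month", "latitude", "longitude", *self.env_variables]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise FormatError(f"metadata missing columns: {missing}")
        bad_months = sorted(set(df["month"]) - set(self.months))
        if bad_months:
            raise FormatError(
                f"months {bad_months} not in configured season set {list(self.months)}"
            )
        if df[["latitude", "longitude"]].isna().any().any() or df["month"].isna().any():
            raise FormatError("missing month or coordinates")
        for col in ("latitude", "longitude", *self.env_variables):
            if df[col].isna().any():
                rows = df.index[df[col].isna()].tolist()
                raise FormatError(f"missing values in column {col!r} at rows {rows}")
        self.env_variables = tuple(self.env_variables)
        self.data = df

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.index]

    def subset(self, ids: Sequence[str]) -> "SampleMetadata":
        missing = [s for s in ids if s not in self.data.index]
        if missing:
            raise AlignmentError(f"samples not in metadata: {missing}")
        return SampleMetadata(self.data.loc[list(ids)].copy(), self.env_variables, self.months)

    def samples_in_month(self, month: str) -> list[str]:
        return [str(s) for s in self.data.index[self.data["month"] == month]]

    def env_matrix(self, variables: Sequence[str] | None = None) -> np.ndarray:
        variables = list(variables) if variables is not None else list(self.env_variables)
        missing = [v for v in variables if v not in self.data.columns]
        if missing:
            raise FormatError(f"environmental variables not present: {missing}")
        return self.data[variables].to_numpy(dtype=float)

    def coordinates(self) -> np.ndarray:
        return self.data[["latitude", "longitude"]].to_numpy(dtype=float)

    def month_of(self) -> dict[str, str]:
        return {str(s): str(m) for s, m in self.data["month"].items()}


class PhyloTree:
    """Rooted tree over tip labels, with non-negative branch lengths."""

    def __init__(self, tree: dendropy.Tree, default_branch_length: float | None = None):
        self.tree = tree
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if any(lbl is None for lbl in labels):
            raise FormatError("tree has unlabeled tips")
        dups = _find_duplicates(labels)
        if dups:
            raise FormatError(f"duplicate tip labels in tree: {dups}")
        self.tip_labels: list[str] = labels
        for edge in tree.preorder_edge_iter():
            if edge.head_node is tree.seed_node:
                if edge.length is None:
                    edge.length = 0.0
                continue
            if edge.length is None:
                if default_branch_length is None:
                    raise FormatError(
                        "tree has edges without branch lengths "
                        "(pass default_branch_length to impute)"
                    )
                edge.length = float(default_branch_length)
            if edge.length < 0:
                raise FormatError(f"negative branch length {edge.length}")

    @classmethod
    def from_newick(cls, newick: str, default_branch_length: float | None = None) -> "PhyloTree":
        try:
            tree = dendropy.Tree.get(
                data=newick, schema="newick", preserve_underscores=True
            )
        except dendropy.utility.error.DataParseError as exc:
            msg = str(exc)
            if "Duplicate taxon" in msg:
                raise FormatError(f"duplicate tip labels in newick: {msg}") from exc
            raise FormatError(f"invalid newick: {msg}") from exc
        return cls(tree, default_branch_length=default_branch_length)

    def to_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)


@dataclasses.dataclass
class DistanceMatrix:
    """Symmetric, zero-diagonal pairwise distances over a labeled index."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.ids = [str(s) for s in self.ids]
        dups = _find_duplicates(self.ids)
        if dups:
            raise FormatError(f"duplicate ids in distance matrix: {dups}")
        values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if values.shape != (n, n):
            raise FormatError(f"matrix shape {values.shape} does not match {n} ids")
        if not np.all(np.isfinite(values)):
            raise FormatError("distance matrix contains non-finite values")
        if np.any(np.abs(values - values.T) > _SYM_TOL):
            raise FormatError(f"matrix not symmetric within {_SYM_TOL}")
        values = (values + values.T) / 2.0
        if np.any(np.diagonal(values) != 0.0):
            raise FormatError("matrix diagonal not exactly zero")
        if np.any(values < 0):
            raise FormatError("negative distances")
        self.values = values

    @property
    def n(self) -> int:
        return len(self.ids)

    def index(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.ids)}

    def subset(self, ids: Sequence[str]) -> "DistanceMatrix":
        idx = self.index()
        missing = [s for s in ids if s not in idx]
        if missing:
            raise AlignmentError(f"ids not in distance matrix: {missing}")
        rows = [idx[s] for s in ids]
        return DistanceMatrix(list(ids), self.values[np.ix_(rows, rows)])

    def condensed(self) -> np.ndarray:
        """Strict lower-triangle entries, row-major."""
        i, j = np.tril_indices(self.n, k=-1)
        return self.values[i, j]


# ---------------------------------------------------------------------------
# readers / writers


def _check_header_duplicates(path: str | Path) -> None:
    # pandas silently renames duplicate header fields, so inspect them raw
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    dups = _find_duplicates(header[1:])
    if dups:
        raise FormatError(f"duplicate ids in header of {path}: {dups}")


def read_otu_table(
    path: str | Path,
    taxonomy_column: str | None = "taxonomy",
    samples_as: str = "columns",
) -> OtuTable:
    """Read a TSV OTU count table.

    With ``samples_as="columns"`` (default) rows are OTUs, columns are
    samples, and ``taxonomy_column`` names the per-OTU taxonomy column.
    With ``samples_as="rows"`` rows are samples and no taxonomy column is
    read (all OTUs become "Unclassified").
    """
    if samples_as not in ("columns", "rows"):
        raise ValueError("samples_as must be 'columns' or 'rows'")
    _check_header_duplicates(path)
    df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str)
    df.index = df.index.astype(str)
    if len(df.index) == 0:
        raise FormatError(f"no samples: table {path} has no data rows")
    if samples_as == "columns":
        if taxonomy_column is None:
            taxonomy = {str(o): "Unclassified" for o in df.index}
        else:
            if taxonomy_column not in df.columns:
                raise FormatError(
                    f"taxonomy column {taxonomy_column!r} not found in {path}"
                )
            taxonomy = {str(o): str(t) for o, t in df[taxonomy_column].items()}
            df = df.drop(columns=[taxonomy_column])
        otu_ids = [str(o) for o in df.index]
        sample_ids = [str(s) for s in df.columns]
        raw = df
    else:
        if taxonomy_column is not None and taxonomy_column in df.columns:
            raise FormatError(
                "taxonomy column requires samples-as-columns orientation"
            )
        sample_ids = [str(s) for s in df.index]
        otu_ids = [str(o) for o in df.columns]
        taxonomy = {o: "Unclassified" for o in otu_ids}
        raw = df
    if len(sample_ids) == 0:
        raise FormatError(f"no samples in {path}")
    if len(otu_ids) == 0:
        raise FormatError(f"no OTUs in {path}")
    counts = np.empty((len(raw.index), len(raw.columns)), dtype=np.int64)
    for j, col in enumerate(raw.columns):
        for i, (row_id, cell) in enumerate(raw[col].items()):
            try:
                val = float(cell)
            except (TypeError, ValueError):
                raise FormatError(
                    f"unparseable count {cell!r} at row {row_id!r}, column {col!r}"
                ) from None
            if not math.isfinite(val) or val != int(val):
                raise FormatError(
                    f"non-integer count {cell!r} at row {row_id!r}, column {col!r}"
                )
            if val < 0:
                raise FormatError(
                    f"negative count {cell!r} at row {row_id!r}, column {col!r}"
                )
            counts[i, j] = int(val)
    if samples_as == "columns":
        counts = counts.T  # -> samples x OTUs
    return OtuTable(sample_ids, otu_ids, counts, taxonomy)


def write_otu_table(t: OtuTable, path: str | Path) -> None:
    t.to_frame().to_csv(path, sep="\t")


def read_sample_metadata(
    path: str | Path,
    env_variables: Sequence[str] = DEFAULT_ENV_VARIABLES,
    months: Sequence[str] = DEFAULT_MONTHS,
) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str)
    df.index = df.index.astype(str)
    required = ["month", "latitude", "longitude", *env_variables]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"metadata file {path} missing columns: {missing}")
    out = pd.DataFrame(index=df.index)
    out["month"] = df["month"].astype(str)
    for col in ("latitude", "longitude", *env_variables):
        vals = []
        for row_id, cell in df[col].items():
            try:
                vals.append(float(cell))
            except (TypeError, ValueError):
                raise FormatError(
                    f"unparseable value {cell!r} at row {row_id!r}, column {col!r}"
                ) from None
        out[col] = vals
    return SampleMetadata(out, tuple(env_variables), tuple(months))


def write_sample_metadata(md: SampleMetadata, path: str | Path) -> None:
    df = md.data.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def read_tree(path: str | Path, default_branch_length: float | None = None) -> PhyloTree:
    with open(path) as fh:
        newick = fh.read()
    return PhyloTree.from_newick(newick, default_branch_length=default_branch_length)


def write_tree(tree: PhyloTree, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")


def write_distance_matrix(m: DistanceMatrix, path: str | Path) -> None:
    df = pd.DataFrame(m.values, index=m.ids, columns=m.ids)
    df.index.name = "id"
    df.to_csv(path, sep="\t")


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", header=0, index_col=0)
    if list(df.index.astype(str)) != list(df.columns.astype(str)):
        raise FormatError("distance matrix row ids do not match column ids")
    return DistanceMatrix([str(s) for s in df.index], df.to_numpy(dtype=float))


def write_results_table(
    rows: Sequence[Mapping[str, object]],
    path: str | Path,
    columns: Sequence[str] | None = None,
) -> None:
    """Write a list of record dicts as a TSV; empty rows give a header-only file."""
    if rows:
        df = pd.DataFrame(list(rows))
        if columns is not None:
            df = df[list(columns)]
    else:
        df = pd.DataFrame(columns=list(columns) if columns is not None else [])
    df.to_csv(path, sep="\t", index=False)


def read_results_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=0)


def check_sample_alignment(
    otu: OtuTable, md: SampleMetadata, tree: PhyloTree | None = None
) -> list[str]:
    """Verify the sample-id join across inputs; return the shared order.

    Raises AlignmentError reporting the full symmetric difference when the
    OTU-table and metadata sample sets disagree, and the missing tips when a
    tree is supplied that does not cover all OTU ids.
    """
    otu_set = set(otu.sample_ids)
    md_set = set(md.sample_ids)
    if otu_set != md_set:
        only_otu = sorted(otu_set - md_set)
        only_md = sorted(md_set - otu_set)
        raise AlignmentError(
            f"sample id mismatch: only in OTU table {only_otu}; "
            f"only in metadata {only_md}"
        )
    if tree is not None:
        missing = sorted(set(otu.otu_ids) - set(tree.tip_labels))
        if missing:
            raise AlignmentError(f"OTUs absent from tree: {missing}")
    return list(otu.sample_ids)
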