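"""Data model and file I/O for amplicon count tables, metadata, trees and alignments.

The pipeline currency is a :class:`CountTable` (OTUs as rows, samples as
columns, non-negative integer counts) plus a :class:`SampleMetadata` table
annotating each sample with its subject, study and before/after timepoint.
Distance matrices are :class:`skbio.DistanceMatrix` objects; trees are
:class:`skbio.TreeNode`. All text formats are UTF-8, tab-separated where
tabular, with "." as the decimal point.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

__all__ = [
    "ParseError",
    "ValidationError",
    "CountTable",
    "SampleMetadata",
    "read_count_table",
    "write_count_table",
    "read_metadata",
    "write_metadata",
    "read_newick",
    "write_newick",
    "read_fasta_alignment",
    "write_fasta_alignment",
    "read_distance_matrix",
    "write_distance_matrix",
]

TIMEPOINTS = ("before", "after")


class ParseError(ValueError):
    """A file could not be parsed into the expected structure."""


class ValidationError(ValueError):
    """Parsed data violates a type invariant."""


@dataclass(frozen=True)
class CountTable:
    """OTU-by-sample matrix of non-negative integer read counts.

    Rows are OTUs/ESVs, columns are samples. Orientation is explicit and
    never guessed from the header.
    """

    otu_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    counts: np.ndarray  # shape (n_otus, n_samples), integer dtype

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValidationError("counts must be a 2-D matrix")
        if counts.shape != (len(self.otu_ids), len(self.sample_ids)):
            raise ValidationError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.otu_ids)} OTUs x {len(self.sample_ids)} samples"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            if np.issubdtype(counts.dtype, np.floating) and np.all(
                counts == np.floor(counts)
            ):
                counts = counts.astype(np.int64)
            else:
                raise ValidationError("counts must be integers")
        if counts.size and counts.min() < 0:
            i, j = np.argwhere(counts < 0)[0]
            raise ValidationError(
                f"negative count at OTU {self.otu_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )
        for name, ids in (("otu", self.otu_ids), ("sample", self.sample_ids)):
            if len(set(ids)) != len(ids):
                dup = next(x for x in ids if list(ids).count(x) > 1)
                raise ValidationError(f"duplicate {name} ID {dup!r}")
        object.__setattr__(self, "otu_ids", tuple(str(x) for x in self.otu_ids))
        object.__setattr__(self, "sample_ids", tuple(str(x) for x in self.sample_ids))
        object.__setattr__(self, "counts", np.ascontiguousarray(counts, dtype=np.int64))

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.otu_ids), columns=list(self.sample_ids)
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CountTable":
        return cls(
            tuple(map(str, df.index)), tuple(map(str, df.columns)), df.to_numpy()
        )

    def select_samples(self, sample_ids) -> "CountTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return CountTable(self.otu_ids, tuple(sample_ids), self.counts[:, idx])

    def select_otus(self, otu_ids) -> "CountTable":
        pos = {o: i for i, o in enumerate(self.otu_ids)}
        idx = [pos[o] for o in otu_ids]
        return CountTable(tuple(otu_ids), self.sample_ids, self.counts[idx, :])


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample annotations: subject, study, before/after timepoint, order.

    ``order`` is the collection sequence within a subject and drives the
    earliest-before / latest-after pairing used by the alpha-diversity
    response test.
    """

    table: pd.DataFrame = field(repr=False)

    REQUIRED = ("sample_id", "subject_id", "study_id", "timepoint", "order")

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValidationError(f"metadata missing columns: {missing}")
        df = df.loc[:, list(self.REQUIRED)].copy()
        df["sample_id"] = df["sample_id"].astype(str)
        df["subject_id"] = df["subject_id"].astype(str)
        df["study_id"] = df["study_id"].astype(str)
        tp = df["timepoint"].astype(str).str.lower().str.strip()
        bad = sorted(set(tp) - set(TIMEPOINTS))
        if bad:
            raise ValidationError(
                f"unknown timepoint token(s) {bad}; accepted tokens are "
                f"{list(TIMEPOINTS)} (case-insensitive)"
            )
        df["timepoint"] = tp
        df["order"] = pd.to_numeric(df["order"], errors="raise").astype(int)
        if (df["order"] < 0).any():
            sid = df.loc[df["order"] < 0, "sample_id"].iloc[0]
            raise ValidationError(f"negative order for sample {sid!r}")
        dups = df["sample_id"][df["sample_id"].duplicated()]
        if len(dups):
            raise ValidationError(f"duplicate sample_id {dups.iloc[0]!r}")
        grp = df.groupby(["subject_id", "timepoint"])["order"]
        for (subj, t), orders in grp:
            if orders.duplicated().any():
                raise ValidationError(
                    f"duplicate order value within subject {subj!r} "
                    f"timepoint {t!r}"
                )
        object.__setattr__(self, "table", df.reset_index(drop=True))

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(self.table["sample_id"])

    def subset(self, sample_ids) -> "SampleMetadata":
        df = self.table.set_index("sample_id").loc[list(sample_ids)].reset_index()
        return SampleMetadata(df)

    def timepoint_of(self) -> Mapping[str, str]:
        return dict(zip(self.table["sample_id"], self.table["timepoint"]))

    def paired_subjects(self) -> list[str]:
        """Subjects with at least one 'before' and one 'after' sample."""
        piv = self.table.groupby(["subject_id", "timepoint"]).size().unstack(
            fill_value=0
        )
        for t in TIMEPOINTS:
            if t not in piv:
                piv[t] = 0
        return sorted(piv.index[(piv["before"] > 0) & (piv["after"] > 0)])


# ---------------------------------------------------------------------------
# count tables


def read_count_table(path) -> CountTable:
    """Read a tab-separated OTU x sample count table.

    First column holds OTU IDs, the header row holds sample IDs, the body
    holds non-negative integers. Row and column order is preserved.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\r\n")
        if not header:
            raise ParseError(f"{path}: empty file")
        sample_ids = header.split("\t")[1:]
        otu_ids: list[str] = []
        rows: list[list[int]] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\r\n")
            if not line:
                continue
            cells = line.split("\t")
            if len(cells) != len(sample_ids) + 1:
                raise ParseError(
                    f"{path}:{lineno}: expected {len(sample_ids) + 1} columns, "
                    f"got {len(cells)}"
                )
            otu_ids.append(cells[0])
            row = []
            for j, cell in enumerate(cells[1:]):
                try:
                    v = int(cell)
                except ValueError:
                    raise ParseError(
                        f"{path}:{lineno}: non-integer count {cell!r} for OTU "
                        f"{cells[0]!r}, sample {sample_ids[j]!r}"
                    ) from None
                if v < 0:
                    raise ParseError(
                        f"{path}:{lineno}: negative count {v} for OTU "
                        f"{cells[0]!r}, sample {sample_ids[j]!r}"
                    )
                row.append(v)
            rows.append(row)
    if not rows:
        raise ParseError(f"{path}: no OTU rows")
    return CountTable(tuple(otu_ids), tuple(sample_ids), np.array(rows, dtype=np.int64))


def write_count_table(table: CountTable, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("otu_id\t" + "\t".join(table.sample_ids) + "\n")
        for otu, row in zip(table.otu_ids, table.counts):
            fh.write(otu + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# metadata


def read_metadata(path) -> SampleMetadata:
    """Read a tab-separated metadata table.

    Requires columns sample_id, subject_id, study_id, timepoint, order.
    Timepoint strings are mapped case-insensitively onto {before, after}.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: {exc}") from exc
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path) -> None:
    meta.table.to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# trees


def read_newick(path_or_str) -> TreeNode:
    """Read a Newick tree with branch lengths.

    Branch lengths are required on all edges except (optionally) the root;
    internal node labels are preserved but otherwise unused.
    """
    if isinstance(path_or_str, str) and path_or_str.lstrip().startswith("("):
        src = _io.StringIO(path_or_str)
    else:
        src = str(path_or_str)
    try:
        tree = TreeNode.read(src, format="newick")
    except Exception as exc:
        raise ParseError(f"invalid newick: {exc}") from exc
    for node in tree.traverse(include_self=False):
        if node.length is None:
            raise ValidationError(
                f"edge above node {node.name!r} has no branch length"
            )
        if not np.isfinite(node.length) or node.length < 0:
            raise ValidationError(
                f"edge above node {node.name!r} has invalid length {node.length}"
            )
    tips = [t.name for t in tree.tips()]
    if len(set(tips)) != len(tips):
        dup = next(x for x in tips if tips.count(x) > 1)
        raise ValidationError(f"duplicate tip label {dup!r}")
    return tree


def write_newick(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


# ---------------------------------------------------------------------------
# alignments


def read_fasta_alignment(path) -> dict[str, str]:
    """Read an aligned FASTA file into an ordered {label: sequence} mapping.

    All sequences must have equal length (gaps included); unequal lengths
    are a validation error, since downstream distances assume positional
    homology.
    """
    path = Path(path)
    seqs: dict[str, str] = {}
    label = None
    chunks: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip()
            if not line:
                continue
            if line.startswith(">"):
                if label is not None:
                    seqs[label] = "".join(chunks)
                label = line[1:].split()[0]
                if label in seqs:
                    raise ValidationError(f"{path}: duplicate label {label!r}")
                chunks = []
            else:
                if label is None:
                    raise ParseError(f"{path}: sequence data before first header")
                chunks.append(line.upper())
    if label is not None:
        seqs[label] = "".join(chunks)
    if not seqs:
        raise ParseError(f"{path}: no sequences")
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) > 1:
        detail = ", ".join(f"{k}={len(v)}" for k, v in list(seqs.items())[:4])
        raise ValidationError(
            f"{path}: aligned sequences must have equal length (got {detail}...)"
        )
    return seqs


def write_fasta_alignment(seqs: Mapping[str, str], path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for label, seq in seqs.items():
            fh.write(f">{label}\n{seq}\n")


# ---------------------------------------------------------------------------
# distance matrices


def read_distance_matrix(path) -> DistanceMatrix:
    """Read a square labeled TSV distance matrix."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ValidationError(f"{path}: row and column labels differ")
    try:
        return DistanceMatrix(df.to_numpy(dtype=float), ids=list(map(str, df.index)))
    except Exception as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_distance_matrix(dm: DistanceMatrix, path) -> None:
    df = pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids))
    df.to_csv(path, sep="\t", lineterminator="\n")
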