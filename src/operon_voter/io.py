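"""On-disk formats: GFF3 gene annotations, per-base coverage tracks, pair
label tables, feature tables and prediction tables.

All genomic coordinates are 1-based inclusive, matching GFF3 and per-base
depth files; conversion to 0-based happens only at array indexing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The twelve model features, in the fixed column order used everywhere.
FEATURE_COLUMNS: tuple = (
    "lenA",
    "lenB",
    "intergenic_length",
    "strand_match",
    "kw_AI_H",
    "kw_AI_logp",
    "kw_BI_H",
    "kw_BI_logp",
    "kw_AB_H",
    "kw_AB_logp",
    "kw_AIB_H",
    "kw_AIB_logp",
)

FEATURE_META_COLUMNS = ("pair_id", "sample_id")
ALGORITHM_KEYS = ("LR", "SVM", "RF", "XGB", "MLP", "GNB")

PAIR_ID_SEP = "|"


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass(frozen=True, order=True)
class GeneRecord:
    """One annotated gene with 1-based inclusive coordinates."""

    seqid: str
    start: int
    end: int
    gene_id: str
    strand: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if PAIR_ID_SEP in self.gene_id:
            raise ValueError(
                f"gene id {self.gene_id!r} may not contain {PAIR_ID_SEP!r}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


class CoverageTrack:
    """Dense per-base read depth for one sample, keyed by sequence id."""

    def __init__(self, sample_id: str, depths: Mapping[str, np.ndarray]):
        self.sample_id = sample_id
        self.depths: Dict[str, np.ndarray] = {
            seqid: np.asarray(arr, dtype=np.int64) for seqid, arr in depths.items()
        }
        for seqid, arr in self.depths.items():
            if arr.ndim != 1:
                raise ValueError(f"{seqid}: depth array must be 1-D")
            if arr.size and arr.min() < 0:
                raise ValueError(f"{seqid}: negative depth values")

    def depth(self, seqid: str, start: int, end: int) -> np.ndarray:
        """Depth over [start, end], 1-based inclusive."""
        if seqid not in self.depths:
            raise KeyError(f"sequence {seqid!r} not in coverage track")
        arr = self.depths[seqid]
        if start < 1 or end > arr.size:
            raise IndexError(
                f"window {seqid}:{start}-{end} outside track bounds (1-{arr.size})"
            )
        return arr[start - 1 : end]

    def __contains__(self, seqid: str) -> bool:
        return seqid in self.depths


@dataclass(frozen=True)
class PairLabel:
    geneA_id: str
    geneB_id: str
    label: int

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(
                f"label for ({self.geneA_id}, {self.geneB_id}) must be 0 or 1, "
                f"got {self.label!r}"
            )


def _parse_gff3_attributes(field: str) -> Dict[str, str]:
    attrs: Dict[str, str] = {}
    for item in field.strip().split(";"):
        item = item.strip()
        if not item or "=" not in item:
            continue
        key, _, value = item.partition("=")
        attrs[key.strip()] = value.strip()
    return attrs


def read_gff3_genes(path, feature_type: str = "gene") -> List[GeneRecord]:
    """Read gene records from a GFF3 file.

    Keeps only rows whose type column equals ``feature_type``. The gene id is
    taken from the ``ID`` attribute, falling back to ``locus_tag`` then
    ``Name``; rows with none of these are skipped with a warning. Output is
    sorted by (seqid, start).
    """
    records: List[GeneRecord] = []
    seen_ids = set()
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(
                    f"{path}: line {lineno}: expected 9 tab-separated columns, "
                    f"got {len(fields)}"
                )
            seqid, _source, ftype, start_s, end_s, _score, strand, _phase, attr_s = fields
            if ftype != feature_type:
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(
                    f"{path}: line {lineno}: non-integer coordinate"
                ) from exc
            attrs = _parse_gff3_attributes(attr_s)
            gene_id = attrs.get("ID") or attrs.get("locus_tag") or attrs.get("Name")
            if gene_id is None:
                logger.warning(
                    "%s: line %d: no ID/locus_tag/Name attribute; record skipped",
                    path,
                    lineno,
                )
                continue
            # strip the common "gene:" prefix Ensembl puts on ID values
            if gene_id.startswith("gene:"):
                gene_id = gene_id[len("gene:"):]
            if gene_id in seen_ids:
                raise FormatError(
                    f"{path}: line {lineno}: duplicate gene id {gene_id!r}"
                )
            seen_ids.add(gene_id)
            if strand not in ("+", "-"):
                raise FormatError(
                    f"{path}: line {lineno}: strand must be + or -, got {strand!r}"
                )
            records.append(GeneRecord(seqid, start, end, gene_id, strand))
    records.sort(key=lambda g: (g.seqid, g.start))
    return records


def write_gff3_genes(genes: Iterable[GeneRecord], path) -> None:
    """Write gene records as a minimal genes-only GFF3 file."""
    with open(path, "wt", encoding="utf-8", newline="\n") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes):
            fh.write(
                f"{g.seqid}\tsim\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )


def read_coverage(path, sample_id: str) -> CoverageTrack:
    """Read per-base depth text (seqid, 1-based position, depth per line).

    Positions must be ascending within each seqid; gaps are filled with
    depth 0. Duplicate positions and non-integer fields are errors.
    """
    arrays: Dict[str, list] = {}
    last_pos: Dict[str, int] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) != 3:
                raise FormatError(
                    f"{path}: line {lineno}: expected 3 columns, got {len(fields)}"
                )
            seqid, pos_s, depth_s = fields
            try:
                pos, depth = int(pos_s), int(depth_s)
            except ValueError as exc:
                raise FormatError(
                    f"{path}: line {lineno}: non-integer position or depth"
                ) from exc
            if depth < 0:
                raise FormatError(f"{path}: line {lineno}: negative depth")
            if pos < 1:
                raise FormatError(f"{path}: line {lineno}: position must be >= 1")
            prev = last_pos.get(seqid, 0)
            if pos == prev:
                raise FormatError(
                    f"{path}: line {lineno}: duplicate position {seqid}:{pos}"
                )
            if pos < prev:
                raise FormatError(
                    f"{path}: line {lineno}: positions not ascending for {seqid}"
                )
            arr = arrays.setdefault(seqid, [])
            if pos > prev + 1:  # gap -> zero fill
                arr.extend([0] * (pos - prev - 1))
            arr.append(depth)
            last_pos[seqid] = pos
    if not arrays:
        logger.warning("%s: empty coverage file", path)
    return CoverageTrack(
        sample_id, {s: np.asarray(a, dtype=np.int64) for s, a in arrays.items()}
    )


def write_coverage(track: CoverageTrack, path) -> None:
    with open(path, "wt", encoding="utf-8", newline="\n") as fh:
        for seqid in sorted(track.depths):
            arr = track.depths[seqid]
            for pos0, depth in enumerate(arr):
                fh.write(f"{seqid}\t{pos0 + 1}\t{depth}\n")


_LABEL_HEADER = ["geneA_id", "geneB_id", "label"]


def read_pair_labels(path) -> List[PairLabel]:
    """Read a 3-column TSV (geneA_id, geneB_id, 0/1 label) with header."""
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    if list(df.columns) != _LABEL_HEADER:
        raise FormatError(
            f"{path}: expected header {_LABEL_HEADER}, got {list(df.columns)}"
        )
    labels = []
    seen = set()
    for row in df.itertuples(index=False):
        label = int(row.label)
        if label not in (0, 1):
            raise FormatError(
                f"{path}: non-binary label {row.label!r} for "
                f"({row.geneA_id}, {row.geneB_id})"
            )
        key = (row.geneA_id, row.geneB_id)
        if key in seen:
            raise FormatError(f"{path}: duplicate pair {key}")
        seen.add(key)
        labels.append(PairLabel(str(row.geneA_id), str(row.geneB_id), label))
    return labels


def write_pair_labels(labels: Iterable[PairLabel], path) -> None:
    df = pd.DataFrame(
        [(l.geneA_id, l.geneB_id, l.label) for l in labels], columns=_LABEL_HEADER
    )
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def pair_id(geneA_id: str, geneB_id: str) -> str:
    return f"{geneA_id}{PAIR_ID_SEP}{geneB_id}"


def split_pair_id(pid: str) -> tuple:
    a, sep, b = pid.partition(PAIR_ID_SEP)
    if not sep:
        raise ValueError(f"malformed pair id {pid!r}")
    return a, b


def _check_columns(df: pd.DataFrame, expected: Sequence[str], path) -> None:
    missing = [c for c in expected if c not in df.columns]
    unknown = [c for c in df.columns if c not in expected]
    if missing or unknown:
        raise FormatError(
            f"{path}: expected columns {list(expected)}; "
            f"missing {missing}, unknown {unknown}"
        )


def feature_table_columns(with_label: bool = True) -> List[str]:
    cols = list(FEATURE_META_COLUMNS) + list(FEATURE_COLUMNS)
    if with_label:
        cols.append("label")
    return cols


def write_feature_table(df: pd.DataFrame, path) -> None:
    """Write a feature table: pair_id, sample_id, the 12 features, optional label."""
    with_label = "label" in df.columns
    cols = feature_table_columns(with_label)
    _check_columns(df, cols, path)
    df[cols].to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_feature_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"pair_id": str, "sample_id": str})
    with_label = "label" in df.columns
    _check_columns(df, feature_table_columns(with_label), path)
    return df


def prediction_table_columns() -> List[str]:
    cols = list(FEATURE_META_COLUMNS)
    for key in ALGORITHM_KEYS:
        cols.append(f"call_{key}")
    for key in ALGORITHM_KEYS:
        cols.append(f"prob_{key}")
    return cols


def write_predictions(df: pd.DataFrame, path) -> None:
    cols = prediction_table_columns()
    _check_columns(df, cols, path)
    df[cols].to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_predictions(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"pair_id": str, "sample_id": str})
    _check_columns(df, prediction_table_columns(), path)
    return df
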