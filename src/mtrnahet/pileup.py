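"""Quality-filtered per-position base counting from aligned reads.

Converts SAM records on the mitochondrial contig into a
:class:`BaseCountTable` — per-position counts of A/C/G/T surviving the
mapping-quality and base-quality filters — and defines the canonical
tab-separated exchange format for those counts.

Pileup semantics: a read contributes nothing if it is unmapped, flagged as a
duplicate, or has mapping quality below the threshold; an aligned base
contributes only if its base quality meets the threshold; insertions,
deletions and soft-clipped segments contribute no counts; 'N' never counts.
Depth everywhere downstream is this quality-filtered depth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

TSV_COLUMNS = ["sample_id", "pos", "ref", "A", "C", "G", "T"]


class PileupError(ValueError):
    pass


@dataclass
class BaseCountTable:
    """Per-sample, per-position quality-filtered base counts.

    ``positions`` is strictly increasing (1-based); ``counts`` is an
    (n_positions, 4) integer array in A/C/G/T order; ``ref`` holds the
    reference base per position.
    """

    sample_id: str
    positions: np.ndarray
    ref: np.ndarray
    counts: np.ndarray

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype="U1")
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.positions), 4):
            raise PileupError("counts must be (n_positions, 4)")
        if len(self.ref) != len(self.positions):
            raise PileupError("ref and positions length mismatch")
        if len(self.positions) and np.any(np.diff(self.positions) <= 0):
            raise PileupError("positions must be strictly increasing")
        if np.any(self.counts < 0):
            raise PileupError("negative counts")

    def __len__(self) -> int:
        return len(self.positions)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, BaseCountTable)
            and self.sample_id == other.sample_id
            and np.array_equal(self.positions, other.positions)
            and np.array_equal(self.ref, other.ref)
            and np.array_equal(self.counts, other.counts)
        )

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def depth_at(self, position: int) -> int:
        i = np.searchsorted(self.positions, position)
        if i < len(self.positions) and self.positions[i] == position:
            return int(self.depth[i])
        return 0

    def count_at(self, position: int, base: str) -> int:
        i = np.searchsorted(self.positions, position)
        if i < len(self.positions) and self.positions[i] == position:
            return int(self.counts[i, _BASE_INDEX[base]])
        return 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_id,
                "pos": self.positions,
                "ref": self.ref,
                "A": self.counts[:, 0],
                "C": self.counts[:, 1],
                "G": self.counts[:, 2],
                "T": self.counts[:, 3],
            }
        )

    @classmethod
    def empty(cls, sample_id: str) -> "BaseCountTable":
        return cls(
            sample_id,
            np.empty(0, dtype=np.int64),
            np.empty(0, dtype="U1"),
            np.empty((0, 4), dtype=np.int64),
        )


@dataclass(frozen=True)
class ReadFilter:
    """Read-level and base-level quality thresholds (inclusive minima)."""

    min_mapq: int = 20
    min_baseq: int = 30

    def __post_init__(self):
        if self.min_mapq < 0 or self.min_baseq < 0:
            raise ValueError("quality minima must be >= 0")


def _iter_alignments(
    reads: str | Path | pysam.AlignmentFile | Iterable[pysam.AlignedSegment],
) -> Iterator[pysam.AlignedSegment]:
    if isinstance(reads, (str, Path)):
        with pysam.AlignmentFile(str(reads), "r", check_sq=False) as fh:
            yield from fh
    elif isinstance(reads, pysam.AlignmentFile):
        yield from reads
    else:
        yield from reads


def ingest_alignments(
    reads,
    filters: ReadFilter | None = None,
    genome_length: int | None = None,
    reference: str | None = None,
    sample_id: str = "sample",
) -> BaseCountTable:
    """Pile up aligned reads into quality-filtered base counts.

    ``reads`` may be a SAM path, an open ``pysam.AlignmentFile`` or an
    iterable of ``pysam.AlignedSegment``. ``reference`` (the contig sequence)
    fills the table's ref column; ``genome_length`` defaults to its length.
    Reads extending past the genome end are skipped with a warning.
    """
    filters = filters or ReadFilter()
    if genome_length is None:
        if reference is None:
            raise PileupError("need genome_length or reference")
        genome_length = len(reference)
    counts = np.zeros((genome_length, 4), dtype=np.int64)

    n_used = n_skipped = 0
    for read in _iter_alignments(reads):
        if read.is_unmapped or read.is_duplicate:
            n_skipped += 1
            continue
        if read.mapping_quality < filters.min_mapq:
            n_skipped += 1
            continue
        if read.reference_end is not None and read.reference_end > genome_length:
            logger.warning(
                "read %s extends past genome end (%d > %d); skipped",
                read.query_name, read.reference_end, genome_length,
            )
            n_skipped += 1
            continue
        seq = read.query_sequence
        quals = read.query_qualities
        if seq is None or quals is None:
            n_skipped += 1
            continue
        for qpos, rpos in read.get_aligned_pairs(matches_only=True):
            if quals[qpos] < filters.min_baseq:
                continue
            base = seq[qpos]
            if base not in _BASE_INDEX:
                continue  # 'N' and other ambiguity codes never count
            counts[rpos, _BASE_INDEX[base]] += 1
        n_used += 1
    logger.info("pileup %s: %d reads used, %d skipped", sample_id, n_used, n_skipped)

    covered = np.flatnonzero(counts.sum(axis=1) > 0)
    if reference is not None:
        ref = np.array([reference[i] for i in covered], dtype="U1")
    else:
        ref = np.full(len(covered), "N", dtype="U1")
    return BaseCountTable(sample_id, covered + 1, ref, counts[covered])


# -- canonical TSV ----------------------------------------------------------


def write_basecounts(table: BaseCountTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


def read_basecounts(path: str | Path) -> BaseCountTable:
    """Read the canonical base-count TSV; ``write_basecounts`` round-trips."""
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            dtype={"sample_id": str, "pos": np.int64, "ref": str,
                   "A": np.int64, "C": np.int64, "G": np.int64, "T": np.int64},
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise PileupError(f"{path}: {exc}") from exc
    if list(df.columns) != TSV_COLUMNS:
        raise PileupError(f"{path}: expected header {TSV_COLUMNS}, got {list(df.columns)}")
    if df.empty:
        return BaseCountTable.empty(Path(path).stem)
    bad = df[(df[["A", "C", "G", "T"]] < 0).any(axis=1)]
    if not bad.empty:
        raise PileupError(f"{path}: negative count at line {bad.index[0] + 2}")
    sample_ids = df["sample_id"].unique()
    if len(sample_ids) != 1:
        raise PileupError(f"{path}: expected one sample_id, found {list(sample_ids)}")
    return BaseCountTable(
        sample_ids[0],
        df["pos"].to_numpy(),
        df["ref"].to_numpy(dtype="U1"),
        df[["A", "C", "G", "T"]].to_numpy(),
    )
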