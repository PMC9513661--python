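"""Threshold-based single-nucleotide variant calling from base counts.

A variant is a single-base deviation from the consensus sequence. A call is
emitted at a position when the quality-filtered depth is at least
``min_depth`` (default 100) and the alternate-base frequency is at least
``min_af`` (default 1%); both boundaries are inclusive. The heteroplasmy
level of a call is h = alt_count / depth. Indels and multi-nucleotide
substitutions are out of scope by design; multi-allelic positions emit one
record per qualifying alternate base.

This is a transparent threshold caller: the four thresholds (depth, allele
frequency, mapping quality, base quality) are the whole model — there are no
priors, strand-bias terms or genotype likelihoods.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .pileup import BASES, BaseCountTable

logger = logging.getLogger(__name__)


class CallingError(ValueError):
    pass


@dataclass(frozen=True)
class FilterConfig:
    """Variant-calling thresholds (the paper-standard values are defaults)."""

    min_depth: int = 100
    min_af: float = 0.01
    min_mapq: int = 20
    min_baseq: int = 30
    detection_threshold: float = 0.01

    def __post_init__(self):
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")
        if not 0 < self.min_af <= 1:
            raise ValueError("min_af must be in (0, 1]")
        if self.min_mapq < 0 or self.min_baseq < 0:
            raise ValueError("quality minima must be >= 0")
        if not 0 < self.detection_threshold <= 1:
            raise ValueError("detection_threshold must be in (0, 1]")


@dataclass(frozen=True)
class VariantCall:
    sample_id: str
    position: int
    ref: str
    alt: str
    alt_count: int
    depth: int

    def __post_init__(self):
        if self.alt == self.ref:
            raise CallingError("alt equals ref")
        if not 0 < self.alt_count <= self.depth:
            raise CallingError("need 0 < alt_count <= depth")

    @property
    def h(self) -> float:
        """Heteroplasmy level: alternate reads over quality-filtered depth."""
        return self.alt_count / self.depth


def heteroplasmy(alt_count: int, depth: int) -> float:
    """h = alt_count / depth, the fraction of transcripts carrying the variant."""
    if depth < 1:
        raise CallingError(f"depth must be >= 1, got {depth}")
    if not 0 <= alt_count <= depth:
        raise CallingError(f"alt_count {alt_count} outside [0, depth={depth}]")
    return alt_count / depth


def consensus_from_tables(tables: Iterable[BaseCountTable], genome_length: int) -> str:
    """Majority-base consensus across a whole study (ties broken by A<C<G<T);
    positions with no coverage anywhere keep 'N'."""
    total = np.zeros((genome_length, 4), dtype=np.int64)
    for t in tables:
        total[t.positions - 1] += t.counts
    best = total.argmax(axis=1)
    out = np.array([BASES[i] for i in best], dtype="U1")
    out[total.sum(axis=1) == 0] = "N"
    return "".join(out)


def call_variants(
    table: BaseCountTable,
    consensus: str,
    filters: FilterConfig | None = None,
) -> list[VariantCall]:
    """Emit every (position, alternate base) passing the depth and allele
    frequency thresholds, sorted by (position, alt)."""
    filters = filters or FilterConfig()
    if len(table) == 0:
        return []
    if table.positions[-1] > len(consensus):
        raise CallingError(
            f"table position {table.positions[-1]} beyond consensus length {len(consensus)}"
        )
    depth = table.depth
    keep = depth >= filters.min_depth
    calls: list[VariantCall] = []
    cons = np.array([consensus[p - 1] for p in table.positions], dtype="U1")
    if "N" in cons[keep]:
        raise CallingError("consensus base missing (N) at a callable position")
    for i in np.flatnonzero(keep):
        pos = int(table.positions[i])
        d = int(depth[i])
        ref = cons[i]
        for j, base in enumerate(BASES):
            if base == ref:
                continue
            c = int(table.counts[i, j])
            if c > 0 and c / d >= filters.min_af:
                calls.append(VariantCall(table.sample_id, pos, ref, base, c, d))
    calls.sort(key=lambda v: (v.position, v.alt))
    return calls


def calls_to_frame(calls: Sequence[VariantCall]) -> pd.DataFrame:
    """Flat TSV-ready mirror: sample_id pos ref alt alt_count depth h."""
    return pd.DataFrame(
        [
            {
                "sample_id": c.sample_id,
                "pos": c.position,
                "ref": c.ref,
                "alt": c.alt,
                "alt_count": c.alt_count,
                "depth": c.depth,
                "h": c.h,
            }
            for c in calls
        ],
        columns=["sample_id", "pos", "ref", "alt", "alt_count", "depth", "h"],
    )


def frame_to_calls(df: pd.DataFrame) -> list[VariantCall]:
    return [
        VariantCall(r.sample_id, int(r.pos), r.ref, r.alt, int(r.alt_count), int(r.depth))
        for r in df.itertuples()
    ]


def write_calls_tsv(calls: Sequence[VariantCall], path: str | Path) -> None:
    calls_to_frame(calls).to_csv(path, sep="\t", index=False)


def read_calls_tsv(path: str | Path) -> list[VariantCall]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "ref": str, "alt": str})
    return frame_to_calls(df)


# -- minimal VCF 4.2 ---------------------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=mtrnahet
##contig=<ID={contig},length={length}>
##INFO=<ID=DP,Number=1,Type=Integer,Description="Quality-filtered read depth">
##INFO=<ID=AF,Number=A,Type=Float,Description="Heteroplasmy level (alt reads / depth)">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Quality-filtered read depth">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Read counts (ref, alt)">
##FORMAT=<ID=AF,Number=A,Type=Float,Description="Heteroplasmy level">
"""


def write_vcf(
    calls: Sequence[VariantCall],
    path: str | Path,
    contig: str = "chrM",
    genome_length: int = 16299,
    filter_lines: Sequence[str] = (),
) -> None:
    """Write calls as a minimal single-sample VCF 4.2 file.

    ``filter_lines`` are extra ``##`` header lines (e.g. the thresholds used).
    Calls must be sorted by (position, alt).
    """
    order = [(c.position, c.alt) for c in calls]
    if order != sorted(order):
        raise CallingError("calls must be sorted by (position, alt)")
    sample = calls[0].sample_id if calls else "SAMPLE"
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER.format(contig=contig, length=genome_length))
        for line in filter_lines:
            fh.write(line.rstrip("\n") + "\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample + "\n"
        )
        for c in calls:
            ref_count = c.depth - c.alt_count  # non-alt reads reported as ref support
            fh.write(
                f"{contig}\t{c.position}\t.\t{c.ref}\t{c.alt}\t.\tPASS\t"
                f"DP={c.depth};AF={c.h:.6g}\tDP:AD:AF\t"
                f"{c.depth}:{ref_count},{c.alt_count}:{c.h:.6g}\n"
            )


def read_vcf(path: str | Path) -> list[VariantCall]:
    """Parse back a VCF written by :func:`write_vcf` (lossless round-trip)."""
    calls: list[VariantCall] = []
    sample = "SAMPLE"
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#CHROM"):
                sample = line.split("\t")[9]
                continue
            if line.startswith("#") or not line:
                continue
            cols = line.split("\t")
            pos, ref, alt = int(cols[1]), cols[3], cols[4]
            fmt = dict(zip(cols[8].split(":"), cols[9].split(":")))
            depth = int(fmt["DP"])
            alt_count = int(fmt["AD"].split(",")[1])
            calls.append(VariantCall(sample, pos, ref, alt, alt_count, depth))
    return calls
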