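"""Mitochondrial genome reference: annotation, feature lookup, synonymy.

Holds the mitochondrial genome sequence and gene map (protein-coding genes,
tRNAs, rRNAs, the non-coding D-loop control region), assigns positions to
features, and classifies single-base substitutions in coding genes as
synonymous or non-synonymous under the vertebrate mitochondrial genetic code
(NCBI translation table 2).

Coordinates are 1-based and inclusive throughout, on the heavy-strand
reference. The packaged default annotation follows the mouse mitochondrial
genome layout (16,299 bp; D-loop at 15443-16299); the packaged *sequence* is
a deterministic synthetic stand-in with that layout, suitable for simulation
and testing but not for interpreting real mouse data.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Data import CodonTable

logger = logging.getLogger(__name__)

FEATURE_TYPES = ("protein_coding", "tRNA", "rRNA", "D_loop", "other_noncoding")

#: region_class priority when a position falls in several overlapping features
REGION_PRIORITY = ("protein_coding", "tRNA", "rRNA", "D_loop", "other_noncoding")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

SYNONYMOUS = "synonymous"
NON_SYNONYMOUS = "non_synonymous"
NON_CODING = "non_coding"


class AnnotationError(ValueError):
    """Malformed or out-of-bounds annotation input."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Feature:
    name: str
    ftype: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str
    reading_frame_offset: int = 0

    def __post_init__(self):
        if self.ftype not in FEATURE_TYPES:
            raise AnnotationError(f"unknown feature type {self.ftype!r} for {self.name}")
        if self.strand not in "+-":
            raise AnnotationError(f"strand must be + or -, got {self.strand!r}")
        if not 1 <= self.start <= self.end:
            raise AnnotationError(f"bad span {self.start}-{self.end} for {self.name}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass(frozen=True)
class FeatureAssignment:
    """All features overlapping one genomic position, plus its primary class."""

    position: int
    hits: tuple[tuple[str, str, str], ...]  # (name, ftype, strand)
    region_class: str


@dataclass
class MitoAnnotation:
    """Genome sequence plus validated feature map of a mitochondrial genome."""

    sequence: str
    features: list[Feature]
    translation_table: int = 2
    _codon_table: CodonTable.CodonTable = field(init=False, repr=False)

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - set("ACGT")
        if bad:
            raise AnnotationError(f"sequence contains non-ACGT characters: {sorted(bad)}")
        for f in self.features:
            if f.end > self.genome_length:
                raise AnnotationError(
                    f"feature {f.name} ends at {f.end}, beyond genome length {self.genome_length}"
                )
        self._codon_table = CodonTable.unambiguous_dna_by_id[self.translation_table]

    @property
    def genome_length(self) -> int:
        return len(self.sequence)

    def base(self, position: int) -> str:
        self._check_position(position)
        return self.sequence[position - 1]

    def _check_position(self, position: int) -> None:
        if not 1 <= position <= self.genome_length:
            raise ValueError(
                f"position {position} outside genome [1, {self.genome_length}]"
            )

    # -- feature lookup ----------------------------------------------------

    def locate(self, position: int) -> FeatureAssignment:
        """Return every feature whose span contains ``position``.

        The primary ``region_class`` uses the fixed priority
        protein_coding > tRNA > rRNA > D_loop; positions in no feature are
        ``other_noncoding``.
        """
        self._check_position(position)
        hits = tuple(
            (f.name, f.ftype, f.strand) for f in self.features if f.contains(position)
        )
        if not hits:
            return FeatureAssignment(position, (), "other_noncoding")
        klass = min(hits, key=lambda h: REGION_PRIORITY.index(h[1]))[1]
        return FeatureAssignment(position, hits, klass)

    def coding_features_at(self, position: int) -> list[Feature]:
        return [
            f
            for f in self.features
            if f.ftype == "protein_coding" and f.contains(position)
        ]

    def feature_by_name(self, name: str) -> Feature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    # -- synonymy ----------------------------------------------------------

    def _codon_at(self, feat: Feature, position: int) -> tuple[str, int] | None:
        """Return (codon on the coding strand, 0-based offset of ``position``
        inside that codon), or None when the position falls in a trailing
        partial codon (incomplete stop completed by polyadenylation)."""
        if feat.strand == "+":
            idx = (position - feat.start) - feat.reading_frame_offset
        else:
            idx = (feat.end - position) - feat.reading_frame_offset
        if idx < 0:
            return None
        codon_i, within = divmod(idx, 3)
        # genome coordinates of the codon, in coding-strand order
        if feat.strand == "+":
            first = feat.start + feat.reading_frame_offset + 3 * codon_i
            coords = (first, first + 1, first + 2)
        else:
            first = feat.end - feat.reading_frame_offset - 3 * codon_i
            coords = (first, first - 1, first - 2)
        lo, hi = min(coords), max(coords)
        if lo < feat.start or hi > feat.end:
            return None  # trailing partial codon
        codon = "".join(self.sequence[c - 1] for c in coords)
        if feat.strand == "-":
            codon = codon.translate(_COMPLEMENT)
        return codon, within

    def _translate_codon(self, codon: str) -> str:
        if codon in self._codon_table.stop_codons:
            return "*"
        return self._codon_table.forward_table[codon]

    def classify_substitution(self, position: int, alt: str) -> str:
        """Classify a single-base substitution as synonymous / non_synonymous
        / non_coding under the configured mitochondrial genetic code.

        A substitution is non_synonymous if it changes the encoded amino acid
        (stop counts as an amino-acid state) in ANY overlapping coding gene.
        Positions inside a coding gene's trailing partial codon are treated as
        non_coding with a warning.
        """
        self._check_position(position)
        alt = alt.upper()
        if alt not in "ACGT":
            raise ValueError(f"ambiguous alternate base {alt!r}")
        ref = self.base(position)
        if alt == ref:
            raise ValueError(f"not a variant: alt equals reference {ref} at {position}")
        feats = self.coding_features_at(position)
        if not feats:
            return NON_CODING
        verdicts = []
        for feat in feats:
            got = self._codon_at(feat, position)
            if got is None:
                warnings.warn(
                    f"position {position} falls in the trailing partial codon of "
                    f"{feat.name}; synonymy indeterminate, treated as non-coding",
                    stacklevel=2,
                )
                continue
            codon, within = got
            sub = alt if feat.strand == "+" else alt.translate(_COMPLEMENT)
            mutated = codon[:within] + sub + codon[within + 1 :]
            verdicts.append(self._translate_codon(codon) == self._translate_codon(mutated))
        if not verdicts:
            return NON_CODING
        return SYNONYMOUS if all(verdicts) else NON_SYNONYMOUS


# -- loading ---------------------------------------------------------------

_REQUIRED_COLUMNS = ["name", "ftype", "start", "end", "strand", "frame"]


def load_annotation(features_path: str | Path, fasta_path: str | Path) -> MitoAnnotation:
    """Load a feature table (TSV) and genome (single-record FASTA).

    The TSV has header columns name/ftype/start/end/strand/frame; lines
    starting with ``#`` before the header may set ``key=value`` options,
    currently only ``translation_table``.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(records) != 1:
        raise AnnotationError(f"expected a single FASTA record, found {len(records)}")
    sequence = str(records[0].seq).upper()

    table_id = 2
    features: list[Feature] = []
    header: list[str] | None = None
    with open(features_path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith("translation_table="):
                    table_id = int(body.split("=", 1)[1])
                continue
            cols = line.split("\t")
            if header is None:
                header = cols
                missing = [c for c in _REQUIRED_COLUMNS if c not in header]
                if missing:
                    raise AnnotationError(
                        f"{features_path}:{lineno}: missing columns {missing}"
                    )
                continue
            row = dict(zip(header, cols))
            try:
                frame = 0 if row["frame"] in (".", "") else int(row["frame"])
                feat = Feature(
                    name=row["name"],
                    ftype=row["ftype"],
                    start=int(row["start"]),
                    end=int(row["end"]),
                    strand=row["strand"],
                    reading_frame_offset=frame,
                )
            except (KeyError, ValueError, AnnotationError) as exc:
                raise AnnotationError(f"{features_path}:{lineno}: {exc}") from exc
            features.append(feat)
    if header is None:
        raise AnnotationError(f"{features_path}: no header line found")
    return MitoAnnotation(sequence=sequence, features=features, translation_table=table_id)


def load_default_annotation() -> MitoAnnotation:
    """The packaged mouse-layout annotation with its synthetic sequence."""
    data = resources.files("mtrnahet.data")
    with resources.as_file(data / "mouse_mt_features.tsv") as tsv, resources.as_file(
        data / "mouse_mt_synthetic.fa"
    ) as fa:
        return load_annotation(tsv, fa)


# -- known modification sites ----------------------------------------------


def load_modification_catalogue(path: str | Path | None = None) -> list[tuple[int, str, str]]:
    """Load a (position, molecule, modification) catalogue of known rRNA
    modification sites. Without ``path`` the packaged synthetic stand-in
    catalogue is used."""
    if path is None:
        data = resources.files("mtrnahet.data")
        with resources.as_file(data / "rrna_modification_sites_synthetic.tsv") as p:
            return load_modification_catalogue(p)
    out: list[tuple[int, str, str]] = []
    header = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            if header is None:
                header = line.split("\t")
                continue
            pos, molecule, modification = line.split("\t")[:3]
            out.append((int(pos), molecule, modification))
    return out


def check_known_modification_sites(
    positions: Iterable[int],
    catalogue: Iterable[tuple[int, str, str]] | None = None,
) -> dict[int, list[tuple[int, str, str]]]:
    """Report, per query position, the catalogue entries at that position.

    An empty list for every query means none of the positions correspond to
    a known rRNA modification site.
    """
    if catalogue is None:
        catalogue = load_modification_catalogue()
    by_pos: dict[int, list[tuple[int, str, str]]] = {}
    for entry in catalogue:
        by_pos.setdefault(entry[0], []).append(entry)
    return {p: list(by_pos.get(p, [])) for p in positions}
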