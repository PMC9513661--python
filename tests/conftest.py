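import numpy as np
import pysam
import pytest

from mtrnahet import (
    BaseCountTable,
    Feature,
    MitoAnnotation,
    SimConfig,
    load_default_annotation,
    simulate_study,
)


@pytest.fixture(scope="session")
def ann():
    return load_default_annotation()


@pytest.fixture(scope="session")
def toy_ann():
    """Tiny genome: a + strand CDS at 4-12 whose first codon is ATT, a - strand
    CDS at 16-24, and a gap, for hand-checkable synonymy cases."""
    #           123 456 789 012 345 678 901 234 567
    sequence = "GGG" "ATT" "CTA" "AAA" "CCC" "TTA" "CAT" "TAA" "GGG"
    features = [
        Feature("plusgene", "protein_coding", 4, 12, "+"),
        Feature("minusgene", "protein_coding", 16, 24, "-"),
    ]
    return MitoAnnotation(sequence=sequence, features=features)


@pytest.fixture(scope="session")
def sim_study(ann):
    """One default synthetic study, shared across tests that only read it."""
    return simulate_study(SimConfig(seed=11), ann)


def make_table(sample_id, rows, reference=None):
    """rows: list of (pos, ref, countA, countC, countG, countT)."""
    rows = sorted(rows)
    positions = np.array([r[0] for r in rows], dtype=np.int64)
    ref = np.array(
        [r[1] if reference is None else reference[r[0] - 1] for r in rows], dtype="U1"
    )
    counts = np.array([r[2:] for r in rows], dtype=np.int64).reshape(len(rows), 4)
    return BaseCountTable(sample_id, positions, ref, counts)


def make_sam(path, reads, genome_length=16299, contig="chrM"):
    """reads: list of dicts with pos (1-based), seq, quals (list of ints),
    and optional mapq/flag/cigar."""
    header = pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6"}, "SQ": [{"SN": contig, "LN": genome_length}]}
    )
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for i, r in enumerate(reads):
            seg = pysam.AlignedSegment(header)
            seg.query_name = r.get("name", f"r{i}")
            seg.query_sequence = r["seq"]
            seg.flag = r.get("flag", 0)
            seg.reference_id = 0
            seg.reference_start = r["pos"] - 1
            seg.mapping_quality = r.get("mapq", 60)
            seg.cigartuples = r.get("cigar", [(0, len(r["seq"]))])
            seg.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(q + 33) for q in r["quals"])
            )
            fh.write(seg)
    return path
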