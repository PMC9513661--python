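"""Synthetic paired oocyte-cumulus study generator.

Generates a full study — sample metadata, per-sample base-count tables,
optionally SAM records — with a known truth table, emulating the structure
the analysis assumes: three age groups, ~4 mice per group, usually two
oocyte-cumulus complexes (OCC) per mouse (one mouse with a single OCC and one
with three, mirroring real-world collection accidents), deeper sequencing in
the bulk cumulus samples, maternal heteroplasmies shared within a mouse, and
cell-type-specific modification artifacts at fixed positions.

Generative model per mouse: a Poisson number of maternal heteroplasmies with
founder levels h0 from a truncated Beta; each sample re-draws its realized
level from Beta(c*h0, c*(1-h0)) (sister samples share the post-bottleneck
maternal pool, so c is large — this models sampling noise between sisters,
not the full germline bottleneck); cumulus expected levels are scaled up by a
constant factor. Post-transcriptional modification artifacts are modeled as
fixed apparent alternate-base fractions per cell type, independent of mouse
(no chemistry is modeled). Read counts per position are multinomial at a
Poisson depth with a uniform per-base miscall error spread over the three
non-reference bases.

Random numbers are consumed in a fixed, documented order (per-mouse variant
counts, then positions/alts/founder levels per mouse in metadata order, then
per sample: depths, realized levels, base counts), so a seed pins the output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

from .cohort import AGE_GROUPS, RecurrentVariant, validate_metadata
from .pileup import BASES, BaseCountTable, _BASE_INDEX
from .reference import MitoAnnotation, REGION_PRIORITY

logger = logging.getLogger(__name__)


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class ModificationSite:
    """A cell-type-specific apparent-variant site (RT miscall artifact)."""

    position: int
    rate_oocyte: float
    rate_cumulus: float
    alt: str | None = None  # None: first non-reference base in A<C<G<T order

    def __post_init__(self):
        for r in (self.rate_oocyte, self.rate_cumulus):
            if not 0 <= r <= 1:
                raise SimulationError("modification rates must lie in [0, 1]")


#: Default artifact sites: three rRNA-gene sites and a tRNA-Glu site elevated
#: in cumulus cells, plus one rRNA site elevated in oocytes instead (the
#: direction the real position-233 variant shows). Rates are descriptive
#: placeholders on the scale the study reports (tens of percent in the
#: elevated cell type), not measured values.
DEFAULT_MODIFICATION_SITES = (
    ModificationSite(179, rate_oocyte=0.010, rate_cumulus=0.080),
    ModificationSite(233, rate_oocyte=0.120, rate_cumulus=0.020),
    ModificationSite(729, rate_oocyte=0.010, rate_cumulus=0.100),
    ModificationSite(14131, rate_oocyte=0.005, rate_cumulus=0.230),
)

DEFAULT_DEPTH_PROFILE = {
    "protein_coding": 6000.0,
    "tRNA": 4000.0,
    "rRNA": 8000.0,
    "D_loop": 2200.0,  # control region is transcribed at comparatively low levels
    "other_noncoding": 2200.0,
}


@dataclass
class SimConfig:
    """Study-shape and generative parameters; defaults are the packaged
    study conditions."""

    n_mice_per_group: int = 4
    occ_per_mouse: int = 2
    occ_overrides: dict[int, int] = field(default_factory=lambda: {5: 3, 7: 1})
    age_groups: tuple[str, ...] = AGE_GROUPS
    maternal_variants_per_mouse: float = 6.0  # Poisson mean
    founder_h_beta: tuple[float, float] = (1.5, 15.0)
    founder_h_min: float = 0.05
    founder_h_max: float = 0.90
    segregation_concentration: float = 300.0
    cumulus_h_scale: float = 1.5
    modification_sites: tuple[ModificationSite, ...] = DEFAULT_MODIFICATION_SITES
    error_rate: float = 0.001
    depth_profile: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DEPTH_PROFILE)
    )
    cumulus_depth_multiplier: float = 3.0
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.error_rate <= 1:
            raise SimulationError("error_rate must lie in [0, 1]")
        if self.cumulus_h_scale < 1 or self.cumulus_depth_multiplier < 1:
            raise SimulationError("scale factors must be >= 1")
        if any(v < 0 for v in self.depth_profile.values()):
            raise SimulationError("depths must be >= 0")
        if self.maternal_variants_per_mouse < 0:
            raise SimulationError("maternal_variants_per_mouse must be >= 0")
        if not 0 < self.founder_h_min <= self.founder_h_max <= 1:
            raise SimulationError("founder h bounds must satisfy 0 < min <= max <= 1")


@dataclass
class SimTruth:
    """Ground truth of one simulated study."""

    maternal: pd.DataFrame  # mouse_id, pos, ref, alt, founder_h
    realized: pd.DataFrame  # sample_id, pos, alt, h_realized (pre-binomial)
    modification_sites: pd.DataFrame  # pos, ref, alt, rate_oocyte, rate_cumulus
    error_rate: float
    seed: int


def build_metadata(cfg: SimConfig) -> pd.DataFrame:
    """Deterministic study layout (no randomness): mice numbered across age
    groups in order, complexes per mouse from occ_per_mouse plus overrides."""
    rows = []
    mouse_no = 0
    for age in cfg.age_groups:
        for _ in range(cfg.n_mice_per_group):
            mouse_no += 1
            mouse = f"mouse{mouse_no:02d}"
            n_occ = cfg.occ_overrides.get(mouse_no, cfg.occ_per_mouse)
            for j in range(1, n_occ + 1):
                cx = f"{mouse}_occ{j}"
                for cell_type, tag in (("oocyte", "ooc"), ("cumulus", "cum")):
                    rows.append({"sample_id": f"{cx}_{tag}", "mouse_id": mouse,
                                 "age_group": age, "cell_type": cell_type,
                                 "complex_id": cx})
    return validate_metadata(pd.DataFrame(rows))


def _position_classes(ann: MitoAnnotation) -> np.ndarray:
    """Primary region class per position (priority order), as indices into
    REGION_PRIORITY."""
    classes = np.full(ann.genome_length, REGION_PRIORITY.index("other_noncoding"))
    for prio in reversed(range(len(REGION_PRIORITY) - 1)):
        ftype = REGION_PRIORITY[prio]
        for f in ann.features:
            if f.ftype == ftype:
                classes[f.start - 1 : f.end] = prio
    return classes


def _truncated_beta(rng: np.random.Generator, a: float, b: float,
                    lo: float, hi: float) -> float:
    for _ in range(10_000):
        x = rng.beta(a, b)
        if lo <= x <= hi:
            return float(x)
    raise SimulationError(
        f"founder Beta({a},{b}) has negligible mass in [{lo},{hi}]"
    )


def simulate_study(
    cfg: SimConfig, ann: MitoAnnotation
) -> tuple[pd.DataFrame, dict[str, BaseCountTable], SimTruth]:
    """Generate (metadata, per-sample base-count tables, truth).

    Deterministic given ``cfg.seed``; see the module docstring for the RNG
    consumption order.
    """
    rng = np.random.default_rng(cfg.seed)
    meta = build_metadata(cfg)
    L = ann.genome_length
    seq = np.array(list(ann.sequence), dtype="U1")
    ref_idx = np.array([_BASE_INDEX[b] for b in ann.sequence])

    # resolve modification-site alternates against the reference
    mod_rows = []
    for site in cfg.modification_sites:
        ref = ann.base(site.position)
        alt = site.alt or next(b for b in BASES if b != ref)
        if alt == ref:
            raise SimulationError(f"modification alt equals reference at {site.position}")
        mod_rows.append({"pos": site.position, "ref": ref, "alt": alt,
                         "rate_oocyte": site.rate_oocyte,
                         "rate_cumulus": site.rate_cumulus})
    mod_df = pd.DataFrame(mod_rows,
                          columns=["pos", "ref", "alt", "rate_oocyte", "rate_cumulus"])
    mod_positions = set(mod_df["pos"])

    # 1) per-mouse maternal variants (planted once, shared across samples)
    mice = list(dict.fromkeys(meta["mouse_id"]))
    candidates = np.array([p for p in range(1, L + 1) if p not in mod_positions])
    a, b = cfg.founder_h_beta
    maternal_rows = []
    per_mouse: dict[str, list[tuple[int, str, float]]] = {m: [] for m in mice}
    for mouse in mice:
        n_var = int(rng.poisson(cfg.maternal_variants_per_mouse))
        n_var = min(n_var, len(candidates))
        positions = np.sort(rng.choice(candidates, size=n_var, replace=False))
        for pos in positions:
            ref = ann.base(int(pos))
            others = [x for x in BASES if x != ref]
            alt = others[int(rng.integers(0, 3))]
            h0 = _truncated_beta(rng, a, b, cfg.founder_h_min, cfg.founder_h_max)
            per_mouse[mouse].append((int(pos), alt, h0))
            maternal_rows.append({"mouse_id": mouse, "pos": int(pos), "ref": ref,
                                  "alt": alt, "founder_h": h0})

    # 2) per-sample tables, in metadata order
    classes = _position_classes(ann)
    class_depth = np.array(
        [cfg.depth_profile[REGION_PRIORITY[c]] for c in classes], dtype=float
    )
    c = cfg.segregation_concentration
    e = cfg.error_rate
    tables: dict[str, BaseCountTable] = {}
    realized_rows = []
    for row in meta.itertuples():
        is_cumulus = row.cell_type == "cumulus"
        mean_depth = class_depth * (cfg.cumulus_depth_multiplier if is_cumulus else 1.0)
        depth = rng.poisson(mean_depth)

        p_signal = np.zeros((L, 4))
        p_signal[np.arange(L), ref_idx] = 1.0
        for pos, alt, h0 in per_mouse[row.mouse_id]:
            target = min(h0 * (cfg.cumulus_h_scale if is_cumulus else 1.0), 0.97)
            h_real = float(rng.beta(c * target, c * (1.0 - target)))
            i = pos - 1
            p_signal[i, _BASE_INDEX[alt]] += h_real
            p_signal[i, ref_idx[i]] -= h_real
            realized_rows.append({"sample_id": row.sample_id, "pos": pos,
                                  "alt": alt, "h_realized": h_real})
        for m in mod_df.itertuples():
            rate = m.rate_cumulus if is_cumulus else m.rate_oocyte
            i = m.pos - 1
            rate = min(rate, p_signal[i, ref_idx[i]])
            p_signal[i, _BASE_INDEX[m.alt]] += rate
            p_signal[i, ref_idx[i]] -= rate

        p_obs = p_signal * (1.0 - e) + (1.0 - p_signal) * (e / 3.0)
        counts = rng.multinomial(depth, p_obs)
        covered = np.flatnonzero(depth > 0)
        tables[row.sample_id] = BaseCountTable(
            row.sample_id, covered + 1, seq[covered], counts[covered]
        )

    truth = SimTruth(
        maternal=pd.DataFrame(maternal_rows,
                              columns=["mouse_id", "pos", "ref", "alt", "founder_h"]),
        realized=pd.DataFrame(realized_rows,
                              columns=["sample_id", "pos", "alt", "h_realized"]),
        modification_sites=mod_df,
        error_rate=e,
        seed=cfg.seed,
    )
    logger.info("simulated %d samples, %d planted maternal variants",
                len(tables), len(truth.maternal))
    return meta, tables, truth


# -- SAM emission --------------------------------------------------------------


def emit_alignments(
    table: BaseCountTable,
    read_length: int = 75,
    genome_length: int = 16299,
    contig: str = "chrM",
    mapq: int = 60,
    baseq: int = 40,
) -> tuple[pysam.AlignmentHeader, list[pysam.AlignedSegment]]:
    """Decompose a base-count table into aligned reads that pile back up to
    exactly the same table under the default quality filters.

    Greedy run decomposition: each read covers a contiguous run (up to
    ``read_length``) of positions with remaining counts, consuming one base
    per covered position; all reads carry passing MAPQ and base qualities.
    """
    if read_length < 1:
        raise SimulationError("read_length must be >= 1")
    if len(table) and table.positions[-1] > genome_length:
        raise SimulationError("table references positions beyond the genome end")
    header = pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6", "SO": "coordinate"},
         "SQ": [{"SN": contig, "LN": genome_length}]}
    )
    residual = table.counts.copy()
    positions = table.positions
    reads: list[pysam.AlignedSegment] = []
    n = len(positions)
    i = 0
    serial = 0
    while i < n:
        if residual[i].sum() == 0:
            i += 1
            continue
        j = i
        bases = []
        while (
            j < n
            and residual[j].sum() > 0
            and (j == i or positions[j] == positions[j - 1] + 1)
            and len(bases) < read_length
        ):
            k = int(residual[j].argmax())
            residual[j, k] -= 1
            bases.append(BASES[k])
            j += 1
        seg = pysam.AlignedSegment(header)
        serial += 1
        seg.query_name = f"{table.sample_id}.r{serial}"
        seg.query_sequence = "".join(bases)
        seg.flag = 0
        seg.reference_id = 0
        seg.reference_start = int(positions[i]) - 1  # SAM is 0-based in pysam
        seg.mapping_quality = mapq
        seg.cigartuples = [(0, len(bases))]
        seg.query_qualities = pysam.qualitystring_to_array(chr(baseq + 33) * len(bases))
        reads.append(seg)
    return header, reads


def write_sam(
    table: BaseCountTable, path: str | Path, read_length: int = 75,
    genome_length: int = 16299, contig: str = "chrM",
) -> int:
    header, reads = emit_alignments(table, read_length, genome_length, contig)
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for r in reads:
            fh.write(r)
    return len(reads)


# -- truth comparison ----------------------------------------------------------


def recovery_metrics(
    rvs: Sequence[RecurrentVariant],
    truth: SimTruth,
    meta: pd.DataFrame,
    maternal_min_cumulus: int = 2,
) -> dict[str, float]:
    """Compare recovered recurrent variants with the planted truth.

    recall    — planted maternal variants recovered as recurrent in their mouse;
    precision — recovered variants explained by truth (planted for that mouse,
                or a configured modification site);
    maternal_agreement — of recovered planted variants in mice able to satisfy
                the maternal criterion (>= maternal_min_cumulus cumulus
                samples), the fraction labelled maternal.
    """
    planted = set(zip(truth.maternal["mouse_id"], truth.maternal["pos"],
                      truth.maternal["alt"]))
    mod_keys = set(zip(truth.modification_sites["pos"],
                       truth.modification_sites["alt"]))
    found = {(rv.mouse_id, rv.position, rv.alt): rv for rv in rvs}

    recovered = planted & set(found)
    recall = len(recovered) / len(planted) if planted else float("nan")
    n_true = sum(
        1 for key in found
        if key in planted or (key[1], key[2]) in mod_keys
    )
    precision = n_true / len(found) if found else float("nan")

    n_cum = meta[meta["cell_type"] == "cumulus"].groupby("mouse_id").size()
    eligible = [k for k in recovered if n_cum.get(k[0], 0) >= maternal_min_cumulus]
    if eligible:
        agree = sum(1 for k in eligible if found[k].origin == "maternal")
        maternal_agreement = agree / len(eligible)
    else:
        maternal_agreement = float("nan")
    return {
        "n_planted": len(planted),
        "n_recovered": len(recovered),
        "n_called_recurrent": len(found),
        "recall": recall,
        "precision": precision,
        "maternal_agreement": maternal_agreement,
    }
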