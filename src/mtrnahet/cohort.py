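"""Study-level aggregation of per-sample variant calls.

The study design is paired: each oocyte-cumulus complex (OCC) yields one
single-oocyte sample and one bulk cumulus sample; a mouse contributes one or
more complexes and belongs to one age group. This module implements the
cohort logic built on that design:

* recurrence — a variant (position, alt) is kept for a mouse only when
  detected in at least two of that mouse's samples;
* maternal-origin classification — a recurrent variant is called maternal
  when found in more than one cumulus sample of the mouse (cumulus cells are
  somatic, so sharing across them implies inheritance rather than a de novo
  germline event), with an ``oocyte_detected`` / ``cumulus_only`` split at
  the 1% detection threshold;
* paired oocyte-cumulus heteroplasmy changes (delta = h_oocyte - h_cumulus,
  negative when the cumulus level is higher);
* heteroplasmy-level binning, synonymy/region summaries, and top-variant
  ranking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Literal, Sequence

import pandas as pd

from .calling import FilterConfig, VariantCall
from .reference import NON_CODING, MitoAnnotation

logger = logging.getLogger(__name__)

AGE_GROUPS = ("3wk", "9wk", "12mo")
CELL_TYPES = ("oocyte", "cumulus")

META_COLUMNS = ["sample_id", "mouse_id", "age_group", "cell_type", "complex_id"]

BIN_LABELS = ("(1%,10%)", "[10%,50%]", "(50%,100%]")


class CohortError(ValueError):
    pass


# -- metadata ----------------------------------------------------------------


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Validate the sample table: columns, uniqueness, pairing invariants."""
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise CohortError(f"metadata missing columns {missing}")
    if meta["sample_id"].duplicated().any():
        raise CohortError("duplicate sample_id in metadata")
    bad_age = set(meta["age_group"]) - set(AGE_GROUPS)
    if bad_age:
        raise CohortError(f"unknown age groups {sorted(bad_age)}")
    bad_ct = set(meta["cell_type"]) - set(CELL_TYPES)
    if bad_ct:
        raise CohortError(f"unknown cell types {sorted(bad_ct)}")
    per_complex = meta.groupby(["complex_id", "cell_type"]).size()
    if (per_complex > 1).any():
        raise CohortError("a complex_id maps to more than one sample of a cell type")
    per_mouse_age = meta.groupby("mouse_id")["age_group"].nunique()
    if (per_mouse_age > 1).any():
        raise CohortError("a mouse belongs to more than one age group")
    per_complex_mouse = meta.groupby("complex_id")["mouse_id"].nunique()
    if (per_complex_mouse > 1).any():
        raise CohortError("a complex_id spans more than one mouse")
    return meta


def read_metadata(path: str | Path) -> pd.DataFrame:
    return validate_metadata(pd.read_csv(path, sep="\t", dtype=str))


# -- recurrence and origin ---------------------------------------------------


@dataclass
class RecurrentVariant:
    """A variant detected in >= 2 samples of one mouse."""

    mouse_id: str
    position: int
    ref: str
    alt: str
    per_sample_h: dict[str, float]  # every sample of the mouse; 0.0 = not detected
    n_samples_detected: int
    origin: Literal["maternal", "unclassified"] = "unclassified"
    oocyte_detection: Literal["oocyte_detected", "cumulus_only"] = "cumulus_only"

    @property
    def key(self) -> tuple[int, str]:
        return (self.position, self.alt)


def _calls_frame(calls: Sequence[VariantCall], meta: pd.DataFrame) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {"sample_id": c.sample_id, "pos": c.position, "ref": c.ref,
             "alt": c.alt, "h": c.h}
            for c in calls
        ],
        columns=["sample_id", "pos", "ref", "alt", "h"],
    )
    unknown = set(df["sample_id"]) - set(meta["sample_id"])
    if unknown:
        raise CohortError(f"calls reference unknown sample_ids: {sorted(unknown)}")
    if df.duplicated(["sample_id", "pos", "alt"]).any():
        dup = df[df.duplicated(["sample_id", "pos", "alt"])].iloc[0]
        raise CohortError(
            f"duplicate call record: sample {dup.sample_id} pos {dup.pos} alt {dup.alt}"
        )
    return df.merge(meta, on="sample_id")


def recurrent_variants(
    calls: Sequence[VariantCall],
    meta: pd.DataFrame,
    filters: FilterConfig | None = None,
) -> list[RecurrentVariant]:
    """Variants detected (h >= detection threshold) in >= 2 samples of the
    same mouse; singletons are dropped. Detection never crosses mice."""
    filters = filters or FilterConfig()
    meta = validate_metadata(meta)
    df = _calls_frame(calls, meta)
    df = df[df["h"] >= filters.detection_threshold]
    out: list[RecurrentVariant] = []
    samples_by_mouse = meta.groupby("mouse_id")["sample_id"].apply(list)
    for (mouse, pos, alt), grp in df.groupby(["mouse_id", "pos", "alt"], sort=True):
        if len(grp) < 2:
            continue
        per_sample = {s: 0.0 for s in samples_by_mouse[mouse]}
        per_sample.update(dict(zip(grp["sample_id"], grp["h"])))
        out.append(
            RecurrentVariant(
                mouse_id=mouse,
                position=int(pos),
                ref=grp["ref"].iloc[0],
                alt=alt,
                per_sample_h=per_sample,
                n_samples_detected=len(grp),
            )
        )
    return out


def classify_origin(
    rv: RecurrentVariant,
    meta: pd.DataFrame,
    filters: FilterConfig | None = None,
    maternal_min_cumulus: int = 2,
) -> RecurrentVariant:
    """Set origin and oocyte-detection class on a recurrent variant.

    origin = maternal when the variant is detected in at least
    ``maternal_min_cumulus`` cumulus samples of the mouse (default 2, the
    literal "more than one sample of cumulus cells" rule; 1 admits mice with
    a single complex). oocyte_detection = cumulus_only when no oocyte of the
    mouse reaches the detection threshold.
    """
    filters = filters or FilterConfig()
    if maternal_min_cumulus not in (1, 2):
        raise CohortError("maternal_min_cumulus must be 1 or 2")
    mmeta = meta[meta["mouse_id"] == rv.mouse_id]
    ct = dict(zip(mmeta["sample_id"], mmeta["cell_type"]))
    thr = filters.detection_threshold
    cum_hits = sum(
        1 for s, h in rv.per_sample_h.items() if ct.get(s) == "cumulus" and h >= thr
    )
    ooc_hits = sum(
        1 for s, h in rv.per_sample_h.items() if ct.get(s) == "oocyte" and h >= thr
    )
    n_cumulus = sum(1 for v in ct.values() if v == "cumulus")
    if n_cumulus == 0:
        logger.warning("mouse %s has no cumulus samples; origin unclassified", rv.mouse_id)
        origin = "unclassified"
    else:
        origin = "maternal" if cum_hits >= maternal_min_cumulus else "unclassified"
    return replace(
        rv,
        origin=origin,
        oocyte_detection="oocyte_detected" if ooc_hits > 0 else "cumulus_only",
    )


def classify_origins(
    rvs: Sequence[RecurrentVariant],
    meta: pd.DataFrame,
    filters: FilterConfig | None = None,
    maternal_min_cumulus: int = 2,
) -> list[RecurrentVariant]:
    return [classify_origin(rv, meta, filters, maternal_min_cumulus) for rv in rvs]


# -- paired oocyte-cumulus deltas ---------------------------------------------


@dataclass(frozen=True)
class PairedDelta:
    """Heteroplasmy change within one oocyte-cumulus complex.

    delta = h_oocyte - h_cumulus: negative when the cumulus level is higher
    (the heatmap's blue), positive when the oocyte level is higher (red).
    """

    mouse_id: str
    complex_id: str
    position: int
    ref: str
    alt: str
    h_oocyte: float
    h_cumulus: float

    @property
    def delta(self) -> float:
        return self.h_oocyte - self.h_cumulus


def paired_deltas(
    calls: Sequence[VariantCall],
    meta: pd.DataFrame,
    filters: FilterConfig | None = None,
) -> list[PairedDelta]:
    """One row per (complex, position, alt) where either member is detected;
    the undetected member's h is recorded as 0. Complexes missing a member
    are skipped with a warning."""
    filters = filters or FilterConfig()
    meta = validate_metadata(meta)
    df = _calls_frame(calls, meta)
    df = df[df["h"] >= filters.detection_threshold]
    out: list[PairedDelta] = []
    for complex_id, cmeta in meta.groupby("complex_id", sort=True):
        ct = dict(zip(cmeta["cell_type"], cmeta["sample_id"]))
        if "oocyte" not in ct or "cumulus" not in ct:
            logger.warning("complex %s missing a member; skipped", complex_id)
            continue
        sub = df[df["complex_id"] == complex_id]
        by_sample = {
            s: dict(zip(zip(g["pos"], g["alt"]), zip(g["h"], g["ref"])))
            for s, g in sub.groupby("sample_id")
        }
        ooc = by_sample.get(ct["oocyte"], {})
        cum = by_sample.get(ct["cumulus"], {})
        mouse = cmeta["mouse_id"].iloc[0]
        for pos, alt in sorted(set(ooc) | set(cum)):
            h_o, ref_o = ooc.get((pos, alt), (0.0, None))
            h_c, ref_c = cum.get((pos, alt), (0.0, None))
            out.append(
                PairedDelta(
                    mouse_id=mouse,
                    complex_id=str(complex_id),
                    position=int(pos),
                    ref=ref_o or ref_c,
                    alt=alt,
                    h_oocyte=h_o,
                    h_cumulus=h_c,
                )
            )
    return out


def deltas_to_frame(deltas: Sequence[PairedDelta]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"mouse_id": d.mouse_id, "complex_id": d.complex_id, "pos": d.position,
             "ref": d.ref, "alt": d.alt, "h_oocyte": d.h_oocyte,
             "h_cumulus": d.h_cumulus, "delta": d.delta}
            for d in deltas
        ],
        columns=["mouse_id", "complex_id", "pos", "ref", "alt",
                 "h_oocyte", "h_cumulus", "delta"],
    )


def variant_delta_averages(
    deltas: Sequence[PairedDelta], n_complexes: int
) -> pd.DataFrame:
    """Per-variant mean delta across complexes: ``avg_A`` counts complexes
    where the variant is absent as zero deltas (zeros included); ``avg_B``
    averages only over complexes where the variant was seen."""
    df = deltas_to_frame(deltas)
    if df.empty:
        return pd.DataFrame(columns=["pos", "alt", "avg_A", "avg_B", "n_present"])
    g = df.groupby(["pos", "alt"])["delta"]
    out = g.agg(avg_B="mean", n_present="size").reset_index()
    out["avg_A"] = g.sum().to_numpy() / n_complexes
    return out[["pos", "alt", "avg_A", "avg_B", "n_present"]]


# -- binning and summaries -----------------------------------------------------


def bin_by_level(h_values: Sequence[float], min_af: float = 0.01) -> tuple[int, int, int]:
    """Partition heteroplasmy levels into (below 10%, 10-50%, above 50%).

    Bin edges: [min_af, 0.10) / [0.10, 0.50] / (0.50, 1]. Values below
    min_af should never reach this point and raise.
    """
    low = mid = high = 0
    for h in h_values:
        if h < min_af or h > 1:
            raise CohortError(f"heteroplasmy {h} outside [{min_af}, 1]")
        if h < 0.10:
            low += 1
        elif h <= 0.50:
            mid += 1
        else:
            high += 1
    return (low, mid, high)


def bin_label(h: float, min_af: float = 0.01) -> str:
    i = [i for i, n in enumerate(bin_by_level([h], min_af)) if n][0]
    return BIN_LABELS[i]


def synonymy_summary(
    rvs: Sequence[RecurrentVariant],
    ann: MitoAnnotation,
    meta: pd.DataFrame,
    min_af: float = 0.01,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Count coding recurrent variants by (cell_type, heteroplasmy bin,
    synonymy class); each variant counts once per cell type in which it is
    detected, at that cell type's maximum h.

    Returns (synonymy table, companion region summary of ALL recurrent
    variants by region class).
    """
    ct_of = dict(zip(meta["sample_id"], meta["cell_type"]))
    rows = []
    region_counts: dict[str, int] = {}
    for rv in rvs:
        region = ann.locate(rv.position).region_class
        region_counts[region] = region_counts.get(region, 0) + 1
        syn = ann.classify_substitution(rv.position, rv.alt)
        if syn == NON_CODING:
            continue
        for cell_type in CELL_TYPES:
            hs = [
                h for s, h in rv.per_sample_h.items()
                if ct_of.get(s) == cell_type and h > 0
            ]
            if hs:
                rows.append(
                    {"cell_type": cell_type, "bin": bin_label(max(hs), min_af),
                     "synonymy": syn}
                )
    index = pd.MultiIndex.from_product(
        [CELL_TYPES, BIN_LABELS, ["synonymous", "non_synonymous"]],
        names=["cell_type", "bin", "synonymy"],
    )
    counts = pd.Series(0, index=index, dtype=int)
    for r in rows:
        counts.loc[(r["cell_type"], r["bin"], r["synonymy"])] += 1
    syn_table = counts.rename("count").reset_index()
    region_table = pd.DataFrame(
        sorted(region_counts.items()), columns=["region_class", "count"]
    )
    return syn_table, region_table


def top_variants(
    rvs: Sequence[RecurrentVariant],
    k: int,
    criterion: Literal["mean_h", "mean_abs_delta"] = "mean_h",
    meta: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Rank variants (position, alt) across the study.

    ``mean_h`` averages detected (non-zero) per-sample levels; it selects the
    variants with the highest average heteroplasmy. ``mean_abs_delta``
    averages |h_oocyte - h_cumulus| over complete complexes where the variant
    is present, and needs ``meta``; it selects the variants with the greatest
    oocyte-cumulus change. Ties break by (position, alt).
    """
    if k < 1:
        raise CohortError("k must be >= 1")
    scores: dict[tuple[int, str], list[float]] = {}
    if criterion == "mean_h":
        for rv in rvs:
            vals = [h for h in rv.per_sample_h.values() if h > 0]
            scores.setdefault(rv.key, []).extend(vals)
    elif criterion == "mean_abs_delta":
        if meta is None:
            raise CohortError("mean_abs_delta ranking requires the metadata table")
        ct_of = dict(zip(meta["sample_id"], meta["cell_type"]))
        cx_of = dict(zip(meta["sample_id"], meta["complex_id"]))
        for rv in rvs:
            per_cx: dict[str, dict[str, float]] = {}
            for s, h in rv.per_sample_h.items():
                per_cx.setdefault(cx_of[s], {})[ct_of[s]] = h
            for members in per_cx.values():
                if {"oocyte", "cumulus"} <= set(members):
                    h_o, h_c = members["oocyte"], members["cumulus"]
                    if h_o > 0 or h_c > 0:
                        scores.setdefault(rv.key, []).append(abs(h_o - h_c))
    else:
        raise CohortError(f"unknown criterion {criterion!r}")
    rows = [
        {"pos": pos, "alt": alt, "score": sum(v) / len(v), "n": len(v)}
        for (pos, alt), v in scores.items()
        if v
    ]
    df = pd.DataFrame(rows, columns=["pos", "alt", "score", "n"])
    df = df.sort_values(["score", "pos", "alt"], ascending=[False, True, True])
    if k > len(df):
        logger.info("k=%d exceeds %d ranked variants; returning all", k, len(df))
    return df.head(k).reset_index(drop=True)


def recurrent_to_frame(rvs: Sequence[RecurrentVariant]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"mouse_id": rv.mouse_id, "pos": rv.position, "ref": rv.ref,
             "alt": rv.alt, "n_samples_detected": rv.n_samples_detected,
             "origin": rv.origin, "oocyte_detection": rv.oocyte_detection,
             "max_h": max(rv.per_sample_h.values())}
            for rv in rvs
        ],
        columns=["mouse_id", "pos", "ref", "alt", "n_samples_detected",
                 "origin", "oocyte_detection", "max_h"],
    )
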