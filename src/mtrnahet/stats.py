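"""Statistical layer: ANOVA with Holm-Sidak correction, paired t-tests,
linear fits, sister-sample coefficient of variation, D-loop cumulative
frequency curves.

Conventions: sample standard deviation (n-1 denominator) throughout,
two-sided p-values, F and t distributions via scipy. The Holm-Sidak
step-down adjustment is implemented directly from its defining transform
1 - (1 - p)^(m - i + 1) with running-maximum monotonicity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .calling import FilterConfig, VariantCall
from .cohort import AGE_GROUPS, CELL_TYPES, _calls_frame, validate_metadata
from .reference import MitoAnnotation

logger = logging.getLogger(__name__)


class StatsError(ValueError):
    pass


@dataclass
class StatResult:
    method: str
    statistic: float
    df: float | tuple[float, float]
    p_raw: float
    p_adjusted: float | None = None
    extras: dict = field(default_factory=dict)


def one_way_anova(groups: Sequence[Sequence[float]]) -> StatResult:
    """Classical one-way fixed-effects ANOVA across k groups."""
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2 or any(len(a) < 2 for a in arrs):
        raise StatsError("need >= 2 groups with >= 2 values each")
    pooled = np.concatenate(arrs)
    if np.ptp(pooled) == 0:
        raise StatsError("degenerate input: all values identical")
    f, p = sps.f_oneway(*arrs)
    k, n = len(arrs), len(pooled)
    return StatResult("one_way_anova", float(f), (k - 1, n - k), float(p),
                      extras={"n": n, "k": k})


def holm_sidak(p_raw: Sequence[float]) -> list[float]:
    """Holm-Sidak step-down adjusted p-values, returned in input order.

    Sorted ascending, adjusted_(i) = 1 - (1 - p_(i))^(m - i + 1) with a
    running maximum so adjusted values never decrease along the sorted order;
    clipped to <= 1.
    """
    p = np.asarray(p_raw, dtype=float)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise StatsError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        step = 1.0 - (1.0 - p[idx]) ** (m - rank)
        running = max(running, step)
        adj[idx] = min(running, 1.0)
    return adj.tolist()


def paired_t(pairs: Sequence[tuple[float, float]]) -> StatResult:
    """Two-sided paired-sample t-test on (x, y) pairs; t > 0 when x > y."""
    if len(pairs) < 2:
        raise StatsError("need >= 2 pairs")
    x = np.array([a for a, _ in pairs], dtype=float)
    y = np.array([b for _, b in pairs], dtype=float)
    d = x - y
    if np.all(d == 0):
        raise StatsError("degenerate input: all paired differences are zero")
    t, p = sps.ttest_rel(x, y)
    return StatResult("paired_t", float(t), len(pairs) - 1, float(p),
                      extras={"n": len(pairs), "mean_diff": float(d.mean())})


def linear_fit(x: Sequence[float], y: Sequence[float]) -> StatResult:
    """Ordinary least squares y ~ x with R^2 and a two-sided slope test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise StatsError("need >= 3 paired observations")
    if np.ptp(x) == 0:
        raise StatsError("constant x: slope undefined")
    if np.ptp(y) == 0:
        # flat response: slope 0, no explained variance
        return StatResult("linear_fit", 0.0, len(x) - 2, 1.0,
                          extras={"r_squared": 0.0, "intercept": float(y[0]),
                                  "n": len(x)})
    fit = sps.linregress(x, y)
    return StatResult(
        "linear_fit", float(fit.slope), len(x) - 2, float(fit.pvalue),
        extras={"r_squared": float(fit.rvalue ** 2),
                "intercept": float(fit.intercept), "n": len(x)},
    )


# -- study-level wrappers ------------------------------------------------------


def age_group_comparison(
    calls: Sequence[VariantCall],
    meta: pd.DataFrame,
    filters: FilterConfig | None = None,
) -> pd.DataFrame:
    """Per cell type: pooled variant heteroplasmy levels by age group, an
    omnibus one-way ANOVA, and all pairwise age comparisons corrected with
    Holm-Sidak (one correction family per cell type)."""
    filters = filters or FilterConfig()
    meta = validate_metadata(meta)
    df = _calls_frame(calls, meta)
    rows = []
    for cell_type in CELL_TYPES:
        sub = df[df["cell_type"] == cell_type]
        groups = {g: sub.loc[sub["age_group"] == g, "h"].to_numpy() for g in AGE_GROUPS}
        usable = {g: v for g, v in groups.items() if len(v) >= 2}
        if len(usable) < 2:
            logger.warning("%s: fewer than two age groups with data; ANOVA skipped",
                           cell_type)
            continue
        try:
            omni = one_way_anova(list(usable.values()))
        except StatsError as exc:
            logger.warning("%s: ANOVA degenerate (%s); skipped", cell_type, exc)
            continue
        rows.append({"cell_type": cell_type, "comparison": "omnibus",
                     "method": "one_way_anova", "statistic": omni.statistic,
                     "df": str(omni.df), "p_raw": omni.p_raw, "p_adjusted": None,
                     "family_id": cell_type})
        names = list(usable)
        pair_rows = []
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                res = one_way_anova([usable[names[i]], usable[names[j]]])
                pair_rows.append((f"{names[i]}_vs_{names[j]}", res))
        adj = holm_sidak([r.p_raw for _, r in pair_rows])
        for (name, res), pa in zip(pair_rows, adj):
            rows.append({"cell_type": cell_type, "comparison": name,
                         "method": "one_way_anova", "statistic": res.statistic,
                         "df": str(res.df), "p_raw": res.p_raw, "p_adjusted": pa,
                         "family_id": cell_type})
    return pd.DataFrame(rows, columns=["cell_type", "comparison", "method",
                                       "statistic", "df", "p_raw", "p_adjusted",
                                       "family_id"])


def sister_cv(
    calls: Sequence[VariantCall],
    meta: pd.DataFrame,
    cell_type: str,
    filters: FilterConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Heteroplasmy dispersion between sister samples of one cell type.

    For each mouse with >= 2 samples of ``cell_type``, every variant detected
    in at least two of those sister samples contributes
    CV = sd(h) / mean(h) across all the sisters (undetected sisters count as
    h = 0). Returns (per-mouse table: mean CV over variants, per-age-group
    table: mean over mice).
    """
    filters = filters or FilterConfig()
    meta = validate_metadata(meta)
    df = _calls_frame(calls, meta)
    df = df[(df["cell_type"] == cell_type) & (df["h"] >= filters.detection_threshold)]
    mouse_rows = []
    for mouse, mmeta in meta[meta["cell_type"] == cell_type].groupby("mouse_id"):
        sisters = list(mmeta["sample_id"])
        if len(sisters) < 2:
            logger.warning("mouse %s has < 2 %s samples; skipped", mouse, cell_type)
            continue
        sub = df[df["mouse_id"] == mouse]
        cvs = []
        for (pos, alt), grp in sub.groupby(["pos", "alt"]):
            if len(grp) < 2:
                continue  # shared = detected in >= 2 sisters
            h = np.zeros(len(sisters))
            lookup = dict(zip(grp["sample_id"], grp["h"]))
            for i, s in enumerate(sisters):
                h[i] = lookup.get(s, 0.0)
            mean = h.mean()
            if mean == 0:
                logger.warning("variant %d%s of mouse %s has zero mean; skipped",
                               pos, alt, mouse)
                continue
            cvs.append(h.std(ddof=1) / mean)
        if cvs:
            mouse_rows.append({"mouse_id": mouse,
                               "age_group": mmeta["age_group"].iloc[0],
                               "n_variants": len(cvs),
                               "mean_cv": float(np.mean(cvs))})
    per_mouse = pd.DataFrame(mouse_rows,
                             columns=["mouse_id", "age_group", "n_variants", "mean_cv"])
    if per_mouse.empty:
        per_age = pd.DataFrame(columns=["age_group", "n_mice", "mean_cv"])
    else:
        per_age = (per_mouse.groupby("age_group", sort=False)["mean_cv"]
                   .agg(n_mice="size", mean_cv="mean").reset_index())
    return per_mouse, per_age


def dloop_cumulative(
    calls: Sequence[VariantCall],
    meta: pd.DataFrame,
    ann: MitoAnnotation,
    thresholds: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Cumulative D-loop variant counts by (age group, cell type).

    For each group the value at threshold x is the number of D-loop variant
    observations with h >= x; curves are non-increasing in x and start at the
    group's total D-loop variant count. Long format: age_group, cell_type,
    threshold, count.
    """
    meta = validate_metadata(meta)
    try:
        dloop = next(f for f in ann.features if f.ftype == "D_loop")
    except StopIteration:
        raise StatsError("annotation has no D_loop feature") from None
    if thresholds is None:
        thresholds = np.round(np.arange(0.01, 1.0001, 0.01), 6)
    df = _calls_frame(calls, meta)
    df = df[(df["pos"] >= dloop.start) & (df["pos"] <= dloop.end)]
    rows = []
    for age in AGE_GROUPS:
        for cell_type in CELL_TYPES:
            h = df.loc[(df["age_group"] == age) & (df["cell_type"] == cell_type),
                       "h"].to_numpy()
            for x in thresholds:
                rows.append({"age_group": age, "cell_type": cell_type,
                             "threshold": float(x), "count": int((h >= x).sum())})
    return pd.DataFrame(rows, columns=["age_group", "cell_type", "threshold", "count"])


def oocyte_cumulus_fit(deltas_frame: pd.DataFrame) -> StatResult:
    """Linear fit of cumulus heteroplasmy on oocyte heteroplasmy over variants
    found in BOTH members of a complex."""
    both = deltas_frame[(deltas_frame["h_oocyte"] > 0) & (deltas_frame["h_cumulus"] > 0)]
    return linear_fit(both["h_oocyte"].to_numpy(), both["h_cumulus"].to_numpy())
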