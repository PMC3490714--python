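"""Morphometric statistics for chloroplast and starch-granule measurements.

Shape is summarized by circularity, 4*pi*area/perimeter^2 — exactly 1 for
a circle and approaching 0 for elongated outlines (the isoperimetric
inequality bounds it above by 1 for any simple closed curve).  Group
differences between plant lines are tested with the Mann–Whitney U
statistic: exact by full enumeration of label assignments for small
pooled samples (midranks handle ties), and by the tie- and
continuity-corrected normal approximation otherwise.  Relative mean ranks
accompany the tests as the effect summary, and granule counts per
chloroplast are summarized as per-line histograms and windowed shares.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "circularity",
    "mann_whitney_u",
    "relative_mean_ranks",
    "count_distribution",
    "morphology_report",
]


def circularity(area, perimeter):
    """Circularity = 4*pi*area / perimeter^2, in (0, 1] for simple shapes.

    Values a hair above 1 from measurement round-off are clamped to 1.
    """
    area = np.asarray(area, dtype=float)
    perimeter = np.asarray(perimeter, dtype=float)
    if np.any(area <= 0) or np.any(perimeter <= 0):
        raise ValueError("area and perimeter must be positive")
    c = 4.0 * np.pi * area / perimeter**2
    c = np.minimum(c, 1.0)
    return float(c) if c.ndim == 0 else c


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for sample x from midrank sums: U = R_x - n_x(n_x+1)/2."""
    nx = len(x)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)  # midranks
    return float(ranks[:nx].sum() - nx * (nx + 1) / 2.0)


def _exact_p(x: np.ndarray, y: np.ndarray, u_obs: float) -> float:
    """Two-sided exact p by full enumeration of label assignments.

    p = P(|U - n_x n_y / 2| >= |u_obs - n_x n_y / 2|) under the null that
    every assignment of pooled values to the two groups is equally likely.
    Handles ties via midranks.
    """
    nx, ny = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n = nx + ny
    mu = nx * ny / 2.0
    obs_dev = abs(u_obs - mu) - 1e-12  # tolerance for midrank float round-off
    hits = 0
    base = nx * (nx + 1) / 2.0
    for idx in combinations(range(n), nx):
        u = ranks[list(idx)].sum() - base
        if abs(u - mu) >= obs_dev:
            hits += 1
    return hits / comb(n, nx)


def _approx_p(x: np.ndarray, y: np.ndarray, u_obs: float) -> float:
    """Normal approximation with tie correction and continuity correction."""
    nx, ny = len(x), len(y)
    n = nx + ny
    pooled = np.concatenate([x, y])
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (n * (n - 1)) if n > 1 else 0.0
    var = nx * ny / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return 1.0
    mu = nx * ny / 2.0
    z = (abs(u_obs - mu) - 0.5) / np.sqrt(var)
    return float(min(1.0, 2.0 * stats.norm.sf(max(z, 0.0))))


def mann_whitney_u(x, y, mode: str = "auto", exact_max_n: int = 12) -> tuple[float, float]:
    """Mann–Whitney U and two-sided p-value.

    ``mode`` is ``exact`` (full enumeration), ``approx`` (corrected normal
    approximation), or ``auto`` (exact when the pooled size is at most
    ``exact_max_n``).  Returns (U for sample x, two-sided p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    u = _u_statistic(x, y)
    if mode == "auto":
        mode = "exact" if x.size + y.size <= exact_max_n else "approx"
    if mode == "exact":
        return u, _exact_p(x, y, u)
    if mode == "approx":
        return u, _approx_p(x, y, u)
    raise ValueError(f"unknown mode: {mode!r}")


def relative_mean_ranks(x, y) -> tuple[float, float]:
    """Mean pooled midrank of each group.

    Satisfies mean_rank_x * n_x + mean_rank_y * n_y = N(N+1)/2.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    ranks = stats.rankdata(np.concatenate([x, y]))
    return float(ranks[: x.size].mean()), float(ranks[x.size :].mean())


def count_distribution(
    table: pd.DataFrame,
    window: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Per-line granule-count histogram, windowed share, and size trend.

    Operates on chloroplast rows with a ``granule_count`` column.  Returns
    one row per (line_label, granule_count) with the normalized frequency,
    the share of chloroplasts whose count falls in ``window`` (inclusive),
    and — when an ``area`` column is present — the mean chloroplast area
    at that count (the granule-number vs chloroplast-size relationship).
    """
    rows = table.loc[table["object_class"] == "chloroplast"] if "object_class" in table else table
    if "granule_count" not in rows.columns:
        raise ValueError("granule_count column required")
    out = []
    for line, grp in rows.groupby("line_label"):
        counts = grp["granule_count"].astype(int)
        total = len(counts)
        share = float("nan")
        if window is not None:
            lo, hi = window
            share = ((counts >= lo) & (counts <= hi)).sum() / total
        for c, n in counts.value_counts().sort_index().items():
            mean_area = (
                float(grp.loc[counts == c, "area"].mean()) if "area" in grp.columns else float("nan")
            )
            out.append(
                {
                    "line_label": line,
                    "granule_count": int(c),
                    "n_chloroplasts": int(n),
                    "frequency": n / total,
                    "window_share": share,
                    "mean_area": mean_area,
                }
            )
    return pd.DataFrame(out)


def morphology_report(
    table: pd.DataFrame,
    reference_line: str,
    measures: tuple[str, ...] = ("area", "width", "height", "circularity"),
    mode: str = "auto",
    exact_max_n: int = 12,
) -> pd.DataFrame:
    """Line-vs-reference Mann–Whitney comparisons per object class.

    For each non-reference line, object class, and measure, reports the
    relative mean ranks of the two groups, U, and the two-sided p-value —
    the layout of a morphometric comparison table.
    """
    if "circularity" in measures and "circularity" not in table.columns:
        table = table.copy()
        table["circularity"] = circularity(
            table["area"].to_numpy(), table["perimeter"].to_numpy()
        )
    lines = [l for l in table["line_label"].unique() if l != reference_line]
    rows = []
    for cls, cls_rows in table.groupby("object_class"):
        ref = cls_rows.loc[cls_rows["line_label"] == reference_line]
        for line in lines:
            other = cls_rows.loc[cls_rows["line_label"] == line]
            if ref.empty or other.empty:
                continue
            for m in measures:
                if m not in cls_rows.columns:
                    continue
                x = other[m].dropna().to_numpy()
                y = ref[m].dropna().to_numpy()
                if x.size == 0 or y.size == 0:
                    continue
                u, p = mann_whitney_u(x, y, mode=mode, exact_max_n=exact_max_n)
                mr_x, mr_y = relative_mean_ranks(x, y)
                rows.append(
                    {
                        "object_class": cls,
                        "line_label": line,
                        "measure": m,
                        "mean_rank_line": mr_x,
                        "mean_rank_reference": mr_y,
                        "U": u,
                        "p_value": p,
                    }
                )
    return pd.DataFrame(rows)
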