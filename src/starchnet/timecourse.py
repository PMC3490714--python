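"""Time-course differential expression by nested spline-model comparison.

Each gene's diurnal profile is tested against the null hypothesis of a flat
line.  The alternative fits a natural cubic spline of the sampling times;
the two fits are compared by an F-statistic and per-gene significance is
obtained either by permuting array labels (default, robust at n ~ 10) or
from the parametric F distribution.  Multiple testing is handled with
Storey-style q-values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SplineBasis",
    "build_spline_basis",
    "fit_flat_vs_spline",
    "f_statistic",
    "de_pvalues",
    "parametric_pvalues",
    "qvalues",
    "run_de",
]


@dataclass
class SplineBasis:
    """Natural cubic spline design matrix over the sampling times.

    ``design`` has shape (n_arrays, df + 1): a constant intercept column
    followed by ``df`` centered natural-spline basis columns with zero
    second derivatives beyond the boundary knots.
    """

    timepoints: np.ndarray
    df: int
    design: np.ndarray


def _natural_spline_columns(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    # truncated-power natural cubic basis: x plus K-2 curvature terms
    K = len(knots)
    xk = knots

    def d(k: int) -> np.ndarray:
        num = np.maximum(x - xk[k], 0.0) ** 3 - np.maximum(x - xk[K - 1], 0.0) ** 3
        return num / (xk[K - 1] - xk[k])

    cols = [x]
    dK2 = d(K - 2)
    for k in range(K - 2):
        cols.append(d(k) - dK2)
    return np.column_stack(cols)


def build_spline_basis(time_h: np.ndarray, df: int = 3) -> SplineBasis:
    """Build the (arrays x df+1) natural cubic spline design.

    Knots sit at ``df + 1`` quantiles of the distinct timepoints, so a
    basis of dimension ``df`` (plus intercept) results.  Requires at least
    ``df + 2`` distinct timepoints so the design has full column rank.
    """
    time_h = np.asarray(time_h, dtype=float)
    distinct = np.unique(time_h)
    if distinct.size < 2:
        raise ValueError("no temporal variation: all timepoints identical")
    if df < 1:
        raise ValueError("df must be >= 1")
    if distinct.size < df + 2:
        raise ValueError(
            f"df={df} too large for {distinct.size} distinct timepoints "
            f"(need at least df+2)"
        )
    n_knots = df + 1
    quantiles = np.linspace(0.0, 1.0, n_knots)
    knots = np.quantile(distinct, quantiles)
    knots = np.unique(knots)
    if knots.size < n_knots:  # quantile collisions on small grids
        knots = np.linspace(distinct.min(), distinct.max(), n_knots)
    if df == 1:
        cols = time_h[:, None].astype(float).copy()
    else:
        cols = _natural_spline_columns(time_h, knots)
    cols = cols - cols.mean(axis=0, keepdims=True)
    design = np.column_stack([np.ones(len(time_h)), cols])
    return SplineBasis(timepoints=time_h, df=design.shape[1] - 1, design=design)


def fit_flat_vs_spline(y: np.ndarray, basis: SplineBasis) -> tuple[float, float]:
    """Residual sums of squares under the flat-line and spline models."""
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("expression values must be finite")
    if y.shape[0] != basis.design.shape[0]:
        raise ValueError("profile length does not match design rows")
    rss_null = float(np.sum((y - y.mean()) ** 2))
    coef, _, _, _ = np.linalg.lstsq(basis.design, y, rcond=None)
    resid = y - basis.design @ coef
    rss_alt = float(resid @ resid)
    # lstsq noise can leave rss_alt a hair above rss_null on flat profiles
    return rss_null, min(rss_alt, rss_null)


def f_statistic(rss_null: float, rss_alt: float, n: int, df: int) -> float:
    """F = ((rss0 - rss1)/df) / (rss1/(n - df - 1)); inf on a perfect fit."""
    if n <= df + 1:
        raise ValueError(f"need n > df+1 (got n={n}, df={df})")
    if rss_alt <= 0.0:
        return 0.0 if rss_null <= 0.0 else float("inf")
    f = ((rss_null - rss_alt) / df) / (rss_alt / (n - df - 1))
    return max(f, 0.0)


def _rss_matrix(Y: np.ndarray, design: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-row RSS under the flat and spline models."""
    centered = Y - Y.mean(axis=1, keepdims=True)
    rss_null = np.sum(centered**2, axis=1)
    Q, _ = np.linalg.qr(design)
    proj = centered @ Q  # intercept column absorbs the mean
    rss_alt = np.maximum(rss_null - np.sum(proj**2, axis=1), 0.0)
    return rss_null, rss_alt


def f_statistics_matrix(Y: np.ndarray, basis: SplineBasis) -> np.ndarray:
    """Per-gene F-statistics for a genes x arrays matrix."""
    n = Y.shape[1]
    df = basis.df
    rss_null, rss_alt = _rss_matrix(Y, basis.design)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ((rss_null - rss_alt) / df) / (rss_alt / (n - df - 1))
    f = np.where(rss_alt <= 1e-300, np.where(rss_null > 1e-300, np.inf, 0.0), f)
    return np.maximum(np.nan_to_num(f, nan=0.0, posinf=np.inf), 0.0)


def de_pvalues(
    f_stats: np.ndarray,
    Y: np.ndarray,
    basis: SplineBasis,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Permutation p-values: shuffle array labels identically across genes.

    p = (1 + #{permuted F >= observed F}) / (1 + n_perm), so the smallest
    attainable p-value is 1/(1 + n_perm).  Zero-variance genes get p = 1.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    f_stats = np.asarray(f_stats, dtype=float)
    n = Y.shape[1]
    exceed = np.zeros(len(f_stats), dtype=np.int64)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        f_perm = f_statistics_matrix(Y[:, perm], basis)
        exceed += f_perm >= f_stats
    p = (1.0 + exceed) / (1.0 + n_perm)
    flat = np.sum((Y - Y.mean(axis=1, keepdims=True)) ** 2, axis=1) <= 1e-300
    p[flat] = 1.0
    return p


def parametric_pvalues(f_stats: np.ndarray, n: int, df: int) -> np.ndarray:
    """p-values from the F(df, n-df-1) reference distribution."""
    f_stats = np.asarray(f_stats, dtype=float)
    p = stats.f.sf(f_stats, df, n - df - 1)
    return np.where(np.isinf(f_stats), 0.0, p)


def qvalues(p: np.ndarray, pi0: float | None = None, lambda_: float = 0.5) -> np.ndarray:
    """Storey-style q-values with the single-lambda pi0 plug-in.

    pi0 is estimated as #{p > lambda} / (m (1 - lambda)), clamped to (0, 1];
    pass ``pi0=1.0`` to recover Benjamini–Hochberg.  q-values are the
    monotone step-up transform of pi0 * m * p / rank.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if pi0 is None:
        pi0 = np.sum(p > lambda_) / (m * (1.0 - lambda_))
        pi0 = min(max(pi0, 1.0 / m), 1.0)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * pi0 * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def run_de(
    matrix,
    df: int = 3,
    n_perm: int = 1000,
    seed: int = 0,
    q_threshold: float = 0.01,
    mode: str = "permutation",
) -> pd.DataFrame:
    """Full DE pass over an ExpressionMatrix.

    Returns a table with gene_id, rss_null, rss_alt, f_stat, p_value,
    q_value and the significance call at ``q_threshold``.
    """
    basis = build_spline_basis(matrix.absolute_time_h(), df=df)
    Y = matrix.values
    rss_null, rss_alt = _rss_matrix(Y, basis.design)
    f = f_statistics_matrix(Y, basis)
    if mode == "permutation":
        p = de_pvalues(f, Y, basis, n_perm=n_perm, seed=seed)
    elif mode == "parametric":
        p = parametric_pvalues(f, matrix.n_arrays, basis.df)
    else:
        raise ValueError(f"unknown p-value mode: {mode!r}")
    q = qvalues(p)
    return pd.DataFrame(
        {
            "gene_id": matrix.gene_ids,
            "rss_null": rss_null,
            "rss_alt": rss_alt,
            "f_stat": f,
            "p_value": p,
            "q_value": q,
            "significant": q <= q_threshold,
        }
    )
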