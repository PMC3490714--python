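"""Candidate-regulator refinement from condition-independent co-expression.

Regulator-target edges surviving the network stage are ranked against a
compendium of condition-independent correlations (an ATTED-style table):
for each target, regulators are sorted by correlation and given
competition ranks overall, among regulators, and within their family.  A
candidate passes the co-expression cutoff when its correlation exceeds
the regulator-population mean with the configured one-sided confidence
(97.5% by default), treating the population as normal.  A temporal
precedence filter then removes regulators whose diurnal peak follows
their target's — a regulator must be expressed at the same time as, or
earlier than, its target.  Binding-site support enters as an annotation
join, never as a hard filter.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "competition_ranks",
    "rank_regulators",
    "ttest_cutoff",
    "precedence_filter",
    "annotate_binding_support",
    "select_final_candidates",
    "build_candidate_report",
]


def competition_ranks(values: np.ndarray) -> np.ndarray:
    """Descending competition ranking: ties share the smaller rank ("1224")."""
    values = np.asarray(values, dtype=float)
    order = np.argsort(-values, kind="mergesort")
    ranks = np.empty(len(values), dtype=int)
    prev_val, prev_rank = None, 0
    for pos, idx in enumerate(order, start=1):
        if prev_val is not None and values[idx] == prev_val:
            ranks[idx] = prev_rank
        else:
            ranks[idx] = pos
            prev_rank, prev_val = pos, values[idx]
    return ranks


def rank_regulators(compendium: pd.DataFrame, target: str) -> pd.DataFrame:
    """Rank all regulators of one target by compendium correlation.

    Returns one row per regulator with rank_all_regulators and, when a
    ``family`` column is present, rank_in_family.  Raises if the target is
    absent from the table.
    """
    sub = compendium.loc[compendium["target_gene"] == target].copy()
    if sub.empty:
        raise KeyError(f"target {target!r} not in compendium")
    sub = sub.reset_index(drop=True)
    corr = sub["correlation"].to_numpy(dtype=float)
    sub["rank_all_regulators"] = competition_ranks(corr)
    if "family" in sub.columns:
        sub["rank_in_family"] = 0
        for fam, idx in sub.groupby("family").groups.items():
            idx = list(idx)
            sub.loc[idx, "rank_in_family"] = competition_ranks(corr[idx])
        sub["family_size"] = sub.groupby("family")["regulator_gene"].transform("size")
    return sub.sort_values("rank_all_regulators").reset_index(drop=True)


def ttest_cutoff(
    population: np.ndarray,
    candidate_value: float,
    confidence: float = 0.975,
    leave_one_out: bool = True,
) -> bool:
    """One-sided population-mean cutoff for a candidate correlation.

    Passes iff candidate > mean + t_{confidence, n-1} * sd, with mean/sd of
    the (assumed normal) population of regulator-target correlations.  By
    default the candidate's own value is excluded from the population
    statistics so the nominal tail probability is preserved.
    """
    pop = np.asarray(population, dtype=float)
    if leave_one_out:
        match = np.nonzero(np.isclose(pop, candidate_value))[0]
        if match.size:
            pop = np.delete(pop, match[0])
    if pop.size < 3:
        raise ValueError("population must have at least 3 values")
    if not 0.5 < confidence < 1.0:
        raise ValueError("confidence must be in (0.5, 1)")
    sd = pop.std(ddof=1)
    if sd <= 1e-12 * max(1.0, abs(float(pop.mean()))):
        raise ValueError("zero-variance population")
    t = stats.t.ppf(confidence, pop.size - 1)
    return bool(candidate_value > pop.mean() + t * sd)


def _circular_peak_lag(reg: np.ndarray, target: np.ndarray) -> int:
    """Signed circular lag (in grid steps) maximizing cross-correlation.

    Positive lag means the regulator's profile is delayed relative to the
    target's; the shorter signed direction around the cycle is reported.
    """
    n = len(reg)
    reg_z = reg - reg.mean()
    tar_z = target - target.mean()
    scores = np.array([float(np.dot(np.roll(reg_z, -lag), tar_z)) for lag in range(n)])
    best = int(np.argmax(scores))
    return best - n if best > n // 2 else best


def precedence_filter(
    reg_profile: np.ndarray,
    target_profile: np.ndarray,
    phase: list[str] | None = None,
) -> bool:
    """Temporal precedence: regulator peaks at or before its target.

    The lag is estimated by circular cross-correlation on the shared
    diurnal grid; the candidate passes when the regulator's peak is
    simultaneous or earlier (lag <= 0 after unrolling the 24-h cycle in
    the shorter signed direction).  Flat profiles pass with a warning.
    """
    reg = np.asarray(reg_profile, dtype=float)
    tar = np.asarray(target_profile, dtype=float)
    if reg.shape != tar.shape:
        raise ValueError("profiles must share the same time grid")
    if reg.std() <= 1e-300 or tar.std() <= 1e-300:
        logger.warning("flat profile in precedence filter; passing by default")
        return True
    return _circular_peak_lag(reg, tar) <= 0


def annotate_binding_support(report: pd.DataFrame, binding_table: pd.DataFrame | None) -> pd.DataFrame:
    """Join Y/N binding-site evidence by (regulator family, target gene).

    Pairs absent from the table get ``NA`` — evidence unknown, not absent.
    """
    report = report.copy()
    if binding_table is None or binding_table.empty:
        report["binding_support"] = "NA"
        return report
    key = {(row["family"], row["target_gene"]): row["present"] for _, row in binding_table.iterrows()}
    report["binding_support"] = [
        key.get((row.get("family", ""), row["target_gene"]), "NA") for _, row in report.iterrows()
    ]
    return report


def select_final_candidates(report: pd.DataFrame) -> pd.DataFrame:
    """Keep rows passing both the co-expression cutoff and precedence.

    Binding support is retained as evidence but never required — lack of
    a known site does not disqualify a candidate.
    """
    mask = report["passes_ttest"] & report["passes_precedence"]
    return report.loc[mask].reset_index(drop=True)


def build_candidate_report(
    edges: pd.DataFrame,
    annotation: pd.DataFrame,
    compendium: pd.DataFrame,
    matrix=None,
    binding_table: pd.DataFrame | None = None,
    confidence: float = 0.975,
) -> pd.DataFrame:
    """Assemble the per-candidate evidence table for regulator-target edges.

    ``edges`` is an edge table (gene_a, gene_b, ...); regulator-target
    pairs are identified via the annotation roles, looked up in the
    compendium for correlation and ranks, tested against the population
    cutoff, and — when the expression matrix is supplied — passed through
    the precedence filter.  Binding-site support is joined last.
    """
    roles = dict(zip(annotation["gene_id"], annotation["role"]))
    families = dict(zip(annotation["gene_id"], annotation.get("family", "")))
    comp = compendium.set_index(["regulator_gene", "target_gene"])

    gene_index = {g: i for i, g in enumerate(matrix.gene_ids)} if matrix is not None else {}
    rank_cache: dict[str, pd.DataFrame] = {}
    rows = []
    for _, edge in edges.iterrows():
        a, b = edge["gene_a"], edge["gene_b"]
        ra, rb = roles.get(a), roles.get(b)
        if ra in ("regulator", "clock") and rb == "target":
            reg, tgt = a, b
        elif rb in ("regulator", "clock") and ra == "target":
            reg, tgt = b, a
        else:
            continue
        if (reg, tgt) not in comp.index:
            logger.warning("pair (%s, %s) missing from compendium; skipped", reg, tgt)
            continue
        corr = float(comp.loc[(reg, tgt), "correlation"])
        if tgt not in rank_cache:
            rank_cache[tgt] = rank_regulators(compendium, tgt)
        ranked = rank_cache[tgt]
        row = ranked.loc[ranked["regulator_gene"] == reg].iloc[0]
        population = ranked["correlation"].to_numpy(dtype=float)
        passes_t = ttest_cutoff(population, corr, confidence=confidence)
        if matrix is not None and reg in gene_index and tgt in gene_index:
            passes_prec = precedence_filter(
                matrix.values[gene_index[reg]], matrix.values[gene_index[tgt]]
            )
        else:
            passes_prec = True
        rows.append(
            {
                "target_gene": tgt,
                "regulator_gene": reg,
                "family": families.get(reg, ""),
                "correlation": corr,
                "rank_all_regulators": int(row["rank_all_regulators"]),
                "rank_in_family": int(row.get("rank_in_family", 0)),
                "passes_ttest": passes_t,
                "passes_precedence": passes_prec,
            }
        )
    report = pd.DataFrame(
        rows,
        columns=[
            "target_gene",
            "regulator_gene",
            "family",
            "correlation",
            "rank_all_regulators",
            "rank_in_family",
            "passes_ttest",
            "passes_precedence",
        ],
    )
    return annotate_binding_support(report, binding_table)
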