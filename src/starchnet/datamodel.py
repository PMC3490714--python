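"""Shared data model and text I/O for the diurnal starch-network pipeline.

All on-disk formats are UTF-8 tab-separated text with "." as the decimal
separator.  The central container is :class:`ExpressionMatrix`: a genes x
arrays matrix of log2 expression values together with per-array diurnal
metadata (hours since the last light-on/light-off event, and the phase the
array was sampled in).  Annotation tables assign each gene a role —
metabolic ``target``, ``regulator`` (transcription factor) or ``clock``
gene — which drives edge typing and candidate ranking downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_ROLES = ("target", "regulator", "clock")
VALID_PHASES = ("light", "dark")


@dataclass
class ExpressionMatrix:
    """Genes x arrays log2 expression with diurnal array metadata.

    Parameters
    ----------
    gene_ids : list of str
        Unique gene identifiers, one per row.
    values : ndarray, shape (n_genes, n_arrays)
        Log2-scale expression values; must be finite.
    array_time_h : ndarray, shape (n_arrays,)
        Hours since the most recent light-on (for light-phase arrays) or
        light-off (for dark-phase arrays) event.
    array_phase : list of str
        ``"light"`` or ``"dark"`` per array.
    array_ids : list of str, optional
        Column labels; generated as ``array_0..`` when absent.
    """

    gene_ids: list[str]
    values: np.ndarray
    array_time_h: np.ndarray
    array_phase: list[str]
    array_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.array_time_h = np.asarray(self.array_time_h, dtype=float)
        n_genes, n_arrays = self.values.shape
        if len(self.gene_ids) != n_genes:
            raise ValueError("gene_ids length does not match value rows")
        if len(set(self.gene_ids)) != n_genes:
            dupes = sorted({g for g in self.gene_ids if self.gene_ids.count(g) > 1})
            raise ValueError(f"duplicate gene id: {', '.join(dupes)}")
        if n_arrays < 2:
            raise ValueError("at least 2 arrays are required")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")
        if len(self.array_time_h) != n_arrays or len(self.array_phase) != n_arrays:
            raise ValueError("array metadata length does not match columns")
        for ph in self.array_phase:
            if ph not in VALID_PHASES:
                raise ValueError(f"unknown phase label: {ph!r}")
        if not self.array_ids:
            self.array_ids = [f"array_{i}" for i in range(n_arrays)]
        elif len(self.array_ids) != n_arrays:
            raise ValueError("array_ids length does not match columns")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_arrays(self) -> int:
        return self.values.shape[1]

    def light_indicator(self) -> np.ndarray:
        """0/1 vector over arrays, 1 for light-phase arrays."""
        return np.array([1.0 if p == "light" else 0.0 for p in self.array_phase])

    def absolute_time_h(self) -> np.ndarray:
        """Time on a single 24-h axis: dark hours as-is, light hours offset.

        Dark-phase arrays keep their hours-in-darkness; light-phase arrays
        are shifted by the dark-period length so the whole course is
        monotone in diurnal time (dark period first, then light period).
        """
        dark_t = self.array_time_h[self.light_indicator() == 0]
        offset = float(dark_t.max()) if dark_t.size else 0.0
        out = self.array_time_h.copy()
        out[self.light_indicator() == 1] += offset
        return out

    def subset_genes(self, gene_ids: list[str]) -> "ExpressionMatrix":
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in index]
        if missing:
            raise KeyError(f"genes not in matrix: {', '.join(missing)}")
        rows = [index[g] for g in gene_ids]
        return ExpressionMatrix(
            gene_ids=list(gene_ids),
            values=self.values[rows],
            array_time_h=self.array_time_h.copy(),
            array_phase=list(self.array_phase),
            array_ids=list(self.array_ids),
        )


@dataclass
class PipelineConfig:
    """Tunable thresholds of the pipeline, defaults per the study design."""

    de_q_threshold: float = 0.01
    edge_q_threshold: float = 0.05
    kmeans_k: int = 30
    rng_seed: int = 0
    spline_df: int = 3
    ranking_confidence: float = 0.975
    input_is_linear: bool = False  # log2-transform on load if True

    def __post_init__(self) -> None:
        for name in ("de_q_threshold", "edge_q_threshold"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0,1), got {v}")
        if self.kmeans_k < 1:
            raise ValueError("kmeans_k must be >= 1")
        if self.spline_df < 1:
            raise ValueError("spline_df must be >= 1")
        if not 0.5 < self.ranking_confidence < 1.0:
            raise ValueError("ranking_confidence must be in (0.5, 1)")


def read_expression_matrix(
    path: str | Path, metadata_path: str | Path | None = None
) -> ExpressionMatrix:
    """Read a genes x arrays TSV (first column gene ids, header array ids).

    A sidecar metadata TSV with columns ``array_id``, ``time_h``, ``phase``
    supplies the diurnal labels; when absent, the default study grid of
    1, 2, 4, 8, 12 h in darkness then light is assumed if the array count
    is 10, otherwise arrays are labelled light at hour index.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str}, float_precision="round_trip")
    if df.index.has_duplicates:
        dupes = sorted(df.index[df.index.duplicated()].unique())
        raise ValueError(f"duplicate gene id: {', '.join(map(str, dupes))}")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"non-numeric expression cell in {path}: {exc}") from exc
    array_ids = [str(c) for c in df.columns]

    if metadata_path is not None:
        meta = pd.read_csv(metadata_path, sep="\t", dtype={"array_id": str})
        meta = meta.set_index("array_id").loc[array_ids]
        time_h = meta["time_h"].to_numpy(dtype=float)
        phase = [str(p) for p in meta["phase"]]
    else:
        time_h, phase = default_diurnal_grid(len(array_ids))
    return ExpressionMatrix(
        gene_ids=[str(g) for g in df.index],
        values=values,
        array_time_h=time_h,
        array_phase=phase,
        array_ids=array_ids,
    )


def default_diurnal_grid(n_arrays: int) -> tuple[np.ndarray, list[str]]:
    """The study's sampling grid: 1, 2, 4, 8, 12 h in darkness, then light."""
    base = [1.0, 2.0, 4.0, 8.0, 12.0]
    if n_arrays == 10:
        return np.array(base + base), ["dark"] * 5 + ["light"] * 5
    half = n_arrays // 2
    times = np.arange(1, n_arrays + 1, dtype=float)
    times[half:] = times[half:] - half
    return times, ["dark"] * half + ["light"] * (n_arrays - half)


def write_expression_matrix(
    matrix: ExpressionMatrix, path: str | Path, metadata_path: str | Path | None = None
) -> None:
    """Write the matrix TSV and (optionally) its metadata sidecar."""
    df = pd.DataFrame(matrix.values, index=matrix.gene_ids, columns=matrix.array_ids)
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format="%.17g")
    if metadata_path is not None:
        meta = pd.DataFrame(
            {
                "array_id": matrix.array_ids,
                "time_h": matrix.array_time_h,
                "phase": matrix.array_phase,
            }
        )
        meta.to_csv(metadata_path, sep="\t", index=False)


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read the gene annotation TSV (gene_id, role, family).

    Roles must be one of ``target``, ``regulator``, ``clock``; the family
    column may be empty for target genes.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"gene_id", "role", "family"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation missing columns: {sorted(missing)}")
    if df["gene_id"].duplicated().any():
        dupes = sorted(df.loc[df["gene_id"].duplicated(), "gene_id"].unique())
        raise ValueError(f"duplicate gene id: {', '.join(dupes)}")
    bad = df.loc[~df["role"].isin(VALID_ROLES)]
    if len(bad):
        row = bad.iloc[0]
        raise ValueError(
            f"unknown role {row['role']!r} for gene {row['gene_id']!r} "
            f"(allowed: {', '.join(VALID_ROLES)})"
        )
    return df.reset_index(drop=True)


def check_annotation_coverage(matrix: ExpressionMatrix, annotation: pd.DataFrame) -> set[str]:
    """Return matrix genes absent from the annotation, logging a warning."""
    missing = set(matrix.gene_ids) - set(annotation["gene_id"])
    if missing:
        logger.warning(
            "annotation covers %d of %d matrix genes (%d unannotated)",
            matrix.n_genes - len(missing),
            matrix.n_genes,
            len(missing),
        )
    return missing


def read_binding_table(path: str | Path) -> pd.DataFrame:
    """Read the binding-site table: family, target_gene, present (Y/N)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"family", "target_gene", "present"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"binding table missing columns: {sorted(missing)}")
    bad = df.loc[~df["present"].isin(["Y", "N"])]
    if len(bad):
        raise ValueError(f"binding 'present' must be Y or N, got {bad.iloc[0]['present']!r}")
    return df


def read_compendium(path: str | Path) -> pd.DataFrame:
    """Read condition-independent co-expression correlations.

    Columns: regulator_gene, target_gene, correlation, and optionally
    family. One row per (regulator, target) pair.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"regulator_gene", "target_gene", "correlation"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"compendium missing columns: {sorted(missing)}")
    if df.duplicated(["regulator_gene", "target_gene"]).any():
        raise ValueError("compendium has duplicate (regulator, target) rows")
    corr = df["correlation"].to_numpy(dtype=float)
    if not np.all(np.isfinite(corr)):
        raise ValueError("compendium correlations must be finite")
    return df


def read_morphology(path: str | Path) -> pd.DataFrame:
    """Read a per-object morphology measurement table."""
    df = pd.read_csv(path, sep="\t")
    required = {"object_id", "line_label", "object_class"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"morphology table missing columns: {sorted(missing)}")
    for col in ("area", "perimeter"):
        if col in df.columns:
            vals = df[col].dropna()
            if (vals <= 0).any():
                raise ValueError(f"{col} must be positive for measured objects")
    return df


def canonical_edge(a: str, b: str) -> tuple[str, str]:
    """Lexicographically ordered endpoint pair — the canonical edge form."""
    return (a, b) if a <= b else (b, a)


def write_edge_list(network, path: str | Path, format: str = "tsv") -> None:
    """Serialize a network's selected edges as SIF, TSV or GraphML.

    SIF rows are ``source<TAB>relation<TAB>target`` with relation ``pos`` or
    ``neg`` by the sign of the partial correlation.  TSV carries the full
    precision pcor/p/q columns.  GraphML goes through networkx and carries
    node role attributes when the network has them.
    """
    path = Path(path)
    edges = network.edge_table()
    if format == "sif":
        with open(path, "w", encoding="utf-8") as fh:
            for _, row in edges.iterrows():
                rel = "pos" if row["pcor"] >= 0 else "neg"
                fh.write(f"{row['gene_a']}\t{rel}\t{row['gene_b']}\n")
    elif format == "tsv":
        edges.to_csv(path, sep="\t", index=False, float_format="%.17g")
    elif format == "graphml":
        import networkx as nx

        g = nx.Graph()
        for gene in network.gene_ids:
            g.add_node(gene, role=getattr(network, "roles", {}).get(gene, ""))
        for _, row in edges.iterrows():
            g.add_edge(
                row["gene_a"],
                row["gene_b"],
                pcor=float(row["pcor"]),
                p=float(row["p_value"]),
                q=float(row["q_value"]),
                sign="pos" if row["pcor"] >= 0 else "neg",
            )
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown edge-list format: {format!r}")


def read_edge_list_tsv(path: str | Path) -> pd.DataFrame:
    """Read back a TSV edge list written by :func:`write_edge_list`."""
    return pd.read_csv(path, sep="\t")
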