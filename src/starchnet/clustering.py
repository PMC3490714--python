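"""k-means clustering of diurnal profiles and light/dark group assignment.

Significant genes are clustered on per-gene standardized profiles (k = 30
in the study design) and each cluster centroid is assigned to one of four
diurnal response groups:

* **A** — induced in the dark, repressed in the light;
* **B** — repressed in the dark, induced in the light;
* **C** — roughly constant but stepping up at the dark-to-light transition;
* **D** — roughly constant but stepping down at the dark-to-light transition.

The A/B calls come from the correlation of the centroid with the light
indicator; C/D from the standardized step across the transition.  The
defaults tau = 0.5 (correlation) and delta = 0.5 (step, in centroid sd
units) make the otherwise subjective grouping an explicit, reproducible
rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

__all__ = ["ClusterAssignment", "standardize_profiles", "kmeans_cluster", "assign_group", "run_clustering"]


@dataclass
class ClusterAssignment:
    gene_ids: list[str]
    cluster_id: np.ndarray  # 1-based labels
    centroids: np.ndarray  # k x arrays
    groups: dict[int, str] | None = None  # cluster -> A|B|C|D

    def table(self) -> pd.DataFrame:
        rows = {"gene_id": self.gene_ids, "cluster_id": self.cluster_id}
        if self.groups is not None:
            rows["group"] = [self.groups[c] for c in self.cluster_id]
        return pd.DataFrame(rows)


def standardize_profiles(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene z-scoring; zero-variance rows become zero vectors.

    Returns the standardized matrix and a boolean mask of flat rows.
    """
    X = np.asarray(X, dtype=float)
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=0, keepdims=True)
    flat = (sd[:, 0] <= 1e-300)
    sd_safe = np.where(sd > 1e-300, sd, 1.0)
    Z = (X - mean) / sd_safe
    Z[flat] = 0.0
    return Z, flat


def kmeans_cluster(
    X_std: np.ndarray,
    gene_ids: list[str],
    k: int = 30,
    seed: int = 0,
    n_restarts: int = 10,
) -> ClusterAssignment:
    """Seed-deterministic k-means (k-means++ init, best of n_restarts)."""
    X_std = np.asarray(X_std, dtype=float)
    if k > X_std.shape[0]:
        raise ValueError(f"k={k} exceeds number of genes {X_std.shape[0]}")
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(X_std)
    return ClusterAssignment(
        gene_ids=list(gene_ids),
        cluster_id=labels + 1,
        centroids=km.cluster_centers_,
    )


def assign_group(
    centroid: np.ndarray,
    phase: list[str] | np.ndarray,
    transition_index: int | None = None,
    tau: float = 0.5,
    delta: float = 0.5,
) -> str:
    """Label a centroid A/B/C/D from its light response.

    Let c be the Pearson correlation of the centroid with the light
    indicator and d the standardized centroid change across the
    dark-to-light transition.  A if c <= -tau; B if c >= tau; otherwise C
    if d > delta, else D.  Invariant to adding a constant to the centroid
    and to positive rescaling.
    """
    centroid = np.asarray(centroid, dtype=float)
    light = np.array([1.0 if p == "light" else 0.0 for p in phase])
    if light.min() == light.max():
        raise ValueError("phase vector must contain both light and dark arrays")
    if transition_index is None:
        transition_index = int(np.argmax(light))  # first light array
    sd = centroid.std(ddof=0)
    if sd <= 1e-300:
        return "D"  # perfectly flat: no step, no light response
    c = float(np.corrcoef(centroid, light)[0, 1])
    z = (centroid - centroid.mean()) / sd
    d = float(z[transition_index] - z[transition_index - 1])
    if c <= -tau:
        return "A"
    if c >= tau:
        return "B"
    return "C" if d > delta else "D"


def run_clustering(
    matrix,
    k: int = 30,
    seed: int = 0,
    n_restarts: int = 10,
    tau: float = 0.5,
    delta: float = 0.5,
) -> ClusterAssignment:
    """Standardize, cluster, and group-label an ExpressionMatrix."""
    Z, _ = standardize_profiles(matrix.values)
    assignment = kmeans_cluster(Z, matrix.gene_ids, k=k, seed=seed, n_restarts=n_restarts)
    groups = {}
    for i, centroid in enumerate(assignment.centroids):
        groups[i + 1] = assign_group(centroid, matrix.array_phase, tau=tau, delta=delta)
    assignment.groups = groups
    return assignment
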