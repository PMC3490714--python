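"""Synthetic inputs with known ground truth for every pipeline stage.

The expression generator plants a sparse graphical Gaussian model: a
precision matrix with unit diagonal and off-diagonal entries equal to
minus the desired partial correlations on a random sparse support, so the
true partial correlations are known exactly.  Diurnal mean profiles
follow the four light/dark response shapes (dark-induced A, light-induced
B, transition-bump C/D) on the study's sampling grid of 1, 2, 4, 8 and
12 hours in darkness and then light; residuals are multivariate normal
with the planted dependence.  Compendium tables plant strong
regulator-target correlations among null decoys, and morphology tables
draw random ellipses (Ramanujan's second perimeter approximation) with
line-specific granule-count distributions, so the mutant-vs-wild-type
contrasts are planted with known effect sizes.

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import ExpressionMatrix, canonical_edge, default_diurnal_grid

__all__ = [
    "GroundTruth",
    "make_sparse_ggm",
    "simulate_ggm_matrix",
    "simulate_diurnal_matrix",
    "make_annotation",
    "make_compendium",
    "make_binding_table",
    "make_morphology",
    "GROUP_SHAPES",
]

#: diurnal mean shape per response group on a (phase, hour) grid;
#: evaluated on the light indicator and the first light timepoints.
GROUP_SHAPES = ("A", "B", "C", "D")


@dataclass
class GroundTruth:
    """Planted structure behind one synthetic data set."""

    gene_ids: list[str]
    precision: np.ndarray
    true_pcor: np.ndarray
    true_edges: set[tuple[str, str]]
    group_assignment: list[str]  # A|B|C|D|flat per gene
    roles: list[str]  # target|regulator|clock per gene
    planted_regulators: list[tuple[str, str]] = field(default_factory=list)
    rng_seed: int = 0

    @property
    def p(self) -> int:
        return len(self.gene_ids)

    def annotation(self) -> pd.DataFrame:
        return make_annotation(self)


def make_sparse_ggm(
    p: int,
    edge_density: float | None = None,
    pcor_magnitude: float = 0.3,
    seed: int = 0,
    n_edges: int | None = None,
    flat_fraction: float = 0.0,
    n_planted_regulators: int = 2,
    min_eig: float = 0.05,
) -> GroundTruth:
    """Random sparse GGM with approximately +/- pcor_magnitude on true edges.

    The precision matrix starts as the identity minus a random-sign
    support matrix at the requested magnitude; if the smallest eigenvalue
    falls below ``min_eig`` the off-diagonal block is scaled down until
    positive definiteness holds, diluting the achieved magnitude.  When
    dilution would halve the requested magnitude the combination is
    declared infeasible.  Exactly one of ``edge_density``/``n_edges``
    selects the support size.
    """
    if not 0.0 < pcor_magnitude < 0.9:
        raise ValueError("pcor_magnitude must be in (0, 0.9)")
    rng = np.random.default_rng(seed)
    all_pairs = [(i, j) for i in range(p) for j in range(i + 1, p)]
    if n_edges is None:
        if edge_density is None:
            edge_density = 0.0
        if not 0.0 <= edge_density < 1.0:
            raise ValueError("edge_density must be in [0, 1)")
        n_edges = int(round(edge_density * len(all_pairs)))
    if n_edges > len(all_pairs):
        raise ValueError("more edges requested than available pairs")
    chosen = (
        [all_pairs[k] for k in rng.choice(len(all_pairs), size=n_edges, replace=False)]
        if n_edges
        else []
    )

    M = np.zeros((p, p))
    for i, j in chosen:
        sign = 1.0 if rng.random() < 0.5 else -1.0
        M[i, j] = M[j, i] = sign * pcor_magnitude
    omega = np.eye(p) - M
    if n_edges:
        lam_min = float(np.linalg.eigvalsh(omega)[0])
        if lam_min < min_eig:
            scale = (1.0 - min_eig) / (1.0 - lam_min)
            if scale * pcor_magnitude < 0.5 * pcor_magnitude:
                raise ValueError(
                    "infeasible magnitude/density: positive definiteness requires "
                    f"diluting |pcor| to {scale * pcor_magnitude:.3f}"
                )
            M *= scale
            omega = np.eye(p) - M

    gene_ids = [f"g{i:03d}" for i in range(p)]
    true_edges = {canonical_edge(gene_ids[i], gene_ids[j]) for i, j in chosen}

    # recompute the implied pcor from the precision (exactly M by construction)
    d = np.sqrt(np.diag(omega))
    true_pcor = -omega / np.outer(d, d)
    np.fill_diagonal(true_pcor, 0.0)

    n_flat = int(round(flat_fraction * p))
    groups = ["flat"] * n_flat + [GROUP_SHAPES[i % 4] for i in range(p - n_flat)]
    # role mix emulating the study's 21 targets / 106 regulators / 6 clock genes
    roles = []
    for i in range(p):
        r = i % 19
        roles.append("target" if r < 3 else ("clock" if r == 18 else "regulator"))

    regulators = [g for g, r in zip(gene_ids, roles) if r == "regulator"]
    targets = [g for g, r in zip(gene_ids, roles) if r == "target"]
    planted = []
    if n_planted_regulators and regulators and targets:
        k = min(n_planted_regulators, len(regulators), len(targets))
        ridx = rng.choice(len(regulators), size=k, replace=False)
        tidx = rng.choice(len(targets), size=k, replace=False)
        planted = [(regulators[a], targets[b]) for a, b in zip(ridx, tidx)]
    return GroundTruth(
        gene_ids=gene_ids,
        precision=omega,
        true_pcor=true_pcor,
        true_edges=true_edges,
        group_assignment=groups,
        roles=roles,
        planted_regulators=planted,
        rng_seed=seed,
    )


def _residual_cholesky(truth: GroundTruth) -> np.ndarray:
    sigma = np.linalg.inv(truth.precision)
    d = np.sqrt(np.diag(sigma))
    corr = sigma / np.outer(d, d)  # unit marginal variances
    corr = 0.5 * (corr + corr.T)
    return np.linalg.cholesky(corr + 1e-12 * np.eye(truth.p))


def simulate_ggm_matrix(
    truth: GroundTruth,
    n_arrays: int,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> ExpressionMatrix:
    """Pure-residual draws from the planted GGM (no diurnal mean structure)."""
    rng = np.random.default_rng(seed)
    L = _residual_cholesky(truth)
    values = noise_sd * (L @ rng.standard_normal((truth.p, n_arrays)))
    times, phases = default_diurnal_grid(n_arrays)
    return ExpressionMatrix(
        gene_ids=list(truth.gene_ids),
        values=values,
        array_time_h=times,
        array_phase=phases,
    )


def group_mean_profiles(
    groups: list[str],
    phase: list[str],
    bump: tuple[float, ...] = (1.0,),
) -> np.ndarray:
    """Mean diurnal shape per gene on the array grid, unit amplitude.

    A = high in the dark, B = high in the light, C = flat except for a
    transient elevation at the first post-transition sample, D = its
    negative, flat = 0.  Confining the C/D bump to the transition keeps
    those shapes essentially uncorrelated with the phase indicator, which
    is their defining feature (a transient, not a sustained, response).
    """
    light = np.array([1.0 if p == "light" else 0.0 for p in phase])
    n = len(light)
    first_light = int(np.argmax(light)) if light.max() > 0 else n
    bump_vec = np.zeros(n)
    for k, height in enumerate(bump):
        if first_light + k < n:
            bump_vec[first_light + k] = height
    shape = {
        "A": 1.0 - light,
        "B": light,
        "C": bump_vec,
        "D": -bump_vec,
        "flat": np.zeros(n),
    }
    return np.vstack([shape[g] for g in groups])


def simulate_diurnal_matrix(
    truth: GroundTruth,
    timepoints: np.ndarray | None = None,
    phases: list[str] | None = None,
    amplitude: float = 1.0,
    noise_sd: float = 0.25,
    seed: int = 0,
) -> ExpressionMatrix:
    """Diurnal means plus GGM-correlated residuals on the study grid.

    value(g, t) = amplitude * shape(group(g), t) + noise_sd * residual,
    with residuals multivariate normal under the planted precision.  The
    default grid is 1, 2, 4, 8, 12 h in darkness then light (10 arrays).
    """
    if timepoints is None or phases is None:
        timepoints, phases = default_diurnal_grid(10)
    timepoints = np.asarray(timepoints, dtype=float)
    rng = np.random.default_rng(seed)
    means = amplitude * group_mean_profiles(truth.group_assignment, phases)
    L = _residual_cholesky(truth)
    resid = noise_sd * (L @ rng.standard_normal((truth.p, len(phases))))
    return ExpressionMatrix(
        gene_ids=list(truth.gene_ids),
        values=means + resid,
        array_time_h=timepoints,
        array_phase=list(phases),
    )


def make_annotation(truth: GroundTruth) -> pd.DataFrame:
    """Annotation table for the planted genes (family = role-based label)."""
    families = []
    fam_counter = 0
    for role in truth.roles:
        if role == "regulator":
            families.append(f"F{fam_counter % 5}")
            fam_counter += 1
        else:
            families.append("")
    return pd.DataFrame({"gene_id": truth.gene_ids, "role": truth.roles, "family": families})


def make_compendium(
    planted: "GroundTruth | list[tuple[str, str]]",
    n_decoys: int = 40,
    effect: float = 0.5,
    noise_sd: float = 0.15,
    seed: int = 0,
    n_families: int = 5,
) -> pd.DataFrame:
    """ATTED-style correlation table with planted strong regulators.

    Planted (regulator, target) pairs get correlation ~ N(effect, noise_sd)
    truncated to [-1, 1]; each target also receives ``n_decoys`` decoy
    regulators with correlation ~ N(0, noise_sd).  Families are assigned
    round-robin; every planted regulator keeps its own family slot.
    """
    if not 0.0 < effect < 1.0:
        raise ValueError("effect must be in (0, 1)")
    pairs = planted.planted_regulators if isinstance(planted, GroundTruth) else list(planted)
    rng = np.random.default_rng(seed)
    rows = []
    targets = sorted({t for _, t in pairs}) or []
    for reg, tgt in pairs:
        corr = float(np.clip(rng.normal(effect, noise_sd), -1.0, 1.0))
        rows.append(
            {"regulator_gene": reg, "target_gene": tgt, "correlation": corr, "family": "F0"}
        )
    for tgt in targets:
        for d in range(n_decoys):
            corr = float(np.clip(rng.normal(0.0, noise_sd), -1.0, 1.0))
            rows.append(
                {
                    "regulator_gene": f"decoy{d:03d}",
                    "target_gene": tgt,
                    "correlation": corr,
                    "family": f"F{d % n_families}",
                }
            )
    return pd.DataFrame(rows, columns=["regulator_gene", "target_gene", "correlation", "family"])


def make_binding_table(
    compendium: pd.DataFrame,
    support_pairs: list[tuple[str, str]] | None = None,
    seed: int = 0,
    background_rate: float = 0.1,
) -> pd.DataFrame:
    """Binding-site table: planted pairs' families marked Y, background N/Y."""
    rng = np.random.default_rng(seed)
    fam_of = dict(zip(compendium["regulator_gene"], compendium["family"]))
    supported = set()
    for reg, tgt in support_pairs or []:
        supported.add((fam_of.get(reg, "F0"), tgt))
    rows = []
    seen = set()
    for _, row in compendium.iterrows():
        key = (row["family"], row["target_gene"])
        if key in seen:
            continue
        seen.add(key)
        present = "Y" if key in supported else ("Y" if rng.random() < background_rate else "N")
        rows.append({"family": key[0], "target_gene": key[1], "present": present})
    return pd.DataFrame(rows, columns=["family", "target_gene", "present"])


def _ellipse_perimeter(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Ramanujan's second approximation for the ellipse perimeter."""
    h = ((a - b) / (a + b)) ** 2
    return np.pi * (a + b) * (1.0 + 3.0 * h / (10.0 + np.sqrt(4.0 - 3.0 * h)))


# per-line granule-count distributions; the wild type concentrates its mass
# on 1-4 granules, the mutant shifts to 2-5 with a heavier upper tail
DEFAULT_COUNT_PMF = {
    "wild_type": {1: 0.18, 2: 0.22, 3: 0.275, 4: 0.185, 5: 0.09, 6: 0.05},
    "mutant": {1: 0.06, 2: 0.20, 3: 0.254, 4: 0.22, 5: 0.188, 6: 0.05, 7: 0.028},
}


def make_morphology(
    n_objects: int = 200,
    seed: int = 0,
    mean_radius: float = 2.5,
    radius_cv: float = 0.25,
    wild_axis_ratio: float = 1.4,
    mutant_area_scale: float = 0.7,
    mutant_axis_ratio: float = 2.0,
    shape_jitter: float = 0.1,
    count_pmf: dict[str, dict[int, float]] | None = None,
    lines: tuple[str, str] = ("wild_type", "mutant"),
) -> pd.DataFrame:
    """Per-object morphology table for a wild-type and a mutant line.

    Chloroplast cross-sections are random ellipses: the wild type with a
    moderate axis ratio, the mutant with its area scaled down and a more
    elongated axis ratio, so both size and shape contrasts are planted.
    Granule counts per chloroplast follow line-specific distributions and
    each granule contributes a smaller ellipse row of its own.
    """
    rng = np.random.default_rng(seed)
    pmf = count_pmf or DEFAULT_COUNT_PMF
    rows = []
    for line in lines:
        is_mutant = line != lines[0]
        area_scale = mutant_area_scale if is_mutant else 1.0
        ratio = mutant_axis_ratio if is_mutant else wild_axis_ratio
        line_pmf = pmf.get(line, pmf[list(pmf)[-1] if is_mutant else list(pmf)[0]])
        counts = np.array(sorted(line_pmf))
        probs = np.array([line_pmf[c] for c in counts], dtype=float)
        probs = probs / probs.sum()
        for i in range(n_objects):
            r = rng.lognormal(np.log(mean_radius), radius_cv) * np.sqrt(area_scale)
            jitter = np.exp(rng.normal(0.0, shape_jitter))
            a, b = r * np.sqrt(ratio) * jitter, r / np.sqrt(ratio) / jitter
            if b > a:
                a, b = b, a
            area = np.pi * a * b
            perim = float(_ellipse_perimeter(np.array(a), np.array(b)))
            count = int(rng.choice(counts, p=probs))
            rows.append(
                {
                    "object_id": f"{line}_chl_{i:04d}",
                    "line_label": line,
                    "object_class": "chloroplast",
                    "area": area,
                    "perimeter": perim,
                    "width": 2 * a,
                    "height": 2 * b,
                    "granule_count": count,
                }
            )
            for k in range(count):
                gr = rng.lognormal(np.log(0.35 * mean_radius), radius_cv) * np.sqrt(area_scale)
                gj = np.exp(rng.normal(0.0, 0.8 * shape_jitter))
                ga, gb = gr * np.sqrt(1.2) * gj, gr / np.sqrt(1.2) / gj
                if gb > ga:
                    ga, gb = gb, ga
                rows.append(
                    {
                        "object_id": f"{line}_chl_{i:04d}_gr_{k}",
                        "line_label": line,
                        "object_class": "granule",
                        "area": np.pi * ga * gb,
                        "perimeter": float(_ellipse_perimeter(np.array(ga), np.array(gb))),
                        "width": 2 * ga,
                        "height": 2 * gb,
                        "granule_count": np.nan,
                    }
                )
    return pd.DataFrame(rows)
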