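"""Sorting/mixing phases of binary cell mixtures on lattice clusters.

A finite binary mixture passes through four structures as the heterotypic
attraction grows relative to the homotypic ones: complete sorting (one
compact minority blob), shell-core sorting (minority enriched on the
aggregate surface around a majority core), partial mixing (fewer
heterotypic contacts than random, but no segregation), and complete mixing
(statistically random).  Equilibrium contact-number fluctuations peak at
the boundaries between these structures, so phase boundaries are located as
interior maxima of the fluctuation curves along the attraction-ratio axis.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .adhesion import AttractionSet, MCConfig, metropolis_equilibrate
from .exceptions import ConfigError, ValidationError
from .io import BINARY_PAIRS, canonical_pair
from .lattice import LatticeCluster


#: Monte-Carlo defaults for phase exemplars and diagrams.  The four
#: structures are visually distinct only at low cell motility; at the
#: fluctuation energies appropriate for attraction inference the weakly
#: sorted structures blur into near-random mixtures.  E_f = 0.25 sits above
#: the homotypic/heterotypic energy gap of real islets (~0.1) yet well below
#: the attraction energies (~1), and separates all four phases cleanly on a
#: 1357-site cluster.
def phase_mc_config(seed: int = 0) -> "MCConfig":
    return MCConfig(
        e_f=0.25, n_equilibration_sweeps=4000, n_recording_sweeps=500, seed=seed
    )


class PhaseLabel(enum.IntEnum):
    """The four structures, ordered along increasing heterotypic attraction."""

    complete_sorting = 0
    shell_core_sorting = 1
    partial_mixing = 2
    complete_mixing = 3


@dataclass(frozen=True)
class ClassifierThresholds:
    """Decision thresholds for structure classification.

    ``mixing_high``: mixing indices above this (but still distinguishable
    from random) label partial mixing.  ``surface_enrichment``: minority
    surface fraction over the cluster's surface fraction at or above this
    labels shell-core.  ``blob_fraction``: minimum share of minority cells
    in the largest minority component for complete sorting.  ``n_shuffles``
    sets the permutation sample behind the "indistinguishable from random"
    test.
    """

    mixing_high: float = 0.88
    surface_enrichment: float = 1.5
    blob_fraction: float = 0.5
    n_shuffles: int = 200
    z_random: float = 2.0


@dataclass
class StructureMetrics:
    mixing_index: float
    shuffle_sd: float
    surface_enrichment: float
    n_minority_components: int
    largest_component_fraction: float
    minority_type: str


def _minority_components(cluster: LatticeCluster, minority_mask: np.ndarray):
    idx = np.flatnonzero(minority_mask)
    if len(idx) == 0:
        return 0, 0.0
    pos = -np.ones(cluster.n_sites, dtype=np.int64)
    pos[idx] = np.arange(len(idx))
    e = cluster.adjacency.edges
    keep = minority_mask[e[:, 0]] & minority_mask[e[:, 1]]
    sub = e[keep]
    m = coo_matrix(
        (np.ones(len(sub)), (pos[sub[:, 0]], pos[sub[:, 1]])),
        shape=(len(idx), len(idx)),
    )
    n_comp, labels = connected_components(m, directed=False)
    largest = np.bincount(labels).max() / len(idx)
    return int(n_comp), float(largest)


def structure_metrics(
    cluster: LatticeCluster,
    types,
    thresholds: ClassifierThresholds | None = None,
    random_state: int = 0,
) -> StructureMetrics:
    """Sorting metrics of a binary assignment on a cluster."""
    thresholds = thresholds or ClassifierThresholds()
    types = np.asarray(types, dtype=object)
    present = [t for t in ("alpha", "beta", "delta") if np.any(types == t)]
    if len(present) != 2:
        raise ValidationError(
            f"structure classification needs exactly 2 types, found {present}"
        )
    counts = {t: int(np.sum(types == t)) for t in present}
    minority = min(counts, key=counts.get)
    majority = max(counts, key=counts.get)
    if minority == majority:  # equal counts: break the tie deterministically
        minority, majority = sorted(present)
    n = cluster.n_sites
    p_min, p_maj = counts[minority] / n, counts[majority] / n
    expected_het = 2.0 * p_min * p_maj
    edges = cluster.adjacency.edges
    total = len(edges)
    if total == 0:
        raise ValidationError("cluster adjacency has no edges")

    is_min = (types == minority).astype(np.int8)

    def het_ratio(mask):
        n_het = int(np.sum(mask[edges[:, 0]] != mask[edges[:, 1]]))
        return n_het / total / expected_het

    m = het_ratio(is_min)

    rng = np.random.default_rng(random_state)
    shuffled_m = np.empty(thresholds.n_shuffles)
    work = is_min.copy()
    for k in range(thresholds.n_shuffles):
        rng.shuffle(work)
        shuffled_m[k] = het_ratio(work)
    shuffle_sd = float(shuffled_m.std())

    surface = cluster.surface_mask()
    minority_mask = types == minority
    surf_frac_all = surface.mean()
    surf_frac_min = surface[minority_mask].mean()
    enrichment = float(surf_frac_min / surf_frac_all) if surf_frac_all > 0 else np.nan

    n_comp, largest = _minority_components(cluster, minority_mask)
    return StructureMetrics(
        mixing_index=float(m),
        shuffle_sd=shuffle_sd,
        surface_enrichment=enrichment,
        n_minority_components=n_comp,
        largest_component_fraction=largest,
        minority_type=minority,
    )


def classify_structure(
    cluster: LatticeCluster,
    types,
    thresholds: ClassifierThresholds | None = None,
    random_state: int = 0,
    return_metrics: bool = False,
    mixing_value: float | None = None,
):
    """Label a binary assignment with one of the four phases.

    Decision rule, in order: a mixing index within ``z_random`` shuffle SDs
    of 1 (or above 1) is complete mixing; a high-but-depressed mixing index
    is partial mixing; low mixing with minority surface enrichment is
    shell-core sorting; low mixing with one dominant minority blob is
    complete sorting; low mixing with scattered small clumps and no surface
    enrichment falls back to partial mixing.

    ``mixing_value`` substitutes a better mixing-index estimate than the
    single supplied snapshot — e.g. the equilibrium mean over recorded
    sweeps — for the decision; geometric metrics still use the snapshot.
    """
    thresholds = thresholds or ClassifierThresholds()
    met = structure_metrics(cluster, types, thresholds, random_state)
    m = met.mixing_index if mixing_value is None else float(mixing_value)
    if m >= 1.0 - thresholds.z_random * met.shuffle_sd:
        label = PhaseLabel.complete_mixing
    elif m >= thresholds.mixing_high:
        label = PhaseLabel.partial_mixing
    elif met.surface_enrichment >= thresholds.surface_enrichment:
        label = PhaseLabel.shell_core_sorting
    elif met.largest_component_fraction >= thresholds.blob_fraction:
        label = PhaseLabel.complete_sorting
    else:
        label = PhaseLabel.partial_mixing
    return (label, met) if return_metrics else label


def equilibrium_label(
    cluster: LatticeCluster,
    p_beta: float,
    ratio: float,
    cfg: MCConfig | None = None,
    thresholds: ClassifierThresholds | None = None,
    seed: int = 0,
):
    """Equilibrate a fresh binary mixture and classify its structure.

    The mixing index entering the decision is the equilibrium mean over the
    recorded sweeps (far less noisy than a single snapshot); surface and
    component metrics come from the final configuration.  Returns
    ``(PhaseLabel, StructureMetrics, final_types)``.
    """
    cfg = cfg or phase_mc_config()
    rng = np.random.default_rng(seed)
    init = _binary_assignment(cluster.n_sites, p_beta, rng)
    from dataclasses import replace

    final, summary = metropolis_equilibrate(
        cluster.adjacency,
        init,
        AttractionSet.binary(j_bb=1.0, j_ab=float(ratio), j_aa=1.0),
        replace(cfg, seed=int(rng.integers(0, 2**31 - 1))),
        keep_samples=False,
    )
    n = cluster.n_sites
    n_beta = int(np.sum(final == "beta"))
    p_b = n_beta / n
    expected_het = 2.0 * p_b * (1.0 - p_b)
    m_mean = summary.mean[("alpha", "beta")] / summary.n_edges / expected_het
    label, met = classify_structure(
        cluster,
        final,
        thresholds,
        random_state=int(rng.integers(0, 2**31 - 1)),
        return_metrics=True,
        mixing_value=m_mean,
    )
    return label, met, final


@dataclass
class FluctuationCurves:
    """Equilibrium contact-count variances along an attraction-ratio grid."""

    ratio_grid: np.ndarray
    var: dict  # pair -> array over grid
    mean: dict

    def curve(self, pair) -> np.ndarray:
        return self.var[canonical_pair(pair)]


def _binary_assignment(n: int, p_beta: float, rng) -> np.ndarray:
    n_beta = int(round(p_beta * n))
    types = np.array(["beta"] * n_beta + ["alpha"] * (n - n_beta), dtype=object)
    rng.shuffle(types)
    return types


def sweep_fluctuations(
    cluster: LatticeCluster,
    p_beta: float,
    ratio_grid,
    cfg: MCConfig | None = None,
) -> FluctuationCurves:
    """Equilibrium fluctuations of N_aa, N_ab, N_bb along a ratio grid.

    Homotypic attractions are fixed at the reference (J_aa = J_bb = 1); the
    heterotypic attraction is swept as ratio = J_ab / J_hom.  Each grid
    point starts from a fresh random assignment and is fully reproducible
    from the config seed.
    """
    cfg = cfg or phase_mc_config()
    ratio_grid = np.asarray(ratio_grid, dtype=float)
    if np.any(ratio_grid <= 0):
        raise ConfigError("attraction ratios must be positive")
    var = {p: np.empty(len(ratio_grid)) for p in BINARY_PAIRS}
    mean = {p: np.empty(len(ratio_grid)) for p in BINARY_PAIRS}
    rng = np.random.default_rng(cfg.seed)
    for k, ratio in enumerate(ratio_grid):
        j = AttractionSet.binary(j_bb=1.0, j_ab=float(ratio), j_aa=1.0)
        init = _binary_assignment(cluster.n_sites, p_beta, rng)
        from dataclasses import replace

        point_cfg = replace(cfg, seed=int(rng.integers(0, 2**31 - 1)))
        _, summary = metropolis_equilibrate(
            cluster.adjacency, init, j, point_cfg, keep_samples=False
        )
        for p in BINARY_PAIRS:
            var[p][k] = summary.var[p]
            mean[p][k] = summary.mean[p]
    return FluctuationCurves(ratio_grid=ratio_grid, var=var, mean=mean)


def detect_phase_boundaries(
    curves,
    ratio_grid=None,
    smooth_window: int = 3,
    prominence_fraction: float = 0.2,
) -> np.ndarray:
    """Boundary ratios: interior maxima of smoothed fluctuation curves.

    ``curves`` may be a :class:`FluctuationCurves`, a dict of arrays, or a
    single array (with ``ratio_grid`` given).  Peaks from all curves are
    pooled, deduplicated to within one grid spacing, and returned in
    increasing ratio order; an empty result is a valid single-phase window.
    """
    if isinstance(curves, FluctuationCurves):
        grid = curves.ratio_grid
        arrays = list(curves.var.values())
    elif isinstance(curves, dict):
        grid = np.asarray(ratio_grid, dtype=float)
        arrays = list(curves.values())
    else:
        grid = np.asarray(ratio_grid, dtype=float)
        arrays = [np.asarray(curves, dtype=float)]
    if len(grid) < 5:
        raise ValidationError("boundary detection needs at least 5 grid points")

    kernel = np.ones(smooth_window) / smooth_window
    found = []
    for arr in arrays:
        arr = np.asarray(arr, dtype=float)
        pad = smooth_window // 2
        padded = np.pad(arr, pad, mode="edge")
        smooth = np.convolve(padded, kernel, mode="valid")
        rng_ = smooth.max() - smooth.min()
        if rng_ <= 0:
            continue
        peaks, _ = find_peaks(smooth, prominence=prominence_fraction * rng_)
        found.extend(grid[p] for p in peaks)
    if not found:
        return np.array([])
    found = np.sort(np.array(found))
    spacing = np.min(np.diff(grid)) if len(grid) > 1 else 0.0
    merged = [found[0]]
    for v in found[1:]:
        if v - merged[-1] > spacing + 1e-12:
            merged.append(v)
    return np.array(merged)


@dataclass
class PhaseDiagram:
    """Phase labels and fluctuation statistics over a (p_beta, ratio) grid."""

    p_beta_grid: np.ndarray
    ratio_grid: np.ndarray
    labels: np.ndarray  # (n_p, n_ratio) of PhaseLabel values
    curves: list  # FluctuationCurves per p_beta
    boundaries: list  # boundary ratio arrays per p_beta
    overlay_points: list = field(default_factory=list)  # (p_beta, ratio, tag)

    def label_at(self, p_beta: float, ratio: float) -> PhaseLabel:
        i = int(np.argmin(np.abs(self.p_beta_grid - p_beta)))
        k = int(np.argmin(np.abs(self.ratio_grid - ratio)))
        return PhaseLabel(self.labels[i, k])


def build_phase_diagram(
    cluster: LatticeCluster,
    p_beta_grid=None,
    ratio_grid=None,
    cfg: MCConfig | None = None,
    thresholds: ClassifierThresholds | None = None,
    overlay_points=None,
) -> PhaseDiagram:
    """Sweep composition and attraction ratio; label every grid point.

    At each point an equilibrium assignment is generated and classified;
    boundaries per composition row come from the fluctuation peaks.
    Observed islets can be overlaid as (p_beta, ratio, tag) points for the
    species comparison.
    """
    cfg = cfg or phase_mc_config()
    p_beta_grid = np.asarray(
        p_beta_grid if p_beta_grid is not None else np.arange(0.1, 0.91, 0.1)
    )
    ratio_grid = np.asarray(
        ratio_grid if ratio_grid is not None else np.arange(0.6, 1.201, 0.05)
    )
    if np.any((p_beta_grid <= 0) | (p_beta_grid >= 1)):
        raise ConfigError("p_beta grid must lie strictly inside (0, 1)")
    if np.any(ratio_grid <= 0):
        raise ConfigError("attraction ratios must be positive")

    labels = np.empty((len(p_beta_grid), len(ratio_grid)), dtype=np.int64)
    curves = []
    boundaries = []
    rng = np.random.default_rng(cfg.seed)
    from dataclasses import replace

    for i, p_beta in enumerate(p_beta_grid):
        var = {p: np.empty(len(ratio_grid)) for p in BINARY_PAIRS}
        mean = {p: np.empty(len(ratio_grid)) for p in BINARY_PAIRS}
        for k, ratio in enumerate(ratio_grid):
            j = AttractionSet.binary(j_bb=1.0, j_ab=float(ratio), j_aa=1.0)
            init = _binary_assignment(cluster.n_sites, float(p_beta), rng)
            final, summary = metropolis_equilibrate(
                cluster.adjacency,
                init,
                j,
                replace(cfg, seed=int(rng.integers(0, 2**31 - 1))),
                keep_samples=False,
            )
            for p in BINARY_PAIRS:
                var[p][k] = summary.var[p]
                mean[p][k] = summary.mean[p]
            n_beta = int(np.sum(final == "beta"))
            p_b = n_beta / cluster.n_sites
            m_mean = (
                summary.mean[("alpha", "beta")]
                / summary.n_edges
                / (2.0 * p_b * (1.0 - p_b))
            )
            labels[i, k] = int(
                classify_structure(
                    cluster,
                    final,
                    thresholds,
                    random_state=int(rng.integers(0, 2**31 - 1)),
                    mixing_value=m_mean,
                )
            )
        fc = FluctuationCurves(ratio_grid=ratio_grid, var=var, mean=mean)
        curves.append(fc)
        boundaries.append(
            detect_phase_boundaries(fc) if len(ratio_grid) >= 5 else np.array([])
        )
    return PhaseDiagram(
        p_beta_grid=p_beta_grid,
        ratio_grid=ratio_grid,
        labels=labels,
        curves=curves,
        boundaries=boundaries,
        overlay_points=list(overlay_points or []),
    )
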