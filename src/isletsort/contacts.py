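"""Cell-cell contact determination from 3D nuclear coordinates.

In soft tissue, "who touches whom" is not given by a lattice.  Contacts are
determined by a double criterion: two cells are candidate neighbors when
their nuclei lie within a threshold distance ``d_c`` (in multiples of the
cell diameter ``d``), and a candidate is discarded when the angle it subtends
at the focal cell with an already-retained nearer neighbor falls below a
threshold ``theta_c`` — such narrow-angle neighbors are second-nearest cells
hiding behind a true contact.  The double criterion tolerates the slight
z-flattening of large aggregates that distance alone would misread.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from sklearn.base import BaseEstimator

from .exceptions import ConfigError, TuningError, ValidationError
from .io import (
    BINARY_PAIRS,
    TERNARY_PAIRS,
    Composition,
    IsletPointCloud,
    canonical_pair,
)


@dataclass(frozen=True)
class ContactCriteria:
    """Thresholds of the distance+angle contact criterion.

    ``d_c`` is expressed in multiples of the cell diameter ``d``;
    ``theta_c`` in degrees; ``d`` in coordinate units.  ``d=None`` means
    "estimate as the median nearest-neighbor distance of the cloud", the
    practical surrogate for cell diameter.
    """

    d_c: float = 1.25
    theta_c: float = 30.0
    d: float | None = None

    def __post_init__(self):
        if self.d_c <= 0:
            raise ConfigError("d_c must be positive")
        if not (0 < self.theta_c < 90):
            raise ConfigError("theta_c must lie in (0, 90) degrees")
        if self.d is not None and self.d <= 0:
            raise ConfigError("cell diameter d must be positive")


@dataclass
class ContactGraph:
    """Symmetric contact adjacency over the cells of one cloud.

    ``edges`` is an (E, 2) int array with ``edges[:, 0] < edges[:, 1]``
    (positional indices into the cloud's row order).
    """

    n_cells: int
    edges: np.ndarray

    def __post_init__(self):
        self.edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        if len(self.edges):
            lo = self.edges.min(axis=1)
            hi = self.edges.max(axis=1)
            if np.any(lo == hi):
                raise ValidationError("self-edges are not allowed")
            if lo.min() < 0 or hi.max() >= self.n_cells:
                raise ValidationError("edge endpoint outside the cloud")
            self.edges = np.unique(
                np.column_stack([lo, hi]), axis=0
            )

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_cells, dtype=np.int64)
        np.add.at(deg, self.edges.ravel(), 1)
        return deg

    def adjacency_csr(self):
        """Symmetric adjacency as (indptr, indices) CSR arrays."""
        from scipy.sparse import coo_matrix

        if not len(self.edges):
            m = coo_matrix((self.n_cells, self.n_cells)).tocsr()
            return m.indptr.astype(np.int64), m.indices.astype(np.int64)
        i, j = self.edges[:, 0], self.edges[:, 1]
        data = np.ones(2 * len(i), dtype=np.int8)
        m = coo_matrix(
            (data, (np.concatenate([i, j]), np.concatenate([j, i]))),
            shape=(self.n_cells, self.n_cells),
        ).tocsr()
        return m.indptr.astype(np.int64), m.indices.astype(np.int64)


@dataclass
class ContactCounts:
    """Edge counts per unordered type pair; keys are canonical pairs."""

    counts: dict
    ternary: bool = False

    @property
    def total(self) -> int:
        return int(sum(self.counts.values()))

    def __getitem__(self, pair) -> int:
        return self.counts.get(canonical_pair(pair), 0)

    @property
    def pairs(self):
        return TERNARY_PAIRS if self.ternary else BINARY_PAIRS


@dataclass
class ContactRatios:
    """Contact counts normalized by the total; ratios sum to 1."""

    ratios: dict

    def __getitem__(self, pair) -> float:
        return self.ratios.get(canonical_pair(pair), 0.0)


def estimate_cell_diameter(coords: np.ndarray) -> float:
    """Median nearest-neighbor distance, the surrogate for cell diameter d."""
    tree = cKDTree(coords)
    dist, _ = tree.query(coords, k=2)
    nn = dist[:, 1]
    if np.any(nn == 0):
        raise ValidationError("coincident cell coordinates (distance 0)")
    return float(np.median(nn))


def _angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    c = float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def build_contact_graph(
    cloud: IsletPointCloud, criteria: ContactCriteria | None = None
) -> ContactGraph:
    """Contacts by the distance+angle criterion.

    For each cell, distance-neighbors (within ``d_c * d``) are processed
    nearest-first (distance ties broken by cell_id); a farther candidate is
    pruned when it subtends an angle below ``theta_c`` with any retained
    nearer neighbor.  An edge survives only if retained from both endpoints,
    so the graph is symmetric by construction.
    """
    criteria = criteria or ContactCriteria()
    coords = cloud.coords
    n = cloud.n_cells
    d = criteria.d if criteria.d is not None else estimate_cell_diameter(coords)
    r = criteria.d_c * d

    tree = cKDTree(coords)
    neighbor_lists = tree.query_ball_point(coords, r)

    # per-cell retention under the angle rule
    retained = [set() for _ in range(n)]
    ids = cloud.cell_ids
    for i in range(n):
        cand = [j for j in neighbor_lists[i] if j != i]
        if not cand:
            continue
        vec = coords[cand] - coords[i]
        dist = np.linalg.norm(vec, axis=1)
        if np.any(dist == 0):
            raise ValidationError(
                f"coincident coordinates between distinct cells near index {i}"
            )
        order = np.lexsort((np.array([str(ids[j]) for j in cand], dtype=object), dist))
        kept_idx: list[int] = []
        for o in order:
            ok = True
            for k in kept_idx:
                if _angle_deg(vec[o], vec[k]) < criteria.theta_c:
                    ok = False
                    break
            if ok:
                kept_idx.append(o)
                retained[i].add(cand[o])

    edges = [
        (i, j)
        for i in range(n)
        for j in retained[i]
        if i < j and i in retained[j]
    ]
    return ContactGraph(n_cells=n, edges=np.array(edges, dtype=np.int64).reshape(-1, 2))


def distance_only_graph(cloud: IsletPointCloud, criteria: ContactCriteria) -> ContactGraph:
    """Contacts by the distance threshold alone (no angle pruning)."""
    d = criteria.d if criteria.d is not None else estimate_cell_diameter(cloud.coords)
    tree = cKDTree(cloud.coords)
    pairs = tree.query_pairs(criteria.d_c * d, output_type="ndarray")
    return ContactGraph(n_cells=cloud.n_cells, edges=pairs)


@dataclass(frozen=True)
class DegreeTarget:
    """Target contact-number distribution for threshold tuning.

    Defaults encode the working criterion for islet data: mean number of
    neighbors between 8 and 9, no cell with more than 12 or fewer than 1.
    """

    mean_range: tuple = (8.0, 9.0)
    min_degree: int = 1
    max_degree: int = 12


@dataclass
class TuningResult:
    criteria: ContactCriteria
    mean_degree: float
    min_degree: int
    max_degree: int
    graph: ContactGraph


def tune_contact_thresholds(
    cloud: IsletPointCloud,
    target: DegreeTarget | None = None,
    d_c_grid=None,
    theta_c_grid=None,
) -> TuningResult:
    """Grid-search (d_c, theta_c) toward the target degree distribution.

    A grid point is feasible when min degree >= target.min_degree, max degree
    <= target.max_degree and mean degree >= the lower end of the target mean
    range (a cloud too sparse to reach it cannot satisfy the criterion).
    Among feasible points the one whose mean degree is closest to the target
    interval wins.  The d_c grid stays below sqrt(2), the second-nearest
    neighbor distance of the cubic reference lattice, which bounds admissible
    thresholds from above.
    """
    if cloud.n_cells < 50:
        raise ValidationError("threshold tuning needs at least 50 cells")
    target = target or DegreeTarget()
    if d_c_grid is None:
        d_c_grid = np.arange(1.05, 1.401, 0.05)
    if theta_c_grid is None:
        theta_c_grid = np.array([20.0, 25.0, 30.0, 35.0, 40.0])

    lo, hi = target.mean_range
    best = None
    best_feasible = None
    for d_c in d_c_grid:
        for theta_c in theta_c_grid:
            crit = ContactCriteria(d_c=float(d_c), theta_c=float(theta_c))
            graph = build_contact_graph(cloud, crit)
            deg = graph.degrees()
            mean_deg = float(deg.mean())
            res = TuningResult(
                crit, mean_deg, int(deg.min()), int(deg.max()), graph
            )
            gap = max(lo - mean_deg, mean_deg - hi, 0.0)
            feasible = (
                res.min_degree >= target.min_degree
                and res.max_degree <= target.max_degree
                and mean_deg >= lo - 1e-12
            )
            if best is None or gap < best[0]:
                best = (gap, res)
            if feasible and (best_feasible is None or gap < best_feasible[0]):
                best_feasible = (gap, res)
    if best_feasible is None:
        raise TuningError(
            "no grid point satisfies the degree target "
            f"(best mean degree {best[1].mean_degree:.2f}, "
            f"min {best[1].min_degree}, max {best[1].max_degree})",
            best_candidate=best[1],
        )
    return best_feasible[1]


def contact_counts(
    graph: ContactGraph, cloud: IsletPointCloud, ternary: bool | None = None
) -> ContactCounts:
    """Classify every edge by its endpoint types."""
    if graph.n_cells != cloud.n_cells:
        raise ValidationError("graph and cloud sizes disagree")
    if ternary is None:
        ternary = bool(np.any(cloud.cell_types == "delta"))
    pairs = TERNARY_PAIRS if ternary else BINARY_PAIRS
    counts = {p: 0 for p in pairs}
    types = cloud.cell_types
    for i, j in graph.edges:
        counts[canonical_pair((types[i], types[j]))] += 1
    return ContactCounts(counts=counts, ternary=ternary)


def contact_ratios(counts: ContactCounts) -> ContactRatios:
    """Counts normalized by the total number of contacts."""
    total = counts.total
    if total < 1:
        raise ValidationError("cannot form ratios: no contacts")
    return ContactRatios({p: c / total for p, c in counts.counts.items()})


def random_contact_probabilities(comp: Composition) -> ContactRatios:
    """Contact probabilities of a random cell aggregate.

    For a well-mixed aggregate the probability that a contact joins two x
    cells is p_x**2 and that it joins x with y (x != y) is 2*p_x*p_y.
    """
    ps = comp.as_dict()
    active = BINARY_PAIRS if comp.is_binary else TERNARY_PAIRS
    ratios = {}
    for a, b in active:
        ratios[(a, b)] = ps[a] * ps[b] if a == b else 2 * ps[a] * ps[b]
    return ContactRatios(ratios)


def mean_coordination(graph: ContactGraph) -> float:
    """Mean number of contacting neighbors per cell: 2E/n."""
    return 2.0 * graph.n_edges / graph.n_cells


class ContactGraphBuilder(BaseEstimator):
    """Estimator wrapper for contact determination.

    Parameters mirror :class:`ContactCriteria`; with ``tune=True`` the
    thresholds are grid-searched toward `degree_target` instead of taken
    as given.  After :meth:`fit`, ``graph_``, ``criteria_`` and the degree
    statistics are available.
    """

    def __init__(
        self,
        d_c: float = 1.25,
        theta_c: float = 30.0,
        d: float | None = None,
        tune: bool = False,
        degree_target: DegreeTarget | None = None,
    ):
        self.d_c = d_c
        self.theta_c = theta_c
        self.d = d
        self.tune = tune
        self.degree_target = degree_target

    def fit(self, X: IsletPointCloud, y=None):
        if self.tune:
            res = tune_contact_thresholds(X, target=self.degree_target)
            self.criteria_ = res.criteria
            self.graph_ = res.graph
        else:
            self.criteria_ = ContactCriteria(d_c=self.d_c, theta_c=self.theta_c, d=self.d)
            self.graph_ = build_contact_graph(X, self.criteria_)
        deg = self.graph_.degrees()
        self.mean_degree_ = float(deg.mean())
        self.min_degree_ = int(deg.min()) if len(deg) else 0
        self.max_degree_ = int(deg.max()) if len(deg) else 0
        return self

    def fit_transform(self, X: IsletPointCloud, y=None) -> ContactGraph:
        return self.fit(X).graph_
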