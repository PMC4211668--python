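"""Finite, approximately spherical lattice clusters.

Two reference packings stand in for islet geometry: the simple cubic lattice
(6 interior neighbors) and hexagonal close packing (12 interior neighbors,
realized as ABAB stacking of triangular layers with inter-layer spacing
sqrt(2/3)).  A cluster of n sites is cut from a large generating block by
keeping the n sites nearest the block's lattice-point centroid, which gives
a roughly spherical free-boundary aggregate like an isolated islet.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .exceptions import ConfigError, ValidationError
from .contacts import ContactGraph

LATTICE_KINDS = ("cubic", "hcp")
INTERIOR_DEGREE = {"cubic": 6, "hcp": 12}


@dataclass
class LatticeCluster:
    """A finite lattice cluster with unit nearest-neighbor spacing."""

    lattice_kind: str
    sites: np.ndarray  # (n, 3) coordinates in units of the lattice spacing
    adjacency: ContactGraph

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def interior_degree(self) -> int:
        return INTERIOR_DEGREE[self.lattice_kind]

    def surface_mask(self) -> np.ndarray:
        """Sites with fewer neighbors than an interior site."""
        return self.adjacency.degrees() < self.interior_degree


def _cubic_block(m: int) -> np.ndarray:
    g = np.arange(-m, m + 1)
    return (
        np.array(np.meshgrid(g, g, g, indexing="ij")).reshape(3, -1).T.astype(float)
    )


def _hcp_block(m: int) -> np.ndarray:
    dz = np.sqrt(2.0 / 3.0)
    pts = []
    for layer in range(-m, m + 1):
        ox, oy = (0.5, np.sqrt(3.0) / 6.0) if layer % 2 else (0.0, 0.0)
        for i in range(-m, m + 1):
            for j in range(-m, m + 1):
                pts.append((i + 0.5 * j + ox, j * np.sqrt(3.0) / 2.0 + oy, layer * dz))
    return np.array(pts)


def build_cluster(kind: str, n_sites: int) -> LatticeCluster:
    """Cut an approximately spherical n-site cluster from a lattice block.

    The n sites nearest the centroid of the generating block are kept
    (distance ties broken by lexicographic coordinate order); adjacency
    joins site pairs at unit distance.
    """
    if kind not in LATTICE_KINDS:
        raise ConfigError(f"unknown lattice kind {kind!r}")
    if n_sites < 1:
        raise ValidationError("n_sites must be >= 1")
    # block sized so the selected ball never reaches the block boundary
    m = max(3, int(np.ceil(1.6 * n_sites ** (1.0 / 3.0))))
    block = _cubic_block(m) if kind == "cubic" else _hcp_block(m)
    if n_sites > len(block):  # pragma: no cover - auto-sizing prevents this
        raise ConfigError("n_sites exceeds the generating block")
    centroid = block.mean(axis=0)
    d2 = ((block - centroid) ** 2).sum(axis=1)
    order = np.lexsort((block[:, 2], block[:, 1], block[:, 0], d2))
    sites = block[order[:n_sites]]
    tree = cKDTree(sites)
    pairs = tree.query_pairs(1.0 + 1e-9, output_type="ndarray")
    if len(pairs):
        dist = np.linalg.norm(sites[pairs[:, 0]] - sites[pairs[:, 1]], axis=1)
        pairs = pairs[dist > 1.0 - 1e-9]
    adjacency = ContactGraph(n_cells=n_sites, edges=pairs)
    return LatticeCluster(lattice_kind=kind, sites=sites, adjacency=adjacency)


def cluster_degree_stats(cluster: LatticeCluster) -> tuple[float, int, int]:
    """(mean, min, max) site degree of the cluster adjacency."""
    deg = cluster.adjacency.degrees()
    if len(deg) == 0:
        return 0.0, 0, 0
    return float(deg.mean()), int(deg.min()), int(deg.max())
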