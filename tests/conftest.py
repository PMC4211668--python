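"""Shared fixtures: tiny hand-built clouds and session-scoped lattice clusters."""

import numpy as np
import pytest

from isletsort.contacts import ContactGraph
from isletsort.io import IsletPointCloud
from isletsort.lattice import build_cluster


def make_cloud(coords, types, islet_id="islet-1"):
    coords = np.asarray(coords, dtype=float)
    return IsletPointCloud(
        islet_id=islet_id,
        cell_ids=np.array([f"c{i}" for i in range(len(coords))], dtype=object),
        coords=coords,
        cell_types=np.array(types, dtype=object),
    )


@pytest.fixture(scope="session")
def hcp_1357():
    return build_cluster("hcp", 1357)


@pytest.fixture(scope="session")
def cubic_1357():
    return build_cluster("cubic", 1357)


@pytest.fixture(scope="session")
def hcp_200():
    return build_cluster("hcp", 200)


@pytest.fixture(scope="session")
def jittered_hcp_cloud(hcp_200):
    """200-site HCP cluster with Gaussian jitter (SD 0.05 spacings), fixed seed."""
    rng = np.random.default_rng(20)
    coords = hcp_200.sites + rng.normal(0.0, 0.05, size=hcp_200.sites.shape)
    return make_cloud(coords, ["beta"] * hcp_200.n_sites, islet_id="jittered-hcp")


@pytest.fixture
def triangle_abb():
    """Triangle alpha-beta-beta: 3 cells at unit spacing, fully connected."""
    cloud = make_cloud(
        [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.5, np.sqrt(3) / 2, 0.0]],
        ["alpha", "beta", "beta"],
    )
    graph = ContactGraph(n_cells=3, edges=np.array([[0, 1], [0, 2], [1, 2]]))
    return cloud, graph
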