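"""Adhesion model: self-energy, Metropolis swap dynamics, mixing index."""

from itertools import combinations, permutations

import numpy as np
import pytest
from scipy.stats import chisquare

from isletsort.adhesion import (
    AttractionSet,
    MCConfig,
    metropolis_equilibrate,
    mixing_index,
    self_energy,
)
from isletsort.contacts import ContactGraph, contact_counts
from isletsort.exceptions import ConfigError, ValidationError
from isletsort.io import Composition
from isletsort.lattice import build_cluster

from conftest import make_cloud


def complete_graph(n):
    return ContactGraph(
        n_cells=n, edges=np.array(list(combinations(range(n), 2)), dtype=np.int64)
    )


def boltzmann_pair_means(graph, type_multiset, j, e_f):
    """Exact Boltzmann averages of pair contact counts by full enumeration."""
    seen = set()
    states = []
    for perm in permutations(type_multiset):
        if perm in seen:
            continue
        seen.add(perm)
        states.append(perm)
    energies = np.array([self_energy(graph, np.array(s, dtype=object), j) for s in states])
    w = np.exp(-(energies - energies.min()) / e_f)
    w /= w.sum()
    means = {}
    for s, wk in zip(states, w):
        types = np.array(s, dtype=object)
        for i, jdx in graph.edges:
            key = tuple(sorted((types[i], types[jdx])))
            means[key] = means.get(key, 0.0) + wk
    return means, states, w


class TestSelfEnergy:
    def test_single_edge(self):
        g = ContactGraph(n_cells=2, edges=np.array([[0, 1]]))
        j = AttractionSet.binary(j_bb=1.0, j_ab=0.9)
        assert self_energy(g, ["beta", "beta"], j) == -1.0

    def test_triangle(self):
        g = complete_graph(3)
        j = AttractionSet.binary(j_bb=1.0, j_ab=0.9)
        assert self_energy(g, ["alpha", "beta", "beta"], j) == pytest.approx(-2.8)

    def test_edgeless(self):
        g = ContactGraph(n_cells=3, edges=np.empty((0, 2), dtype=np.int64))
        j = AttractionSet.binary(1.0, 0.9)
        assert self_energy(g, ["alpha", "beta", "beta"], j) == 0.0

    def test_always_nonpositive(self):
        rng = np.random.default_rng(4)
        g = build_cluster("hcp", 60).adjacency
        types = rng.choice(["alpha", "beta"], size=60)
        j = AttractionSet.binary(1.2, 0.7)
        assert self_energy(g, types, j) <= 0

    def test_missing_pair_rejected(self):
        g = ContactGraph(n_cells=2, edges=np.array([[0, 1]]))
        j = AttractionSet({("beta", "beta"): 1.0})
        with pytest.raises(ConfigError):
            self_energy(g, ["alpha", "beta"], j)


class TestAttractionSet:
    def test_reference_defaults_to_one(self):
        j = AttractionSet({("beta", "beta"): 0.97})
        assert j[("alpha", "alpha")] == 1.0

    def test_symmetry_of_keys(self):
        j = AttractionSet.binary(1.0, 0.9)
        assert j[("beta", "alpha")] == j[("alpha", "beta")] == 0.9

    def test_nonpositive_rejected(self):
        with pytest.raises(ConfigError):
            AttractionSet.binary(j_bb=0.0, j_ab=0.9)


class TestMetropolis:
    def test_equal_attractions_match_permutation_expectation(self, hcp_200):
        # with all J equal every assignment is equally likely, so the mean
        # heterotypic count has the exact random-permutation expectation
        n = hcp_200.n_sites
        n_alpha = 50
        types = np.array(["alpha"] * n_alpha + ["beta"] * (n - n_alpha), dtype=object)
        j = AttractionSet.binary(j_bb=1.0, j_ab=1.0, j_aa=1.0)
        _, summary = metropolis_equilibrate(
            hcp_200.adjacency,
            types,
            j,
            MCConfig(e_f=0.6, n_equilibration_sweeps=300, n_recording_sweeps=600, seed=7),
        )
        n_edges = hcp_200.adjacency.n_edges
        expected = n_edges * 2 * n_alpha * (n - n_alpha) / (n * (n - 1))
        samples = summary.samples[:, 1]  # kernel pair index 1 = alpha-beta
        se = samples.std(ddof=1) / np.sqrt(len(samples))
        assert abs(summary.mean[("alpha", "beta")] - expected) < 3 * max(se, 1.0)

    def test_complete_graph_matches_enumeration(self):
        # K4 with 2 alpha / 2 beta: 6 assignments, exact Boltzmann averages
        g = complete_graph(4)
        j = AttractionSet.binary(j_bb=1.3, j_ab=0.7, j_aa=1.0)
        e_f = 0.5
        exact, _, _ = boltzmann_pair_means(g, ("alpha", "alpha", "beta", "beta"), j, e_f)
        types = np.array(["alpha", "alpha", "beta", "beta"], dtype=object)
        _, summary = metropolis_equilibrate(
            g,
            types,
            j,
            MCConfig(e_f=e_f, n_equilibration_sweeps=500, n_recording_sweeps=4000, seed=3),
        )
        for kidx, pair in [(1, ("alpha", "beta")), (2, ("beta", "beta")), (0, ("alpha", "alpha"))]:
            samples = summary.samples[:, kidx]
            se = samples.std(ddof=1) / np.sqrt(len(samples))
            assert abs(summary.mean[pair] - exact[pair]) < 3 * max(se, 0.05)

    def test_type_counts_conserved(self, hcp_200):
        rng = np.random.default_rng(0)
        types = rng.choice(["alpha", "beta"], size=hcp_200.n_sites, p=[0.3, 0.7])
        final, _ = metropolis_equilibrate(
            hcp_200.adjacency,
            types,
            AttractionSet.binary(1.0, 0.8),
            MCConfig(n_equilibration_sweeps=50, n_recording_sweeps=10, seed=1),
        )
        assert np.sum(final == "alpha") == np.sum(types == "alpha")

    def test_contact_count_conservation_each_sample(self, hcp_200):
        rng = np.random.default_rng(2)
        types = rng.choice(["alpha", "beta"], size=hcp_200.n_sites)
        _, summary = metropolis_equilibrate(
            hcp_200.adjacency,
            types,
            AttractionSet.binary(1.0, 0.9),
            MCConfig(n_equilibration_sweeps=50, n_recording_sweeps=50, seed=1),
        )
        totals = summary.samples.sum(axis=1)
        assert np.all(totals == hcp_200.adjacency.n_edges)
        assert sum(summary.mean.values()) == pytest.approx(hcp_200.adjacency.n_edges)

    def test_detailed_balance_small_graph(self):
        # 8-cell path fragment, 3 alpha / 5 beta: the empirical stationary
        # distribution over the 56 assignments matches Boltzmann weights
        g = ContactGraph(
            n_cells=8, edges=np.array([[i, i + 1] for i in range(7)], dtype=np.int64)
        )
        j = AttractionSet.binary(j_bb=1.2, j_ab=0.8, j_aa=1.0)
        e_f = 0.7
        _, states, w_exact = boltzmann_pair_means(
            g, ("alpha",) * 3 + ("beta",) * 5, j, e_f
        )
        state_index = {s: k for k, s in enumerate(states)}

        from isletsort.adhesion import types_to_codes
        from isletsort import _mc

        codes = types_to_codes(np.array(states[0], dtype=object))
        indptr, indices = g.adjacency_csr()
        samples_counts = np.zeros(len(states))
        # sample the chain state every 100 sweeps via repeated short runs
        rng = np.random.default_rng(9)
        code_states = np.array([types_to_codes(np.array(s, dtype=object)) for s in states])
        work = codes.copy()
        for rep in range(400):
            _mc.run_chain(
                indptr, indices, np.ascontiguousarray(g.edges), work,
                np.nan_to_num(j.matrix(), nan=1.0), e_f, 0, 100,
                int(rng.integers(0, 2**31 - 1)),
            )
            # accumulate state visits by matching the mutated assignment
            k = int(np.flatnonzero((code_states == work).all(axis=1))[0])
            samples_counts[k] += 1
        # chi-square over states aggregated to avoid tiny expected counts
        order = np.argsort(w_exact)[::-1]
        top = order[:10]
        rest = order[10:]
        f_obs = np.append(samples_counts[top], samples_counts[rest].sum())
        f_exp = np.append(w_exact[top], w_exact[rest].sum()) * samples_counts.sum()
        stat, p = chisquare(f_obs, f_exp)
        assert p > 0.01

    def test_mean_heterotypic_monotone_in_j_ab(self, hcp_1357):
        # stronger heterotypic attraction never reduces mixing at equilibrium
        n = hcp_1357.n_sites
        n_alpha = n // 10
        base = np.array(["alpha"] * n_alpha + ["beta"] * (n - n_alpha), dtype=object)
        means = []
        ses = []
        for k, j_ab in enumerate([0.7, 0.85, 1.0, 1.15, 1.3]):
            rng = np.random.default_rng(5)
            t = base.copy()
            rng.shuffle(t)
            _, s = metropolis_equilibrate(
                hcp_1357.adjacency,
                t,
                AttractionSet.binary(j_bb=1.0, j_ab=j_ab),
                MCConfig(e_f=0.6, n_equilibration_sweeps=600, n_recording_sweeps=300, seed=20 + k),
            )
            samples = s.samples[:, 1]
            means.append(s.mean[("alpha", "beta")])
            ses.append(samples.std(ddof=1) / np.sqrt(len(samples)))
        for a, b, sa, sb in zip(means, means[1:], ses, ses[1:]):
            assert b > a - 3 * (sa + sb)

    def test_local_delta_e_equals_full_resummation(self, hcp_200):
        # the swap energy change computed from the two affected
        # neighborhoods must equal the brute-force energy difference
        rng = np.random.default_rng(6)
        g = hcp_200.adjacency
        types = rng.choice(["alpha", "beta"], size=hcp_200.n_sites).astype(object)
        j = AttractionSet.binary(j_bb=1.3, j_ab=0.7, j_aa=0.9)
        indptr_indices = g.adjacency_csr()
        indptr, indices = indptr_indices
        jm = np.nan_to_num(j.matrix(), nan=1.0)
        from isletsort.adhesion import types_to_codes

        codes = types_to_codes(types)
        for _ in range(50):
            i, k = rng.choice(hcp_200.n_sites, size=2, replace=False)
            a, b = codes[i], codes[k]
            local = 0.0
            for p in range(indptr[i], indptr[i + 1]):
                nb = indices[p]
                if nb == k:
                    continue
                local -= jm[b, codes[nb]] - jm[a, codes[nb]]
            for p in range(indptr[k], indptr[k + 1]):
                nb = indices[p]
                if nb == i:
                    continue
                local -= jm[a, codes[nb]] - jm[b, codes[nb]]
            before = self_energy(g, types, j)
            swapped = types.copy()
            swapped[i], swapped[k] = swapped[k], swapped[i]
            after = self_energy(g, swapped, j)
            assert local == pytest.approx(after - before, abs=1e-9)

    def test_invalid_config(self):
        with pytest.raises(ConfigError):
            MCConfig(e_f=0.0)
        with pytest.raises(ConfigError):
            MCConfig(n_equilibration_sweeps=0)

    def test_mismatched_assignment_rejected(self, hcp_200):
        with pytest.raises(ValidationError):
            metropolis_equilibrate(
                hcp_200.adjacency,
                np.array(["beta"] * 10, dtype=object),
                AttractionSet.binary(1.0, 0.9),
                MCConfig(seed=0),
            )


class TestMixingIndex:
    def test_random_shuffle_near_one(self, hcp_200):
        rng = np.random.default_rng(8)
        n = hcp_200.n_sites
        types = np.array(["alpha"] * 60 + ["beta"] * (n - 60), dtype=object)
        comp = Composition(60 / n, (n - 60) / n)
        vals = []
        for _ in range(1000):
            rng.shuffle(types)
            cloud = make_cloud(hcp_200.sites, types)
            counts = contact_counts(hcp_200.adjacency, cloud)
            vals.append(mixing_index(counts, comp))
        vals = np.array(vals)
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        # finite-N correction: expectation is N/(N-1) of the p-squared law
        expected = n / (n - 1)
        assert abs(vals.mean() - expected) < 3 * se

    def test_two_block_sorting_far_below_one(self):
        # two homogeneous blocks joined by one interface edge
        edges = [[i, i + 1] for i in range(9)]
        g = ContactGraph(n_cells=10, edges=np.array(edges))
        cloud = make_cloud(
            [[i, 0, 0] for i in range(10)], ["alpha"] * 5 + ["beta"] * 5
        )
        counts = contact_counts(g, cloud)
        m = mixing_index(counts, Composition(0.5, 0.5))
        assert m == pytest.approx((1 / 9) / 0.5)
        assert m < 0.5

    def test_checkerboard_above_one(self):
        edges = [[i, i + 1] for i in range(9)]
        g = ContactGraph(n_cells=10, edges=np.array(edges))
        cloud = make_cloud(
            [[i, 0, 0] for i in range(10)], ["alpha", "beta"] * 5
        )
        counts = contact_counts(g, cloud)
        assert mixing_index(counts, Composition(0.5, 0.5)) == pytest.approx(2.0)

    def test_undefined_for_single_type(self, triangle_abb):
        cloud, graph = triangle_abb
        counts = contact_counts(graph, cloud)
        with pytest.raises(ValidationError):
            mixing_index(counts, Composition(0.0, 1.0))
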