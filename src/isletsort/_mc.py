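"""Numba kernel for Metropolis type-swap dynamics on a fixed contact graph.

Cell positions never move; a Monte-Carlo step proposes exchanging the types
of two uniformly chosen cells and accepts with probability
min(1, exp(-dE/E_f)).  dE is computed from the two affected neighborhoods
only (the shared edge, if the cells are adjacent, cancels because J is
symmetric).  Contact counts are tallied per unordered type-pair index:

    0: alpha-alpha  1: alpha-beta  2: beta-beta
    3: delta-delta  4: alpha-delta 5: beta-delta
"""

import numpy as np
from numba import njit

N_PAIRS = 6


@njit(cache=True, inline="always")
def pair_index(a, b):
    if a > b:
        a, b = b, a
    if b <= 1:
        return a + b
    if a == 2:
        return 3
    return 4 + a


@njit(cache=True)
def count_contacts(edges, types):
    c = np.zeros(N_PAIRS, dtype=np.int64)
    for k in range(edges.shape[0]):
        c[pair_index(types[edges[k, 0]], types[edges[k, 1]])] += 1
    return c


@njit(cache=True)
def run_chain(indptr, indices, edges, types, jmat, e_f, n_equil, n_record, seed):
    """Equilibrate then record contact counts once per sweep.

    Mutates ``types`` in place; returns (samples, n_accepted, n_proposed)
    where samples is (n_record, 6) int64.  A sweep is n_cells proposals;
    proposals picking the same cell twice or two same-type cells are no-ops
    that still count as steps.
    """
    np.random.seed(seed)
    n = types.shape[0]
    samples = np.zeros((n_record, N_PAIRS), dtype=np.int64)
    n_acc = 0
    n_prop = 0
    rec = 0
    for sweep in range(n_equil + n_record):
        for _ in range(n):
            n_prop += 1
            i = np.random.randint(0, n)
            j = np.random.randint(0, n)
            if i == j:
                continue
            a = types[i]
            b = types[j]
            if a == b:
                n_acc += 1  # dE = 0: always accepted, counts invariant
                continue
            d_e = 0.0
            for p in range(indptr[i], indptr[i + 1]):
                k = indices[p]
                if k == j:
                    continue
                d_e -= jmat[b, types[k]] - jmat[a, types[k]]
            for p in range(indptr[j], indptr[j + 1]):
                k = indices[p]
                if k == i:
                    continue
                d_e -= jmat[a, types[k]] - jmat[b, types[k]]
            if d_e <= 0.0 or np.random.random() < np.exp(-d_e / e_f):
                types[i] = b
                types[j] = a
                n_acc += 1
        if sweep >= n_equil:
            samples[rec] = count_contacts(edges, types)
            rec += 1
    return samples, n_acc, n_prop
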