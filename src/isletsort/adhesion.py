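"""Differential-adhesion lattice-gas model on a fixed contact graph.

The islet self-energy is the negated sum of pairwise attraction energies
over all contacts,

    E = - sum_{<i,j>} J_{tau(i) tau(j)},

where tau(i) is the cell type at site i and J_xy > 0 is the relative
attraction between types x and y, measured in units of the reference
attraction J_aa = 1 (alpha-alpha).  Minimizing E by exchanging cell
positions at fluctuation energy E_f (a temperature-like stand-in for cell
motility) yields equilibrium structures; type counts are exactly conserved
because the dynamics only swaps cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _mc
from .contacts import ContactCounts, ContactGraph
from .exceptions import ConfigError, ValidationError
from .io import (
    BINARY_PAIRS,
    CELL_TYPES,
    TERNARY_PAIRS,
    TYPE_CODES,
    Composition,
    canonical_pair,
)

# pair-index order used by the MC kernel
KERNEL_PAIRS = (
    ("alpha", "alpha"),
    ("alpha", "beta"),
    ("beta", "beta"),
    ("delta", "delta"),
    ("alpha", "delta"),
    ("beta", "delta"),
)


class AttractionSet:
    """Symmetric relative attractions J_xy, reference J_alpha,alpha = 1."""

    def __init__(self, j: dict):
        self._j = {}
        for pair, value in j.items():
            key = canonical_pair(pair)
            value = float(value)
            if value <= 0:
                raise ConfigError(f"attraction J_{key} must be positive, got {value}")
            prev = self._j.get(key)
            if prev is not None and prev != value:
                raise ConfigError(f"conflicting values for J_{key}")
            self._j[key] = value
        self._j.setdefault(("alpha", "alpha"), 1.0)

    @classmethod
    def binary(cls, j_bb: float, j_ab: float, j_aa: float = 1.0) -> "AttractionSet":
        return cls({("beta", "beta"): j_bb, ("alpha", "beta"): j_ab, ("alpha", "alpha"): j_aa})

    @classmethod
    def ternary(
        cls,
        j_bb: float,
        j_ab: float,
        j_dd: float,
        j_ad: float,
        j_bd: float,
        j_aa: float = 1.0,
    ) -> "AttractionSet":
        return cls(
            {
                ("beta", "beta"): j_bb,
                ("alpha", "beta"): j_ab,
                ("delta", "delta"): j_dd,
                ("alpha", "delta"): j_ad,
                ("beta", "delta"): j_bd,
                ("alpha", "alpha"): j_aa,
            }
        )

    def __getitem__(self, pair) -> float:
        key = canonical_pair(pair)
        if key not in self._j:
            raise ConfigError(f"no attraction configured for pair {key}")
        return self._j[key]

    def __contains__(self, pair) -> bool:
        return canonical_pair(pair) in self._j

    def as_dict(self) -> dict:
        return dict(self._j)

    def matrix(self) -> np.ndarray:
        """3x3 J matrix indexed by type codes; missing pairs are NaN."""
        m = np.full((3, 3), np.nan)
        for (a, b), v in self._j.items():
            ia, ib = TYPE_CODES[a], TYPE_CODES[b]
            m[ia, ib] = m[ib, ia] = v
        return m


@dataclass(frozen=True)
class MCConfig:
    """Metropolis run lengths and fluctuation energy.

    ``e_f`` is in units of the reference attraction; a sweep is one proposed
    swap per cell.  Defaults (2000 equilibration + 1000 recording sweeps)
    hold the running mean of every contact count steady to within its own
    Monte-Carlo standard error for clusters up to a few thousand cells.
    """

    e_f: float = 0.6
    n_equilibration_sweeps: int = 2000
    n_recording_sweeps: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.e_f <= 0:
            raise ConfigError("fluctuation energy E_f must be positive")
        if self.n_equilibration_sweeps < 1 or self.n_recording_sweeps < 1:
            raise ConfigError("sweep counts must be >= 1")


@dataclass
class EquilibriumSummary:
    """Mean and variance of per-pair contact counts over recorded sweeps."""

    mean: dict
    var: dict
    n_samples: int
    n_edges: int
    acceptance_rate: float
    samples: np.ndarray | None = None  # (n_samples, 6) kernel-order counts

    def __getitem__(self, pair):
        key = canonical_pair(pair)
        return self.mean[key], self.var[key]


def types_to_codes(cell_types) -> np.ndarray:
    return np.array([TYPE_CODES[t] for t in cell_types], dtype=np.int8)


def codes_to_types(codes) -> np.ndarray:
    rev = {v: k for k, v in TYPE_CODES.items()}
    return np.array([rev[int(c)] for c in codes], dtype=object)


def self_energy(graph: ContactGraph, cell_types, j: AttractionSet) -> float:
    """Islet self-energy E = -sum over contacts of J_xy; always <= 0."""
    types = np.asarray(cell_types, dtype=object)
    if len(types) != graph.n_cells:
        raise ValidationError("type assignment does not cover the graph")
    e = 0.0
    for i, jdx in graph.edges:
        e -= j[(types[i], types[jdx])]
    return e


def _active_pairs(codes: np.ndarray):
    return TERNARY_PAIRS if np.any(codes == 2) else BINARY_PAIRS


def metropolis_equilibrate(
    graph: ContactGraph,
    initial_types,
    j: AttractionSet,
    cfg: MCConfig | None = None,
    keep_samples: bool = True,
):
    """Equilibrate a type assignment by Metropolis swap dynamics.

    Returns ``(final_types, EquilibriumSummary)``.  Swap proposals choose
    two cells uniformly (same-type picks are accepted no-ops), so type
    counts are conserved exactly; contact counts are recorded once per sweep
    after the equilibration phase.
    """
    cfg = cfg or MCConfig()
    codes = types_to_codes(initial_types)
    if len(codes) != graph.n_cells:
        raise ValidationError("initial assignment does not cover the graph")
    jmat = j.matrix()
    present = np.unique(codes)
    for a in present:
        for b in present:
            if np.isnan(jmat[a, b]):
                raise ConfigError(
                    f"no attraction configured for present pair ({CELL_TYPES[a]}, {CELL_TYPES[b]})"
                )
    jmat = np.nan_to_num(jmat, nan=1.0)
    indptr, indices = graph.adjacency_csr()
    samples, n_acc, n_prop = _mc.run_chain(
        indptr,
        indices,
        np.ascontiguousarray(graph.edges, dtype=np.int64),
        codes,
        jmat,
        float(cfg.e_f),
        int(cfg.n_equilibration_sweeps),
        int(cfg.n_recording_sweeps),
        int(cfg.seed) & 0x7FFFFFFF,
    )
    pairs = _active_pairs(codes)
    kernel_idx = {p: KERNEL_PAIRS.index(p) for p in pairs}
    mean = {p: float(samples[:, kernel_idx[p]].mean()) for p in pairs}
    var = {p: float(samples[:, kernel_idx[p]].var()) for p in pairs}
    summary = EquilibriumSummary(
        mean=mean,
        var=var,
        n_samples=samples.shape[0],
        n_edges=graph.n_edges,
        acceptance_rate=n_acc / max(n_prop, 1),
        samples=samples if keep_samples else None,
    )
    return codes_to_types(codes), summary


def equilibrium_counts(summary: EquilibriumSummary) -> ContactCounts:
    """Rounded mean contact counts as a ContactCounts (diagnostic helper)."""
    ternary = ("delta", "delta") in summary.mean
    return ContactCounts(
        {p: int(round(v)) for p, v in summary.mean.items()}, ternary=ternary
    )


def mixing_index(counts_or_summary, comp: Composition) -> float:
    """Heterotypic alpha-beta contact ratio over its random expectation.

    1 means random-like mixing; below 1, a sorting tendency; above 1, an
    anti-sorting (checkerboard) tendency.
    """
    if comp.p_alpha == 0 or comp.p_beta == 0:
        raise ValidationError("mixing index undefined when p_alpha or p_beta is 0")
    if isinstance(counts_or_summary, EquilibriumSummary):
        total = sum(counts_or_summary.mean.values())
        r_ab = counts_or_summary.mean[("alpha", "beta")] / total
    else:
        counts = counts_or_summary
        total = counts.total
        if total < 1:
            raise ValidationError("mixing index undefined without contacts")
        r_ab = counts[("alpha", "beta")] / total
    return r_ab / (2.0 * comp.p_alpha * comp.p_beta)
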