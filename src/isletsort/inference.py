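"""Bayesian inference of relative cell-cell attractions.

The inverse problem: given one observed islet structure (its contact graph
and per-pair contact counts), find the relative attractions J_xy that make
the adhesion model's equilibrium reproduce it.  Candidate attraction sets
are sampled (reference pair pinned at J_aa = 1), each is equilibrated on
the islet's own contact graph with its own type counts, and the candidate
is scored by the mismatch

    X = sum_pairs (N_obs_xy - <N_xy>)^2 / (2 var(N_xy)),

the variance-weighted squared deviation between observed and equilibrium
contact counts.  By maximum entropy the likelihood of a candidate is
proportional to exp(-X); posterior means and SDs of each J_xy (and of the
ratio J_ab/J_bb) are likelihood-weighted moments over all trials.  To spend
trials where they matter, a second sampling phase draws from a focus zone
around the lowest-mismatch candidates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.base import BaseEstimator

from .adhesion import (
    AttractionSet,
    EquilibriumSummary,
    MCConfig,
    metropolis_equilibrate,
)
from .contacts import (
    ContactCounts,
    ContactCriteria,
    ContactGraph,
    build_contact_graph,
    contact_counts,
)
from .exceptions import ConfigError, DegenerateLikelihoodError, ValidationError
from .io import (
    BINARY_PAIRS,
    Composition,
    IsletPointCloud,
    canonical_pair,
)

#: free parameters per mode; the reference pair (alpha, alpha) is pinned at 1
BINARY_FREE = (("beta", "beta"), ("alpha", "beta"))
TERNARY_FREE = (
    ("beta", "beta"),
    ("alpha", "beta"),
    ("delta", "delta"),
    ("alpha", "delta"),
    ("beta", "delta"),
)


@dataclass
class MismatchScore:
    """Variance-weighted squared deviation between observed and model counts."""

    x: float
    contributions: dict

    @property
    def is_infinite(self) -> bool:
        return not np.isfinite(self.x)


def mismatch(
    observed: ContactCounts,
    summary: EquilibriumSummary,
    convention: str = "half",
    var_floor: float = 1.0,
) -> MismatchScore:
    """Mismatch X between an observed census and an equilibrium summary.

    ``convention="half"`` uses 1/(2 var) weights, ``"plain"`` 1/var; the
    posterior ratio statistics are insensitive to the choice.  Variances
    below ``var_floor`` are floored to keep rare pairs (e.g. alpha-alpha in
    a 90%-beta islet) from dominating with near-singular weights.  With the
    floor disabled, a zero-variance pair matching exactly contributes 0 and
    any deviation on it makes X infinite.
    """
    if convention not in ("half", "plain"):
        raise ConfigError(f"unknown mismatch convention {convention!r}")
    denom_scale = 2.0 if convention == "half" else 1.0
    contributions = {}
    for pair in observed.counts:
        if pair not in summary.mean:
            raise ValidationError(f"pair {pair} missing from equilibrium summary")
        dev = observed[pair] - summary.mean[pair]
        var = max(summary.var[pair], var_floor)
        if var == 0.0:
            contributions[pair] = 0.0 if dev == 0 else np.inf
        else:
            contributions[pair] = dev * dev / (denom_scale * var)
    extra = set(summary.mean) - set(observed.counts)
    if extra:
        raise ValidationError(f"pairs {extra} present only in the summary")
    return MismatchScore(x=float(sum(contributions.values())), contributions=contributions)


def likelihood_weights(scores) -> np.ndarray:
    """Normalized weights w_k proportional to exp(-X_k).

    The minimum score is subtracted before exponentiation for stability.
    """
    xs = np.array(
        [s.x if isinstance(s, MismatchScore) else float(s) for s in scores]
    )
    if len(xs) == 0:
        raise ValidationError("need at least one mismatch score")
    finite = np.isfinite(xs)
    if not finite.any():
        raise DegenerateLikelihoodError("all mismatch scores are infinite")
    w = np.zeros_like(xs)
    w[finite] = np.exp(-(xs[finite] - xs[finite].min()))
    return w / w.sum()


@dataclass(frozen=True)
class InferenceConfig:
    """Sampling plan for the attraction search.

    ``j_range`` is the uniform prior box per free pair.  After the uniform
    fraction of trials, the remainder are drawn in ``focus_rounds`` rounds
    from the focus zone: the bounding box of the candidates whose mismatch
    lies within ``focus_delta`` of the best so far (at least ``focus_min_keep``
    of them), expanded by ``focus_margin`` per side and clipped to
    ``j_range``.  A likelihood-ratio window exp(-focus_delta) keeps the zone
    aligned with where the posterior carries weight, which matters most in
    the five-dimensional ternary search.
    """

    j_range: tuple = (0.5, 1.5)
    n_trials: int = 2000
    focus_fraction: float = 0.5
    focus_delta: float = 6.0
    focus_min_keep: int = 10
    focus_margin: float = 0.25
    focus_rounds: int = 3
    focus_min_span: float = 0.1
    mc: MCConfig = field(
        default_factory=lambda: MCConfig(
            e_f=0.6, n_equilibration_sweeps=100, n_recording_sweeps=50
        )
    )
    mismatch_convention: str = "half"
    var_floor: float = 1.0
    ess_floor: float = 50.0
    seed: int = 0

    def __post_init__(self):
        if self.n_trials < 100:
            raise ConfigError("n_trials must be >= 100")
        if not (0 < self.j_range[0] < self.j_range[1]):
            raise ConfigError("j_range must be positive and increasing")
        if not (0.0 <= self.focus_fraction < 1.0):
            raise ConfigError("focus_fraction must lie in [0, 1)")


@dataclass
class PosteriorSummary:
    """Likelihood-weighted posterior moments of the attractions."""

    mean: dict
    sd: dict
    ratio_mean: float  # J_ab / J_bb
    ratio_sd: float
    n_trials: int
    ess: float
    low_ess: bool
    trials_j: np.ndarray  # (n_trials, n_free) sampled attractions
    trials_x: np.ndarray  # (n_trials,) mismatch scores
    weights: np.ndarray
    free_pairs: tuple

    def __getitem__(self, pair):
        key = canonical_pair(pair)
        return self.mean[key], self.sd[key]


def _sample_uniform(rng, lo, hi, n, dim):
    return rng.uniform(lo, hi, size=(n, dim))


def _composition_to_counts(comp: Composition, n_cells: int) -> dict:
    """Largest-remainder rounding of fractions to integer counts."""
    fracs = comp.as_dict()
    raw = {t: p * n_cells for t, p in fracs.items()}
    counts = {t: int(np.floor(v)) for t, v in raw.items()}
    short = n_cells - sum(counts.values())
    for t in sorted(raw, key=lambda t: raw[t] - counts[t], reverse=True)[:short]:
        counts[t] += 1
    return counts


def infer_attractions(
    graph: ContactGraph,
    observed: ContactCounts,
    comp,
    cfg: InferenceConfig | None = None,
) -> PosteriorSummary:
    """Posterior attractions for one islet from its graph and contact census.

    ``comp`` gives the cells occupying the graph, either as a dict of
    integer type counts or as a :class:`Composition` (converted to counts by
    largest-remainder rounding); the counts are conserved by the swap
    dynamics.  Ternary mode (five free attractions) is used when the census
    contains delta pairs, otherwise binary mode (two free attractions).
    """
    cfg = cfg or InferenceConfig()
    if isinstance(comp, Composition):
        type_counts = _composition_to_counts(comp, graph.n_cells)
    else:
        type_counts = dict(comp)
    ternary = observed.ternary
    free = TERNARY_FREE if ternary else BINARY_FREE
    rng = np.random.default_rng(cfg.seed)
    n_cells = graph.n_cells
    counts_list = [(t, c) for t, c in type_counts.items() if c > 0]
    if sum(c for _, c in counts_list) != n_cells:
        raise ValidationError("type counts do not sum to the number of cells")

    base_types = np.concatenate(
        [np.array([t] * c, dtype=object) for t, c in counts_list]
    )

    lo, hi = cfg.j_range
    n_uniform = int(round(cfg.n_trials * (1.0 - cfg.focus_fraction)))
    n_uniform = min(max(n_uniform, 1), cfg.n_trials)
    n_focus = cfg.n_trials - n_uniform

    def run_trial(j_vec):
        j = AttractionSet({p: v for p, v in zip(free, j_vec)})
        init = base_types.copy()
        rng.shuffle(init)
        _, summary = metropolis_equilibrate(
            graph,
            init,
            j,
            replace(cfg.mc, seed=int(rng.integers(0, 2**31 - 1))),
            keep_samples=False,
        )
        return mismatch(
            observed, summary, convention=cfg.mismatch_convention, var_floor=cfg.var_floor
        ).x

    trials_j = np.empty((cfg.n_trials, len(free)))
    trials_x = np.empty(cfg.n_trials)
    trials_j[:n_uniform] = _sample_uniform(rng, lo, hi, n_uniform, len(free))
    for k in range(n_uniform):
        trials_x[k] = run_trial(trials_j[k])

    # focus refinement: each round samples inside the (expanded) bounding box
    # of the lowest-mismatch candidates accumulated so far, progressively
    # concentrating trials where exp(-X) carries weight
    done = n_uniform
    rounds = max(1, cfg.focus_rounds)
    for r in range(rounds):
        remaining_rounds = rounds - r
        n_round = (cfg.n_trials - done + remaining_rounds - 1) // remaining_rounds
        if n_round <= 0:
            continue
        masked = np.where(np.isfinite(trials_x[:done]), trials_x[:done], np.inf)
        x_min = masked.min()
        keep = masked <= x_min + cfg.focus_delta
        if keep.sum() < cfg.focus_min_keep:
            keep = np.argsort(masked)[: cfg.focus_min_keep]
        best = trials_j[:done][keep]
        span = np.maximum(best.max(axis=0) - best.min(axis=0), cfg.focus_min_span)
        zone_lo = np.clip(best.min(axis=0) - cfg.focus_margin * span, lo, hi)
        zone_hi = np.clip(best.max(axis=0) + cfg.focus_margin * span, lo, hi)
        zone_hi = np.maximum(zone_hi, zone_lo + 1e-6)
        trials_j[done : done + n_round] = rng.uniform(
            zone_lo, zone_hi, size=(n_round, len(free))
        )
        for k in range(done, done + n_round):
            trials_x[k] = run_trial(trials_j[k])
        done += n_round

    w = likelihood_weights(trials_x)
    ess = float(1.0 / np.sum(w**2))

    mean = {}
    sd = {}
    for d, pair in enumerate(free):
        mu = float(np.sum(w * trials_j[:, d]))
        var = float(np.sum(w * (trials_j[:, d] - mu) ** 2))
        mean[pair] = mu
        sd[pair] = float(np.sqrt(max(var, 0.0)))
    mean[("alpha", "alpha")] = 1.0
    sd[("alpha", "alpha")] = 0.0

    i_bb = free.index(("beta", "beta"))
    i_ab = free.index(("alpha", "beta"))
    ratio = trials_j[:, i_ab] / trials_j[:, i_bb]
    ratio_mean = float(np.sum(w * ratio))
    ratio_sd = float(np.sqrt(max(np.sum(w * (ratio - ratio_mean) ** 2), 0.0)))

    return PosteriorSummary(
        mean=mean,
        sd=sd,
        ratio_mean=ratio_mean,
        ratio_sd=ratio_sd,
        n_trials=cfg.n_trials,
        ess=ess,
        low_ess=ess < cfg.ess_floor,
        trials_j=trials_j,
        trials_x=trials_x,
        weights=w,
        free_pairs=free,
    )


def delta_ignored_census(
    cloud: IsletPointCloud, criteria: ContactCriteria | None = None
):
    """Binary census with delta cells treated as empty sites.

    The contact graph is built on ALL cells — delta cells still occupy
    space — but every edge touching a delta cell is excluded, leaving only
    beta-beta, alpha-beta and alpha-alpha counts.  Returns
    ``(counts, subgraph, keep_index)`` where ``subgraph`` is the induced
    graph on the non-delta cells (reindexed by ``keep_index``).
    """
    import warnings

    graph = build_contact_graph(cloud, criteria)
    is_delta = cloud.cell_types == "delta"
    if not is_delta.any():
        warnings.warn("cloud contains no delta cells; census is the full census")
    keep = np.flatnonzero(~is_delta)
    new_index = -np.ones(cloud.n_cells, dtype=np.int64)
    new_index[keep] = np.arange(len(keep))
    mask = ~(is_delta[graph.edges[:, 0]] | is_delta[graph.edges[:, 1]])
    sub_edges = new_index[graph.edges[mask]]
    subgraph = ContactGraph(n_cells=len(keep), edges=sub_edges)
    types = cloud.cell_types[keep]
    counts = {p: 0 for p in BINARY_PAIRS}
    for i, j in subgraph.edges:
        counts[canonical_pair((types[i], types[j]))] += 1
    return ContactCounts(counts=counts, ternary=False), subgraph, keep


class AttractionEstimator(BaseEstimator):
    """Scikit-learn style estimator: fit posterior attractions to one islet.

    ``fit(cloud)`` builds the contact graph from the cloud's coordinates
    (unless a prebuilt graph is passed), takes the observed census, and runs
    the trial-sampling inference.  Fitted attributes:

    ``attraction_mean_``, ``attraction_sd_``
        per-pair posterior moments (reference pair pinned at 1, SD 0);
    ``ratio_mean_``, ``ratio_sd_``
        posterior moments of J_ab/J_bb, the headline sorting/mixing ratio;
    ``ess_``, ``low_ess_``
        effective sample size of the likelihood weights and its warning flag;
    ``posterior_``, ``graph_``, ``counts_``
        the full summary and the intermediates.
    """

    def __init__(
        self,
        n_trials: int = 2000,
        e_f: float = 0.6,
        j_range: tuple = (0.5, 1.5),
        ternary: bool | None = None,
        delta_ignored: bool = False,
        n_equilibration_sweeps: int = 100,
        n_recording_sweeps: int = 50,
        focus_fraction: float = 0.5,
        focus_delta: float = 6.0,
        focus_margin: float = 0.25,
        focus_rounds: int = 3,
        mismatch_convention: str = "half",
        var_floor: float = 1.0,
        criteria: ContactCriteria | None = None,
        random_state: int = 0,
    ):
        self.n_trials = n_trials
        self.e_f = e_f
        self.j_range = j_range
        self.ternary = ternary
        self.delta_ignored = delta_ignored
        self.n_equilibration_sweeps = n_equilibration_sweeps
        self.n_recording_sweeps = n_recording_sweeps
        self.focus_fraction = focus_fraction
        self.focus_delta = focus_delta
        self.focus_margin = focus_margin
        self.focus_rounds = focus_rounds
        self.mismatch_convention = mismatch_convention
        self.var_floor = var_floor
        self.criteria = criteria
        self.random_state = random_state

    def _config(self) -> InferenceConfig:
        return InferenceConfig(
            j_range=tuple(self.j_range),
            n_trials=self.n_trials,
            focus_fraction=self.focus_fraction,
            focus_delta=self.focus_delta,
            focus_margin=self.focus_margin,
            focus_rounds=self.focus_rounds,
            mc=MCConfig(
                e_f=self.e_f,
                n_equilibration_sweeps=self.n_equilibration_sweeps,
                n_recording_sweeps=self.n_recording_sweeps,
            ),
            mismatch_convention=self.mismatch_convention,
            var_floor=self.var_floor,
            seed=self.random_state,
        )

    def fit(self, X: IsletPointCloud, y=None, graph: ContactGraph | None = None):
        cfg = self._config()
        if self.delta_ignored:
            counts, subgraph, keep = delta_ignored_census(X, self.criteria)
            self.graph_ = subgraph
            types = X.cell_types[keep]
            type_counts = {t: int(np.sum(types == t)) for t in ("alpha", "beta")}
        else:
            self.graph_ = graph if graph is not None else build_contact_graph(X, self.criteria)
            ternary = self.ternary
            if ternary is None:
                ternary = bool(np.any(X.cell_types == "delta"))
            counts = contact_counts(self.graph_, X, ternary=ternary)
            type_counts = X.type_counts()
            if not ternary and type_counts.get("delta", 0):
                raise ValidationError(
                    "delta cells present: use ternary=True or delta_ignored=True"
                )
        self.counts_ = counts
        self.posterior_ = infer_attractions(self.graph_, counts, type_counts, cfg)
        self.attraction_mean_ = self.posterior_.mean
        self.attraction_sd_ = self.posterior_.sd
        self.ratio_mean_ = self.posterior_.ratio_mean
        self.ratio_sd_ = self.posterior_.ratio_sd
        self.ess_ = self.posterior_.ess
        self.low_ess_ = self.posterior_.low_ess
        return self
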