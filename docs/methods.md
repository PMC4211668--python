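# Methods

## The model

An islet is treated as a fixed packing of cells whose *types* are mobile:
cells may exchange positions, but the geometry (and hence the contact
graph) does not change.  Each unordered type pair `(x, y)` carries a
relative attraction energy `J_xy > 0`, the energy required to dissociate
one x–y contact, measured in units of the α–α attraction (`J_αα = 1`; only
energy differences are dynamically meaningful, so one pair must be pinned).
The self-energy of a configuration `τ` on contact graph `G` is

    E(τ) = − Σ_{(i,j) ∈ G} J_{τ(i) τ(j)} ,

negative because energy must be supplied, not extracted, to pull contacts
apart.  Equilibrium at fluctuation energy `E_f` — a temperature-like
parameter standing in for cell motility — is the Boltzmann distribution
over type arrangements with fixed type counts.

Assumptions worth stating plainly: morphogenesis is treated as an
equilibrium process (motivated by pseudo-islet re-aggregation from
dissociated cells); cell number and composition are fixed (no replication,
death, or detachment); attractions are pairwise, additive, and isotropic;
and cell positions carry no further information once the contact graph is
built.

## Contact determination

Nuclear point clouds do not come with adjacency.  Two criteria define a
contact: distance below `d_c` (default 1.25, in units of the cell diameter
`d`, itself estimated as the median nearest-neighbor spacing), and an
angular exclusion — processing each cell's distance-neighbors
nearest-first, a candidate is dropped if it subtends an angle below `θ_c`
(default 30°) with an already-retained nearer neighbor, since such a cell
is geometrically behind a true contact.  Retention is required from both
endpoints, making the graph well-defined and symmetric.  The cubic and HCP
reference lattices bound the thresholds from above: second-neighbor
distances are √2·d and √2·d, and nearest-neighbor angles 90° and 60°, so
`d_c < √2` and `θ_c < 60°`.

`tune_contact_thresholds` grid-searches `(d_c, θ_c)` (d_c ∈ [1.05, 1.40]
step 0.05, θ_c ∈ {20°…40°}) against a degree target: mean contacting
neighbors in [8, 9], minimum ≥ 1, maximum ≤ 12.  A grid point is feasible
when the min/max constraints hold and the mean is at least 8 (a cloud too
sparse to reach 8 cannot satisfy the criterion and tuning fails with the
best candidate attached); among feasible points the mean closest to the
target interval wins.  On a perfect HCP cluster every admissible threshold
reproduces the exact 12-neighbor shells, so tuning succeeds with mean
coordination above the target band — the band binds only noisy clouds.

## Lattice clusters

`build_cluster` cuts an approximately spherical n-site cluster from a
large generating block (simple cubic, or HCP as ABAB-stacked triangular
layers at spacing √(2/3)) by keeping the n sites nearest the block
centroid, ties broken lexicographically.  At n = 1357 this yields mean
coordination 5.36 (cubic) and 10.53 (HCP) — free-boundary surface sites
pull the means below the interior degrees 6 and 12.

## Metropolis swap dynamics

A sweep is N proposals (N = cell count).  Each proposal picks two cells
uniformly at random; same-cell or same-type picks are accepted no-ops, so
type counts are conserved exactly and the chain satisfies detailed balance
without proposal corrections.  ΔE for a heterotype swap is computed from
the two affected neighborhoods only; the shared edge (adjacent swap
partners) cancels because J is symmetric.  Acceptance is
min(1, exp(−ΔE/E_f)).  Contact counts per type pair are recorded once per
sweep after equilibration; their variance over recorded sweeps is used as
a relative weight in inference, deliberately without autocorrelation
correction.  The kernel is numba-compiled and runs ~10⁷ proposals/s on one
core.

Default run lengths (2000 equilibration + 1000 recording sweeps for
standalone equilibration; 100 + 50 inside inference trials) were chosen so
the running mean of every contact count is stationary to within its own
Monte-Carlo standard error — at `E_f ≥ 0.2` with global swaps the chain
decorrelates within tens of sweeps, and doubling these budgets changes
equilibrium means by less than one SE.

## Attraction inference

For one islet (graph `G`, observed counts `N_obs`, type counts fixed):

1. sample a candidate `J` (free pairs: `J_ββ, J_αβ` binary; plus
   `J_δδ, J_αδ, J_βδ` ternary) uniformly from [0.5, 1.5] per pair;
2. equilibrate on `G` from a fresh random assignment; record the
   per-pair mean `⟨N_xy⟩` and variance `σ²_xy`;
3. score the mismatch `X = Σ_pairs (N_obs,xy − ⟨N_xy⟩)² / (2 σ²_xy)`;
4. weight every trial by `w ∝ exp(−X)` and report weighted means and SDs
   of each `J_xy` and of the per-trial ratio `J_αβ/J_ββ`.

Numerical choices:

- **Variance floor 1.** Rare pairs (α–α in a 90 %-β islet) can have
  near-zero sampled variance; the floor prevents singular weights.  A
  config switch (`mismatch_convention="plain"`) drops the factor 2 in the
  denominator; posterior *ratios* are insensitive to the choice (tested).
- **Focus zone.** Half the trial budget is uniform; the rest is spent in
  refinement rounds (default 3) sampling the bounding box of all
  candidates whose mismatch lies within `focus_delta = 6` of the running
  best (≥ 10 of them), expanded 25 % per side and clipped to the prior
  box.  A likelihood-ratio window, rather than a fixed quantile, is what
  makes the five-dimensional ternary search concentrate: a quantile box
  barely shrinks in 5-D and the effective sample size collapses.  Weights
  remain plain `exp(−X)` — the induced sampling-density distortion is the
  price of the speedup and is surfaced through the reported effective
  sample size `ESS = 1/Σw²` and its `low_ess` flag (floor 50).
- **Trials.** Default 2000 per islet, far below the "tens of thousands"
  a production study would use; at this budget the binary posterior ratio
  carries SD ≈ 0.012–0.02 on a 1357-cell islet, and the ternary posterior
  is usable but ESS-limited (single digits).  Posterior SD scales roughly
  with the inverse square root of the trial budget until the inner-MC
  noise floor is reached.
- **δ-ignored mode** builds the contact graph on *all* cells (δ cells
  occupy space), drops every δ-touching edge, and runs the binary
  inference on the induced α/β subgraph — the protocol for validating
  binary inferences on islets where δ cells are unlabeled.

The posterior mean is a likelihood-weighted average over a finite,
partially adaptive sample, not an exact Bayesian integral; with jittered
geometry the recovered ratio carries a small upward bias (~+0.01–0.02
toward 1) because jitter breaks a few true contacts and makes the census
look slightly more mixed than the generating equilibrium.

## Phase analysis

Binary mixtures at homotypic reference (`J_αα = J_ββ = 1`) pass through
four structures as `r = J_αβ/J_hom` grows: complete sorting, shell-core
sorting, partial mixing, complete mixing.  Classification uses three
metrics: the mixing index `m` (heterotypic contact ratio over its random
expectation `2 p_α p_β`), minority surface enrichment (minority fraction
on surface sites — degree below the interior degree — over the cluster's
surface fraction), and minority connectivity (largest minority component
share).  The rule, with defaults in parentheses:

1. `m` within 2 shuffle-SDs of 1, or above → **complete mixing**;
2. `m ≥ mixing_high` (0.88) → **partial mixing**;
3. surface enrichment ≥ 1.5 → **shell-core sorting**;
4. largest minority component ≥ 50 % of the minority → **complete
   sorting**;
5. otherwise (scattered small clumps) → **partial mixing**.

When the assignment comes from an equilibration, the decision uses the
equilibrium-mean mixing index over recorded sweeps (via
`equilibrium_label` / the diagram builder) instead of a single snapshot,
which removes label flicker near boundaries.  Thresholds were validated
against constructed exemplars (a centered minority ball; minority confined
to surface sites; a uniform shuffle) and against equilibria at the
reference settings `(p_β, r)` = (0.9, 0.7 / 0.91 / 0.93 / 1.1) and
(0.6, 0.98) across seeds.

**Fluctuation energy for phase work.**  Inference and generation default
to `E_f = 0.6`, comfortably between the homotypic/heterotypic energy gap
(~0.1) and the attraction scale (~1), where inference is well-conditioned.
The four phases, however, are only geometrically distinct at lower
motility: mapping the two-type mixture onto an Ising model gives an
effective coupling `(2 − 2r)/4`, so at `r = 0.93` the order-disorder point
sits near `E_f ≈ 0.34` — at `E_f = 0.6` every weakly-sorted structure
blurs into near-random mixing.  Phase exemplars and diagrams therefore
default to `E_f = 0.25` (`phase_mc_config`), which separates all four
structures on a 1357-site cluster while staying above the energy gap.
Both values are plain config parameters.

Phase boundaries are detected as interior local maxima of the
moving-average-smoothed (window 3) contact-count variance curves along the
ratio grid, with prominence at least 20 % of the curve's range; peaks from
the three pair curves are pooled and deduplicated to one grid spacing.

## Synthetic islets

`generate_islet` builds an HCP cluster (the lattice whose coordination
matches measured islets), equilibrates types at the ground-truth `J` and
`E_f`, then perturbs coordinates: isotropic Gaussian jitter (default SD
5 % of the 10 µm cell diameter) and optional z-compression (gravity
flattening, factor ∈ [0.7, 1]).  Jitter is applied *after* type
equilibration, so the ground-truth contact structure is exactly the
lattice adjacency and noise stresses only the geometric stage.  The
generator is a pure function of its spec; the emitted ground-truth record
regenerates the cloud bit-exactly.

What the generator does **not** emulate: real nuclear-spacing statistics
beyond a single jitter scale, cell-size heterogeneity between types,
vasculature and ducts, non-spherical islet shapes beyond z-flattening, and
segmentation errors (missed or doubled nuclei).  Passing recovery tests
therefore demonstrate that the inference machinery is correct and
well-calibrated *under the model's own generative assumptions*, not that
real microscopy data would yield equally tight posteriors.

## Problem sizes used in the checks

The verification suite runs islets of 1357 cells (the reference cluster
size) for binary recovery — four ground-truth ratios, ten independent
islets at 0.91 and two at each other ratio, 2000 trials each — and a
588-cell ternary islet for the δ-ignored consistency check; exactness of
the sampler is established against full enumeration on ≤ 12-site graphs.
These sizes keep a full run in the tens of minutes on one core while
leaving every statistical margin (2–3 SE/SD) intact.

## Known limitations

- Absolute attraction magnitudes are not identifiable — only ratios to
  the pinned reference pair; likewise `J` and `E_f` trade off, so `E_f`
  must be fixed a priori.
- The likelihood reweighting ignores the non-uniform sampling density of
  the focus rounds; ESS is the honesty metric and small-ESS ternary
  posteriors should be treated as approximate.
- Boundary detection reports grid-resolution peaks, not finite-size-scaled
  transition points.
- The classifier's thresholds are calibrated conventions; near phase
  boundaries the label is genuinely ambiguous and the underlying metrics
  (returned alongside the label) are the more faithful description.
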