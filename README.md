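# isletsort

Quantitative analysis of 3D pancreatic-islet architecture under the
differential adhesion hypothesis.

Islets of Langerhans are micro-organs in which glucagon-secreting α cells,
insulin-secreting β cells and somatostatin-secreting δ cells pack into
aggregates of a few hundred to a few thousand cells.  Mouse islets show a
shell-core arrangement (β core, non-β mantle) while human islets look far
more intermixed.  `isletsort` asks whether a single physical rule —
slightly stronger attraction between like cells than between unlike cells —
can account for both, and makes that rule quantitative:

- **Contact determination.** Given per-cell nuclear coordinates, cells i
  and j are contacting when their distance is below `d_c` (in multiples of
  the cell diameter `d`) *and* neither is shadowed by a nearer neighbor at
  an angle below `θ_c` — the double criterion that separates true contacts
  from second-shell neighbors in soft, slightly flattened tissue.
- **Adhesion model.** With relative attraction energies `J_xy > 0` per
  type pair (reference `J_αα = 1`), an islet's self-energy is
  `E = −Σ_contacts J_τ(i)τ(j)`.  Equilibrium structures at fluctuation
  energy `E_f` (a temperature-like proxy for cell motility) are sampled by
  Metropolis type-swap Monte Carlo on the fixed contact graph.
- **Attraction inference.** The inverse problem: sample candidate `J`
  sets, equilibrate each on the islet's own contact graph, score the
  mismatch `X = Σ_pairs (N_obs − ⟨N⟩)² / 2σ²` between observed and
  equilibrium contact counts, weight by the maximum-entropy likelihood
  `∝ exp(−X)`, and report posterior means and SDs of each `J_xy` and of
  the headline ratio `J_αβ/J_ββ` (1 = random mixing, <1 = sorting).
- **Phase diagrams.** On 1357-site cubic and hexagonal-close-packed
  clusters, binary mixtures pass through complete sorting, shell-core
  sorting, partial mixing and complete mixing as `J_het/J_hom` grows;
  contact-number fluctuations peak at the phase boundaries.
- **Synthetic islets.** A generator produces islet-like point clouds from
  the model's own equilibrium at known ground truth, so the whole pipeline
  (geometry → census → inference) is verifiable end to end without any
  external data.

## Worked example

Generate a mouse-like synthetic islet (1357 cells, 90 % β, ground-truth
ratio `J_αβ/J_ββ = 0.91`, `E_f = 0.6`) and re-infer the attractions from
its coordinates alone:

```python
import isletsort as isl

spec = isl.SyntheticSpec(seed=1)          # mouse-like defaults
cloud, truth = isl.generate_islet(spec)

est = isl.AttractionEstimator(n_trials=2000, random_state=1).fit(cloud)
print(f"J_bb = {est.attraction_mean_[('beta','beta')]:.3f} "
      f"± {est.attraction_sd_[('beta','beta')]:.3f}")
print(f"J_ab = {est.attraction_mean_[('alpha','beta')]:.3f} "
      f"± {est.attraction_sd_[('alpha','beta')]:.3f}")
print(f"ratio J_ab/J_bb = {est.ratio_mean_:.3f} ± {est.ratio_sd_:.3f} "
      f"(truth {truth['ratio_true']})")
```

which prints

```
J_bb = 1.177 ± 0.093
J_ab = 1.082 ± 0.086
ratio J_ab/J_bb = 0.919 ± 0.012 (truth 0.91)
```

The ratio is the robust readout — it sits within one posterior SD of the
generating truth, with an order-of-magnitude smaller uncertainty than the
individual attractions.  That asymmetry is physics, not a bug: in a
90 %-β islet the absolute scale is pinned only by the rare α–α reference
contacts, so `J_ββ` and `J_αβ` float together along a soft direction while
their ratio (the sorting strength) stays sharply determined.  `est.ess_`
reports the effective sample size of the likelihood weights; `est.low_ess_`
flags runs whose trial budget was too small for tight absolute posteriors.

The same machinery classifies architectures.  A mouse-like point
(`p_β = 0.9`, ratio 0.91) on the HCP lattice equilibrates to a shell-core
sorted structure, while a human-like point (`p_β = 0.6`, ratio 0.98) only
partially mixes:

```python
hcp = isl.build_cluster("hcp", 1357)
print(isl.equilibrium_label(hcp, p_beta=0.9, ratio=0.91, seed=61)[0].name)
# shell_core_sorting
print(isl.equilibrium_label(hcp, p_beta=0.6, ratio=0.98, seed=62)[0].name)
# partial_mixing
```

A `click` CLI mirrors the library: `isletsort simulate`, `isletsort
contacts`, `isletsort equilibrate`, `isletsort infer`, `isletsort
phase-diagram`, `isletsort lattice`; each writes JSON or the canonical
CSV cell-table dialect (`islet_id, cell_id, x_um, y_um, z_um, cell_type`).

## Layout

```
src/isletsort/
  io.py          cell tables, islet point clouds, compositions
  contacts.py    distance+angle contact graphs, censuses, tuning
  lattice.py     spherical cubic / HCP cluster construction
  adhesion.py    self-energy, AttractionSet, Metropolis equilibration
  _mc.py         numba swap-dynamics kernel
  inference.py   mismatch, likelihood weighting, AttractionEstimator
  phases.py      structure classification, fluctuation sweeps, diagrams
  synthetic.py   ground-truth islet generator
  cli.py         command-line interface
docs/methods.md  model, assumptions, parameter choices, limitations
```
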