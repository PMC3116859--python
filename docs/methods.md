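# Model and methods

`metarep` simulates the evolution of enzyme specificity in a population of
surface-bound, metabolically coupled replicators. This note records the
model as implemented, the choices made where the design was genuinely
open, and what the package's synthetic experiments do and do not show.

## The model

**Habitat.** An `L x L` toroidal lattice; each site is empty or holds one
replicator. The torus removes edge effects.

**Phenotype.** Each replicator carries three heritable traits: two enzyme
activities `E1, E2 >= 0` (catalytic efficiencies for the two keystone
reactions of the shared metabolism) and a basic replication rate `k`
(its quality as a template). A replicator with both activities positive
folds into one of two conformations and *expresses* only one activity per
generation; `E1 = E2 = 0` replicators (parasites) have no enzymatic fold.

**Trade-off surface.** The traits are confined below

    C(E1, E2) = k_min + (k_max - k_min) * (1 - u)^(1/g),
    u = ((E1^b + E2^b)^(1/b)) / E_max,   u <= 1,

with `E_max = 10`, `k_min = 2`. `b` shapes the `E1/E2` trade-off
(`b < 1` convex/strong, `b = 1` the budget line `E1 + E2 = E_max`,
`b > 1` concave/weak, `b -> inf` no trade-off) and `g` shapes the
enzymes-versus-replication trade-off (`g < 1` convex/strong). Boundary
points count as feasible, so absolute specialists `(E_max, 0, k_min)`
exist. The surface is evaluated in a factored form
(`max * (1 + (min/max)^b)^(1/b)`) so that large `b` does not overflow.

**Metabolic supply.** For replicator `i`, over its 3x3 Moore
neighbourhood (n = 9 sites, focal site included):

    M_i = sqrt(A1 * A2),

where `A1` and `A2` sum the *expressed* activity of each occupant.
`M_i` is the geometric mean of the two total expressed local activities;
if either enzyme type is absent locally, `M_i = 0` and `i` cannot
replicate. A per-site-averaged variant, `sqrt((A1/n)(A2/n))`, was
examined and rejected: with the empty-site weight at its standard value
`W_e = 20` it starves the standard random initial population faster
than selection can rescue it — the whole lattice dies out within ~150
generations at every tested scale up to 300 x 300 — which contradicts
the long-run coexistence this model family exhibits. The summed form
also matches the antecedent metabolic-replicator models, in which the
metabolic function is a geometric mean of local copy numbers, not
densities.

**Update schedule.** One generation = exactly `L^2` elementary site
updates (a random site, drawn with replacement) and `round(D * L^2)`
diffusion events, randomly interleaved with exact counts; afterwards
every occupant takes its between-generation conformation draw.

- *Occupied site:* dies with probability `p_d = 0.1`, independent of its
  traits.
- *Empty site:* the occupants of its von Neumann replication
  neighbourhood (l = 4) compete for it. Claimant `i` wins with
  probability `W_i / (W_e + sum_j W_j)`, where `W_i = k_i * M_i` and
  `W_e = 20` is the weight of the site staying empty. The winner's copy
  is mutated with probability `p_m`, in which case its entire trait
  triple is replaced by a uniform draw from the feasible volume
  (mutants are unconstrained by their parent's phenotype).
- *Diffusion:* a uniform site swaps contents with a uniform Moore
  neighbour. Swaps with an empty partner are allowed by default —
  occupied-only swaps cannot transport replicators into empty territory;
  the stricter occupied-only behaviour is available via
  `diffusion_occupied_only`.
- *Conformation switch:* with probability `1 - s`,
  `s = |E1 - E2| / (E1 + E2)`, the expressed activity toggles (only to a
  state with positive activity). Pure specialists (`s = 1`) never
  switch; symmetric generalists toggle every generation. Parasites have
  no conformation and never draw.

**Offspring conformation.** Faithful copies inherit the parent's
conformation (a copy plausibly folds like its template); mutants fold
anew, uniformly among their nonzero activities. The alternative
(re-drawing every offspring) desynchronises clonal generalist patches
and was left out of the default on the grounds that the conformation
model is explicitly a worst case for specialisation.

**Mutant sampling.** Uniform over the feasible volume
`{(E1, E2, k): u <= 1, k_min <= k <= C}` by rejection from the bounding
box. When `k_max = k_min` the k-interval is degenerate and every draw
carries `k = k_min`. Initialisation occupies exactly
`round(0.8 * L^2)` uniformly placed sites with independent such draws.

**Randomness.** One `numpy.random.Generator` per run; the jitted kernels
consume the same bit stream in schedule order, so runs are
bit-reproducible given `(params, seed)`.

## Phenotype classes

The `(E1, E2)` plane is partitioned in fixed order: *parasite* if
`E1 + E2 <= 1.0` (a tenth of `E_max`), else *specialist* if
`min(E1, E2) <= 0.5`, else *generalist* if `s <= 0.2`, else *rest*.
The reference phase-plane regions exist only as drawings, so these
widths are read graphically; they are parameters (`ClassRegions`),
recorded in run metadata, and the tests exercise classification
independently of any particular widths. Quasi-equilibrium summaries average class frequencies
over the final 10% of recorded generations, standing in for the single
late-generation snapshot a full-length run would report.

## Problem sizes

The reference experiments for this model family use a 300 x 300 lattice
and 150,000 generations. The package's desk-scale presets use `L = 100`
and 10,000 generations with >= 5 replicate seeds; the full scale
remains available (`full_scale=True`, or the CLI's config). Convergence
studies (seed-replicated class-frequency trajectories at
`b` in {0.4, 0.6, 1.0, 1.4, 1.67, 2.0}, `D` in {0, 5}, lattices 40–300,
horizons to 40,000) show:

- occupancy and the dominant class settle within a few thousand
  generations at `D = 5` for strongly convex or clearly concave
  trade-offs; near the dominance boundary the specialist/generalist
  race takes 10,000–30,000 generations to resolve (at `b = 1.0`,
  `D = 5`, `L = 100` the specialist frequency is ~0.18 at generation
  3,000 and ~0.80 at 30,000);
- the parasite-class frequency at strongly convex trade-offs
  (`b = 0.4`, `D = 5`, `L = 100`) peaks early (~13% around generation
  3,000) and decays as specialist activities sharpen (~6% at 10,000,
  ~1.2–1.6% at 40,000). Smaller lattices show sporadic late parasite
  outbreaks (up to ~20% on 48–64-sided lattices) that full-sized runs
  damp. Short, small runs therefore *overstate* the standing parasite
  load of full-length runs;
- at `D = 0` selection is much slower (clonal patches change only at
  their borders): at `b = 0.4`, `L = 100`, the specialist frequency
  passes 0.9 only around generation 15,000 and holds (~0.94 at
  40,000). Desk-scale `D = 0` frequencies at short horizons are
  conservative lower bounds on the degree of specialisation;
- lattice side matters near the boundary: at `b = 1.0`, `D = 5`,
  specialists win on `L = 100` but lose on `L = 40`, presumably because
  maintaining both complementary specialist types is harder on a small
  torus.

`scripts/acceptance.py` runs `L = 64` — 15,000 generations and 5 seeds
for the specialist-dominance condition (the cell with the slow parasite
transient), 8,000 generations for the other cells of the b grid at both
diffusion intensities; the in-suite phase
tests use lattices of 40–48 with horizons of 3,000–15,000, all chosen
from the convergence diagnostics above. Two reference outcomes are not
reached at these sizes and are reported as measured: the parasite
maximum stays above the 1% containment level (outbreak seeds dominate
the maximum), and the moderate-diffusion crossover estimate sits near
`b ~ 0.9–1.2` rather than 1.67 (it moves right with both lattice size
and horizon; its converged `L = 100` location is between 1.0 and 1.4).

## Known limitations

- Space-free quantities (trade-off surface, sampling, classification)
  are exact; the spatial phase boundaries are estimated on scaled-down
  lattices and horizons, where slow `D = 0` coarsening and the parasite
  transient bias class frequencies relative to full-length runs.
- The algebra of the metabolism, conformation-switch and trade-off
  rules is reconstructed from the model family's stated verbal
  properties; all stated endpoint behaviours are reproduced exactly,
  but numeric thresholds (e.g. the crossover locations in `b`) can
  shift under a different algebraic rendering. The phase-transition
  *structure* (specialist frequency non-increasing in `b`, sharp
  dominance change, parasite containment improving with less convex
  trade-offs) is robust to this.
- No continuous-time variant, no spatial heterogeneity, no sequence
  representation; phenotypes are the unit of evolution.
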