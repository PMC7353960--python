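# Methods

## The vetting procedure

`hypovet` implements the computable core of a five-step design-phase
workflow: (1) specify candidate hypotheses, (2) express each as a
generative model, (3) simulate a sampling distribution of the planned
response statistic from each, (4) quantify within-distribution spread
(noisiness) and between-distribution overlap (degeneracy), (5) revise and
repeat. Steps 3–4 are computed; steps 1, 2 and 5 are supported by the
declarative YAML config (the hypothesis grid *is* the candidate set, and
revision is an edit-and-rerun loop) and by the weight-rule plug-in
contract for user-defined models. The output is inference about the
*distinguishability* of simulation models, never evidence for or against
any one of them.

## The settlement model

Agents settle a rectangular grid of unit cells one at a time; each draw
selects an unoccupied cell with probability proportional to a per-cell
weight evaluated against the current occupancy, and cells hold at most one
settler. Sequential settlement with full weight recomputation is used
because the conspecific-attraction hypothesis conditions each decision on
the locations already settled. Distances are Euclidean between cell
centres (cell `(row, col)` centred at `(col + 0.5, row + 0.5)`), with hard
edges — no toroidal wrap. Edge effects are part of the simulated system,
as they would be in a real finite study area.

Weight rules:

- **null** — weight 1 everywhere; settlement is uniform over free cells,
  so with full weight to habitat assignment below, the per-iteration
  proportion of settlers on habitat A is exactly hypergeometric with mean
  `prop_a`.
- **habitat preference** — odds weight `omega >= 1` on free A cells, 1 on
  B cells. The constraint `omega >= 1` keeps the hypothesis one-sided
  (preference *for* A); `omega = 1` reduces exactly to the null.
- **conspecific attraction** — the first settler is uniform; thereafter a
  free cell at distance `d` from its nearest settled cell gets weight
  `exp(-s d)`, `s >= 0`. The exponential-decay kernel was chosen as the
  simplest smooth single-parameter rule that recovers the null at `s = 0`
  and strengthens monotonically with `s`; the underlying hypothesis
  ("settle near already-settled locations") fixes only the qualitative
  form, not the kernel. Distance-to-*nearest* (rather than, say, summed
  attraction over all settlers) makes the rule local and keeps the
  strong-attraction limit a single tight cluster seeded by the random
  first settler — which is exactly the two-process structure (random
  anchor + attraction) that makes this hypothesis noisy.

Selection is inverse-CDF lookup on the cumulative weight vector in
row-major cell order from a seeded `numpy` PCG64 generator. This is
bit-reproducible and tie-free, and it guarantees the *null-limit
identities*: under a shared seed, `omega = 1` and `s = 0` produce
settlement sequences identical to the null model's, because the weight
vectors are equal element-for-element. Custom weight rules go through the
same selection path and are checked per draw for finiteness,
non-negativity, correct length and at least one positive weight.

## Landscapes

Habitat is assigned by exact count — exactly `round(prop_a * n_cells)`
cells are A, rounding half-up (a fixed, documented tie rule) — rather
than by independent per-cell Bernoulli draws. This makes the null model's
expected response exactly `prop_a` and its per-iteration variance
closed-form hypergeometric, which the tests use as an analytic oracle.
Two layouts are provided: `random` (A cells at uniformly random distinct
positions) and `blocked` (A fills cells in row-major order from the
origin, giving one contiguous band). True patch-cluster random fields are
out of scope.

**The default layout is `blocked`.** This choice is substantive: with
spatially uncorrelated (`random`) habitat at cell grain, even a tightly
clustered group of 150 settlers samples ~150 effectively independent
habitat labels, and the conspecific-attraction model's proportion-A
variance collapses toward the null's. With contiguous habitat, a tight
cluster lands almost entirely in one habitat, the strong-CA sampling
distribution becomes bimodal on {0, 1}, and the characteristic
noisy/degenerate structure the example is meant to exhibit emerges. A
patchy landscape is the intended study system; `blocked` is its minimal
representative.

## Sampling distributions and seed policy

Each parametrization is simulated `n_iter` times (default 1000, a
compromise between overlap-estimate resolution of 0.001 and runtime; the
whole default grid runs in about two minutes on one CPU). Iteration `i`
uses the derived integer seed `base_seed + i`; a `SeedSequence` on that
integer is spawned into two independent child streams, one for the
landscape draw and one for the settlement draws. Landscape and settlement
never read the same stream — reusing one stream for both would correlate
habitat placement with settlement choices and silently bias the response.
Every derived seed is logged (`seeds.csv`), and `vet replay` re-runs any
single iteration in isolation.

By default a fresh landscape is generated per iteration
(`regenerate_landscape: true`), so landscape stochasticity is part of each
hypothesis' sampling distribution; a fixed-landscape mode is provided for
designs where the study area is known in advance. (With the default
`blocked` layout the landscape is deterministic, so the two modes
coincide.)

## Diagnostics

`summarize_distribution` reports min, max, range width, mean, sample
variance (ddof = 1), coefficient of variation (flagged undefined when the
mean is zero) and the 2.5/25/50/75/97.5% quantiles (linear interpolation
between order statistics — one fixed convention).

The overlap bracket defaults to the full empirical min–max range with
*inclusive* endpoints ("capable of being produced" reads as attainable
values; the self-overlap of any distribution is then exactly 1). Because
the extreme order statistics are unstable, a `central_quantile` bracket
(central `1 - alpha` interval, default `alpha = 0.05`) is offered as a
robustness knob. The overlap is conceptually equivalent to a familiar
p-value — the probability of one model's output falling in another
model's attainable range — but it is deliberately never labelled a
significance test, and no threshold is applied automatically.

## Spatial metrics

Mean nearest-neighbour distance and the Clark–Evans aggregation index
`R = mean_nn / (0.5 / sqrt(n/area))` are computed on settled cell centres
(points are not jittered, so the minimum attainable nearest-neighbour
distance is one cell width). **No edge correction is applied**: on small
windows the uncorrected `R` is biased upward (the Monte-Carlo check in the
test suite tolerates ±0.1 around the CSR expectation of 1), but the
toolkit uses the index only comparatively between hypotheses simulated on
the same window, where the bias is shared. Ripley's K/L and
pair-correlation functions are natural extensions, not included.

## Default configuration

| parameter | default | why |
|---|---|---|
| `n_rows x n_cols` | 50×50 | large enough that 150 settlers occupy 6% of cells (weak crowding), small enough for ~10 ms per strong-CA iteration |
| `prop_a` | 0.5 | symmetric baseline; null mean 0.5 |
| `layout` | `blocked` | contiguous habitat; see above |
| `n_agents` | 150 | a population-scale settlement wave; cluster diameter ~14 cells, comparable to the habitat band width, so strong CA is bimodal rather than trivially pinned |
| `omega` grid | 1.5, 2, 4, 8, 16 | geometric ladder from barely-above-null to near-deterministic preference |
| `s` grid | 0.25, 0.5, 1, 2, 4 | kernel e-folding lengths from 4 cells (diffuse) to 0.25 cells (near-deterministic adjacency) |
| `n_iter` | 1000 | overlap resolution 0.001 |
| `base_seed` | 2020 | arbitrary pinned default |

One null model plus the two five-point grids gives the 11-parametrization
candidate set the bundled example is built around.

## What the generator does and does not emulate

The simulator is a stylized settlement system: synchronous-free sequential
arrival, perfect detection, no mortality, no movement after settlement, no
density dependence, no heterospecific interactions, habitat in exactly two
types on a grid. Passing tests therefore demonstrate that the *method* —
sampling-distribution construction, overlap and spread diagnostics,
spatial parsing — behaves correctly on a system whose truth is known, and
that the documented qualitative structure (HP means rising with `omega` at
near-constant variance; strongest CA maximally variable; weak CA
converging on the null; strong CA spatially clustered while HP stays
diffuse) emerges under the default conditions. They do not validate any
of these hypotheses for a real species or landscape; real responses
include observation error and process complexity the generator omits by
design, and users should encode those as additional candidate models.

## Numerical notes and edge cases

- Weighted selection clamps the rare float round-off case `u -> 1` back
  to the last positive-weight cell; zero-weight (occupied) cells can never
  be selected by construction of the right-sided cumulative search.
- A full landscape, an all-zero weight vector, non-finite or negative
  weights, and `n_agents` exceeding the cell count are rejected with the
  offending spec named.
- Constant sampling distributions give zero variance and zero-width
  whiskers; they are valid inputs everywhere (their range bracket is a
  point).
- `n_iter >= 2` is required for summaries (sample variance) and at least
  two parametrizations for an overlap matrix.
- Reports contain no timestamps, so identical configs and seeds reproduce
  byte-identical tables.
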