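# hypovet

**Pre-data-collection vetting of multiple working hypotheses by
simulation.**

Before a field season or an experiment starts, a researcher holding several
plausible hypotheses should ask a question that is routinely skipped: *if
one of these processes were true, could my planned observations actually
tell it apart from the others?* `hypovet` answers this by treating each
candidate hypothesis as a generative simulation model, building the
sampling distribution of the planned response statistic from repeated
iterations of each model, and quantifying two failure modes:

- **Degeneracy** — different processes produce overlapping sampling
  distributions, so no observation can uniquely implicate one of them.
  Measured by the *unidirectional overlap*

  $$p(i \mid j) = \frac{\#\{v \in D_i : \min D_j \le v \le \max D_j\}}{|D_i|},$$

  the proportion of hypothesis *i*'s simulated response values that fall
  inside a bracketed range of hypothesis *j*'s distribution $D_j$ — the
  conditional probability that *i* generates data attainable under *j*.
  It is generally asymmetric because the distributions have unequal
  spreads. (A central-quantile bracket is available as a robust
  alternative to the full min–max range.)

- **Noisiness** — a single process produces a wide or multimodal sampling
  distribution, precluding precise estimation. Measured by each
  distribution's range width, variance and coefficient of variation.

No overlap level or variance is automatically "too much": the toolkit
reports the quantities and leaves the verdict to the researcher. The
analysis is analogous to a power analysis, but for *identifiability* rather
than sample size, and it says nothing about which hypothesis is true —
only whether they are distinguishable in principle.

## The bundled example: animals settling a two-habitat landscape

The package ships a complete worked system: an individual-based model of
`n_agents` animals sequentially settling a rectangular grid whose cells are
habitat A or habitat B. Each settlement draw picks one unoccupied cell with
probability proportional to a per-cell weight; three candidate hypotheses
supply the weights:

| hypothesis | weight of unoccupied cell | parameter |
|---|---|---|
| null (RAND) | $1$ | — |
| habitat preference (HP) | $\omega$ if the cell is habitat A, else $1$ | odds weight $\omega \ge 1$ |
| conspecific attraction (CA) | $e^{-s\,d}$, $d$ = distance to nearest settled cell (uniform for the first settler) | attraction strength $s \ge 0$ |

$\omega = 1$ and $s = 0$ reduce exactly to the null model. The default
configuration crosses one null model with five HP strengths
($\omega \in \{1.5, 2, 4, 8, 16\}$) and five CA strengths
($s \in \{0.25, 0.5, 1, 2, 4\}$) — 11 parametrizations — on a 50×50
half-A landscape with 150 agents and 1000 iterations each. The response
statistic is the proportion of settlers on habitat A. Two spatial metrics
(mean nearest-neighbour distance and the Clark–Evans index
$R = \bar d_{NN} / (0.5/\sqrt{n/\text{area}})$) are available as auxiliary
responses that can parse hypotheses left degenerate by the proportion
statistic. Custom hypotheses plug in as weight-rule callables.

## Worked example

```python
from hypovet import VettingConfig, run_vetting

config = VettingConfig(
    n_rows=20, n_cols=20, n_agents=60,
    omega_values=(2.0, 8.0), s_values=(0.5, 2.0),
    n_iter=200, base_seed=7,
)
report = run_vetting(config, out_dir=None, figures=False)

for s in report.summaries:
    print(f"{s.spec_name:12s} mean={s.mean:.3f} var={s.variance:.4f} "
          f"range=[{s.minimum:.3f}, {s.maximum:.3f}]")

m = report.overlap
i, j = m.spec_names.index("null"), m.spec_names.index("CA(s=2)")
print(f"p(null|CA(s=2)) = {m.entries[i, j]:.3f}")
print(f"p(CA(s=2)|null) = {m.entries[j, i]:.3f}")
```

prints

```
null         mean=0.499 var=0.0040 range=[0.350, 0.700]
HP(omega=2)  mean=0.655 var=0.0035 range=[0.500, 0.833]
HP(omega=8)  mean=0.877 var=0.0021 range=[0.750, 0.967]
CA(s=0.5)    mean=0.502 var=0.0276 range=[0.050, 0.983]
CA(s=2)      mean=0.515 var=0.1384 range=[0.000, 1.000]
p(null|CA(s=2)) = 1.000
p(CA(s=2)|null) = 0.215
```

Reading this as a study-design check: HP means climb with $\omega$ at
roughly constant variance, so habitat preference would be estimable; strong
CA is *noisy* (variance 35× the null's, spanning the whole unit interval)
and *degenerate* with the null — every null simulation falls inside the
CA(s=2) range ($p = 1.000$), so no proportion-A observation could ever rule
out conspecific attraction. The auxiliary Clark–Evans means rescue the
design (null 1.16 vs CA(s=2) 0.80 in the same run): strong attraction
produces spatial clustering the proportion statistic cannot see, so adding
a spatial response makes the hypotheses identifiable.

## Command line

```bash
vet example --out cfg/                 # write the default config as YAML
vet run --config cfg/settlement_example.yaml --out results/ [--seed N] [--n-iter N]
vet replay --config cfg/settlement_example.yaml --spec "CA(s=4)" --iteration 17 --out replays/
```

`vet run` writes `distributions.csv`, `summaries.csv`,
`overlap_matrix.csv/.json`, `aux_summaries.csv`, `seeds.csv`,
`report.json` and figures (a min–max whisker plot per parametrization and
unidirectional-overlap heatmaps per ordered hypothesis-family pair).
Re-running the same config and seed regenerates byte-identical tables; any
single iteration can be replayed in isolation from the recorded seeds.

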