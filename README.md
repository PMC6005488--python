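# costfs — cost-sensitive feature selection with rough sets and Laplacian scores

When every measured feature has a price — a blood panel where each assay
bills separately, a sensor suite where each channel costs power — feature
selection must weigh discriminative value against acquisition cost.
`costfs` selects such panels for tabular decision systems (numeric
conditional features, one categorical decision label) by combining two
ingredients:

1. **The decision-relative core** (neighborhood rough sets).  Two
   instances are indiscernible on a feature subset *B* when every
   per-feature gap is within λ·e(a), where e(a) = Δ·mean(a) is the
   feature's measurement-error half-width (Δ = 0.1 by default, λ = 2).
   The positive region POS_B(D) collects instances whose whole
   B-neighborhood shares their label; the core is every feature whose
   removal from the full set shrinks POS — equivalently the intersection
   of all decision-relative reducts.  Core features are kept
   unconditionally.

2. **The cost-weighted Laplacian score.**  On a k-nearest-neighbor
   affinity graph with weights S, degrees D = diag(S·1) and Laplacian
   L = D − S, each feature column f is scored by the Rayleigh quotient
   LS(f) = f̃ᵀLf̃ / f̃ᵀDf̃ (f̃ degree-centered), then traded against its
   cost through

       LS(a, c) = LS(a) · c(a)^α,   α ≤ 0.

   Remaining slots up to the requested panel size *d* are filled in
   descending LS(a, c) order; α = 0 recovers plain Laplacian-score
   ranking, more negative α favors cheaper tests.

The package also ships the surrounding experimental apparatus: random
test-cost simulators (uniform / normal / Pareto on [1, 100]), an exact
branch-and-bound **minimal-cost reduct** baseline, and the
below/exceeding-factor statistics (MBF, ABF, AEF, and the
finding-optimal factor FOF) for judging a selector over repeated cost
draws.

## Worked example

The packaged fixture is a 6-patient liver-disorder subtable with five
blood tests (Mcv, Alkphos, Sgpt, Sgot, Gammagt), dollar costs
(16, 20, 45, 28, 33) and a published per-feature importance vector.

```python
import costfs as cf

system, costs = cf.fixture_liver_subtable()
importance = cf.fixture_liver_importance()

cf.error_ranges(system).displayed()
# {'Mcv': 0.06, 'Alkphos': 0.04, 'Sgpt': 0.02, 'Sgot': 0.03, 'Gammagt': 0.01}

scores = cf.score_all(system, costs, alpha=-1.0, ls_override=importance)
{a: round(v, 3) for a, v in scores.weighted.items()}
# {'Mcv': 0.053, 'Alkphos': 0.037, 'Sgpt': 0.021, 'Sgot': 0.033, 'Gammagt': 0.029}

result = cf.select(system, costs, d=5, alpha=-1.0,
                   core_override=("Gammagt",), ls_override=importance)
result.selected
# ('Gammagt', 'Mcv', 'Alkphos', 'Sgot', 'Sgpt')

cfg = cf.NeighborhoodConfig.for_system(system)
cf.min_cost_reduct(system, costs, cfg)
# (('Alkphos', 'Sgpt'), 65.0)
```

The error ranges are 0.1 × each column mean (displayed at two decimals);
the weighted scores divide each importance by its dollar cost (α = −1),
so cheap Mcv overtakes expensive Sgpt; the selection puts the injected
core feature first and ranks the rest by weighted score; and the exact
search finds {Alkphos, Sgpt} as the cheapest reduct at $65.

A command-line interface mirrors the library:

```bash
costfs select --data liver.csv --costs costs.csv --decision-column Selector -d 3 --alpha -1
costfs sweep --data liver.csv --decision-column Selector --dist pareto -K 100 --seed 42
```

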