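# grn-evobench

A benchmarking workbench for **evolutionary inference of quantitative gene
regulatory network (GRN) models** from expression time series.

Reverse engineering a GRN quantitatively means fitting a dynamical model —
here an **S-System**,

    dx_i/dt = α_i ∏_j x_j^{g_ij} − β_i ∏_j x_j^{h_ij},

or a **per-gene artificial neural network** (a logistic unit predicting each
gene's next-time-point expression from its regulators) — to noisy, short
microarray-style time courses. The search spaces are large and multimodal,
so evolutionary algorithms (EAs) are the standard fitting machinery. This
package puts seven published EA strategies under one roof with a single cost
accounting (one objective evaluation = one function call, budgets consumed
exactly), so they can be compared fairly:

| name | strategy | scope |
|---|---|---|
| `clga`   | classic real-coded GA | whole network |
| `moga` / `fmoga` | per-gene objective split, Pareto / fuzzy-dominance selection | whole network |
| `gaes`   | binary GA over sparsity structures, nested ES parameter fit | whole network |
| `peace1` | iterative GA with progressive pruning of small kinetic orders | whole network |
| `glsdc`  | memetic GA (pattern-search local phase with skeletalising) | gene-at-a-time |
| `deaic`  | differential evolution on an AIC objective with greedy pruning | gene-at-a-time |
| `gaann`  | GA over regulator subsets, one trained ANN per evaluation | gene-at-a-time |

Around them sit a **synthetic benchmark generator** (scale-free sparse
networks via preferential attachment, 60/80/125-point multi-series datasets,
1–10% multiplicative Gaussian noise), the **evaluation criteria** used to
score inferences (data MSE, parameter MSE per parameter or per gene, edge
sensitivity/specificity, run-robustness variances, notched box-plot
summaries with trimmed means), and an **experiment orchestrator** with the
standard multi-run protocols (7 whole-network runs, 5 runs × first 5 genes,
20 paired-seed runs for the single- vs multi-objective study), resumable and
fully seeded. See `docs/methods.md` for the science and the design choices.

## Worked example

```python
import numpy as np
from grn_evobench import (BenchmarkSpec, InferenceConfig, SolverConfig,
                          generate_benchmark, infer,
                          interactions_from_model, sensitivity_specificity)

# a sparse 2-gene S-System truth and a noiseless 20-point dataset
spec = BenchmarkSpec(n_genes=2, connectivity=(1, 1), seed=3,
                     n_time_points=20, n_series=2)
truth, edges, data = generate_benchmark(spec)

cfg = InferenceConfig(budget=6000, seed=1, solver=SolverConfig(step=0.05))
result = infer("deaic", data, cfg)
sens, spec_ = sensitivity_specificity(interactions_from_model(truth),
                                      interactions_from_model(result.model), 2)
print(f"data MSE {result.data_mse:.2e} after {result.function_calls} calls; "
      f"sensitivity {sens:.2f}, specificity {spec_:.2f}")
```

prints

```
data MSE 4.16e-05 after 6000 calls; sensitivity 1.00, specificity 1.00
```

i.e. with a 6,000-call budget the AIC-guided differential evolution fits the
2-gene time series to a mean squared error of ~4e-5 (expression units²) and
identifies exactly the true regulator pairs, no false edges.

The same machinery is scriptable from the shell:

```bash
grn-evobench generate --genes 5 --seed 1 --out bench5
grn-evobench infer --algo glsdc --data bench5/dataset.csv \
    --budget 100000 --seed 1 --out glsdc.json
grn-evobench evaluate --truth bench5/truth_model.json \
    --inferred model.json --data bench5/dataset.csv
grn-evobench sweep --genes 5 --algos deaic,glsdc --scale 0.01 --out sweep_out
grn-evobench mo-study --data bench2/dataset.csv --budget 100000 --out mo.json
```

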