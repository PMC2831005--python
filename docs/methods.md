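# Methods

## Scope and models

`grn-evobench` benchmarks evolutionary algorithms that fit quantitative gene
regulatory network (GRN) models to expression time series. Two model families
are implemented.

**S-Systems.** Each gene's expression level x_i obeys a power-law ODE,

    dx_i/dt = α_i ∏_j x_j^{g_ij} − β_i ∏_j x_j^{h_ij},

with non-negative rate constants α_i (basal synthesis) and β_i (degradation)
and real kinetic orders g_ij, h_ij quantifying how gene j modulates gene i's
synthesis and degradation. Self-regulation lives on the diagonals; an
interaction j→i "exists" when |g_ij| or |h_ij| exceeds a zero tolerance
(default 1e-8). An n-gene S-System has 2n + 2n² parameters.

**Per-gene ANNs.** Each gene is a single logistic unit predicting its own
expression at the next sampled time point from the expression of at most k
regulators (default k = 4) at the current point. Expression is mapped per
gene from its observed [min, max] onto [0.1, 0.9] before the sigmoid and back
after, keeping targets off the saturated tails. With a bias this is k+1
parameters per gene — n(k+1) per network (25 at n = 5), versus 60 for the
matching S-System, which is part of why the ANN searches converge so readily.
Training is full-batch gradient descent (delta rule) on the scaled one-step
squared error pooled over series; default 20,000 epochs, learning rate 0.1.
There is no hidden layer: the parameter-count arithmetic above pins the
architecture down, and a deeper net would change the budget accounting (one
function call = one trained ANN).

## Simulation

S-Systems are integrated by fixed-step classical RK4. Each inter-sample
interval is subdivided into equal steps no longer than the configured step
(default 0.01 time units), so trajectory rows land exactly on the sample
times. States are clamped to a floor of 1e-6 before every power evaluation:
negative kinetic orders are singular at zero and non-integer orders are
complex below it. Evolutionary search constantly proposes explosive
parameter sets, so divergence (any state above 1e6 or non-finite) is not an
error: the trajectory is truncated, held at its last valid state, and
flagged, and fitness functions convert the flag into a large penalty
(1e12 + 1e6 per lost time point) that still ranks diverged candidates by how
early they blew up.

**Decoupled (divide-and-conquer) mode.** Per-gene methods fit one gene's
equation at a time while every other gene's trajectory is pinned to the
observed data, interpolated piecewise-linearly between sample times. The
implementation pre-computes the log-expressions of the observed genes at all
RK4 stage times once per dataset, so each candidate evaluation costs one
small matrix product plus a scalar integration loop. Note the consequence
tested in the suite: decoupled self-consistency (the generating model
reproduces its own output) holds only up to the *sampling* interval, because
the interpolant, not the model, supplies the neighbours.

## The seven inference algorithms

All algorithms draw parameters from the same search ranges — kinetic orders
[−3, 3], rate constants [0, 20] — and account cost identically: one function
call is one candidate evaluation (one coupled/decoupled simulation, or one
ANN training), and every run consumes its call budget exactly, with no early
stopping.

* **CLGA** — generational real-coded GA over the full parameter vector.
  Operators: binary tournament, BLX-0.5 crossover (p = 0.9), per-coordinate
  Gaussian mutation (p = 1/dim, σ = 5% of range), one elite. Fitness: squared
  error of the coupled simulation started from each series' observed initial
  state, summed over genes/time/series.
* **MOGA / Fuzzy MOGA** — the same encoding with the squared error split into
  one objective per gene; survivor selection by fast nondominated sorting
  with crowding distance. Parent tournaments are crisp (rank, crowding) or
  fuzzy: the dominance degree of u over v is the mean over objectives of
  clip((v_i − u_i)/scale_i, 0, 1), with scales set to the current
  population's per-objective interquartile range (the membership shape is a
  deliberately simple linear choice; the original form is not published in
  enough detail to copy). The reported model is the knee point of the final
  front — minimum sum of max-normalised objectives.
* **GA+ES** — an outer binary GA over sparsity structures (which kinetic
  orders are nonzero, at most 5 per gene per matrix), each structure scored
  by a freshly started inner (3+12)-ES with log-normal self-adaptive
  per-coordinate steps fitting the unmasked parameters; structure fitness
  adds λ_c per nonzero (default 0.01 — see "Calibration notes"). One inner
  parent inherits the best parameter vector found so far; purely random
  inner starts make structure fitness too noisy to rank structures at
  realistic inner budgets.
* **PEACE1** — iterative GA: the budget is split into 10 cycles; after each
  cycle the 10% smallest-magnitude still-free kinetic orders of the best
  model are fixed at zero, and the next cycle restarts from perturbed copies
  of the pruned best. Zeroed entries never return; once no further entries
  qualify, remaining cycles refine parameters only.
* **GLSDC** — per-gene memetic GA: every offspring is refined by coordinate
  pattern search (initial step 10% of range, 3 halvings), followed by
  skeletalising — any kinetic order whose zeroing changes the local objective
  by less than τ_rel = 0.01 (relative) is set to exactly zero. This is both
  the sparsity prior and the noise-control device: parameters that only chase
  noise barely move the objective. The worst half of the population is
  re-randomised every 10 generations.
* **DE+AIC** — per-gene DE/rand/1/bin (F = 0.5, CR = 0.9, population
  10·dim) minimising N·ln(RSS/N) + 2K, where RSS is the decoupled residual
  sum of squares, N the number of fitted points and K the count of
  parameters above the zero tolerance. Each generation a greedy pass tests
  zeroing the best individual's kinetic orders in increasing magnitude and
  keeps any zero that lowers the objective.
* **GA+ANN** — per-gene GA over regulator subsets (bitmask, fan-in capped),
  each subset evaluated by training its ANN; the per-gene winner with the
  lowest trained scaled-space MSE joins the assembled network.

Per-gene methods split the call budget evenly across the analysed genes
(remainder to the first genes), so the total is still budget-exact, and
assemble a whole-network model; genes outside the analysed subset keep an
inert placeholder equation (zero synthesis, unit decay).

## Synthetic benchmarks

The generator emulates sparse time-course benchmark designs. Regulator sets
are sampled by preferential attachment — gene j is picked with probability
proportional to 1 + its current out-degree — with per-gene in-degree uniform
in [3, 5] (capped at n−1; a 2-gene fixture uses exactly one regulator per
gene). This yields the right-skewed out-degree distributions (hubs) of real
GRNs; modularity and feedback motifs beyond what preferential attachment
produces are not modelled, so passing benchmarks here speaks to sparsity
handling only. Every gene carries a degradation self-term h_ii ∈ [0.5, 2].

Generated truth parameters are drawn from deliberately tamer ranges than the
search space: rate constants U[2, 15] and off-diagonal kinetic orders
±U[0.1, 2]. At the extremes of the search ranges (orders near ±3, rates near
0) a large fraction of random scale-free truths either explode or pin at the
state floor from almost every initial condition, which would make dataset
generation a rejection-sampling lottery; the tamer ranges keep truths
integrable while remaining squarely inside what the inference methods must
search.

Datasets total 60 points for networks up to 20 genes, 80 at 30 and 125 at 50
genes, split into 4 short series (5 for the 125-point design) started from
initial states U[0.5, 2], sampled every 0.05 time units (S-System time is
arbitrary; this spacing resolves the transients the default rate constants
produce). A series whose integration diverges is redrawn from a fresh
initial state (bounded retries), and a truth for which no stable dataset
exists is itself re-sampled deterministically. Measurement noise is
multiplicative Gaussian — x → x(1+ε), ε ~ N(0, level) — at 1, 2, 5 and 10%,
reading "percent noise added to all values" as proportional error, the usual
convention for expression data; an additive mode is available as a switch.

## Evaluation criteria

* Data MSE: mean squared residual between the model's own free-running
  simulation (from each series' first observed row) and the data.
* Parameter MSE: per parameter, or per gene (total squared error divided by
  n) — the size-comparable convention when most parameters are true zeros.
* Interactions: sensitivity TP/(TP+FN) and specificity TN/(TN+FP) over all
  n² ordered pairs, self-loops included (a switch excludes them; the
  denominator convention genuinely matters for small dense truths, see
  below). An edge is the union of g and h evidence.
* Robustness: per-entry sample variance across repeated runs, averaged
  separately over kinetic orders and rate constants.
* Run summaries: type-7 quartiles, notches median ± 1.57·IQR/√n reduced to
  the quartile limits when they exceed them, and means trimmed of the best
  and worst `trim` runs.

Run protocols: whole-network methods 7 runs per dataset; per-gene methods 5
runs × first 5 genes (25 cells); the single- vs multi-objective study 20
paired-seed runs, trimmed averaging with trim = 2, and a paired t-test on
best fitness after one fifth of the budget. Per-cell seeds are CRC32 hashes
of (plan seed, algorithm, run, gene), so any cell is reproducible in
isolation and a completed plan re-runs idempotently.

## Calibration notes and known limitations

* **λ_c (GA+ES complexity weight).** With the weight set at 1 error-unit per
  nonzero order, the sparsity penalty of any non-trivial structure exceeds
  the entire squared-error range of a short noiseless series, and the
  structure GA provably settles on the empty structure. The default 0.01
  keeps the sparsity pressure while letting fit dominate; it should be raised
  for long or noisy series where error magnitudes are larger.
* **Problem sizes.** The test suite and the acceptance script exercise the
  pipeline on 2-gene fixtures (20 points, 2 series) with budgets of
  4k–30k calls, a 5-gene/60-point benchmark for noise behaviour and a
  10-gene one for edge recovery; the library defaults keep the published
  protocol budgets (e.g. 100,000 calls for the MO study) for full-scale use.
* **Small dense truths have almost no true negatives.** At 5 genes with 3–4
  regulators each plus self-degradation, 22 of 25 ordered pairs are real
  edges, so specificity rests on a 3-pair denominator and is nearly
  meaningless; edge-recovery quality is therefore reported on the 10-gene
  benchmark.
* **AIC pressure on noiseless data.** On noiseless series the RSS of a good
  fit approaches the integrator error, and N·ln(RSS) then reacts strongly to
  zeroing even a useless parameter, so DE+AIC prunes less than its published
  behaviour on noisy data; its specificity on dense noiseless fixtures is
  correspondingly modest.
* **Decoupled vs coupled fit.** A model assembled from independently fitted
  genes can simulate poorly as a coupled system even when every decoupled
  fit is tight (each gene's fit borrowed the *observed* neighbours); both
  quantities are reported where relevant.
* The ES used inside GA+ES is deliberately small and greedy (μ=3, λ=12);
  it under-performs a GA of equal budget on the full 12-dimensional 2-gene
  problem, which mirrors the method's published cost profile (many cheap
  structure evaluations rather than one strong parameter fit).
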