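# Methods

This note documents the models, conventions and numerical choices behind
knocknet: what exactly is computed, which knobs matter, and what the
synthetic benchmarks do and do not demonstrate.

## Confidence matrices from knockout steady states

Inputs are a wild-type vector `x^wt` and an N×N knockout matrix with
`x^i_j` the steady state of gene *j* after deleting gene *i* (the deleted
gene itself is identically zero). All four confidence scores are
non-negative with a zero diagonal; self-edges are never predicted and are
excluded from rankings and evaluation.

- **D** — `|x^i_j − x^wt_j|`. Scale-equivariant: doubling a gene's
  expression units doubles its column.
- **ND** — `D / x^wt_j`. Comparable across genes whose absolute levels
  differ by orders of magnitude. A wild-type level of exactly zero is an
  error by default; `zero_wildtype="floor"` substitutes machine epsilon
  with a warning (used by the ensemble benchmark, where a fully repressed
  gene can sit exactly at zero).
- **ZD** — per-target-column z-score of the deviations,
  `||x^i_j − x^wt_j| − μ_j| / σ_j`.
- **ZR** — per-target-column z-score of the raw values,
  `|x^i_j − μ_j| / σ_j`. Preferred: deviations subtract one noisy number
  from another, raw values do not.

Column statistics use the sample (n−1) standard deviation and by default
exclude the target's own knockout row: that observation is structurally
zero, a guaranteed outlier that would inflate `σ_j` and shrink every
z-score in the column. Both choices are configurable
(`include_self_knockout`, `ddof`) but the defaults are the tested path.
A zero-variance column carries no signal; it is zeroed with a warning
rather than raised, so fully deterministic fixtures run end-to-end.
Z-scores are invariant to per-column affine rescaling of the data; this
is asserted by property tests.

## Feed-forward down-ranking

Thresholding the confidence matrix at `t ≥ 0` (inclusive, so `t = 0`
retains every pair) gives the causal-influence network G1. Its strongly
connected components are contracted to a condensation DAG (networkx
`condensation`). A gene-level edge (u, v) is *removable* iff its
endpoints lie in different components and some successor component
m ≠ comp(v) of comp(u) still reaches comp(v) — i.e. the condensation
holds a path of length ≥ 2 from comp(u) to comp(v). This is equivalent
to deleting the direct condensation edge and testing reachability; the
test suite asserts agreement of the two formulations against a
brute-force transitive-closure oracle on random digraphs. Edges inside
one component are never touched: every gene in a cycle influences every
other, and which cycle edges could be dropped depends on deletion order,
so cyclic cores are exempt by design.

Removability is decided simultaneously from the condensation of G1 (no
sequential deletion). All retained, non-removable edges then gain a
uniform boost `B = max(w) + 1`: every essential edge outranks every
non-essential one, order is preserved within each group, the output is a
permutation of the input pair set, and applying the operator again with
a threshold above `B` is a no-op. Equal final scores are broken by
ascending (source, target), making rankings and files deterministic.

The threshold is a free parameter deliberately left without a default:
its useful range depends on the score units (z-scores vs raw
deviations), so the CLI provides a sweep mode that reports AUCs per
threshold when a gold standard is available. On simulated ensembles the
effect of down-ranking is a small lift of AUC(PvsR) at intermediate
thresholds (around t ≈ 3 column-sds for ZR) with AUC(ROC) essentially
unchanged; on very small networks (~10 genes) it is typically a no-op
because thresholded subgraphs rarely contain long alternative paths.

## Knockout simulator

Topologies are signed Erdős–Rényi digraphs: undirected G(n, p) with
`p = K/(n−1)` — K is the expected mean **total** (in + out) degree, the
convention under which a stated K is meaningful — each edge oriented
uniformly at random, sign ±1 with probability ½, no self-loops.

Dynamics are additive signed Hill kinetics:

    dx_i/dt = k_i (1 + ε_i) · max(0, b_i + Σ_j A_ji · s · x_j^h/(1 + x_j^h)) − λ_i x_i

| parameter | meaning | unit | default |
|-----------|---------|------|---------|
| `b_i` (basal_rate) | basal transcription rate | activity/time | 1 |
| `λ_i` (degradation) | first-order decay constant | 1/time | 1 |
| `s` (interaction_strength) | per-edge regulatory gain | activity/time | 1 |
| `h` (hill_coeff) | Hill cooperativity | — | 1 |
| `σ` (bio_noise_sd) | CV of the frozen production perturbation | — | 0.15 |
| `measurement_noise_sd` | SD of lognormal measurement noise | — | 0 (off) |

With the all-ones defaults an isolated gene sits at `b/λ = 1`; a single
saturated activator adds `x/(1+x) = 0.5`, a single inhibitor removes the
same. The production floor `max(0, ·)` keeps multiple inhibitors from
driving negative synthesis.

**Noise model.** `ε_i` is drawn once per gene per experiment (wild type
included) and held frozen while the system relaxes, so every experiment
has a well-defined steady state; it multiplies production, so
steady-state fluctuations scale with the expression level itself. This
choice is deliberate: real knockout compendia show per-gene mean
absolute deviations roughly proportional to the wild-type level, and a
multiplicative perturbation reproduces that diagnostic by construction
(asserted as a strong positive Spearman correlation in the test suite),
whereas an additive fixed-SD offset produces flat deviations and, as a
side effect, breaks the normalized-deviation score (dividing uniform
noise by small wild-type levels amplifies it). The default CV of 0.15
sits in the 10–20 % range typical of biological variability in
expression data. Optional multiplicative lognormal measurement noise is
available for emulating instrument noise but is off in all benchmarks.

**Knockout protocol.** The wild type is solved from the unregulated
start `x = b/λ`; each knockout experiment restarts from the wild type
with `k_i = 0` and a fresh noise draw. Gating both production and noise
by `k_i` makes a knocked-out gene's steady state exactly zero.

**Steady-state solver.** The primary path is damped explicit-Euler
relaxation (step `α/λ`, `α = 0.5`) of the kinetics, iterated until the
residual `‖dx/dt‖∞ < 1e−8`; this is two to three orders of magnitude
faster than a stiff integrator for these smooth, strongly damped systems
and is what makes 15,000-solve ensembles take seconds. Trajectories the
fixed step cannot settle fall back to LSODA integration over a long
horizon with the same residual check; a residual that still fails raises
a convergence error naming the experiment. Because activities are
constrained non-negative, the residual is projected: at `x = 0` a
negative drive is a boundary steady state (a fully repressed gene with a
negative noise draw), not a failure. Acyclic networks provably converge;
cyclic ones are covered by the fallback.

## Evaluation

- **AUC(ROC)** is computed in closed Mann–Whitney form with midrank tie
  handling: the probability that a uniformly random true edge outranks a
  uniformly random non-edge, ties counting ½. No curve interpolation is
  involved. A brute-force pairwise-comparison oracle and sklearn's
  `roc_auc_score` serve as independent cross-checks in tests.
- **AUC(PvsR)** walks the ranking over distinct score levels and sums
  `precision · Δrecall` — non-interpolated average precision, with each
  tie group contributing its pooled precision. Consequences asserted in
  tests: a perfect ranking scores 1, an all-ties ranking scores the
  positive prevalence, and the value coincides with sklearn's
  `average_precision_score`. Interpolating PR scorers can differ by
  ~0.01 at realistic candidate counts; comparisons across scorers should
  allow for that.

Rankings must cover all N(N−1) ordered pairs; a gold standard with zero
edges (or zero non-edges) makes the metrics undefined and is an error.
The ensemble benchmark derives one child seed per replicate from a
master seed, so replicate r is reproducible in isolation; replicates
whose random truth has no edges are redrawn and logged.

## Benchmark scope and what passing shows

The shipped benchmarks use 50-replicate ensembles of 100-gene networks
at mean degrees 2, 3 and 5 — large enough for ensemble means with
standard errors around 0.005 while keeping a full run under a minute on
one CPU. Under these conditions the raw-data z-score dominates the other
confidence matrices on AUC(PvsR) at every density, AUC(ROC) declines
with density as feed-forward confusion grows, and down-ranking yields
its small PvsR lift at intermediate thresholds.

Two caveats on realism. First, the simulator's ER topology,
homogeneous all-ones kinetics and purely additive regulation are
idealizations; real transcriptional networks have heavy-tailed degree
distributions, heterogeneous rates and synergistic regulation, and
scores transfer to such data only qualitatively. Second, the relative
ordering of the two weakest matrices (D vs ND) is not robust: their gap
is small and its sign depends on fine details of how noise couples to
expression level, so conclusions should rest on the z-score variants,
which dominate under every noise model we examined. Statistical
calibration of individual edges (p-values), knockdown/time-series/
multifactorial designs, and fan-in/fan-out motif corrections are out of
scope.
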