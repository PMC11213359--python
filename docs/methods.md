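# Methods

This note documents the statistical model, the networks, the missing-data
encodings, the training procedure, the validation machinery, and the
numerical and design choices behind `flowmiss`.

## 1. Inference problem and flow model

Given a mechanistic simulator `x ~ π(x|θ)` over a fixed observation grid
`t₁ < … < t_nx` and a prior `π(θ)`, the goal is the posterior
`π(θ | x_avai)` conditioned on the *available* entries of an incomplete
observed dataset.  The posterior is approximated by a conditional
normalizing flow: an invertible map `z = f_φ(θ; h)` to a standard-normal
latent, conditioned on a summary vector `h = h_ψ(x_aug)` computed from the
encoded data.  By the change of variables,

    π_φ(θ | h) = N(f_φ(θ; h); 0, I) · |det ∂f_φ/∂θ|,

so minimizing the Monte-Carlo objective

    L(φ, ψ) = (1/M) Σₘ [ ½‖f_φ(θ⁽ᵐ⁾; h_ψ(x⁽ᵐ⁾))‖² − log|det J⁽ᵐ⁾| ]

over pairs `(θ, x) ~ π(θ)π(x|θ)` is maximum-likelihood training of the
conditional density, equivalent to minimizing the expected KL divergence
from the true posterior.  With enough capacity and training, the learned
posterior matches the true one for data-distribution-typical inputs;
everything below is machinery for achieving and *verifying* that.

### Coupling layers

The flow stacks K = 5 affine coupling blocks.  Each splits its input
`u = (u₁, u₂)` (sizes ⌈n_θ/2⌉, ⌊n_θ/2⌋) and computes

    v₁ = u₁ ⊙ exp(s₁(u₂, h)) + t₁(u₂, h)
    v₂ = u₂ ⊙ exp(s₂(v₁, h)) + t₂(v₁, h)

with four fully connected internal networks (two hidden layers of width 64,
ELU activations, condition h concatenated to every internal-net input).
The log-Jacobian is `Σ s₁ + Σ s₂` — no matrix determinant is ever formed —
and the inverse is algebraic.  A fixed random permutation (drawn once at
initialization from the seed) mixes dimensions between blocks.

Numerical choices:

* **Scale clamping.** Raw s-outputs pass through `(2α/π)·arctan(s/α)` with
  α = 1.9 before exponentiation, bounding each factor to `e^±1.9`.  The
  log-determinant uses the clamped values, so invertibility and the Jacobian
  stay exact.  Unbounded `exp(s)` is the classic failure mode of affine
  flows early in training.
* **Identity initialization.** Final layers of all s/t networks start at
  zero, so a fresh flow is the identity map (up to its permutations) with
  zero log-determinant.  Training then deforms a well-conditioned start.
* **Parameter standardization.** θ is standardized to zero mean / unit
  variance under the prior before entering the flow and de-standardized on
  output.  The flow therefore always works on O(1) quantities regardless of
  the prior's location and scale.

### Summary network

A single-layer LSTM reads the encoded dataset row by row; its final hidden
state (size H) is the conditioning vector.  H follows the study
configurations: 8 for the 3-point conversion problem, 32 for the 11-point
parameter-dependent variant and the desk-scale oscillatory/epidemic runs
(the full-scale configurations use 64–128, available via `ArchConfig`).
The forget-gate bias starts at 1 (standard practice, stabilizes early
memory).  An empty input sequence — possible under the time-label encoding
when everything is missing — summarizes to the zero vector, the natural
"no information" representation.

### Autodiff

No deep-learning framework is part of the dependency stack; the networks
run on a small reverse-mode automatic-differentiation engine over float64
NumPy arrays (`flowmiss.autodiff`), providing exactly the operations the
architecture needs.  Training uses the taped path; inference and density
evaluation use parallel plain-NumPy implementations.  Correctness is
enforced two ways: an end-to-end gradient check against central finite
differences (relative error < 1e-4 through LSTM + flow + loss), and
bijectivity tests that run the taped forward against the NumPy inverse.

## 2. Missing-data encodings

An availability mask `τ ∈ {0,1}^nx` marks observed time points.  Incomplete
data carry NaN at masked rows; the sentinel is confined to the
`IncompleteData` container and asserted never to reach a network input.

* **E1 ("insert c")** replaces missing entries by a constant c.
* **E2 ("augment by 0/1")** additionally appends τ as an indicator column.
  Its output shape is independent of how much data is missing, and decoding
  by the indicator recovers the incomplete data exactly (lossless).
* **E3 ("time labels")** keeps only available rows and appends each row's
  actual time point as a positional label; the row count is Σ τ.

Dummy-value defaults follow the study configurations: c = −1 for models with
positive trajectories (conversion reaction, SIR), c = −5 for the sinusoid
and FitzHugh–Nagumo models whose signals occupy roughly [−2, 2].

Masking operates at time-point granularity: one mask entry hides the whole
observation row.  Variable-length series embed as trailing missingness
(a length-n series in an n_max grid is a mask with n leading ones).

Mechanisms for `π(τ)`:

* **Uniform (MCAR):** `n_∅ ~ U{0, …, n_∅^max}`, positions uniform without
  replacement.  The count can be drawn per sample or once per batch.
* **Trailing:** series length uniform on `{n_min, …, n_x}`.
* **Parameter-dependent:** a model parameter `p ~ U(0, 0.8)` fixes the
  count deterministically as `n_∅ = ⌊p · n_x⌋`, positions uniform.

E3 produces ragged batches unless the count is shared, so configurations
combining E3 with per-sample sampling are rejected at validation time, as is
E3 with parameter-dependent missingness.

## 3. Benchmark models and priors

| model | θ | prior | grid | noise sd |
|---|---|---|---|---|
| conversion A⇌B | (ln k₁, ln k₂) | N(−0.75, 0.25)² | {0, 5, 10} (or 11 pts on [0,10]) | 0.05 |
| sinusoid sin(2πat)+b | (a, b) | U(0.1,1) × U(−1,1) | 41 pts on [0,10] | 0.05 |
| FitzHugh–Nagumo | (α, β, γ) | U(0.2,1.2)² × U(1,4) | 21 pts on [0,15] | 0.05 |
| SIR (ODE / SSA) | (log₁₀β, log₁₀γ) | N(−0.8,0.3) × N(−1.4,0.3) | 21 pts on [0,60] | 0.05 |

Noise levels, grids and priors are package defaults chosen to be consistent
with the printed ground-truth parameter values of the benchmark datasets;
all are configurable.  Since every reference comparison is computed
internally under the same configuration, the validation logic does not
depend on these specific values.

* The **conversion reaction** (initial state (A,B) = (1,0), B observed) is
  evaluated through its exact solution
  `B(t) = k₁/(k₁+k₂) · (1 − e^{−(k₁+k₂)t})`; the training loop calls it
  ~400k times, and exactness beats any tolerance argument.  Tests verify it
  against an independent adaptive ODE integration.
* **FitzHugh–Nagumo** uses `dV/dt = γ(V − V³/3 + R)`,
  `dR/dt = −(V − α + βR)/γ`, x₀ = (−1, 1), V observed.  The prior box spans
  excitable and oscillatory regimes around the classical (0.7, 0.8, 3).
* **SIR** observes the scaled infected fraction I/N (N = 1000, I₀ = 1).
  ODE integration uses LSODA at rtol = atol = 1e-8 (all stiff-capable needs
  at these sizes are accuracy-dominated, not cost-dominated).
* The **SSA variant** is an exact Gillespie simulation of
  S+I→2I (rate βSI/N) and I→R (rate γI), read off piecewise-constantly at
  the grid times, with the event loop JIT-compiled (numba) so that
  thousand-replicate ensemble checks run in seconds.  A note on validation:
  the ODE is the N→∞ limit, and the jump process's ensemble mean carries a
  genuine O(1) finite-size bias (from β·Cov(S,I)/N).  The large-population
  agreement check therefore uses a mild epidemic from a non-degenerate
  initial state (N = 10⁴, I₀ = 1000), where that bias sits below the
  Monte-Carlo resolution of 2000 replicates; with I₀ of a few individuals
  the deviation near the peak is real and would be misread as a bug.

Gaussian measurement noise is added inside the batch simulation pipeline,
before masking, so missingness always operates on noisy "measurements".

## 4. Training

Online learning: every iteration simulates a fresh batch (sample θ from the
prior, simulate, add noise, sample masks, encode), so no fixed training set
exists to overfit.  Defaults are the desk-scale budget — 30 epochs × 200
iterations × batch 64 ≈ 380k simulations, about a minute for the closed-form
models on one CPU — with the full-scale budget (300 × 1000) behind a flag.
The optimizer is Adam (β = 0.9/0.999) with cosine decay from 5e-4 to 1e-5
and global-norm gradient clipping at 5.  Isolated non-finite batches are
skipped; ten consecutive ones abort with a diagnostic.  Runs are exactly
reproducible from the seed.

**Per-sample vs per-batch missingness sampling.**  Fixed-shape encodings
(E1/E2) allow the number of missing entries to be drawn independently for
every sample; E3 forces one shared count per batch.  Both give unbiased loss
estimates, but batch-level sampling adds a between-batch variance component
equal to the variance of the conditional expected loss across missingness
levels.  `loss_variance_experiment` measures this with frozen networks on
500 fresh batches per level.  The networks are frozen *after a short warm-up
training* (2 epochs × 100 iterations): a zero-initialized flow has a
data-independent loss, for which both sampling levels are trivially
identical — the warm-up makes the loss depend on the data, which is the
regime the comparison is about.  At the variable-length sinusoid setting the
measured variance inflation is roughly an order of magnitude, with means
agreeing well within Monte-Carlo error.

## 5. Inference and validation

**Amortized sampling.**  Observed data are encoded exactly as in training
(the checkpoint stores encoding, dummy value, time grid and standardization
constants, and inference refuses mismatched inputs), summarized once, and L
latent draws are pushed through the inverse flow.  No simulator calls occur;
a call counter makes this assertable.  Default L = 2000 — smooth density
estimates at negligible cost.

**Grid references.**  For gaussian-noise models with tractable trajectories
the available-data log-likelihood is an explicit sum over observed entries
(missing entries contribute nothing).  The posterior is tabulated on a
regular grid: 200 points per axis spanning prior mean ± 5 sd (gaussian) or
the uniform bounds, normalized by log-sum-exp times cell volume.  The
construction is self-validating: it is invariant under grid refinement,
reduces to the prior for all-missing data, matches the conjugate-normal
closed form in a linear-gaussian configuration, and gives the same answer
whether an entry is NaN-masked or physically removed from the dataset.
A warning fires if visible mass reaches the boundary of an unbounded axis.
`compare_to_reference` reports |sample mean − ref mean| / ref sd per
component, sample/ref sd ratios, and the energy distance to
inverse-transform draws from the grid.  The stochastic SIR model has no
tractable likelihood and is validated by posterior predictive checks
instead; the 3-parameter FHN desk-scale experiment likewise relies on
predictive coverage (an 80³ ODE grid is supported but far too slow at desk
scale).

**Posterior predictive checks** re-simulate noisy trajectories for n draws
and report the ensemble, its mean and the central 90% band.

**Simulation-based calibration.**  For n datasets drawn from the training
generative process, the rank of each true parameter among L = 99 posterior
draws is recorded per component; exact posteriors give uniform ranks, tested
by χ² over 10 bins.  Two caveats are built into the test design: SBC is
*data-averaged*, so a sampler that ignores the data and returns the prior is
uniform by construction and cannot be rejected — the negative control is
therefore an underdispersed sampler (correct mean, one third the sd), which
SBC rejects decisively.

**Ambiguous dummy values.**  With c = 0.5 — a value the conversion model can
genuinely produce — E1's input cannot distinguish a measurement near 0.5
from a masked entry, while E2's indicator can.  The trained E1 network
resolves the ambiguity by consistently reading ~0.5 as signal: its posterior
for a dataset whose near-0.5 entry is *declared missing* is visibly
narrower than the correct prior fallback, and for a dataset whose available
entry (0.7) contradicts a fake 0.5 "measurement" its posterior mean misses
the reference by ≈ 0.4 reference sd, where E2 stays within 0.15.  Note one
subtlety of this model: a trajectory equilibrating at 0.5 corresponds
exactly to the prior-symmetric line k₁ = k₂, so datasets whose near-0.5
entry is *consistent* with the rest (e.g. an available value 0.501 at the
final time) cannot separate the two encodings by posterior means — the
discriminating dataset must make the misread dummy dynamically inconsistent.
The indicator-flip check — identical numbers, flipped availability bit —
tests the same mechanism directly via an energy-distance permutation test
(500 permutations, α = 0.01).

**Parameter-dependent missingness.**  With `n_∅ = ⌊p·n_x⌋` the exact
p-posterior given an observed count n_∅ is uniform on
[n_∅/n_x, (n_∅+1)/n_x); the trained network is checked for ≥ 90% of its
p-mass in that interval and for |corr(k₁, p)| < 0.2 (the dynamics and the
missingness mechanism are independent by construction).

## 6. What the synthetic data do and do not cover

All validation data come from the package's own simulators under the stated
priors, noise levels and MCAR/deterministic missingness mechanisms.  Passing
tests show the amortized posteriors match exact available-data posteriors
*within this generative process*.  They do not certify behavior under model
misspecification, non-gaussian or heteroscedastic noise, data-dependent
(MNAR) missingness, irregular sampling beyond grid embedding, or observed
data far outside the prior-predictive support — a trained checkpoint is only
valid for data resembling its training distribution.  Desk-scale budgets
(30 × 200 × 64; LSTM 8–32) are the package's default problem sizes; the
full-scale configurations are supported but not exercised by the test suite.

## 7. Known limitations

* Single-chain LSTM summaries; no attention/transformer encoders.
* Affine couplings only (no spline/autoregressive transforms); posteriors
  with severe multimodality in >2 dimensions may need more layers.
* Grid references are exponential in n_θ and capped at 3 parameters.
* Offline training with simulation reuse is out of scope by design; every
  iteration pays the simulation cost.
* The CPU autodiff engine is adequate for the benchmark scale (minutes per
  training), not for large summary networks or long sequences.
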