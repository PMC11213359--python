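# flowmiss

Amortized simulation-based posterior estimation for **incomplete** time-series
data, built on conditional normalizing flows.

## The problem

Mechanistic models (ODE or stochastic) define a likelihood only implicitly,
through simulation.  Amortized neural posterior estimation solves this by
training, once and up front, a conditional invertible neural network (cINN)
`f(θ; h)` that maps model parameters θ to a standard-normal latent z,
conditioned on a learned fixed-size summary `h = h_ψ(x)` of the data.  After
training, posterior samples for *any* observed dataset cost no further
simulations: encode, summarize, and push latent draws through the inverse flow,

    θ ~ π(θ | x)   ⇔   θ = f⁻¹(z; h(x)),   z ~ N(0, I).

Real datasets, however, have **missing entries** — skipped visits, device
dropouts, censored reports — and neural networks cannot ingest NA values.
`flowmiss` trains the networks on simulated datasets with artificially masked
entries, so that the learned posterior conditions on exactly the available
data.  Three encodings turn an incomplete series into numeric input:

| encoding | idea | shape |
|---|---|---|
| **E1** "insert c" | replace missing entries by a dummy constant c | fixed |
| **E2** "augment by 0/1" | E1 plus a binary availability column | fixed |
| **E3** "time labels" | keep available rows, label them with their time points | varies |

E2 is the robust choice: its indicator disambiguates a genuine measurement
that happens to equal the dummy value, and its fixed shape lets the number of
missing points be drawn per sample rather than per batch, which demonstrably
lowers the variance of the training loss.

The joint training objective is the Monte-Carlo estimate of the negative
conditional flow log-likelihood over fresh simulated batches,

    L(φ, ψ) = (1/M) Σₘ [ ½‖f_φ(θ⁽ᵐ⁾; h_ψ(x⁽ᵐ⁾))‖² − log |det J_f(θ⁽ᵐ⁾)| ].

Five benchmark simulators are built in: a conversion reaction A⇌B (exact
linear-ODE solution), a sinusoid, the FitzHugh–Nagumo neuron model, and SIR
epidemic dynamics as an ODE and as an exact Gillespie jump process.  For
tractable models the package also tabulates the **exact available-data
posterior on a parameter grid**, which serves as ground truth for validating
the amortized posteriors, alongside posterior predictive checks and
simulation-based calibration (SBC).

The networks (affine coupling layers with ELU internal nets; an LSTM summary
encoder) and their training run on a small reverse-mode autodiff engine over
NumPy included in the package — no deep-learning framework is required.

## Worked example

`examples/02_train_and_infer_conversion.py` trains the E2 encoding on the
conversion reaction (two log-rate parameters, three observation times, up to
two entries missing) and queries the amortized posterior:

```
training E2 encoding: 30 epochs x 200 iterations, batch 64
epoch-averaged loss: 1.000 (first) -> 0.310 (last)

ground truth (ln k1, ln k2): [-0.98 -0.66]
amortized posterior mean:    [-0.884 -0.621]
grid reference mean:         [-0.893 -0.607]
mean discrepancy (ref-sd units): [0.045 0.072]
sd ratio (amortized/reference):  [0.963 0.98 ]

uninformative dataset: posterior mean [-0.724 -0.774] sd [0.245 0.235] (prior: mean -0.75, sd 0.25)
```

The amortized posterior mean sits within 0.07 reference standard deviations
of the exact available-data posterior, with matching spread.  For a dataset
whose only available point carries no parameter information, the posterior
correctly falls back to the prior.  The other examples cover encodings
(`01`), the per-sample vs per-batch loss-variance effect (`03`),
parameter-dependent missingness (`04`), and grid references with predictive
checks (`05`).

A thin CLI wraps the same library calls:

```bash
flowmiss train --model conversion_reaction --encoding E2 --out ckpt.h5
flowmiss infer --checkpoint ckpt.h5 --data observed.csv --out samples.csv
flowmiss experiment run conversion_basic --seed 0 --out results_dir
```

Observed CSV files have a `time` column and value columns; empty cells mark
missing observations.

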