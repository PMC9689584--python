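# ctbsi — continuous-time Bayesian structural inference

`ctbsi` infers interpretable state-machine models of **continuous-time,
discrete-event processes** — neural spike trains, animal behaviour records,
seismic event series: any data of the form *(symbol, dwell time), (symbol,
dwell time), …* with a possibly still-ongoing final dwell.  From such a
sequence it recovers a **unifilar hidden semi-Markov model (uhsMm)**: a
finite-state generator in which each hidden state `g` emits one symbol
`x ~ p(x|g)` for a random dwell `τ ~ φ_g(τ)` and then moves deterministically
to `ε⁺(g, x)`.  Unifilarity (the deterministic successor map) means the hidden
path is decodable from the observations plus a start state, which makes the
states *causal states* — minimal sufficient statistics of the past for
predicting the future.

On top of the inferred model the package provides:

* **Structure selection.**  Candidate topologies are enumerated, each is fitted
  by maximum likelihood — emission probabilities by count ratios
  `p*(x|s) = n(s,x)/n(s)`, dwell densities by a normalised-output neural
  estimator trained on the per-state dwell partition — and scored by
  `BIC = (k_M/2)·ln n − log L̂`; the minimum-BIC model wins.
* **Differential entropy-rate estimation**, two ways.  Model-based plug-in:
  `ĥ = −Σ_s p̂(s) μ̂_s ∫ φ̂_s(t) ln φ̂_s(t) dt` with Parzen-window dwell
  densities and the time-weighted stationary distribution `p̂(s)` solved from
  decoded transition counts.  Model-free: the slope of the trajectory entropy
  `H[(x,τ)_{0:T}]` in `T`, estimated by conditioning on the event count and
  combining plug-in discrete entropies with a Kozachenko–Leonenko k-NN
  estimator on the dwell vectors.
* **Causal-state prediction.**  Each time point maps to the triple
  `(g, x₀, τ₀⁺)` — hidden state, current symbol, time since the last symbol
  change.  The symbol a horizon `T` ahead is predicted as the average future
  of the `k` nearest training points sharing `(g, x₀)`, with `k` chosen by
  cross-validation; the floor comparator is the persistence rule.

All experiments run on the package's own simulator; the benchmark generators
are binary-alphabet state cycles with inverse-Gaussian dwell distributions.

## Worked example

Simulate the four-state benchmark cycle (dwells IG(1,5), IG(3,2), IG(3,2),
IG(1,5); forced emissions 0,1,0,1), select its structure by BIC, and estimate
its entropy rate:

```python
import numpy as np
from ctbsi import simulate, select_model, enumerate_topologies, entropy_rate_exact
from ctbsi.density import COMPACT_DENSITY_CONFIG
from ctbsi.entropy_rate import plugin_entropy_rate
from ctbsi.experiments import make_model

model = make_model("fig4_4state")
print(f"exact entropy rate: {entropy_rate_exact(model):.4f} nats")

seq, _ = simulate(model, n_events=5000, seed=11)
best, table = select_model(seq, enumerate_topologies({"0", "1"}, 6),
                           COMPACT_DENSITY_CONFIG)
for topo, bic in table:
    print(f"  {topo.n_states()}-state cycle: BIC = {bic:.1f}")
print(f"selected: {best.model.topology.n_states()}-state model")
print(f"plug-in entropy rate: {plugin_entropy_rate(best):.4f} nats")
```

Output:

```
exact entropy rate: 1.8487 nats
  2-state cycle: BIC = 7786.2
  4-state cycle: BIC = 6985.7
  6-state cycle: BIC = 8479.3
selected: 4-state model
plug-in entropy rate: 1.9405 nats
```

The exact rate (1.8487 nats) is the plug-in formula evaluated with the true
densities.  At 5000 events BIC identifies the true four-state structure —
with ~200 events it prefers the two-state model, and larger candidate
machines are never chosen — and the kernel plug-in estimate lands within
about 0.1 nats of the truth (kernel smoothing biases it slightly upward).

A command-line interface mirrors the library:

```bash
ctbsi fit --events data.tsv --max-states 6 --out model.json --report bic.csv
ctbsi entropy --model model.json --method exact
ctbsi predict --model model.json --train data.tsv --query-time 12.5 --horizon 0.5
ctbsi bench selection_fig3 --scale 0.2 --seed 7 --out results/
```

Event files are plain TSV (`symbol<TAB>dwell`, optional trailing
`# censored`); models serialise to JSON.

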