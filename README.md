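# v1motifs

Directed functional networks, triplet motifs, and peer-prediction of
single-trial activity in mouse V1 calcium-imaging populations.

Trial-averaged tuning curves describe what V1 neurons do *on average*, but on
any single trial they explain little: responses fluctuate strongly, and those
fluctuations are shared across the local population. This package implements
an analysis chain that quantifies how much of a neuron's moment-to-moment
activity is predictable from its neighbors:

1. **Normalize** raw fluorescence to percent dF/F₀ against a time-varying
   baseline (transient masking + 4th-order, 81-point Savitzky–Golay filter).
2. **Classify tuning**: Dunnett-corrected responsiveness against pooled grey
   screens (α = 0.01), permutation trial-vector tests for direction and
   orientation tuning, and asymmetric circular Gaussian fits
   R(θ) = B + A₁·exp(−wrap(θ−θp)²/2σ²) + A₂·exp(−wrap(θ−θp−180°)²/2σ²).
3. **Infer a directed functional graph**: for each neuron pair and stimulus
   block, the partial correlation
   r_xy|z = (r_xy − r_xz·r_yz)/√((1−r_xz²)(1−r_yz²)), iterated over three
   controls (each neuron's stimulus-locked cross-block mean, and the
   within-block population mean), averaged over blocks; edge direction from
   the cross-correlogram peak lag (zero lag ⇒ bidirectional, > 500 ms ⇒ no
   edge).
4. **Count triplet motifs**: per-node cycle / middleman / fan-in / fan-out /
   total clustering on the binarized graph, normalized by sparsity-matched
   directed Erdős–Rényi ensembles.
5. **Reconstruct single-trial activity**: ŷ_j(t) = g·Σᵢ W[i→j]·xᵢ(t) + b,
   with variance explained VE = 1 − Σ(y−ŷ)²/Σy², benchmarked against
   LASSO-optimal weights (5-fold CV, one-standard-error rule) and
   leave-one-block-out cross-validation.

No public recording accompanies the original analysis, so
`v1motifs.synthetic` generates recordings in the same regime — blocked
drifting gratings (12 directions × 3 repetitions, 5 s gratings / 3 s greys at
25–33 Hz), tuned and untuned Poisson neurons, distance-dependent directed
coupling with frame-level lags, a running-linked latent and spatially local
co-fluctuation factors, read out through a slow-indicator kernel — with full
ground truth, so every stage is testable. See `docs/methods.md` for the
model and every numerical choice.

## Worked example

The numbered scripts under `analysis/` run the chain step by step on one
synthetic dataset (100 neurons, 6 blocks by default):

```bash
python analysis/01_simulate.py --seed 1 --out results/data/recording.h5
python analysis/02_preprocess.py
python analysis/03_tuning.py
python analysis/04_network.py
python analysis/05_motifs.py
python analysis/06_reconstruction.py
```

Output at seed 1 (identical seeds reproduce these numbers exactly):

```
$ python analysis/03_tuning.py
49/100 neurons responsive; 8 orientation-tuned, 36 direction-tuned
tuning-curve fit quality: r^2 = 0.88 +/- 0.12 across tuned neurons
mean tuning curves explain only 11.7% of single-trial response variance — most
variability is not stimulus-locked
recovered 78% of ground-truth tuned neurons

$ python analysis/05_motifs.py
ER-matched edge probability: 0.440
clustering vs sparsity-matched ER null (ratio > 1 = enriched):
  cycle      data 0.399  null 0.441 +/- 0.005  ratio 0.91
  middleman  data 0.507  null 0.441 +/- 0.005  ratio 1.15
  fan_in     data 0.461  null 0.441 +/- 0.005  ratio 1.05
  fan_out    data 0.469  null 0.441 +/- 0.005  ratio 1.06
  total      data 0.459  null 0.441 +/- 0.005  ratio 1.04
```

Cycles are *depleted* relative to chance while middleman motifs (one neuron
relaying an existing correlation) are the most *enriched* — the motif
signature associated with well-predicted neurons.

```
$ python analysis/06_reconstruction.py
population VE, partial-correlation weights: 22.4%
population VE, LASSO-optimal weights:       26.0%
population VE, held-out blocks:             15.7%
...
population VE by subsample size: 25: 13.2%, 50: 17.8%, 75: 20.7%, 100: 22.4%
Spearman rho (VE vs size) = 0.98
```

The three benchmarks order as optimal ≥ plug-in ≥ held-out, and the
population variance explained rises with the number of neurons sampled
without a plateau — more of each neuron's predictable variance comes into
view as more of its local neighborhood is recorded. (The absolute VE scale
depends on the synthetic regime; the orderings and trends are the analysis'
claims.)

The same chain is available as a CLI (`v1motifs run-all --seed 1 --out
results/pipeline`, with per-stage subcommands) or programmatically:

```python
from v1motifs import synthetic, preprocessing, funcnet, reconstruction

schedule = synthetic.make_schedule(n_blocks=6, seed=1)
_, rec = synthetic.simulate_population(synthetic.SimConfig(n_neurons=100),
                                       schedule, seed=2)
dff = preprocessing.preprocess(rec)
graph = funcnet.build_functional_graph(dff, schedule,
                                       positions_um=rec.positions_um)
result = reconstruction.reconstruct_population(graph, dff)
print(result.population_variance_explained)
```

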