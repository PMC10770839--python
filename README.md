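# iterlearn

Tools for **iterated-learning transmission-chain experiments** on
non-linguistic sequences.  In this paradigm a participant memorizes and
reproduces length-12 sequences of four colors (`r g b y`); the reproductions
become the next participant's stimuli, and over ten such generations the
sequences evolve culturally.  The package is aimed at cultural-evolution and
language-evolution researchers who want a fully scripted, reproducible
version of this analysis: simulate chains (or load your own trial tables),
compute the standard measures, and fit the multilevel Bayesian models that
quantify condition and generation effects.

Two designs are supported, differing only in who does the learning:

* **transmission** (condition 0): a fresh participant each generation,
  60 trials per generation — cultural transmission between people;
* **individual** (condition 1): one participant relearns their own previous
  reproductions, 30 trials × 10 generations = 300 trials — the
  no-transmission control.

## What it computes

For every trial the package derives four measures:

| measure | definition |
|---|---|
| accuracy | 1 − Levenshtein distance / max sequence length |
| compression ratio | DEFLATE-compressed / raw bytes of a participant-generation's reproductions (smaller = more structured) |
| hierarchy depth | longest chain of nested Sequitur grammar rules in a sequence |
| diversity | within-chain / (within + across-chain) mean similarity; > 0.5 means chains have diverged |

Each measure y is then modeled as
`y ~ Beta(mu, phi)`, `logit(mu) = b0 + b1·condition + b2·generation
(+ b3·condition·generation) + u_chain + v_stimulus`
with crossed random intercepts — **Model 1** without, **Model 2** with the
interaction — sampled by Hamiltonian Monte Carlo, summarized with 89%
credible intervals, and compared by WAIC (ΔWAIC ± dSE from the pointwise
differences).  Posterior-predictive histograms per condition × generation
round out the report.  The Sequitur grammar inducer, the agent-based chain
simulator, and the HMC sampler are all part of the package and covered by
oracle tests (exhaustive edit-distance recursion, structural grammar
invariants, hand-computed WAIC, parameter recovery on a known generative
model).

## Worked example

Simulate 5 chains per condition for 10 generations, fit both models per
measure with a reduced sampler, and write all report files:

```bash
iterlearn run scratch/demo --transmission-chains 5 --individual-chains 5 \
    --generations 10 --chains 2 --warmup 400 --draws 400 --seed 1
```

which prints (about eight minutes on one CPU):

```
accuracy: WAIC model1=-6326.84 model2=-6322.41 dWAIC=-4.42 (dSE=2.31)
compression_ratio: WAIC model1=-25499.21 model2=-25893.93 dWAIC=394.73 (dSE=33.69)
depth: WAIC model1=-2430.15 model2=-2444.36 dWAIC=14.21 (dSE=12.09)
diversity: WAIC model1=-25312.54 model2=-25448.39 dWAIC=135.85 (dSE=21.87)
reports in scratch/demo
```

Positive ΔWAIC favors Model 2: on this run the interaction earns its keep
for compression ratio, depth and diversity (the condition arms structurify
at different rates) but not for accuracy.  `model2_accuracy.csv` holds the
posterior table; here the generation effect is β = 0.170 with 89% interval
[0.158, 0.182] — accuracy reliably rises across generations:

```
parameter,beta,Std,Lower 0.89,Upper 0.89,n_eff,Rhat
Intercept,0.075,0.160,-0.198,0.318,43.9,1.020
Condition,0.148,0.219,-0.171,0.496,36.6,1.037
Generation,0.170,0.007,0.158,0.182,302.0,1.019
Interaction,0.009,0.013,-0.010,0.029,318.0,1.012
```

`generation_means_depth.csv` shows the hierarchy deepening, more under
transmission (condition 0: mean depth 1.11 → 1.59 across generations, with
chain-level bootstrap CIs) than under the individual control (1.11 → 1.31).

The same stages are available programmatically:

```python
from iterlearn import simulate_experiment, measure_table
from iterlearn.pipeline import PipelineConfig, run_pipeline

ds = simulate_experiment(n_transmission_chains=5, n_individual_chains=5, seed=1)
measures = measure_table(ds)   # per-trial accuracy, ratio, depth, diversity
bundle = run_pipeline(PipelineConfig(seed=1, output_dir="out"))
```

Everything derives from the master seed: rerunning a config reproduces the
measures CSV byte-for-byte and the model summaries exactly.  See
`docs/methods.md` for the model details, the agent design, and the pinned
calibration of the generator.

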