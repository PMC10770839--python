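# Methods

`iterlearn` analyses memorize-and-reproduce transmission chains: sequences of
twelve colored flashes (alphabet `r g b y`) are learned and reproduced by a
participant, the reproductions become the next participant's stimuli, and the
question is what ten generations of this cultural transmission do to the
sequences — how accurately they are reproduced, how compressible they become,
how much grammatical hierarchy they acquire, and how far independent chains
diverge from one another.  The package provides the four measures, an
agent-based generator of synthetic chains under the two study designs, and the
multilevel Bayesian beta-regression machinery used to quantify condition and
generation effects.

## Study designs

Two condition arms share one trial-table schema:

* **Transmission** (condition code 0): ten generations, a *fresh* participant
  per generation, 60 trials per generation.  Generation 1 receives 60
  uniform-random seed sequences; generation g > 1 receives generation g−1's
  reproductions.
* **Individual** (condition code 1): the *same* participant works through ten
  generations of 30 trials (300 trials), each generation re-presenting that
  participant's own previous reproductions.  The 30 seeds are a random subset
  of the 60 transmission seeds.

Presentation order is either `fixed` (one global order shared by all chains
and generations) or `randomized` (a fresh permutation per participant-
generation).  The lineage invariant — presented-at-g equals reproduced-at-g−1
per stimulus lineage — is enforced by `validate_dataset` and holds for every
generator output.

## The four measures

* **Accuracy** = 1 − Levenshtein distance / max(len presented, len
  reproduced).  Unit-cost edit distance via `edlib`; an exhaustive recursive
  oracle backs it in the tests.
* **Compression ratio** = compressed / uncompressed bytes under DEFLATE at
  level 9 (pinned for bit-exact reproducibility).  The default unit is one
  participant-generation's reproductions serialized one per line with a
  trailing LF (`per_generation_concat`), attributed to each member trial row;
  a `per_sequence_raw_stream` mode (single sequence, raw DEFLATE stream, no
  container bytes) exists for sensitivity analysis.  The two units differ in
  level: for 60-line files of 4-symbol strings the concatenated ratio sits
  near 0.40 for random input and falls toward 0.30 as structure emerges,
  while the per-sequence raw ratio spans roughly 0.55–1.0; only relative
  change across generations and conditions is interpretable, and both modes
  order structured below random input.
* **Hierarchy depth** is the longest chain of nested rule references in the
  Sequitur grammar of a sequence.  Our Sequitur enforces digram uniqueness
  and rule utility with a work-list repair scheduler (most recently created
  digram first, then utility inlining); this closes a corner case of the
  classic linked-list formulation in which a digram suppressed as
  self-overlapping (`bbb`) can end up duplicated after its left neighbour is
  rewritten.  Consequences of rule utility worth noting: a rule referenced
  once is always inlined, so e.g. `rgbrgbrgbrgb` yields start `CC`,
  `C → BB`, `B → rgb` (depth 2), and rule bodies of length ≥ 2 bound depth by
  floor(log2 L) = 3 at L = 12.  Both constraints are verified structurally on
  every grammar the tests induce, alongside losslessness.
* **Diversity** of a participant-generation = within / (within + across),
  where *within* is the mean pairwise similarity (the accuracy measure)
  among its reproduced sequences and *across* is the mean similarity to the
  reproductions of all other chains of the same condition and generation.
  Values above 0.5 mean a chain resembles itself more than its
  contemporaries.  Within uses unordered pairs without self-pairs; across
  ignores trial alignment.  The statistic is computed once per
  participant-generation and replicated across its trial rows (a
  deduplicated similarity matrix makes this cheap once late generations
  converge on few distinct sequences).

## Regression models

For each measure, **Model 1** regresses the response on condition and
generation (1..10, uncentered by default; a centering flag is recorded in the
output when used) and **Model 2** adds their interaction.  The likelihood is
beta in the mean–precision parameterization with a logit link on the mean;
crossed random intercepts cover the chain (participant lineage, nested in
condition) and the seed-lineage stimulus id (shared across chains and
conditions).  Boundary handling: accuracy/diversity/compression are squeezed
into the open interval by (y·(n−1)+0.5)/n; depth — an integer 0..3 at L=12 —
is divided by 3 first (the shifted-binomial and ordinal alternatives are out
of scope; the transformation is recorded in the fit metadata).  Compression
ratios above 1, possible only in the raw per-sequence mode, are clipped to 1
with a warning before the squeeze.

Priors are weakly informative and configurable: Normal(0, 1.5) on intercept
and slopes (logit scale), Exponential(1) on the random-effect SDs,
Exponential(0.1) on the precision φ.  Posteriors are sampled by Hamiltonian
Monte Carlo with analytic gradients: non-centered random effects,
dual-averaging step-size adaptation toward 0.8 acceptance, two diagonal
mass-matrix re-estimation windows, jittered leapfrog trajectory lengths
(uniform 1..24), and hard support bounds on the log-scale parameters to
reject overflow regions.  Defaults are 4 chains of 1,000 warmup + 1,000 kept
draws; the tests and the worked examples use 2 chains and a few hundred
draws, which is where the reduced-scale parameter-recovery checks are run.
R-hat and effective sample size come from `arviz`; a warning fires above
R-hat 1.01 and one retry with doubled warmup is attempted above 1.1 (an
error carrying the diagnostics is optional via `require_convergence`).

Intervals are central 89% percentile intervals (5.5th–94.5th).  WAIC is
computed from the pointwise log-likelihood on the deviance scale, lppd via
log-sum-exp and p_waic as the ddof=1 sample variance (the R convention;
`arviz` uses ddof=0, a 1/draws-order difference the tests account for
explicitly).  Model comparison reports ΔWAIC with the standard error of the
pointwise difference vector, sqrt(N·var).  Posterior predictive samples at a
(condition, generation) cell integrate the random effects by drawing *new*
group offsets from the fitted SDs — predictions for an unseen chain and
stimulus — then sampling the beta likelihood; histograms use 0.05-wide bins.

## The synthetic-chain generator

No mechanistic participant model exists to copy, so the generator is this
package's own minimal design, built to produce the statistical structure the
analysis assumes rather than to match any quantitative observation.  An
agent holds a chunk inventory (up to 8 substrings of length 2–4) and noisy
unit recall.  Exposure accumulates substring counts; substrings recurring at
least twice are admitted with probability `extraction_rate`, ranked by
chance-corrected weight count·4^(len−2) so that recurring 3–4-mers outrank
the sixteen ubiquitous digrams.  A stimulus is parsed greedily into longest
known chunks (residual symbols as singletons); each unit is reproduced
verbatim with probability min(p_unit + κ·[unit is a known chunk], 0.99).  A
failed unit is filled in from the inventory (weight-proportional) with
probability `intrusion_rate`, otherwise replaced by uniform random symbols of
the unit's length, and the output is trimmed or padded to exactly 12 symbols
as the task forces 12 taps.

The intrusion component deserves emphasis.  With purely uniform substitution
errors the system does not ratchet: selective retention of chunky material
is cancelled by unbiased churn, and calibration sweeps left compression and
depth flat across ten generations.  Pattern-completion intrusions are the
standard structure-amplifying production bias in models of iterated learning
and serial recall — forgotten material is reconstructed from learned
patterns — and with them the chunk structure compounds across generations.

The *sole* structural difference between conditions is agent persistence:
transmission chains sample a fresh agent (empty inventory) per generation,
the individual condition keeps one agent and its growing inventory for all
300 trials.  That one difference yields the observed dissociation: the
individual's familiarity with its own material gives it higher accuracy and
hence fewer errors, so its sequences structurify more slowly, while fresh
transmission agents err often and filter the material toward what any
newcomer finds memorable.

Population hyperpriors (Beta for p_unit and rates, truncated Normal for κ)
have pinned defaults — p_unit mean 0.5, κ mean 0.35, extraction mean 0.5,
intrusion mean 0.5 — chosen by a calibration sweep at the study design so
that the four directional phenomena hold by majority over seeds: accuracy
rises generation 1→10 in both conditions, compression ratio falls (more
steeply under transmission), depth rises (more under transmission), and
generation-10 diversity exceeds 0.5 in both conditions.  Switching chunk
learning off (extraction ≈ 0, κ = 0) abolishes the compression trend — the
null control.  What passing these checks shows is that the analysis pipeline
detects the qualitative phenomena when they are present; it says nothing
about quantitative agreement with human data, serial-position effects,
fatigue, or any other cognitive detail the agents do not have.

`generate_betareg_oracle` bypasses the agents entirely and samples from the
regression likelihood with known coefficients; it is the ground truth for
the parameter-recovery and WAIC-comparison tests.

## Numerical and reproducibility choices

All randomness flows from explicit `numpy` Generators; the pipeline derives
every stage's stream from one master seed via `SeedSequence`, so a config +
seed reproduces the measures CSV byte-for-byte and the model summaries
exactly.  Deterministic tie-breaks: inventory eviction orders by (weight,
chunk length, chunk); Sequitur rule ids follow creation order and are
renumbered compactly on extraction.  Degenerate inputs raise informative
errors (two empty strings for accuracy, empty texts for compression, a
single chain for diversity or for random-intercept fitting); extrapolating a
posterior prediction outside the fitted generation range warns but proceeds.

Reduced problem sizes used by the shipped checks — 5 chains per condition
for the directional properties, 6 chains × 8 stimuli × 6 generations for
parameter recovery, 2-chain samplers with a few hundred draws — are the
package's chosen trade-off between Monte-Carlo error and quick, repeatable
verification; all are overridable.

## Known limitations

* The agent model is intentionally minimal: no serial-position curve, no
  fatigue or break effects, no child/adult bias populations; quantitative
  matches to human generation curves are out of reach by design.
* Beta regression on scaled depth treats an integer response as continuous;
  ordinal alternatives are not implemented.
* The compression unit is a design choice (see above); published ratios from
  other pipelines are only comparable in direction, not level.
* Fixed-length HMC trajectories mix more slowly than NUTS on stiff
  posteriors; tiny-draw configurations can warn on R-hat, and the remedy is
  more warmup/draws rather than looser thresholds.
* The loader for externally deposited trial data maps recognizable CSV
  column names and refuses ambiguity; it has no effect on any shipped
  result.
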