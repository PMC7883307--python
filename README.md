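# seqdisc

Analyses for head-fixed GO/NOGO **tactile sequence discrimination**
experiments, in which a mouse learns to lick for reward after a target
vibration sequence delivered to the whiskers and to withhold licking after a
non-target sequence that differs only in the order of its central segments.
The package implements the behavioral and neural-population statistics such a
study needs, end to end, and ships a synthetic session/neuron generator so
every stage is testable with known ground truth:

* **Behavior** — outcome parsing (HIT/MISS/FA/CR), proportion-corrected
  percent correct over a 50-trial sliding window (balanced accuracy,
  `100 × ½(hit rate + CR rate)`), d′ = z(HR) − z(FAR), lick PSTHs at 100 ms
  resolution, and the **discriminative lick latency (DLL)**: the first bin at
  which HIT lick rates exceed FA lick rates beyond a resampled 95% confidence
  limit for the whole-trial excursion of the difference curve — an upper
  bound on the session's mean decision time.  Plus a within/between-mouse
  sum-of-squares partition of DLL variance.
* **Neural** — neuropil correction (`F = F_raw − αF_neuropil`),
  sliding-baseline ΔF/F₀ (5th percentile for skewed cells, median for
  symmetric ones), outcome- and first-lick-aligned 41-frame mean traces at
  10.8 Hz, 3-SD response latencies, the 246-sample response vector
  `[HIT, MISS, FA, CR, HIT-lick, FA-lick]`, and a rule-based emulation of the
  functional class taxonomy (sensory cue / feature / category, action,
  licking, reward, error).
* **PAIRS** — the projection angle index of response similarity: response
  vectors projected onto a common 8-component PCA basis, unit-normalised, the
  median over neurons of the mean angle to the k = 3 nearest neighbours,
  tested one-sided against marginal-preserving surrogate populations
  (p = (1 + #{surrogate ≤ observed})/(1 + n_surrogates)), with a per-session
  mode for sessions with more than 25 neurons.
* **Decoding** — per-neuron linear SVMs on single-trial ΔF/F₀ time courses
  for GO-vs-NOGO and lick-vs-no-lick labels, with 75%/25% majority-class
  balancing and a >100-trial rule, stratified 5-fold cross-validation over
  C ∈ {0.001, 0.01, 0.1, 1}, label-shuffle surrogates ("better than 95 of
  100" significance), population summaries with χ² trend tests, and Fisher's
  exact test with the sample odds ratio `ad/bc`.

See `docs/methods.md` for the models, assumptions, numerical choices, and
what the synthetic validation does and does not establish.

## Worked example

Simulate a well-trained session (400 trials, ground-truth discriminative
latency 300 ms) and compute its behavioral summary:

```python
from seqdisc.config import AnalysisConfig, seeded_rng
from seqdisc import synth, behavior

cfg = AnalysisConfig(seed=42)
rng = seeded_rng(cfg, "demo")
session, _ = synth.simulate_behavior_session(
    synth.BehaviorSimConfig(n_trials=400, true_dll=0.3), rng
)
print(behavior.session_summary(session, cfg, seeded_rng(cfg, "demo-dll")))
```

```
mouse_id: sim
session_index: 1
percent_correct_best: 92.59   # best 50-trial window, balanced accuracy (%)
dprime: 2.41                  # z(hit rate) - z(false-alarm rate)
dll: 0.300                    # estimated discriminative lick latency (s)
median_first_lick: 0.389      # median first-lick latency on HIT/FA trials (s)
n_trials: 400
```

The estimated DLL recovers the generator's 300 ms ground truth exactly (it is
quantised to the 100 ms analysis bins).  The classification worked example
recomputes the exact test on the published counts of visually classified
neurons (179 of 315 classified in well-trained mice, 72 of 356 in naive
mice):

```python
from seqdisc import benchmarks
print(benchmarks.classification_worked_example())
```

```
{'odds_ratio': 5.1916, 'fisher_p': < 1e-22,
 'pct_classified_well_trained': 56.83, 'pct_classified_naive': 20.22,
 'n_total': 671}
```

i.e. 57% vs 20% classified, odds ratio 5.19.

## Command line

A thin CLI wraps the library:

```bash
seqdisc simulate --seed 1 --out data/           # trials.csv licks.csv fluo.h5 truth.csv
seqdisc behavior --seed 1 --in data/ --out behavior.csv
seqdisc neural   --seed 1 --in data/ --out classes.csv
seqdisc pairs    --seed 1 --in data/ --out pairs.json --surrogates 10000
seqdisc decode   --seed 1 --in data/ --out decoding.csv --task both
```

File conventions: CSV trial/lick tables (UTF-8, header row) and an HDF5
container with `/F_raw`, `/F_neuropil`, `/dff`, `/frame_times`,
`/neuron_ids`.

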