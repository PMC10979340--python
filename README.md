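# socratiq

Adaptive Socratic questioning for automated cognitive behavioral therapy
(CBT), with a classifier-in-the-loop stopping rule and a full simulated
evaluation pipeline.

## The problem

In the cognitive-restructuring exercise of CBT, a client describes a
troubling situation, reports their mood, states the negative *automatic
thought* behind it, and then answers Socratic questions ("What evidence
supports this thought?") until the thought has been re-examined and a
*balanced thought* can be formed. Automated agents that deliver this
exercise must decide **how many** correction questions to ask: too few
and the thought is not restructured, too many and the client is
needlessly fatigued.

This package implements an **adaptive** controller: after every answer a
distress detector classifies the client's recent utterances, and
questioning stops at the first *nondistressed* detection (or after the
21st question, the size of the question pool). A **random** control
controller draws the question count once, uniformly from 1–21. The
detector runs passively in both arms, so every session also yields the
count the detector *would* have chosen — the basis of a same/fewer/more
subgroup analysis.

The components:

- `socratiq.scales` — K6, STAI-S/T, CCI, PHQ-8 and 0–100 mood scoring,
  with the three session change metrics (K6 difference, relative mood
  change, STAI-S difference).
- `socratiq.model` — a hierarchical recurrent classifier (word
  embeddings → bidirectional LSTM turn encoder → document LSTM →
  task heads) trained multitask (emotion / dialogue act / topic /
  depression), then transferred to in-session distress detection by
  replacing the final fully connected layer. Built on a small numpy
  reverse-mode autodiff; no deep-learning framework required.
- `socratiq.engine` — the session state machine (situation → mood →
  gated thought elicitation → correction loop → balanced thought →
  post mood) with both controllers.
- `socratiq.synth` — synthetic token-stream corpora with controlled
  label structure, and simulated participants whose latent distress
  decays with each correction question.
- `socratiq.stats` — exact/asymptotic Mann-Whitney U and Wilcoxon
  signed-rank tests, Cliff's delta, Welch t / Cohen's d, subgroup and
  per-question-count summaries.
- `socratiq.cli` / `socratiq.io` — a reproducible artifact pipeline
  (`socratiq generate-data | pretrain | transfer | simulate-session |
  run-experiment | analyze | report`) with config-hash-stamped outputs.

Real clinical corpora are not redistributable, so all data here is
synthetic; see `docs/methods.md` for the generative model and its
assumptions.

## Worked example

One adapted-arm session with a simulated distressed participant and the
latent-state oracle detector, followed by a small two-arm trial:

```python
import numpy as np
from socratiq.engine import EngineConfig, run_session
from socratiq.stats import Alternative, mann_whitney_u
from socratiq.synth import (GeneratorParams, OracleDetector, SimulatedUser,
                            run_experiment, sample_profile)

params = GeneratorParams(seed=42)
rng = np.random.default_rng(42)
user = SimulatedUser(sample_profile(rng, params, distressed=True),
                     seed=42, params=params)
transcript = run_session(user, "adapted", OracleDetector(user),
                         config=EngineConfig(seed=42))
out = transcript.outcome
print(f"delivered questions : {out.delivered_questions}")
print(f"estimated questions : {out.estimated_questions}")
print(f"K6   pre -> post    : {out.k6_pre.total} -> {out.k6_post.total}")
print(f"mood pre -> post    : {out.mood_pre.value} -> {out.mood_post.value}")
print(f"detections          : {[d['label'] for d in out.detections]}")

table = run_experiment(50, OracleDetector, params, seed=42)
a = table[table.arm == "adapted"]; r = table[table.arm == "random"]
ch_a = (a.k6_pre - a.k6_post).to_numpy(float)
ch_r = (r.k6_pre - r.k6_post).to_numpy(float)
res = mann_whitney_u(ch_a, ch_r, Alternative.GREATER)
print(f"mean change in distress: adapted {ch_a.mean():.2f}, "
      f"random {ch_r.mean():.2f}")
print(f"one-sided Mann-Whitney p = {res.p_value:.3g}, "
      f"Cliff delta = {res.effect_size:.2f}")
```

Output:

```text
delivered questions : 5
estimated questions : 5
K6   pre -> post    : 11 -> 5
mood pre -> post    : 46 -> 21
detections          : ['distressed', 'distressed', 'distressed', 'distressed', 'nondistressed']
mean change in distress: adapted 3.10, random 1.06
one-sided Mann-Whitney p = 0.000907, Cliff delta = 0.36
```

The session stopped at the first nondistressed detection (question 5),
and across 50 participants per arm the adapted controller produced a
larger distress reduction than the random one.

The same pipeline from the command line, with a trained detector instead
of the oracle:

```bash
socratiq generate-data --seed 5 --out data
socratiq pretrain --seed 5 --data data --out ckpt_pre
socratiq transfer --seed 5 --pretrained ckpt_pre --data data --out ckpt_tr
socratiq run-experiment --seed 5 --model ckpt_tr --out table.csv
socratiq analyze --table table.csv --out results
socratiq report --results results
```

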