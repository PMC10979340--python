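# Methods

This note records the modeling choices in `socratiq`, the parameters and
their defaults, and the limits of the synthetic evaluation.

## Scales and change metrics

- **K6** (6 items, 0–4, total 0–24): total ≥ 5 is classified distressed.
- **STAI-S / STAI-T** (20 items each, 1–4, totals 20–80): totals are
  plain sums. The published STAI reverse-scores some items; here items
  are generated and summed directly on the 1–4 scale, so no reverse
  scoring is applied anywhere. This is consistent as long as scoring and
  generation agree, and it keeps totals order-invariant sums.
- **CCI** (5 items, 0–6, total 0–30) and **PHQ-8** (8 items, 0–3,
  cutoff ≥ 10) follow the same plain-sum convention.
- Change metrics: `change_in_distress = K6_pre − K6_post`,
  `change_in_stai_s = STAI-S_pre − STAI-S_post`, and
  `mood_change = (mood_pre − mood_post) / mood_pre`. The first two are
  linear, so they apply equally to individual scores and to condition
  means. The relative mood metric is **not** linear — the metric of the
  means is not the mean of the metrics — and it is undefined at
  `mood_pre = 0`; the package raises `UndefinedMetricError` rather than
  returning a silent 0.

## Session engine

A session follows a fixed phase order: situation → mood (with a 0–100
intensity score) → automatic thought → correction loop → balanced
thought → post mood. The thought-elicitation step is guarded by a
rule-based thought/other gate (marker-token lexicon, replaceable by any
classifier with the same signature) with at most `gate_retry_limit`
(default 2) re-asks before an explicit override event.

The question pool holds exactly 21 Socratic templates, consumed without
repetition (optionally in seeded shuffled order). Controllers:

- **adapted** — after each answer the detector is consulted; STOP at the
  first nondistressed detection or when all 21 questions are spent.
- **random** — one uniform draw from {1..21} at session start.

The detector runs after every answer in both arms, so the
model-estimated question count (first nondistressed index; 21 if all 21
were answered distressed; *censored* if the session ended while still
distressed) is available everywhere. Censored estimates are classified
into the `fewer` subgroup, because the detector would have required at
least one more question.

Detection ties at p = 0.5 resolve to *distressed*: when the evidence is
balanced the safer action is to keep asking rather than stop early.

## Classifier

Hierarchical recurrent network: word embeddings → bidirectional LSTM
turn encoder (final forward/backward states concatenated) → stacked
document LSTM over turn vectors → linear task heads. Per-dialogue heads
(binary depression/distress, topic) read the final document state;
per-turn heads (7 emotions, 4 dialogue acts) read the per-turn document
states. Training: weighted multitask cross-entropy, batch size 1, Adam
at 1e-3, dropout 0.1, early stopping on validation macro F1 of the
depression task with the best snapshot restored.

Transfer to in-session distress detection replaces the final fully
connected (distress) layer with a fresh initialisation, drops the
auxiliary heads, and fine-tunes the encoder (freezable via
`freeze_encoder`). Transfer training and inference are restricted to the
three canonical user utterance types (situation, mood, automatic
thought); inference uses at most 3 recent utterances, selected by the
`canonical_types` window policy (most recent utterance of each type,
falling back to the last user turns).

The network runs on a small numpy reverse-mode autodiff written for this
package (no GPU framework dependency); its gradients are verified
against central differences in the test suite.

`ModelConfig` defaults keep the reference regime (widths 128, up to 100
epochs). The pipeline and tests use a reduced *desk-scale* configuration
(widths 32, 8 epochs, patience 2) because the synthetic corpora are
separable by narrow models; this is a wall-clock choice, not a tuned
hyperparameter — the reference widths give the same test metrics,
slower.

## Synthetic data

No real corpora ship with the package. Utterances are token streams:
label-consistent cue tokens appear per slot with probability
`cue_strength` (default 0.9), the rest are uniform background tokens.
Cue lexicons per label family (distress/calm, 7 emotions, 4 acts, 10
topics, utterance-type markers) are disjoint by construction, so a
bag-of-words model can in principle recover each label at high cue
strength and nothing at `cue_strength = 0` — both ends are asserted in
the tests with an independent scikit-learn logistic-regression oracle.

The CBT corpus enforces its distressed fraction by exact count (default
63 of 94) rather than Bernoulli sampling, and cue density is 1/0 by
label, making the lexical signal a deterministic function of the label.
Consequences worth noting honestly: at the default cue strength the
transferred classifier reaches macro F1 = 1.0 on held-out dialogues, and
pretraining alone (whose depression labels use the same distress-cue
lexicon) already transfers perfectly, so the required `transfer ≥
pretrain-only` ordering holds but is saturated rather than strict. The
generator is a test harness for the machinery, not a model of language.

Nondistressed participants' K6 totals are sampled from {1..4}, not
{0..4}: someone bringing a problem to a session reports at least minimal
negative mood, and the relative mood-change metric is undefined at a
pre-session mood of exactly 0.

## Simulated participants

A participant's latent distress starts at `d0 = K6/24` (monotone map of
the screener onto [0,1]; the distress cutoff 5/24 ≈ 0.208). Answering a
correction question while the automatic thought is still uncorrected
applies `d ← d·(1 − rho) + eps`, `eps ~ N(0, noise_sd)` — cognitive
restructuring works multiplicatively on the distress that remains. The
thought counts as *corrected* the first time `d` drops below the cutoff;
from then on further challenge of an already-balanced thought no longer
helps and instead yields a mild fatigue rebound `d ← d + gamma + eps`.
The correction is an absorbing state: decay does not re-engage if
fatigue pushes `d` back over the cutoff.

Defaults: `decay_rho = 0.15`, `rebound_gamma = 0.01`,
`noise_sd = 0.02`. These were fixed analytically *before* measuring
outcomes, chosen so the model reproduces the qualitative structure of
the target phenomenon: (a) a distressed participant needs a plausible
handful of questions to cross the cutoff (for example from d0 = 0.5,
about six questions at rho = 0.15); (b) over-questioning is mildly,
not catastrophically, harmful (gamma one order of magnitude below the
per-question decay), which yields the same > more > fewer subgroup
ordering and a slightly negative average mood change in the random arm;
(c) noise is small relative to both effects. The saturating form itself
(rather than unconditional decay) is what makes the adapted arm superior
in expectation: with unconditional decay, a uniform random count (mean
11) would out-correct an adaptive stop at the cutoff, inverting the
intended direction. The design analysis is recorded in the project
decision ledger.

Mood is reported as `round(100·d)`; the post-session K6 total is the pre
total scaled by `d/d0`; CCI grows linearly with the relative distress
reduction. The **oracle detector** reads the `corrected` flag directly
(nondistressed from the first crossing on), isolating controller
behaviour from classifier error.

Two-arm experiments pair participants across arms: each adapted/random
pair shares one sampled profile and differs only in session noise and
controller, enforcing baseline balance.

## Statistics

Between-condition comparisons use the Mann-Whitney U test (exact by full
enumeration when n·m ≤ 400 and tie-free, otherwise normal approximation
with midrank tie and continuity corrections), with Cliff's delta as
effect size. Within-condition pre/post comparisons use the Wilcoxon
signed-rank test (zeros dropped; exact for effective n ≤ 15 tie-free),
with r = sign(median diff)·|Z|/√n. Change-metric comparisons are
one-sided (adapted > random) per the directional hypothesis; a Holm
step-down correction is available but not applied by default, matching
the unadjusted reporting convention. Baseline-balance checks use a
two-sided Welch t test with pooled-SD Cohen's d. Exact p-values are
validated in the tests against independent brute-force enumeration of
the permutation/sign null distributions.

Subgroups pool both arms and compare delivered vs. model-estimated
counts (same / fewer / more, censored → fewer). Per-question-count
summaries report means as "not available" (NaN) for counts with no
participants and SDs as NaN for counts with fewer than two.

## Reproducibility

Every generator, trainer and experiment is a pure function of
(parameters, seed); seeds are combined via `numpy.random.SeedSequence`
with fixed stream tags so corpora, training shuffles, session noise and
the random-arm draw are independent streams. Pipeline artifacts carry a
`# config_hash` header (SHA-256 of the effective config) and the
`report` command refuses to collate artifacts with mismatched hashes.
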