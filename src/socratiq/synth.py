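"""Synthetic corpora and simulated participants.

Real corpora for this problem (clinical interviews with depression
labels, everyday dialogues with emotion/act/topic annotations, and
cognitive-restructuring transcripts paired with K6 totals) are not
redistributable, so every input the classifier, dialogue engine and
statistics need is generated here with controlled statistical structure:

* Token streams, not natural language. Each utterance is a sequence of
  synthetic tokens; label-consistent *cue* tokens appear at a rate
  ``cue_strength`` per slot and uniform background tokens fill the rest.
  Cue lexicons per label family are disjoint, so a bag-of-words model
  can in principle recover every label when ``cue_strength`` is high and
  nothing when it is 0.
* A cognitive-restructuring corpus of participants whose K6 totals are
  sampled so that an exact fraction (default 63/94) crosses the
  distressed cutoff (total >= 5), with situation / mood / automatic
  thought utterances whose distress-cue density reflects the label.
* Simulated session participants whose latent distress ``d`` starts at
  ``K6/24`` and decays by a factor ``(1 - rho)`` plus Gaussian noise
  after every thought-correction question — the causal premise that
  Socratic questioning reduces distress, with ``rho`` as the free effect
  size.

All generators are pure functions of (params, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .dialogue import (
    N_ACTS,
    N_EMOTIONS,
    N_TOPICS,
    LabeledDialogue,
    Speaker,
    Utterance,
    UtteranceType,
)
from .scales import K6_DISTRESS_CUTOFF

DISTRESS_PREVALENCE_DEFAULT = 63 / 94

# -- cue lexicons (disjoint by construction: distinct prefixes) -------------

DISTRESS_CUES = tuple(f"dcue{i:02d}" for i in range(8))
CALM_CUES = tuple(f"ccue{i:02d}" for i in range(8))
EMOTION_CUES = tuple(
    tuple(f"ecue{k}_{i}" for i in range(4)) for k in range(N_EMOTIONS)
)
ACT_CUES = tuple(tuple(f"acue{k}_{i}" for i in range(3)) for k in range(N_ACTS))
TOPIC_CUES = tuple(tuple(f"tcue{k}_{i}" for i in range(3)) for k in range(N_TOPICS))
THOUGHT_MARKERS = tuple(f"think{i}" for i in range(5))
MOOD_MARKERS = tuple(f"feel{i}" for i in range(5))
SITUATION_MARKERS = tuple(f"situ{i}" for i in range(5))

_ALL_CUES = (
    set(DISTRESS_CUES)
    | set(CALM_CUES)
    | {t for grp in EMOTION_CUES for t in grp}
    | {t for grp in ACT_CUES for t in grp}
    | {t for grp in TOPIC_CUES for t in grp}
    | set(THOUGHT_MARKERS)
    | set(MOOD_MARKERS)
    | set(SITUATION_MARKERS)
)


@dataclass(frozen=True)
class GeneratorParams:
    """Knobs of the synthetic world; defaults are the study conditions."""

    vocab_size: int = 150  # background tokens
    cue_strength: float = 0.9  # probability a slot carries a label cue
    utterance_len_mean: float = 8.0  # Poisson mean, minimum 1 token
    distress_prevalence: float = DISTRESS_PREVALENCE_DEFAULT
    depression_prevalence: float = 0.3  # interview-style corpus
    n_dialogues: int = 200
    n_participants: int = 94
    decay_rho: float = 0.15  # per-question latent distress decay
    rebound_gamma: float = 0.01  # per-question fatigue once nondistressed
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.cue_strength <= 1.0:
            raise ValueError("cue_strength must be in [0,1]")
        if not 0.0 < self.distress_prevalence < 1.0:
            raise ValueError("distress_prevalence must be in (0,1)")
        if self.vocab_size < len(_ALL_CUES):
            raise ValueError(
                f"vocab_size {self.vocab_size} smaller than the union of cue "
                f"lexicons ({len(_ALL_CUES)})"
            )

    @property
    def background_tokens(self) -> tuple[str, ...]:
        return tuple(f"w{i:03d}" for i in range(self.vocab_size))


def _utterance_tokens(
    rng: np.random.Generator,
    params: GeneratorParams,
    cue_choices: Sequence[str],
    markers: Sequence[str] = (),
    n_tokens: Optional[int] = None,
) -> str:
    """One utterance: optional forced markers + cue/background slots."""
    if n_tokens is None:
        n_tokens = max(1, int(rng.poisson(params.utterance_len_mean)))
    bg = params.background_tokens
    toks = list(markers)
    for _ in range(n_tokens):
        if cue_choices and rng.random() < params.cue_strength:
            toks.append(cue_choices[rng.integers(len(cue_choices))])
        else:
            toks.append(bg[rng.integers(len(bg))])
    return " ".join(toks)


def _distress_cue_pool(d: float, rng: np.random.Generator, k: int = 6) -> list[str]:
    """Cue tokens for one utterance: distress cues with probability d per
    cue slot, calm cues otherwise (drawn per slot by the caller)."""
    return [
        (DISTRESS_CUES if rng.random() < d else CALM_CUES)[rng.integers(8)]
        for _ in range(k)
    ]


# ---------------------------------------------------------------------------
# pretraining corpora
# ---------------------------------------------------------------------------


def generate_pretraining_corpora(
    params: GeneratorParams,
) -> tuple[list[LabeledDialogue], list[LabeledDialogue]]:
    """Everyday-conversation-style and interview-style corpora.

    The first carries per-turn emotion (7 classes) and act (4 classes)
    labels and a per-dialogue topic (10 classes); the second carries a
    per-dialogue binary depression label with an exact-count prevalence.
    """
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 101]))
    daily: list[LabeledDialogue] = []
    for i in range(params.n_dialogues):
        topic = int(rng.integers(N_TOPICS))
        n_turns = int(rng.integers(2, 7))
        turns = []
        for j in range(n_turns):
            emotion = int(rng.integers(N_EMOTIONS))
            act = int(rng.integers(N_ACTS))
            cues = list(EMOTION_CUES[emotion]) + list(ACT_CUES[act]) + list(TOPIC_CUES[topic])
            turns.append(
                Utterance(
                    speaker=Speaker.USER if j % 2 else Speaker.AGENT,
                    text=_utterance_tokens(rng, params, cues),
                    emotion=emotion,
                    act=act,
                )
            )
        daily.append(LabeledDialogue(dialogue_id=f"daily{i:04d}", turns=tuple(turns), topic=topic))

    n_dep = int(round(params.depression_prevalence * params.n_dialogues))
    labels = np.array([1] * n_dep + [0] * (params.n_dialogues - n_dep))
    rng.shuffle(labels)
    interview: list[LabeledDialogue] = []
    for i, lab in enumerate(labels):
        d = 1.0 if lab else 0.0
        n_turns = int(rng.integers(3, 8))
        turns = []
        for j in range(n_turns):
            if j % 2 == 0:
                turns.append(Utterance(speaker=Speaker.AGENT,
                                       text=_utterance_tokens(rng, params, [])))
            else:
                turns.append(
                    Utterance(
                        speaker=Speaker.USER,
                        text=_utterance_tokens(rng, params, _distress_cue_pool(d, rng)),
                    )
                )
        interview.append(
            LabeledDialogue(dialogue_id=f"intv{i:04d}", turns=tuple(turns), distress=int(lab))
        )
    return daily, interview


# ---------------------------------------------------------------------------
# instrument item sampling
# ---------------------------------------------------------------------------


def _allocate_items(total: int, n_items: int, item_max: int, rng: np.random.Generator,
                    item_min: int = 0) -> tuple[int, ...]:
    """Distribute a target total over items one unit at a time (a
    hypergeometric-style kernel keeping item-level validity)."""
    base = total - n_items * item_min
    if not 0 <= base <= n_items * (item_max - item_min):
        raise ValueError(f"total {total} unreachable with {n_items} items")
    items = np.full(n_items, item_min)
    for _ in range(base):
        open_idx = np.flatnonzero(items < item_max)
        items[open_idx[rng.integers(open_idx.size)]] += 1
    return tuple(int(v) for v in items)


def sample_k6_items(distressed: bool, rng: np.random.Generator) -> tuple[int, ...]:
    """K6 items with total >= 5 (distressed) or in 1..4 (nondistressed).

    Nondistressed totals start at 1, not 0: a participant bringing a
    problem to a session reports at least some negative mood, and the
    relative mood-change metric is undefined at a pre-session mood of 0.
    """
    if distressed:
        total = K6_DISTRESS_CUTOFF + int(rng.binomial(19, 0.25))
    else:
        total = int(rng.integers(1, K6_DISTRESS_CUTOFF))
    return _allocate_items(total, 6, 4, rng)


def k6_items_for_total(total: int, rng: np.random.Generator) -> tuple[int, ...]:
    return _allocate_items(total, 6, 4, rng)


def sample_stai_items(d: float, rng: np.random.Generator) -> tuple[int, ...]:
    """20 STAI items in 1-4 with expectation increasing in latent distress."""
    p = float(np.clip(0.15 + 0.6 * d, 0.0, 1.0))
    return tuple(1 + int(v) for v in rng.binomial(3, p, size=20))


# ---------------------------------------------------------------------------
# cognitive-restructuring corpus
# ---------------------------------------------------------------------------

_CBT_PROMPTS = {
    UtteranceType.SITUATION: "prompt_situation please describe the situation",
    UtteranceType.MOOD: "prompt_mood how did you feel",
    UtteranceType.AUTOMATIC_THOUGHT: "prompt_thought what went through your mind",
}

_TYPE_MARKERS = {
    UtteranceType.SITUATION: SITUATION_MARKERS,
    UtteranceType.MOOD: MOOD_MARKERS,
    UtteranceType.AUTOMATIC_THOUGHT: THOUGHT_MARKERS,
}


def make_cbt_utterance(
    utype: UtteranceType,
    distress_level: float,
    rng: np.random.Generator,
    params: GeneratorParams,
) -> Utterance:
    """A user utterance of one canonical type: a type marker plus
    distress/calm cues at the label-dependent density."""
    marker = _TYPE_MARKERS[utype][rng.integers(len(_TYPE_MARKERS[utype]))]
    text = _utterance_tokens(
        rng, params, _distress_cue_pool(distress_level, rng), markers=[marker]
    )
    return Utterance(speaker=Speaker.USER, text=text, utterance_type=utype)


def generate_cbt_corpus(params: GeneratorParams) -> list[LabeledDialogue]:
    """One dialogue per participant with situation/mood/automatic-thought
    user utterances and a K6-derived binary distress label.

    The distressed fraction is enforced by exact count (stratified),
    not Bernoulli sampling; cue density is 1 for distressed and 0 for
    nondistressed participants so that the lexical signal is a
    deterministic function of the label at the per-slot rate
    ``cue_strength``.
    """
    if params.n_participants < 4:
        raise ValueError("need at least 4 participants to stratify")
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 202]))
    n_dist = int(round(params.distress_prevalence * params.n_participants))
    labels = np.array([1] * n_dist + [0] * (params.n_participants - n_dist))
    rng.shuffle(labels)
    dialogues: list[LabeledDialogue] = []
    for i, lab in enumerate(labels):
        items = sample_k6_items(bool(lab), rng)
        total = sum(items)
        assert (total >= K6_DISTRESS_CUTOFF) == bool(lab)
        density = 1.0 if lab else 0.0
        turns: list[Utterance] = []
        for utype in (
            UtteranceType.SITUATION,
            UtteranceType.MOOD,
            UtteranceType.AUTOMATIC_THOUGHT,
        ):
            turns.append(Utterance(speaker=Speaker.AGENT, text=_CBT_PROMPTS[utype]))
            turns.append(make_cbt_utterance(utype, density, rng, params))
        dialogues.append(
            LabeledDialogue(
                dialogue_id=f"cbt{i:04d}", turns=tuple(turns), distress=int(lab)
            )
        )
    return dialogues


# ---------------------------------------------------------------------------
# simulated session participants
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimulatedUserProfile:
    """Static characteristics of one simulated participant."""

    k6_items: tuple[int, ...]
    stai_s_items: tuple[int, ...]
    stai_t_items: tuple[int, ...]
    qids_pre: int
    decay_rho: float = 0.15
    rebound_gamma: float = 0.01
    noise_sd: float = 0.02

    def __post_init__(self) -> None:
        if not 0.0 <= self.decay_rho <= 1.0:
            raise ValueError("decay rho must be in [0,1]")
        if self.rebound_gamma < 0.0:
            raise ValueError("rebound gamma must be >= 0")

    @property
    def k6_total(self) -> int:
        return int(sum(self.k6_items))

    @property
    def d0(self) -> float:
        """Latent distress: the K6 total mapped monotonically to [0,1]."""
        return self.k6_total / 24.0


def sample_profile(rng: np.random.Generator, params: GeneratorParams,
                   distressed: Optional[bool] = None) -> SimulatedUserProfile:
    if distressed is None:
        distressed = bool(rng.random() < params.distress_prevalence)
    k6 = sample_k6_items(distressed, rng)
    d0 = sum(k6) / 24.0
    return SimulatedUserProfile(
        k6_items=k6,
        stai_s_items=sample_stai_items(d0, rng),
        stai_t_items=sample_stai_items(d0, rng),
        qids_pre=int(np.clip(round(27 * d0 * 0.8 + rng.normal(0, 1)), 0, 27)),
        decay_rho=params.decay_rho,
        rebound_gamma=params.rebound_gamma,
        noise_sd=params.noise_sd,
    )


#: latent-distress level corresponding to the K6 distressed cutoff
DISTRESS_THRESHOLD = K6_DISTRESS_CUTOFF / 24.0


class SimulatedUser:
    """A responder whose latent distress decays with each correction question.

    The latent state starts at ``d0 = K6/24``. While the participant is
    still distressed (``d >= 5/24`` and restructuring incomplete),
    answering a thought-correction question updates ``d <- d*(1 - rho) +
    eps`` with ``eps ~ N(0, noise_sd)``, clipped to [0,1]: cognitive
    restructuring works on the distress that remains. Once the state
    first drops below the threshold the automatic thought counts as
    corrected; continued challenge of an already-balanced thought no
    longer helps and instead produces a mild fatigue rebound, ``d <- d +
    gamma + eps``. Utterances carry distress/calm cues at density equal
    to the current latent state, and mood scores are reported as
    ``round(100*d)``.
    """

    def __init__(self, profile: SimulatedUserProfile, seed: int,
                 params: Optional[GeneratorParams] = None):
        self.profile = profile
        self.params = params or GeneratorParams()
        self.rng = np.random.default_rng(np.random.SeedSequence([seed, 303]))
        self.d = profile.d0
        self.questions_answered = 0
        # restructuring is complete once d first drops below the cutoff
        self.corrected = profile.d0 < DISTRESS_THRESHOLD

    # -- responder protocol --------------------------------------------------

    def utterance(self, utype: UtteranceType) -> Utterance:
        return make_cbt_utterance(utype, self.d, self.rng, self.params)

    def answer_correction_question(self, question_text: str) -> Utterance:
        """Reflecting on the question updates latent distress, then the
        answer (a revised automatic thought) is produced at the new level."""
        eps = self.rng.normal(0.0, self.profile.noise_sd) if self.profile.noise_sd else 0.0
        if not self.corrected:
            new_d = self.d * (1.0 - self.profile.decay_rho) + eps
        else:
            new_d = self.d + self.profile.rebound_gamma + eps
        self.d = float(np.clip(new_d, 0.0, 1.0))
        if self.d < DISTRESS_THRESHOLD:
            self.corrected = True
        self.questions_answered += 1
        return make_cbt_utterance(
            UtteranceType.AUTOMATIC_THOUGHT, self.d, self.rng, self.params
        )

    def mood_score(self) -> int:
        return int(round(100 * self.d))

    def balanced_thought(self) -> Utterance:
        return make_cbt_utterance(UtteranceType.AUTOMATIC_THOUGHT, self.d, self.rng, self.params)

    # -- post-session instruments ---------------------------------------------

    def post_k6_items(self) -> tuple[int, ...]:
        """Post K6 re-administration: expected total scaled by d/d0."""
        pre_total = self.profile.k6_total
        if self.profile.d0 == 0:
            return self.profile.k6_items
        target = int(np.clip(round(pre_total * self.d / self.profile.d0), 0, 24))
        return k6_items_for_total(target, self.rng)

    def post_stai_s_items(self) -> tuple[int, ...]:
        return sample_stai_items(self.d, self.rng)

    def cci_items(self) -> tuple[int, ...]:
        """Cognitive change grows with the relative distress reduction."""
        if self.profile.d0 == 0:
            rel = 0.0
        else:
            rel = float(np.clip((self.profile.d0 - self.d) / self.profile.d0, 0.0, 1.0))
        total = int(np.clip(round(30 * rel), 0, 30))
        return _allocate_items(total, 5, 6, self.rng)


class OracleDetector:
    """Detector that reads the simulated user's latent state directly.

    Distressed while uncorrected distress remains (the latent state has
    never dropped below the cutoff 5/24); nondistressed from the first
    crossing on, even if later fatigue raises the reported level again.
    Used to isolate controller behaviour from classifier error.
    """

    threshold = DISTRESS_THRESHOLD

    def __init__(self, user: SimulatedUser):
        self.user = user

    def __call__(self, recent_utterances) -> tuple[str, float]:
        label = "nondistressed" if self.user.corrected else "distressed"
        return label, float(self.user.d)


# ---------------------------------------------------------------------------
# two-arm experiment
# ---------------------------------------------------------------------------


def run_experiment(
    n_per_arm: int | tuple[int, int],
    model,
    params: GeneratorParams,
    seed: int,
    engine_config=None,
) -> pd.DataFrame:
    """Simulate the two-arm trial and return the per-participant table.

    ``model`` is either a transferred DistressModel (used for real
    detection from the utterance window) or a detector factory mapping
    a SimulatedUser to a detector callable (e.g. ``OracleDetector``).
    Baseline balance across arms is enforced by paired sampling: arm
    pairs share a participant profile and differ only in session noise
    and controller behaviour.
    """
    from .engine import EngineConfig, ModelDetector, run_session  # avoid cycle
    from .model.network import DistressModel, Provenance

    if isinstance(model, DistressModel):
        if model.provenance is not Provenance.TRANSFERRED:
            raise ValueError(
                "run_experiment needs a transferred model or a detector oracle"
            )
        the_model = model
        detector_factory = lambda user: ModelDetector(the_model)  # noqa: E731
    elif callable(model):
        detector_factory = model
    else:
        raise ValueError(
            "run_experiment needs a transferred model or a detector oracle"
        )

    if isinstance(n_per_arm, tuple):
        n_adapted, n_random = n_per_arm
    else:
        n_adapted = n_random = int(n_per_arm)
    if min(n_adapted, n_random) < 2:
        raise ValueError("need at least 2 participants per arm")
    engine_config = engine_config or EngineConfig()

    ss = np.random.SeedSequence([seed, 404])
    profile_rng = np.random.default_rng(ss.spawn(1)[0])
    n_pairs = max(n_adapted, n_random)
    profiles = [sample_profile(profile_rng, params) for _ in range(n_pairs)]

    rows = []
    pid = 0
    for arm, n_arm in (("adapted", n_adapted), ("random", n_random)):
        for i in range(n_arm):
            user = SimulatedUser(profiles[i], seed=seed * 100003 + pid, params=params)
            detector = detector_factory(user)
            transcript = run_session(
                user=user,
                arm=arm,
                detector=detector,
                config=replace(engine_config, seed=seed * 100003 + pid),
            )
            out = transcript.outcome
            rows.append(
                {
                    "participant_id": f"p{pid:04d}",
                    "arm": arm,
                    "k6_pre": out.k6_pre.total,
                    "k6_post": out.k6_post.total,
                    "mood_pre": out.mood_pre.value,
                    "mood_post": out.mood_post.value,
                    "stai_s_pre": out.stai_s_pre.total,
                    "stai_s_post": out.stai_s_post.total,
                    "cci": out.cci.total,
                    "qids_pre": profiles[i].qids_pre,
                    "stai_t_pre": sum(profiles[i].stai_t_items),
                    "delivered_questions": out.delivered_questions,
                    "estimated_questions": out.estimated_questions,
                    "detections": out.detections,
                }
            )
            pid += 1
    return pd.DataFrame(rows)
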