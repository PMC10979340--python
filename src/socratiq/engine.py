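"""Cognitive-restructuring session state machine.

One session walks a fixed phase order: describe the situation, report
the mood (with a 0-100 intensity score), identify the automatic thought
(guarded by a thought/other gate with bounded re-asking), correct the
thought through Socratic questions, compose a balanced thought, and
report the mood again. The number of correction questions is governed
by one of two controllers:

* adapted — after each answer a distress detector is consulted;
  questioning stops at the first nondistressed detection or after the
  21st question;
* random — the count is drawn once at session start, uniform on 1..21,
  regardless of detections.

In both arms the detector runs passively after every correction answer,
so per-question detection labels and the model-estimated question count
are available for either controller.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Protocol, Sequence

import numpy as np

from .dialogue import Speaker, Utterance, UtteranceType
from .model.network import DistressModel, WindowPolicy
from .model.training import predict_distress, select_window
from .scales import (
    Arm,
    CENSORED,
    DistressLabel,
    Instrument,
    InstrumentResponse,
    MoodScore,
    SessionOutcome,
    Timing,
    score_instrument,
)
from .synth import THOUGHT_MARKERS

# -- question pool -----------------------------------------------------------

POOL_SIZE = 21

#: Socratic question templates for correcting an automatic thought. The
#: pool size is fixed at 21; within a session questions are consumed
#: sequentially without repetition (optionally in seeded shuffled order).
DEFAULT_QUESTIONS: tuple[str, ...] = (
    "What evidence supports this thought?",
    "What evidence goes against this thought?",
    "Is there another way to look at this situation?",
    "What would you say to a friend who had this thought?",
    "Are you confusing a thought with a fact?",
    "What is the worst that could realistically happen?",
    "What is the best that could happen?",
    "What is the most likely outcome?",
    "Have you experienced a situation like this before? How did it turn out?",
    "Are you overlooking your own strengths or resources?",
    "What would someone who cares about you say about this?",
    "Are you blaming yourself for something not fully in your control?",
    "Is this thought helpful to you right now?",
    "Could you be overestimating the danger in this situation?",
    "Are you focusing only on the negatives and filtering out the positives?",
    "If the roles were reversed, how would you judge someone else here?",
    "Will this matter as much a year from now?",
    "What facts might you be ignoring or discounting?",
    "Is there a smaller first step that would make this feel manageable?",
    "What assumptions are you making, and are they justified?",
    "How else could a neutral observer describe what happened?",
)


@dataclass(frozen=True)
class Question:
    id: str
    text: str


@dataclass(frozen=True)
class QuestionPool:
    """Exactly 21 uniquely identified Socratic question templates."""

    questions: tuple[Question, ...]

    def __post_init__(self) -> None:
        if len(self.questions) != POOL_SIZE:
            raise ValueError(f"question pool must hold exactly {POOL_SIZE} questions")
        ids = [q.id for q in self.questions]
        if len(set(ids)) != POOL_SIZE:
            raise ValueError("question ids must be unique")

    @classmethod
    def default(cls) -> "QuestionPool":
        return cls(
            questions=tuple(
                Question(id=f"q{i + 1:02d}", text=t)
                for i, t in enumerate(DEFAULT_QUESTIONS)
            )
        )

    def shuffled(self, seed: int) -> "QuestionPool":
        rng = np.random.default_rng(seed)
        order = rng.permutation(POOL_SIZE)
        return QuestionPool(questions=tuple(self.questions[i] for i in order))

    @classmethod
    def from_text(cls, text: str) -> "QuestionPool":
        """Parse a plain-text pool: one ``id<TAB>question`` per line
        (lines starting with ``#`` ignored)."""
        qs = []
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            qid, _, qtext = line.partition("\t")
            qs.append(Question(id=qid.strip(), text=qtext.strip()))
        return cls(questions=tuple(qs))

    def to_text(self) -> str:
        return "\n".join(f"{q.id}\t{q.text}" for q in self.questions) + "\n"


# -- session plumbing ---------------------------------------------------------


class Responder(Protocol):
    """What the engine needs from a session participant."""

    profile: object  # carries k6_items, stai_s_items and optionally qids_pre

    def utterance(self, utype: UtteranceType) -> Utterance: ...
    def answer_correction_question(self, question_text: str) -> Utterance: ...
    def balanced_thought(self) -> Utterance: ...
    def mood_score(self) -> int: ...
    def post_k6_items(self) -> tuple[int, ...]: ...
    def post_stai_s_items(self) -> tuple[int, ...]: ...
    def cci_items(self) -> tuple[int, ...]: ...


class ResponderExhausted(RuntimeError):
    """The responder could not supply an answer to a prompt."""


class SessionAborted(RuntimeError):
    def __init__(self, transcript: "SessionTranscript"):
        super().__init__("session aborted: responder exhausted")
        self.transcript = transcript


Detector = Callable[[Sequence[Utterance]], tuple[str, float]]


class ModelDetector:
    """Detector backed by a transferred classifier: selects the recent
    utterance window and runs binary distress inference."""

    def __init__(self, model: DistressModel, policy: Optional[WindowPolicy] = None):
        self.model = model
        self.policy = policy or model.config.window_policy

    def __call__(self, recent: Sequence[Utterance]) -> tuple[str, float]:
        window = select_window(recent, self.policy)
        label, p = predict_distress(self.model, window)
        return label.value, p


@dataclass(frozen=True)
class EngineConfig:
    seed: int = 0
    gate_retry_limit: int = 2
    shuffle_pool: bool = False
    window_policy: WindowPolicy = WindowPolicy.CANONICAL_TYPES


PHASES = (
    "situation",
    "mood_elicit",
    "thought_elicit",
    "correction",
    "balanced_thought",
    "post_mood",
    "done",
)


@dataclass
class SessionState:
    phase: str = "situation"
    questions_asked: int = 0
    detections: list[dict] = field(default_factory=list)
    gate_retries: int = 0

    def advance(self) -> None:
        self.phase = PHASES[PHASES.index(self.phase) + 1]


@dataclass
class SessionTranscript:
    participant_id: str
    arm: Arm
    events: list[dict]
    outcome: Optional[SessionOutcome] = None


# -- controller primitives ----------------------------------------------------

CONTINUE = "CONTINUE"
STOP = "STOP"


def adaptive_step(state: SessionState, detection: str | DistressLabel) -> str:
    """Stopping rule: STOP at the first nondistressed detection or once
    all 21 questions (1 initial + up to 20 additional) are spent."""
    if state.questions_asked < 1:
        raise RuntimeError("adaptive_step called before any question was answered")
    label = detection.value if isinstance(detection, DistressLabel) else str(detection)
    if label == DistressLabel.NONDISTRESSED.value or state.questions_asked >= POOL_SIZE:
        return STOP
    return CONTINUE


def random_question_count(seed_or_rng: int | np.random.Generator) -> int:
    """Single uniform draw on {1..21}, fixed at session start."""
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    return int(rng.integers(1, POOL_SIZE + 1))


def thought_gate(utterance: Utterance, markers: Sequence[str] = THOUGHT_MARKERS) -> str:
    """Rule-based default gate: ``thought`` iff the text carries a
    thought-marker token. Any classifier with the same signature (an
    utterance in, ``"thought"``/``"other"`` out) can replace it."""
    if not utterance.text.strip():
        raise ValueError("cannot gate an empty utterance")
    tokens = set(utterance.text.split())
    return "thought" if tokens & set(markers) else "other"


def estimated_question_count(
    detections: Sequence[dict | str],
    delivered: int,
    arm: Arm | str,
) -> int | str:
    """The question count the detector deemed sufficient.

    First nondistressed detection index (1-based); 21 when all 21
    questions were answered while distressed; otherwise censored (the
    session stopped while distress was still detected, so the model
    would have required at least one more question).
    """
    if len(detections) < delivered:
        raise ValueError(
            f"detections ({len(detections)}) shorter than delivered ({delivered})"
        )

    def label_of(d) -> str:
        return d["label"] if isinstance(d, dict) else str(d)

    for i in range(delivered):
        if label_of(detections[i]) == DistressLabel.NONDISTRESSED.value:
            return i + 1
    if delivered == POOL_SIZE:
        return POOL_SIZE
    return CENSORED


# -- the session itself --------------------------------------------------------


def run_session(
    user: Responder,
    arm: Arm | str,
    detector: Detector,
    pool: Optional[QuestionPool] = None,
    config: Optional[EngineConfig] = None,
    participant_id: str = "anon",
) -> SessionTranscript:
    """Execute one full cognitive-restructuring session.

    The detector is consulted after every correction answer in both
    arms; only the adapted arm's controller acts on it. The transcript
    records every prompt, user utterance, gate decision, detection and
    mood report, and its outcome carries the pre/post instruments and
    both question counts.
    """
    arm = Arm(arm)
    config = config or EngineConfig()
    pool = pool or QuestionPool.default()
    if config.shuffle_pool:
        pool = pool.shuffled(config.seed)

    state = SessionState()
    events: list[dict] = []
    transcript = SessionTranscript(participant_id=participant_id, arm=arm, events=events)
    user_utterances: list[Utterance] = []

    def prompt(text: str) -> None:
        events.append({"type": "prompt", "phase": state.phase, "text": text})

    def record_user(utt: Utterance) -> None:
        user_utterances.append(utt)
        events.append(
            {
                "type": "utterance",
                "phase": state.phase,
                "speaker": Speaker.USER.value,
                "utterance_type": utt.utterance_type.value,
                "text": utt.text,
            }
        )

    def ask_user(fn, *args):
        try:
            return fn(*args)
        except ResponderExhausted as exc:
            events.append({"type": "error", "phase": state.phase, "reason": str(exc)})
            raise SessionAborted(transcript) from exc

    # situation ---------------------------------------------------------------
    prompt("Please tell me about a recent situation that bothered you.")
    record_user(ask_user(user.utterance, UtteranceType.SITUATION))
    state.advance()

    # mood + pre mood score -----------------------------------------------------
    prompt("How did that make you feel, and how intense is that feeling (0-100)?")
    record_user(ask_user(user.utterance, UtteranceType.MOOD))
    mood_pre = MoodScore(value=ask_user(user.mood_score), timing=Timing.PRE)
    events.append({"type": "mood", "timing": "pre", "value": mood_pre.value})
    state.advance()

    # automatic thought, gated ---------------------------------------------------
    prompt("What went through your mind in that situation?")
    thought = ask_user(user.utterance, UtteranceType.AUTOMATIC_THOUGHT)
    record_user(thought)
    decision = thought_gate(thought)
    events.append({"type": "gate", "decision": decision})
    while decision == "other" and state.gate_retries < config.gate_retry_limit:
        state.gate_retries += 1
        prompt("That sounds like how you felt; what thought crossed your mind?")
        thought = ask_user(user.utterance, UtteranceType.AUTOMATIC_THOUGHT)
        record_user(thought)
        decision = thought_gate(thought)
        events.append({"type": "gate", "decision": decision})
    if decision == "other":
        events.append({"type": "override", "reason": "gate retry limit reached"})
    state.advance()

    # correction loop ---------------------------------------------------------------
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 505]))
    target = random_question_count(rng) if arm is Arm.RANDOM else None
    while True:
        q = pool.questions[state.questions_asked]
        prompt(q.text)
        answer = ask_user(user.answer_correction_question, q.text)
        state.questions_asked += 1
        record_user(answer)
        label, p = detector(user_utterances)
        detection = {
            "question_index": state.questions_asked,
            "question_id": q.id,
            "label": str(label),
            "p_distressed": float(p),
        }
        state.detections.append(detection)
        events.append({"type": "detection", **detection})
        if arm is Arm.ADAPTED:
            if adaptive_step(state, detection["label"]) == STOP:
                break
        else:
            if state.questions_asked >= target:
                break
    state.advance()

    # balanced thought --------------------------------------------------------------
    prompt("Taking all of that into account, what would be a more balanced thought?")
    record_user(ask_user(user.balanced_thought))
    state.advance()

    # post mood -----------------------------------------------------------------------
    prompt("Now, how intense is that feeling (0-100)?")
    mood_post = MoodScore(value=ask_user(user.mood_score), timing=Timing.POST)
    events.append({"type": "mood", "timing": "post", "value": mood_post.value})
    state.advance()
    assert state.phase == "done"

    delivered = state.questions_asked
    outcome = SessionOutcome(
        k6_pre=score_instrument(
            InstrumentResponse(Instrument.K6, user.profile.k6_items, Timing.PRE)
        ),
        k6_post=score_instrument(
            InstrumentResponse(Instrument.K6, ask_user(user.post_k6_items), Timing.POST)
        ),
        mood_pre=mood_pre,
        mood_post=mood_post,
        stai_s_pre=score_instrument(
            InstrumentResponse(Instrument.STAI_S, user.profile.stai_s_items, Timing.PRE)
        ),
        stai_s_post=score_instrument(
            InstrumentResponse(
                Instrument.STAI_S, ask_user(user.post_stai_s_items), Timing.POST
            )
        ),
        cci=score_instrument(
            InstrumentResponse(Instrument.CCI, ask_user(user.cci_items), Timing.POST)
        ),
        qids_pre=getattr(user.profile, "qids_pre", None),
        delivered_questions=delivered,
        estimated_questions=estimated_question_count(state.detections, delivered, arm),
        arm=arm,
        detections=state.detections,
    )
    transcript.outcome = outcome
    return transcript
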