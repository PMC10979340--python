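"""Tests of the session state machine and its two controllers."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from socratiq.dialogue import Utterance, UtteranceType
from socratiq.engine import (
    CONTINUE,
    DEFAULT_QUESTIONS,
    POOL_SIZE,
    STOP,
    EngineConfig,
    Question,
    QuestionPool,
    ResponderExhausted,
    SessionAborted,
    SessionState,
    adaptive_step,
    estimated_question_count,
    random_question_count,
    run_session,
    thought_gate,
)
from socratiq.scales import CENSORED, Arm
from socratiq.synth import (
    THOUGHT_MARKERS,
    GeneratorParams,
    OracleDetector,
    SimulatedUser,
    sample_profile,
)


class TestQuestionPool:
    def test_default_pool_has_21_unique_questions(self):
        pool = QuestionPool.default()
        assert len(pool.questions) == POOL_SIZE == 21
        assert len({q.id for q in pool.questions}) == 21
        assert len(set(DEFAULT_QUESTIONS)) == 21

    def test_wrong_size_rejected(self):
        with pytest.raises(ValueError):
            QuestionPool(tuple(Question(f"q{i}", "t") for i in range(20)))

    def test_duplicate_ids_rejected(self):
        qs = tuple(Question("dup", f"t{i}") for i in range(21))
        with pytest.raises(ValueError):
            QuestionPool(qs)

    def test_shuffle_is_seeded_permutation(self):
        pool = QuestionPool.default()
        s1, s2 = pool.shuffled(4), pool.shuffled(4)
        assert s1 == s2
        assert sorted(q.id for q in s1.questions) == sorted(
            q.id for q in pool.questions
        )
        assert s1 != pool.shuffled(5)

    def test_text_roundtrip(self):
        pool = QuestionPool.default()
        text = "# a comment line\n" + pool.to_text()
        assert QuestionPool.from_text(text) == pool


class TestAdaptiveStep:
    def test_stop_on_nondistressed(self):
        st = SessionState(questions_asked=1)
        assert adaptive_step(st, "nondistressed") == STOP

    def test_continue_on_distressed(self):
        st = SessionState(questions_asked=1)
        assert adaptive_step(st, "distressed") == CONTINUE

    def test_stop_at_pool_exhaustion(self):
        st = SessionState(questions_asked=21)
        assert adaptive_step(st, "distressed") == STOP

    def test_requires_at_least_one_answer(self):
        with pytest.raises(RuntimeError):
            adaptive_step(SessionState(questions_asked=0), "distressed")

    def test_exhaustive_short_sequences(self):
        """Over every detection sequence of length 8 (each position
        distressed/nondistressed), the controller stops exactly at the
        first nondistressed index, or never within the prefix."""
        for seq in itertools.product(["distressed", "nondistressed"], repeat=8):
            stopped_at = None
            st = SessionState()
            for label in seq:
                st.questions_asked += 1
                if adaptive_step(st, label) == STOP:
                    stopped_at = st.questions_asked
                    break
            first_nd = next(
                (i + 1 for i, lab in enumerate(seq) if lab == "nondistressed"),
                None,
            )
            assert stopped_at == first_nd

    def test_all_distressed_full_length_stops_at_21(self):
        st = SessionState()
        stopped_at = None
        for _ in range(POOL_SIZE):
            st.questions_asked += 1
            if adaptive_step(st, "distressed") == STOP:
                stopped_at = st.questions_asked
                break
        assert stopped_at == 21


class TestRandomCount:
    def test_range_and_determinism(self):
        for seed in range(50):
            k = random_question_count(seed)
            assert 1 <= k <= 21
            assert k == random_question_count(seed)

    def test_uniformity_chi_square(self):
        rng = np.random.default_rng(123)
        draws = [random_question_count(rng) for _ in range(21000)]
        counts = np.bincount(draws, minlength=22)[1:22]
        assert counts.sum() == 21000
        chi2 = sps.chisquare(counts)
        assert chi2.pvalue > 0.001


class TestGateAndEstimate:
    def test_gate_marker_rule(self):
        u = Utterance(speaker="user", text=f"w001 {THOUGHT_MARKERS[0]} w002",
                      utterance_type=UtteranceType.AUTOMATIC_THOUGHT)
        assert thought_gate(u) == "thought"
        u2 = Utterance(speaker="user", text="w001 w002",
                       utterance_type=UtteranceType.AUTOMATIC_THOUGHT)
        assert thought_gate(u2) == "other"

    def test_gate_rejects_empty(self):
        u = Utterance(speaker="user", text="   ")
        with pytest.raises(ValueError):
            thought_gate(u)

    def test_estimate_first_nondistressed(self):
        dets = ["distressed", "nondistressed", "distressed", "nondistressed"]
        assert estimated_question_count(dets, delivered=4, arm=Arm.RANDOM) == 2

    def test_estimate_censored_when_still_distressed(self):
        dets = ["distressed"] * 3
        assert estimated_question_count(dets, 3, Arm.ADAPTED) == CENSORED

    def test_estimate_21_when_all_answered_distressed(self):
        dets = ["distressed"] * 21
        assert estimated_question_count(dets, 21, Arm.ADAPTED) == 21

    def test_estimate_rejects_short_detections(self):
        with pytest.raises(ValueError):
            estimated_question_count(["distressed"], delivered=2, arm=Arm.RANDOM)


def make_user(seed=0, distressed=True, **params):
    gp = GeneratorParams(seed=seed, **params)
    rng = np.random.default_rng(seed)
    profile = sample_profile(rng, gp, distressed=distressed)
    return SimulatedUser(profile, seed=seed, params=gp)


class AlwaysDetector:
    """Scripted detector: fixed label sequence, then repeat the last."""

    def __init__(self, labels):
        self.labels = list(labels)
        self.i = 0

    def __call__(self, recent):
        label = self.labels[min(self.i, len(self.labels) - 1)]
        self.i += 1
        return label, 1.0 if label == "distressed" else 0.0


class TestRunSession:
    def test_adapted_stops_at_first_nondistressed(self):
        user = make_user(1)
        transcript = run_session(
            user, Arm.ADAPTED, AlwaysDetector(["distressed"] * 2 + ["nondistressed"]),
            config=EngineConfig(seed=1),
        )
        out = transcript.outcome
        assert out.delivered_questions == 3
        assert out.estimated_questions == 3

    def test_adapted_immediate_stop_is_one_question(self):
        user = make_user(2)
        out = run_session(
            user, "adapted", AlwaysDetector(["nondistressed"]),
            config=EngineConfig(seed=2),
        ).outcome
        assert out.delivered_questions == 1

    def test_adapted_never_exceeds_21(self):
        user = make_user(3)
        out = run_session(
            user, "adapted", AlwaysDetector(["distressed"]),
            config=EngineConfig(seed=3),
        ).outcome
        assert out.delivered_questions == 21
        assert out.estimated_questions == 21  # answered all 21, by rule

    def test_random_count_fixed_at_session_start(self):
        user = make_user(4)
        cfg = EngineConfig(seed=4)
        # the draw must match the documented seeding, not detections
        expected = random_question_count(
            np.random.default_rng(np.random.SeedSequence([4, 505]))
        )
        out = run_session(
            user, Arm.RANDOM, AlwaysDetector(["nondistressed"]), config=cfg
        ).outcome
        assert out.delivered_questions == expected

    def test_random_arm_still_records_detections(self):
        user = make_user(5)
        out = run_session(
            user, Arm.RANDOM, AlwaysDetector(["distressed"]),
            config=EngineConfig(seed=5),
        ).outcome
        assert len(out.detections) == out.delivered_questions
        assert all(d["label"] == "distressed" for d in out.detections)
        assert out.estimated_questions == (
            21 if out.delivered_questions == 21 else CENSORED
        )

    def test_questions_are_unique_within_session(self):
        user = make_user(6)
        transcript = run_session(
            user, Arm.ADAPTED, AlwaysDetector(["distressed"]),
            config=EngineConfig(seed=6),
        )
        qids = [d["question_id"] for d in transcript.outcome.detections]
        assert len(qids) == len(set(qids))

    def test_phase_order_in_events(self):
        user = make_user(7)
        transcript = run_session(
            user, Arm.ADAPTED, AlwaysDetector(["nondistressed"]),
            config=EngineConfig(seed=7),
        )
        phases = [e["phase"] for e in transcript.events if "phase" in e]
        order = ["situation", "mood_elicit", "thought_elicit", "correction",
                 "balanced_thought", "post_mood"]
        seen = [p for p, _ in itertools.groupby(phases)]
        assert seen == [p for p in order if p in seen]
        assert seen[0] == "situation" and seen[-1] == "post_mood"

    def test_outcome_scales_are_validated_instruments(self):
        user = make_user(8)
        out = run_session(
            user, Arm.ADAPTED, OracleDetector(user), config=EngineConfig(seed=8)
        ).outcome
        assert 0 <= out.k6_post.total <= 24
        assert 20 <= out.stai_s_post.total <= 80
        assert 0 <= out.cci.total <= 30
        assert 0 <= out.mood_post.value <= 100

    def test_gate_retry_then_override(self):
        """A responder that never produces a thought marker triggers the
        bounded re-ask loop and then an explicit override event."""
        user = make_user(9)

        class NoThought:
            profile = user.profile

            def utterance(self, utype):
                return Utterance(speaker="user", text="w001 w002",
                                 utterance_type=utype)

            answer_correction_question = lambda self, q: user.answer_correction_question(q)
            balanced_thought = lambda self: user.balanced_thought()
            mood_score = lambda self: user.mood_score()
            post_k6_items = lambda self: user.post_k6_items()
            post_stai_s_items = lambda self: user.post_stai_s_items()
            cci_items = lambda self: user.cci_items()

        transcript = run_session(
            NoThought(), Arm.ADAPTED, AlwaysDetector(["nondistressed"]),
            config=EngineConfig(seed=9, gate_retry_limit=2),
        )
        gates = [e for e in transcript.events if e["type"] == "gate"]
        overrides = [e for e in transcript.events if e["type"] == "override"]
        assert len(gates) == 3  # initial + 2 retries
        assert len(overrides) == 1

    def test_exhausted_responder_aborts_with_transcript(self):
        user = make_user(10)

        class Exhausted:
            profile = user.profile

            def utterance(self, utype):
                raise ResponderExhausted("out of answers")

        with pytest.raises(SessionAborted) as exc_info:
            run_session(Exhausted(), Arm.ADAPTED,
                        AlwaysDetector(["nondistressed"]))
        transcript = exc_info.value.transcript
        assert transcript.outcome is None
        assert any(e["type"] == "error" for e in transcript.events)

    def test_shuffled_pool_changes_order_not_content(self):
        user1 = make_user(11)
        user2 = make_user(11)
        det = lambda recent: ("distressed", 1.0)  # noqa: E731
        t_plain = run_session(user1, Arm.ADAPTED, det,
                              config=EngineConfig(seed=11))
        t_shuf = run_session(user2, Arm.ADAPTED, det,
                             config=EngineConfig(seed=11, shuffle_pool=True))
        ids_plain = [d["question_id"] for d in t_plain.outcome.detections]
        ids_shuf = [d["question_id"] for d in t_shuf.outcome.detections]
        assert sorted(ids_plain) == sorted(ids_shuf)
        assert ids_plain != ids_shuf
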