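"""Psychometric instrument scoring and session change metrics.

Implements the instruments used around a single cognitive-restructuring
session — the Kessler K6 distress screener, the State-Trait Anxiety
Inventory state/trait subscales (STAI-S / STAI-T), the Cognitive
Change-Immediate scale (CCI), the PHQ-8 depression screener and the
0-100 self-reported negative-mood score — together with the three change
metrics used to evaluate a session:

* change in psychological distress = K6(pre) - K6(post)
* mood change = (mood(pre) - mood(post)) / mood(pre)
* change in state anxiety = STAI-S(pre) - STAI-S(post)

Positive values always mean improvement (distress/anxiety/negative mood
went down). Totals are plain sums of items; no reverse scoring is applied
(the published STAI reverse-scores some items, but direct 1-4 scoring is
used throughout here — see docs/methods.md).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field


class Instrument(str, enum.Enum):
    K6 = "K6"
    STAI_S = "STAI_S"
    STAI_T = "STAI_T"
    CCI = "CCI"
    PHQ8 = "PHQ8"


class Timing(str, enum.Enum):
    PRE = "pre"
    POST = "post"


class DistressLabel(str, enum.Enum):
    DISTRESSED = "distressed"
    NONDISTRESSED = "nondistressed"


class DepressionLabel(str, enum.Enum):
    DEPRESSED = "depressed"
    NOT_DEPRESSED = "not_depressed"


#: item count, minimum item value, maximum item value per instrument
_ITEM_SPECS: dict[Instrument, tuple[int, int, int]] = {
    Instrument.K6: (6, 0, 4),
    Instrument.STAI_S: (20, 1, 4),
    Instrument.STAI_T: (20, 1, 4),
    Instrument.CCI: (5, 0, 6),
    Instrument.PHQ8: (8, 0, 3),
}

#: valid total range per instrument, derived from the item specs
TOTAL_RANGES: dict[Instrument, tuple[int, int]] = {
    inst: (n * lo, n * hi) for inst, (n, lo, hi) in _ITEM_SPECS.items()
}

K6_DISTRESS_CUTOFF = 5  # total >= 5 -> distressed
PHQ8_DEPRESSION_CUTOFF = 10  # total >= 10 -> depressed


class InstrumentValidationError(ValueError):
    """Item vector violates the instrument's count or range constraints."""


@dataclass(frozen=True)
class InstrumentResponse:
    """Item-level answers to one instrument administration."""

    instrument: Instrument
    items: tuple[int, ...]
    timing: Timing = Timing.PRE

    def __post_init__(self) -> None:
        object.__setattr__(self, "items", tuple(int(v) for v in self.items))
        n, lo, hi = _ITEM_SPECS[self.instrument]
        if len(self.items) != n:
            raise InstrumentValidationError(
                f"{self.instrument.value} expects {n} items, got {len(self.items)}"
            )
        for i, v in enumerate(self.items):
            if not lo <= v <= hi:
                raise InstrumentValidationError(
                    f"{self.instrument.value} item {i} out of range "
                    f"[{lo},{hi}]: {v}"
                )


@dataclass(frozen=True)
class ScaleScore:
    """A validated instrument total."""

    instrument: Instrument
    total: int
    timing: Timing = Timing.PRE

    def __post_init__(self) -> None:
        lo, hi = TOTAL_RANGES[self.instrument]
        if not lo <= self.total <= hi:
            raise InstrumentValidationError(
                f"{self.instrument.value} total out of range [{lo},{hi}]: "
                f"{self.total}"
            )


@dataclass(frozen=True)
class MoodScore:
    """Self-reported negative-mood intensity on a 0-100 percent scale."""

    value: int
    timing: Timing = Timing.PRE

    def __post_init__(self) -> None:
        if not 0 <= self.value <= 100:
            raise InstrumentValidationError(
                f"mood score out of range [0,100]: {self.value}"
            )


class Arm(str, enum.Enum):
    ADAPTED = "adapted"
    RANDOM = "random"


#: sentinel for an estimated question count that is only bounded below
#: (the session ended while distress was still detected)
CENSORED = "censored"


@dataclass
class SessionOutcome:
    """Derived outcomes of one cognitive-restructuring session."""

    k6_pre: ScaleScore
    k6_post: ScaleScore
    mood_pre: MoodScore
    mood_post: MoodScore
    stai_s_pre: ScaleScore
    stai_s_post: ScaleScore
    cci: ScaleScore
    delivered_questions: int
    estimated_questions: int | str  # int or CENSORED
    arm: Arm
    qids_pre: int | None = None  # precomputed total, pass-through
    detections: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 1 <= self.delivered_questions <= 21:
            raise InstrumentValidationError(
                f"delivered_questions out of range [1,21]: "
                f"{self.delivered_questions}"
            )


def score_instrument(resp: InstrumentResponse) -> ScaleScore:
    """Sum the items of a validated response into a total score.

    No reverse scoring; every instrument here is totalled by a plain sum,
    so the score is invariant to item order.
    """
    return ScaleScore(
        instrument=resp.instrument, total=sum(resp.items), timing=resp.timing
    )


def classify_k6_distress(score: ScaleScore) -> DistressLabel:
    """Binary distress cut on the K6 total: >= 5 distressed, < 5 not."""
    if score.instrument is not Instrument.K6:
        raise TypeError(f"expected a K6 score, got {score.instrument.value}")
    if score.total >= K6_DISTRESS_CUTOFF:
        return DistressLabel.DISTRESSED
    return DistressLabel.NONDISTRESSED


def classify_phq8_depression(total: int) -> DepressionLabel:
    """Binary depression cut on a PHQ-8 total: >= 10 depressed."""
    lo, hi = TOTAL_RANGES[Instrument.PHQ8]
    if not lo <= total <= hi:
        raise InstrumentValidationError(
            f"PHQ8 total out of range [{lo},{hi}]: {total}"
        )
    if total >= PHQ8_DEPRESSION_CUTOFF:
        return DepressionLabel.DEPRESSED
    return DepressionLabel.NOT_DEPRESSED


def _require(score: ScaleScore, instrument: Instrument, name: str) -> None:
    if score.instrument is not instrument:
        raise TypeError(
            f"{name} must be {instrument.value}, got {score.instrument.value}"
        )


def _as_total(value: ScaleScore | float, instrument: Instrument, name: str) -> float:
    """Accept a validated score or a bare number (e.g. a condition mean)."""
    if isinstance(value, ScaleScore):
        _require(value, instrument, name)
        return float(value.total)
    return float(value)


def change_in_distress(pre: ScaleScore | float, post: ScaleScore | float) -> float:
    """K6(pre) - K6(post); positive means distress decreased.

    Linear in its arguments, so it applies equally to individual scores
    and to condition means.
    """
    return _as_total(pre, Instrument.K6, "pre") - _as_total(post, Instrument.K6, "post")


class UndefinedMetricError(ZeroDivisionError):
    """A change metric is undefined for the given inputs."""


def mood_change(pre: MoodScore | float, post: MoodScore | float) -> float:
    """(mood(pre) - mood(post)) / mood(pre); positive means mood improved.

    Undefined when the pre-session score is 0 (nothing to improve on a
    relative scale); raises rather than silently returning 0. Unlike the
    two difference metrics this ratio is NOT linear: the metric of the
    condition means differs from the mean of per-subject metrics.
    """
    pre_v = float(pre.value if isinstance(pre, MoodScore) else pre)
    post_v = float(post.value if isinstance(post, MoodScore) else post)
    if pre_v == 0:
        raise UndefinedMetricError(
            "mood change is undefined for a pre-session mood score of 0"
        )
    return (pre_v - post_v) / pre_v


def change_in_stai_s(pre: ScaleScore | float, post: ScaleScore | float) -> float:
    """STAI-S(pre) - STAI-S(post); positive means state anxiety decreased."""
    return _as_total(pre, Instrument.STAI_S, "pre") - _as_total(
        post, Instrument.STAI_S, "post"
    )
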