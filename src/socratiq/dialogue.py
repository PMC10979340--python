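"""Core dialogue containers shared across the package.

A dialogue is an ordered sequence of turns, each with a speaker role, a
free-text utterance and an utterance-type tag used by the
cognitive-restructuring scenario (situation / mood / automatic_thought /
other). Optional labels carry the supervision used by the classifier:
per-turn emotion (7 classes) and dialogue act (4 classes), per-dialogue
topic (10 classes) and a per-dialogue binary depression/distress label.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional

N_EMOTIONS = 7
N_ACTS = 4
N_TOPICS = 10


class Speaker(str, enum.Enum):
    AGENT = "agent"
    USER = "user"


class UtteranceType(str, enum.Enum):
    SITUATION = "situation"
    MOOD = "mood"
    AUTOMATIC_THOUGHT = "automatic_thought"
    OTHER = "other"


@dataclass(frozen=True)
class Utterance:
    speaker: Speaker
    text: str
    utterance_type: UtteranceType = UtteranceType.OTHER
    emotion: Optional[int] = None  # per-turn, 0..6
    act: Optional[int] = None  # per-turn, 0..3

    def __post_init__(self) -> None:
        if self.emotion is not None and not 0 <= self.emotion < N_EMOTIONS:
            raise ValueError(f"emotion label out of range: {self.emotion}")
        if self.act is not None and not 0 <= self.act < N_ACTS:
            raise ValueError(f"act label out of range: {self.act}")


@dataclass(frozen=True)
class LabeledDialogue:
    dialogue_id: str
    turns: tuple[Utterance, ...]
    topic: Optional[int] = None  # per-dialogue, 0..9
    distress: Optional[int] = None  # per-dialogue binary (depression/distress)

    def __post_init__(self) -> None:
        object.__setattr__(self, "turns", tuple(self.turns))
        if not self.turns:
            raise ValueError("a dialogue must contain at least one turn")
        if self.topic is not None and not 0 <= self.topic < N_TOPICS:
            raise ValueError(f"topic label out of range: {self.topic}")
        if self.distress is not None and self.distress not in (0, 1):
            raise ValueError(f"distress label must be 0/1: {self.distress}")

    def user_turns(self) -> tuple[Utterance, ...]:
        return tuple(t for t in self.turns if t.speaker is Speaker.USER)


def dialogue_to_dict(dlg: LabeledDialogue) -> dict:
    return {
        "dialogue_id": dlg.dialogue_id,
        "topic": dlg.topic,
        "distress": dlg.distress,
        "turns": [
            {
                "speaker": t.speaker.value,
                "text": t.text,
                "utterance_type": t.utterance_type.value,
                "emotion": t.emotion,
                "act": t.act,
            }
            for t in dlg.turns
        ],
    }


def dialogue_from_dict(d: dict) -> LabeledDialogue:
    return LabeledDialogue(
        dialogue_id=d["dialogue_id"],
        topic=d.get("topic"),
        distress=d.get("distress"),
        turns=tuple(
            Utterance(
                speaker=Speaker(t["speaker"]),
                text=t["text"],
                utterance_type=UtteranceType(t.get("utterance_type", "other")),
                emotion=t.get("emotion"),
                act=t.get("act"),
            )
            for t in d["turns"]
        ),
    )
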