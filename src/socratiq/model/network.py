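"""Hierarchical recurrent multitask classifier for dialogue distress.

Architecture: word embeddings -> per-turn bidirectional LSTM encoder
(final forward/backward hidden states concatenated) -> document-level
(optionally stacked) LSTM over the turn vectors -> linear task heads.
Per-dialogue heads (binary depression/distress, topic) read the final
document hidden state; per-turn heads (emotion, dialogue act) read the
document hidden state at each turn.

Training follows the multitask regime the classifier was designed for:
cross-entropy per task, batch size 1, Adam, early stopping on the macro
F1 of the depression/distress task. Transfer to the in-session distress
task replaces the final fully connected (distress) layer while keeping
— and by default fine-tuning — the pretrained encoder.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ..dialogue import N_ACTS, N_EMOTIONS, N_TOPICS, LabeledDialogue, Utterance
from .autodiff import Tensor, softmax, softmax_cross_entropy
from .vocab import Tokenizer, Vocabulary, whitespace_tokenizer

TASKS = ("distress", "topic", "emotion", "act")
TASK_CLASSES = {"distress": 2, "topic": N_TOPICS, "emotion": N_EMOTIONS, "act": N_ACTS}


class Provenance(str, enum.Enum):
    PRETRAINED = "pretrained"
    TRANSFERRED = "transferred"


class WindowPolicy(str, enum.Enum):
    #: most recent utterance of each canonical type (situation/mood/thought)
    CANONICAL_TYPES = "canonical_types"
    #: literally the last 3 user turns
    LAST_USER_TURNS = "last_user_turns"


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the hierarchical classifier.

    Defaults match the reference training regime (embedding and turn
    encoder width 128, document hidden in {128,256,512} with 1-3 layers,
    Adam at 1e-3, dropout 0.1, batch size 1, up to 100 epochs with early
    stopping on depression macro F1).
    """

    embedding_dim: int = 128
    turn_hidden: int = 128
    doc_layers: int = 1
    doc_hidden: int = 128
    dropout_turn: float = 0.1
    dropout_doc: float = 0.1
    lr: float = 1e-3
    batch_size: int = 1
    max_epochs: int = 100
    patience: int = 10
    early_stop_metric: str = "macro_f1_depression"
    task_weights: dict = field(
        default_factory=lambda: {t: 1.0 for t in TASKS}
    )
    freeze_encoder: bool = False
    window_policy: WindowPolicy = WindowPolicy.CANONICAL_TYPES
    seed: int = 0

    def __post_init__(self) -> None:
        if self.doc_layers not in (1, 2, 3):
            raise ValueError("doc_layers must be in {1,2,3}")
        for name in ("embedding_dim", "turn_hidden", "doc_hidden", "batch_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("dropout_turn", "dropout_doc"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0,1)")
        if self.max_epochs < 0:
            raise ValueError("max_epochs must be >= 0")


def _glorot(rng: np.random.Generator, n_in: int, n_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-limit, limit, size=(n_in, n_out))


class LSTMParams:
    """One LSTM direction/layer: four gate projections over [x, h]."""

    GATES = ("i", "f", "o", "g")

    def __init__(self, rng: np.random.Generator, n_in: int, hidden: int):
        self.hidden = hidden
        self.W = {g: Tensor(_glorot(rng, n_in + hidden, hidden)) for g in self.GATES}
        self.b = {g: Tensor(np.zeros((1, hidden))) for g in self.GATES}
        # forget-gate bias at 1: standard trick for gradient flow
        self.b["f"].data[:] = 1.0

    def params(self) -> list[Tensor]:
        return [*self.W.values(), *self.b.values()]

    def step(self, x: Tensor, h: Tensor, c: Tensor) -> tuple[Tensor, Tensor]:
        xh = x.concat(h)
        i = (xh.matmul(self.W["i"]) + self.b["i"]).sigmoid()
        f = (xh.matmul(self.W["f"]) + self.b["f"]).sigmoid()
        o = (xh.matmul(self.W["o"]) + self.b["o"]).sigmoid()
        g = (xh.matmul(self.W["g"]) + self.b["g"]).tanh()
        c_new = f * c + i * g
        h_new = o * c_new.tanh()
        return h_new, c_new

    def run(self, inputs: list[Tensor], reverse: bool = False) -> list[Tensor]:
        h = Tensor(np.zeros((1, self.hidden)), requires_grad=False)
        c = Tensor(np.zeros((1, self.hidden)), requires_grad=False)
        seq = reversed(inputs) if reverse else inputs
        hs = []
        for x in seq:
            h, c = self.step(x, h, c)
            hs.append(h)
        if reverse:
            hs.reverse()
        return hs


class DistressModel:
    """Vocabulary + encoders + task heads with training provenance."""

    def __init__(
        self,
        vocabulary: Vocabulary,
        config: ModelConfig,
        tasks: Sequence[str] = TASKS,
        tokenizer: Tokenizer = whitespace_tokenizer,
        provenance: Provenance = Provenance.PRETRAINED,
        rng: Optional[np.random.Generator] = None,
    ):
        unknown = set(tasks) - set(TASKS)
        if unknown:
            raise ValueError(f"unknown tasks: {sorted(unknown)}")
        if rng is None:
            rng = np.random.default_rng(config.seed)
        self.vocabulary = vocabulary
        self.config = config
        self.tokenizer = tokenizer
        self.provenance = provenance
        self.tasks = tuple(tasks)

        self.embedding = Tensor(
            rng.normal(0.0, 0.1, size=(vocabulary.size, config.embedding_dim))
        )
        self.turn_fwd = LSTMParams(rng, config.embedding_dim, config.turn_hidden)
        self.turn_bwd = LSTMParams(rng, config.embedding_dim, config.turn_hidden)
        self.doc_layers: list[LSTMParams] = []
        n_in = 2 * config.turn_hidden
        for _ in range(config.doc_layers):
            self.doc_layers.append(LSTMParams(rng, n_in, config.doc_hidden))
            n_in = config.doc_hidden
        self.heads: dict[str, tuple[Tensor, Tensor]] = {}
        for task in self.tasks:
            self.reset_head(task, rng)
        self._train_mode = False
        self._rng = rng

    # -- parameter bookkeeping --------------------------------------------

    def reset_head(self, task: str, rng: np.random.Generator) -> None:
        k = TASK_CLASSES[task]
        self.heads[task] = (
            Tensor(_glorot(rng, self.config.doc_hidden, k)),
            Tensor(np.zeros((1, k))),
        )

    def encoder_parameters(self) -> list[Tensor]:
        ps = [self.embedding]
        ps += self.turn_fwd.params() + self.turn_bwd.params()
        for layer in self.doc_layers:
            ps += layer.params()
        return ps

    def head_parameters(self) -> list[Tensor]:
        ps = []
        for w, b in self.heads.values():
            ps += [w, b]
        return ps

    def parameters(self) -> list[Tensor]:
        return self.encoder_parameters() + self.head_parameters()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def train(self, mode: bool = True) -> None:
        self._train_mode = mode

    # -- forward ------------------------------------------------------------

    def _encode_turn(self, utt: Utterance) -> Tensor:
        token_ids = self.vocabulary.encode(self.tokenizer(utt.text))
        if not token_ids:
            token_ids = [self.vocabulary.token_to_index["<unk>"]]
        emb = self.embedding.rows(token_ids)
        xs = [emb.row(i) for i in range(len(token_ids))]
        h_fwd = self.turn_fwd.run(xs)[-1]
        h_bwd = self.turn_bwd.run(xs, reverse=True)[0]
        vec = h_fwd.concat(h_bwd)
        if self._train_mode and self.config.dropout_turn > 0:
            vec = vec.dropout(self.config.dropout_turn, self._rng)
        return vec

    def _encode_document(self, dialogue: LabeledDialogue) -> list[Tensor]:
        if not dialogue.turns:
            raise ValueError("cannot encode an empty dialogue")
        seq: list[Tensor] = [self._encode_turn(t) for t in dialogue.turns]
        for layer in self.doc_layers:
            seq = layer.run(seq)
            if self._train_mode and self.config.dropout_doc > 0:
                seq = [h.dropout(self.config.dropout_doc, self._rng) for h in seq]
        return seq

    def forward_logits(self, dialogue: LabeledDialogue) -> dict[str, object]:
        """Logit tensors per task: (1,k) for per-dialogue tasks, a list of
        (1,k) rows (one per turn) for per-turn tasks."""
        hs = self._encode_document(dialogue)
        final = hs[-1]
        out: dict[str, object] = {}
        for task in self.tasks:
            w, b = self.heads[task]
            if task in ("distress", "topic"):
                out[task] = final.matmul(w) + b
            else:  # per-turn heads
                out[task] = [h.matmul(w) + b for h in hs]
        return out

    def forward(self, dialogue: LabeledDialogue) -> dict[str, np.ndarray]:
        """Probability vectors per task (per-turn tasks: (n_turns, k))."""
        was_training = self._train_mode
        self._train_mode = False
        try:
            logits = self.forward_logits(dialogue)
        finally:
            self._train_mode = was_training
        probs: dict[str, np.ndarray] = {}
        for task, val in logits.items():
            if isinstance(val, list):
                probs[task] = softmax(np.concatenate([t.data for t in val], axis=0))
            else:
                probs[task] = softmax(val.data)[0]
        return probs

    def dialogue_loss(self, dialogue: LabeledDialogue) -> Optional[Tensor]:
        """Weighted multitask cross-entropy for one dialogue.

        Tasks whose labels are absent contribute nothing; per-turn task
        losses are averaged over the labeled turns. Returns None when
        the dialogue carries no usable label.
        """
        logits = self.forward_logits(dialogue)
        weights = self.config.task_weights
        total: Optional[Tensor] = None

        def add(term: Tensor, w: float):
            nonlocal total
            if w == 0.0:
                return
            term = term.scale(w)
            total = term if total is None else total + term

        if "distress" in logits and dialogue.distress is not None:
            add(softmax_cross_entropy(logits["distress"], dialogue.distress),
                weights.get("distress", 1.0))
        if "topic" in logits and dialogue.topic is not None:
            add(softmax_cross_entropy(logits["topic"], dialogue.topic),
                weights.get("topic", 1.0))
        for task, attr in (("emotion", "emotion"), ("act", "act")):
            if task not in logits:
                continue
            labeled = [
                (i, getattr(t, attr))
                for i, t in enumerate(dialogue.turns)
                if getattr(t, attr) is not None
            ]
            if not labeled:
                continue
            terms = [softmax_cross_entropy(logits[task][i], y) for i, y in labeled]
            acc = terms[0]
            for t in terms[1:]:
                acc = acc + t
            add(acc.scale(1.0 / len(terms)), weights.get(task, 1.0))
        return total

    # -- inference -----------------------------------------------------------

    def predict_proba_distress(self, dialogue: LabeledDialogue) -> float:
        probs = self.forward(dialogue)
        return float(probs["distress"][1])

    def snapshot(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p.data.copy() for i, p in enumerate(self.parameters())}

    def load_snapshot(self, snap: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.parameters()):
            p.data[...] = snap[f"p{i}"]
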