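"""Training workflows: multitask pretraining, transfer to in-session
distress detection, and evaluation.

Pretraining jointly optimises the auxiliary heads (emotion, act, topic)
on everyday-conversation-style dialogues and the binary depression head
on interview-style dialogues, with batch size 1 and Adam. After every
epoch the depression macro F1 on the validation split is computed and
the best snapshot kept (early stopping with patience).

Transfer learning re-initialises the final fully connected (distress)
layer, keeps the pretrained encoder (fine-tuned by default, freezable
via config) and trains on cognitive-restructuring corpora restricted to
the three canonical user utterance types: situation, mood and automatic
thought.
"""

from __future__ import annotations

import copy
import enum
import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np

from ..dialogue import LabeledDialogue, Speaker, Utterance, UtteranceType
from ..scales import DistressLabel
from .autodiff import Tensor
from .network import DistressModel, ModelConfig, Provenance, WindowPolicy
from .vocab import build_vocabulary

logger = logging.getLogger(__name__)

CANONICAL_TYPES = (
    UtteranceType.SITUATION,
    UtteranceType.MOOD,
    UtteranceType.AUTOMATIC_THOUGHT,
)


@dataclass(frozen=True)
class Splits:
    """Train/validation/test partition of a dialogue corpus."""

    train: tuple[LabeledDialogue, ...]
    val: tuple[LabeledDialogue, ...]
    test: tuple[LabeledDialogue, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "train", tuple(self.train))
        object.__setattr__(self, "val", tuple(self.val))
        object.__setattr__(self, "test", tuple(self.test))


class Averaging(str, enum.Enum):
    BINARY_POSITIVE = "binary_positive"
    MACRO = "macro"


@dataclass(frozen=True)
class EvalMetrics:
    accuracy: float
    precision: float
    recall: float
    f1: float
    averaging: Averaging
    n: int

    def __post_init__(self) -> None:
        for name in ("accuracy", "precision", "recall", "f1"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} out of [0,1]: {v}")


class Adam:
    """Adam over a fixed parameter list (step count shared)."""

    def __init__(self, params: list[Tensor], lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _binary_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, float, float]:
    tp = int(np.sum((y_pred == 1) & (y_true == 1)))
    fp = int(np.sum((y_pred == 1) & (y_true == 0)))
    fn = int(np.sum((y_pred == 0) & (y_true == 1)))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f1


def binary_eval(
    y_true: Sequence[int],
    y_pred: Sequence[int],
    averaging: Averaging = Averaging.BINARY_POSITIVE,
) -> EvalMetrics:
    """Confusion-matrix metrics for a binary task.

    ``binary_positive`` reports precision/recall/F1 of the positive
    (distressed/depressed) class; ``macro`` averages them over both
    classes.
    """
    yt = np.asarray(y_true, dtype=int)
    yp = np.asarray(y_pred, dtype=int)
    if yt.size == 0:
        raise ValueError("cannot evaluate on an empty set")
    acc = float(np.mean(yt == yp))
    if averaging is Averaging.BINARY_POSITIVE:
        p, r, f = _binary_metrics(yt, yp)
    else:
        ps, rs, fs = [], [], []
        for cls in (0, 1):
            p_c, r_c, f_c = _binary_metrics((yt == cls).astype(int), (yp == cls).astype(int))
            ps.append(p_c)
            rs.append(r_c)
            fs.append(f_c)
        p, r, f = float(np.mean(ps)), float(np.mean(rs)), float(np.mean(fs))
    return EvalMetrics(accuracy=acc, precision=p, recall=r, f1=f, averaging=averaging, n=yt.size)


def macro_f1(y_true: Sequence[int], y_pred: Sequence[int]) -> float:
    return binary_eval(y_true, y_pred, Averaging.MACRO).f1


# ---------------------------------------------------------------------------
# training loops
# ---------------------------------------------------------------------------


@dataclass
class TrainingLog:
    """Per-epoch records: mean loss per task and validation macro F1."""

    epochs: list[dict] = field(default_factory=list)

    def best_epoch(self) -> Optional[int]:
        if not self.epochs:
            return None
        f1s = [e["val_macro_f1"] for e in self.epochs]
        return int(np.argmax(f1s))


def _labels_ok(dialogues: Iterable[LabeledDialogue]) -> None:
    labels = {d.distress for d in dialogues if d.distress is not None}
    if len(labels) < 2:
        raise ValueError(
            "depression/distress labels are all one class; macro F1 is undefined"
        )


def _val_macro_f1(model: DistressModel, val: Sequence[LabeledDialogue]) -> float:
    y_true, y_pred = [], []
    for d in val:
        if d.distress is None:
            continue
        p = model.predict_proba_distress(d)
        y_true.append(d.distress)
        y_pred.append(1 if p >= 0.5 else 0)
    return macro_f1(y_true, y_pred)


def _fit(
    model: DistressModel,
    train_dialogues: Sequence[LabeledDialogue],
    val_dialogues: Sequence[LabeledDialogue],
    config: ModelConfig,
    trainable: list[Tensor],
    rng: np.random.Generator,
) -> TrainingLog:
    """Shared epoch loop with early stopping on validation macro F1."""
    log = TrainingLog()
    if config.max_epochs == 0:
        logger.warning("max_epochs is 0; returning the initialized model")
        return log
    opt = Adam(trainable, lr=config.lr)
    best_f1, best_snap, best_epoch = -1.0, model.snapshot(), -1
    order = np.arange(len(train_dialogues))
    for epoch in range(config.max_epochs):
        rng.shuffle(order)
        model.train(True)
        total_losses: list[float] = []
        for idx in order:
            dlg = train_dialogues[idx]
            model.zero_grad()
            loss = model.dialogue_loss(dlg)
            if loss is None:
                continue
            loss.backward()
            opt.step()
            total_losses.append(float(loss.data[0, 0]))
        model.train(False)
        val_f1 = _val_macro_f1(model, val_dialogues)
        log.epochs.append(
            {
                "epoch": epoch,
                "mean_loss": float(np.mean(total_losses)) if total_losses else float("nan"),
                "val_macro_f1": val_f1,
            }
        )
        if val_f1 > best_f1:
            best_f1, best_snap, best_epoch = val_f1, model.snapshot(), epoch
        elif epoch - best_epoch >= config.patience:
            break
    model.load_snapshot(best_snap)
    return log


def pretrain(
    daily_like: Splits | Sequence[LabeledDialogue],
    interview_like: Splits,
    config: ModelConfig,
    min_count: int = 1,
) -> tuple[DistressModel, TrainingLog]:
    """Multitask pretraining on the two corpus families.

    ``daily_like`` supplies auxiliary labels (emotion/act/topic);
    ``interview_like`` supplies the binary depression labels that drive
    early stopping. Reproducible for a fixed ``config.seed``.
    """
    if not isinstance(interview_like, Splits) or not interview_like.val:
        raise ValueError("interview_like must provide a validation split")
    daily_train = daily_like.train if isinstance(daily_like, Splits) else tuple(daily_like)
    has_aux = any(
        d.topic is not None or any(t.emotion is not None or t.act is not None for t in d.turns)
        for d in daily_train
    )
    if not has_aux:
        raise ValueError("daily_like carries no auxiliary labels")
    _labels_ok(interview_like.train)
    _labels_ok(interview_like.val)

    ss = np.random.SeedSequence(config.seed)
    init_rng, shuffle_rng = (np.random.default_rng(s) for s in ss.spawn(2))
    corpus = list(daily_train) + list(interview_like.train)
    vocab = build_vocabulary(corpus, min_count=min_count)
    model = DistressModel(vocab, config, provenance=Provenance.PRETRAINED, rng=init_rng)
    log = _fit(model, corpus, interview_like.val, config, model.parameters(), shuffle_rng)
    return model, log


def cbt_view(dialogue: LabeledDialogue) -> LabeledDialogue:
    """Restrict a dialogue to the three canonical user utterance types."""
    turns = tuple(
        t
        for t in dialogue.turns
        if t.speaker is Speaker.USER and t.utterance_type in CANONICAL_TYPES
    )
    if not turns:
        raise ValueError(
            f"dialogue {dialogue.dialogue_id} has no situation/mood/"
            "automatic-thought user utterances"
        )
    return LabeledDialogue(
        dialogue_id=dialogue.dialogue_id,
        turns=turns,
        topic=dialogue.topic,
        distress=dialogue.distress,
    )


def transfer_learn(
    pretrained: DistressModel,
    cbt_corpus: Splits,
    config: Optional[ModelConfig] = None,
) -> tuple[DistressModel, TrainingLog]:
    """Adapt the pretrained encoder to in-session distress detection.

    The final fully connected (distress) layer is replaced with a fresh
    initialisation; encoder weights start from the pretrained values and
    are fine-tuned unless ``config.freeze_encoder``. Training sees only
    situation/mood/automatic-thought user turns.
    """
    if pretrained.provenance is not Provenance.PRETRAINED:
        raise ValueError("transfer_learn requires a pretrained (not transferred) model")
    config = config or pretrained.config
    train_view = [cbt_view(d) for d in cbt_corpus.train]
    val_view = [cbt_view(d) for d in cbt_corpus.val]
    _labels_ok(train_view)
    _labels_ok(val_view)

    ss = np.random.SeedSequence(config.seed + 1)
    head_rng, shuffle_rng = (np.random.default_rng(s) for s in ss.spawn(2))
    model = copy.deepcopy(pretrained)
    model.config = config
    model.provenance = Provenance.TRANSFERRED
    model.tasks = ("distress",)  # auxiliary heads dropped after transfer
    model.heads = {}
    model.reset_head("distress", head_rng)
    model._rng = np.random.default_rng(ss.spawn(1)[0])
    trainable = model.head_parameters()
    if not config.freeze_encoder:
        trainable = model.encoder_parameters() + trainable
    log = _fit(model, train_view, val_view, config, trainable, shuffle_rng)
    return model, log


def select_window(
    utterances: Sequence[Utterance],
    policy: WindowPolicy = WindowPolicy.CANONICAL_TYPES,
) -> list[Utterance]:
    """Choose the (at most) 3 utterances fed to the detector.

    ``canonical_types``: the most recent utterance of each canonical type
    when available, falling back to the last 3 user turns; ``last_user_turns``:
    literally the last 3 user turns.
    """
    users = [u for u in utterances if u.speaker is Speaker.USER]
    if policy is WindowPolicy.CANONICAL_TYPES:
        chosen: dict[UtteranceType, Utterance] = {}
        for u in users:
            if u.utterance_type in CANONICAL_TYPES:
                chosen[u.utterance_type] = u
        if chosen:
            picked = [chosen[t] for t in CANONICAL_TYPES if t in chosen]
            if len(picked) == 3:
                return picked
            # pad with the most recent remaining user turns, keep order
            extra = [u for u in users if u not in picked]
            return (picked + extra[::-1])[:3]
    return users[-3:]


def predict_distress(
    model: DistressModel, recent: Sequence[Utterance]
) -> tuple[DistressLabel, float]:
    """Binary distress inference on at most 3 recent utterances.

    Ties at p = 0.5 resolve to distressed (keep asking rather than stop
    early). Fewer than 3 utterances are allowed early in a session; no
    padding turns are fabricated.
    """
    if model.provenance is not Provenance.TRANSFERRED:
        raise ValueError("predict_distress requires a transferred model")
    recent = list(recent)
    if not 1 <= len(recent) <= 3:
        raise ValueError("predict_distress takes 1-3 utterances")
    dlg = LabeledDialogue(dialogue_id="_inference", turns=tuple(recent))
    p = model.predict_proba_distress(dlg)
    label = DistressLabel.DISTRESSED if p >= 0.5 else DistressLabel.NONDISTRESSED
    return label, p


def evaluate(
    model: DistressModel,
    test: Sequence[LabeledDialogue],
    averaging: Averaging = Averaging.BINARY_POSITIVE,
    restrict_to_cbt: bool = False,
) -> EvalMetrics:
    """Confusion-matrix metrics of the distress head on labeled dialogues."""
    test = list(test)
    if not test:
        raise ValueError("cannot evaluate on an empty test set")
    y_true, y_pred = [], []
    for d in test:
        if d.distress is None:
            continue
        view = cbt_view(d) if restrict_to_cbt else d
        p = model.predict_proba_distress(view)
        y_true.append(d.distress)
        y_pred.append(1 if p >= 0.5 else 0)
    if not y_true:
        raise ValueError("test set has no distress labels")
    return binary_eval(y_true, y_pred, averaging)


def tune_grid(
    daily_like: Splits | Sequence[LabeledDialogue],
    interview_like: Splits,
    base_config: ModelConfig,
    doc_layers_grid: Sequence[int] = (1, 2, 3),
    doc_hidden_grid: Sequence[int] = (128, 256, 512),
) -> tuple[DistressModel, TrainingLog, ModelConfig]:
    """Grid search over document-encoder depth and width, selecting by
    validation macro F1 of the depression task."""
    best = None
    for layers in doc_layers_grid:
        for hidden in doc_hidden_grid:
            cfg = replace(base_config, doc_layers=layers, doc_hidden=hidden)
            model, log = pretrain(daily_like, interview_like, cfg)
            idx = log.best_epoch()
            f1 = log.epochs[idx]["val_macro_f1"] if idx is not None else -1.0
            if best is None or f1 > best[0]:
                best = (f1, model, log, cfg)
    assert best is not None
    return best[1], best[2], best[3]
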