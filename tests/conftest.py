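import numpy as np
import pytest
from hypothesis import settings

from socratiq.model import ModelConfig, Splits, stratified_split
from socratiq.synth import (
    GeneratorParams,
    generate_cbt_corpus,
    generate_pretraining_corpora,
)

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


def small_config(seed: int = 7, **overrides) -> ModelConfig:
    """Narrow, fast classifier configuration used throughout the suite."""
    defaults = dict(
        embedding_dim=24,
        turn_hidden=24,
        doc_hidden=24,
        max_epochs=4,
        patience=2,
        seed=seed,
    )
    defaults.update(overrides)
    return ModelConfig(**defaults)


def split_by_label(dialogues, fractions, seed):
    tr, va, te = stratified_split(dialogues, fractions, seed, key=lambda d: d.distress)
    return Splits(tr, va, te)


@pytest.fixture(scope="session")
def gen_params() -> GeneratorParams:
    return GeneratorParams(seed=7)


@pytest.fixture(scope="session")
def small_corpora(gen_params):
    """Reduced pretraining corpora shared across training tests."""
    params = GeneratorParams(seed=7, n_dialogues=80)
    daily, interview = generate_pretraining_corpora(params)
    return daily, split_by_label(interview, (0.6, 0.2, 0.2), seed=7)


@pytest.fixture(scope="session")
def cbt_splits(gen_params):
    corpus = generate_cbt_corpus(GeneratorParams(seed=13))
    return split_by_label(corpus, (0.55, 0.19, 0.26), seed=13)


@pytest.fixture(scope="session")
def trained_models(small_corpora, cbt_splits):
    """One pretrained + one transferred model reused by several tests."""
    from socratiq.model import pretrain, transfer_learn

    daily, interview = small_corpora
    cfg = small_config(seed=7)
    pretrained, pre_log = pretrain(daily, interview, cfg)
    transferred, tr_log = transfer_learn(pretrained, cbt_splits, cfg)
    return {
        "pretrained": pretrained,
        "pre_log": pre_log,
        "transferred": transferred,
        "tr_log": tr_log,
    }


def bow_logistic_auc(train, test) -> float:
    """Independent bag-of-words logistic-regression oracle.

    Fits scikit-learn logistic regression on token-count vectors of the
    user turns and returns the held-out ROC AUC for the binary
    distress/depression label.
    """
    from sklearn.linear_model import LogisticRegression
    from sklearn.metrics import roc_auc_score

    vocab: dict[str, int] = {}
    for d in list(train) + list(test):
        for t in d.turns:
            for tok in t.text.split():
                vocab.setdefault(tok, len(vocab))

    def feats(dialogues):
        X = np.zeros((len(dialogues), len(vocab)))
        y = np.zeros(len(dialogues), dtype=int)
        for i, d in enumerate(dialogues):
            y[i] = d.distress
            for t in d.turns:
                for tok in t.text.split():
                    X[i, vocab[tok]] += 1
        return X, y

    Xtr, ytr = feats(list(train))
    Xte, yte = feats(list(test))
    clf = LogisticRegression(max_iter=2000).fit(Xtr, ytr)
    return float(roc_auc_score(yte, clf.predict_proba(Xte)[:, 1]))
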