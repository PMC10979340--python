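"""Checkpoint directory layout: config + vocabulary as JSON, parameters
as an .npz blob, and the training log as CSV."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .network import DistressModel, ModelConfig, Provenance, WindowPolicy
from .training import TrainingLog
from .vocab import Vocabulary


def save_checkpoint(model: DistressModel, log: TrainingLog, directory: str | Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cfg = dataclasses.asdict(model.config)
    cfg["window_policy"] = model.config.window_policy.value
    meta = {
        "config": cfg,
        "provenance": model.provenance.value,
        "tasks": list(model.tasks),
    }
    (directory / "config.json").write_text(json.dumps(meta, indent=2))
    (directory / "vocabulary.json").write_text(
        json.dumps(
            {"token_to_index": model.vocabulary.token_to_index,
             "min_count": model.vocabulary.min_count}
        )
    )
    np.savez(directory / "parameters.npz", **model.snapshot())
    pd.DataFrame(log.epochs).to_csv(directory / "training_log.csv", index=False)
    return directory


def load_checkpoint(directory: str | Path) -> tuple[DistressModel, TrainingLog]:
    directory = Path(directory)
    if not (directory / "config.json").exists():
        raise FileNotFoundError(f"no checkpoint at {directory}: missing config.json")
    meta = json.loads((directory / "config.json").read_text())
    cfg_dict = dict(meta["config"])
    cfg_dict["window_policy"] = WindowPolicy(cfg_dict["window_policy"])
    config = ModelConfig(**cfg_dict)
    vocab_d = json.loads((directory / "vocabulary.json").read_text())
    vocab = Vocabulary(token_to_index=vocab_d["token_to_index"],
                       min_count=vocab_d["min_count"])
    model = DistressModel(
        vocab, config, tasks=tuple(meta["tasks"]),
        provenance=Provenance(meta["provenance"]),
    )
    snap = dict(np.load(directory / "parameters.npz"))
    model.load_snapshot(snap)
    log = TrainingLog()
    log_path = directory / "training_log.csv"
    if log_path.exists():
        df = pd.read_csv(log_path)
        log.epochs = df.to_dict("records")
    return model, log
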