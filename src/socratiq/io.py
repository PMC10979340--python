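"""Artifact I/O: JSONL streams, CSV tables, run configuration.

Every artifact begins with a metadata header carrying the tool version,
the hash of the effective configuration and the seed, so downstream
steps can refuse to mix artifacts from different runs. CSV and
plain-text artifacts use ``#``-prefixed header lines; JSONL streams use
a leading ``{"_meta": ...}`` record. Writes are atomic (temp file +
rename).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
import yaml

from . import __version__
from .dialogue import LabeledDialogue, dialogue_from_dict, dialogue_to_dict
from .model.network import ModelConfig, WindowPolicy
from .synth import GeneratorParams


def desk_scale_model_config(seed: int = 0) -> ModelConfig:
    """Reduced classifier configuration for CPU pipeline runs.

    The synthetic corpora are separable by narrow models, so the
    pipeline default trades the reference widths (128) for minutes of
    wall time; pass an explicit ModelConfig to train at full width.
    """
    return ModelConfig(
        embedding_dim=32,
        turn_hidden=32,
        doc_hidden=32,
        max_epochs=8,
        patience=2,
        seed=seed,
    )


@dataclass(frozen=True)
class RunConfig:
    """Single source of truth for a pipeline run."""

    seed: int = 0
    out_dir: str = "runs"
    pool_path: Optional[str] = None
    n_adapted: int = 25
    n_random: int = 24
    gate_retry_limit: int = 2
    shuffle_pool: bool = False
    window_policy: str = "canonical_types"
    generator: GeneratorParams = field(default_factory=GeneratorParams)
    model: ModelConfig = field(default_factory=desk_scale_model_config)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["model"]["window_policy"] = self.model.window_policy.value
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        gen = d.pop("generator", {})
        mdl = d.pop("model", {})
        if "window_policy" in mdl:
            mdl["window_policy"] = WindowPolicy(mdl["window_policy"])
        return cls(
            generator=GeneratorParams(**gen), model=ModelConfig(**mdl), **d
        )

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(data)


def dump_config(config: RunConfig, path: str | Path) -> None:
    _atomic_write(path, yaml.safe_dump(config.to_dict(), sort_keys=True))


def _meta(config: Optional[RunConfig], seed: Optional[int]) -> dict:
    return {
        "tool": "socratiq",
        "version": __version__,
        "config_hash": config.config_hash if config else None,
        "seed": seed if seed is not None else (config.seed if config else None),
    }


def _atomic_write(path: str | Path, text: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    try:
        with os.fdopen(fd, "w", encoding="utf-8") as fh:
            fh.write(text)
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def header_lines(config: Optional[RunConfig] = None, seed: Optional[int] = None) -> str:
    m = _meta(config, seed)
    return (
        f"# tool: {m['tool']} {m['version']}\n"
        f"# config_hash: {m['config_hash']}\n"
        f"# seed: {m['seed']}\n"
    )


def read_header(path: str | Path) -> dict:
    """Parse the ``#``-prefixed metadata header of a CSV/text artifact."""
    meta: dict = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].partition(":")
            meta[key.strip()] = val.strip()
    return meta


# -- JSONL -------------------------------------------------------------------


def write_jsonl(path: str | Path, records: Iterable[dict],
                config: Optional[RunConfig] = None, seed: Optional[int] = None) -> None:
    lines = [json.dumps({"_meta": _meta(config, seed)})]
    lines += [json.dumps(r) for r in records]
    _atomic_write(path, "\n".join(lines) + "\n")


def read_jsonl(path: str | Path) -> tuple[dict, list[dict]]:
    records, meta = [], {}
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line:
                continue
            obj = json.loads(line)
            if i == 0 and "_meta" in obj:
                meta = obj["_meta"]
            else:
                records.append(obj)
    return meta, records


def write_dialogues(path: str | Path, dialogues: Iterable[LabeledDialogue],
                    config: Optional[RunConfig] = None, seed: Optional[int] = None) -> None:
    write_jsonl(path, (dialogue_to_dict(d) for d in dialogues), config, seed)


def read_dialogues(path: str | Path) -> list[LabeledDialogue]:
    _, records = read_jsonl(path)
    return [dialogue_from_dict(r) for r in records]


# -- CSV tables -----------------------------------------------------------------


def write_table(path: str | Path, df: pd.DataFrame,
                config: Optional[RunConfig] = None, seed: Optional[int] = None) -> None:
    df = df.copy()
    if "detections" in df.columns:
        df["detections"] = df["detections"].apply(json.dumps)
    _atomic_write(path, header_lines(config, seed) + df.to_csv(index=False))


def read_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    if "detections" in df.columns:
        df["detections"] = df["detections"].apply(json.loads)
    if "estimated_questions" in df.columns:
        df["estimated_questions"] = df["estimated_questions"].apply(
            lambda v: v if v == "censored" else int(v)
        )
    return df
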