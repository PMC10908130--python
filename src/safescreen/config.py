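"""YAML/JSON run configuration.

A run config bundles everything needed to replay a run bit-identically:
where the corpus comes from (a file, or a synthetic-corpus spec), the model
and oracle choices, the stopping thresholds and the master seed.  The
``simulate`` command echoes the fully resolved config (defaults included)
into the output directory.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .engine import SafeConfig
from .synthetic import CorpusSpec


@dataclass
class RunConfig:
    safe: SafeConfig = field(default_factory=SafeConfig)
    corpus_path: str | None = None
    corpus_format: str = "csv"
    label_column: str = "label"
    corpus_spec: CorpusSpec | None = None
    output_dir: str = "safescreen_run"

    def to_dict(self) -> dict:
        return {
            "safe": self.safe.to_dict(),
            "corpus": {
                "path": self.corpus_path,
                "format": self.corpus_format,
                "label_column": self.label_column,
                "spec": self.corpus_spec.to_dict() if self.corpus_spec else None,
            },
            "output_dir": self.output_dir,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        corpus = d.get("corpus", {}) or {}
        spec = corpus.get("spec")
        return cls(
            safe=SafeConfig.from_dict(d.get("safe", {}) or {}),
            corpus_path=corpus.get("path"),
            corpus_format=corpus.get("format", "csv"),
            label_column=corpus.get("label_column", "label"),
            corpus_spec=CorpusSpec.from_dict(spec) if spec else None,
            output_dir=d.get("output_dir", "safescreen_run"),
        )


def load_run_config(path: str | Path) -> RunConfig:
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return RunConfig.from_dict(data)


def dump_run_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
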