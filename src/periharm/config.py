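"""Pipeline configuration: paths to resource files, context-window settings
and behaviour switches, loadable from YAML."""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    # resource files; None means the packaged defaults
    lexicon_dir: str | None = None
    rules_file: str | None = None
    exceptions_file: str | None = None
    headers_file: str | None = None
    # contextual-search window
    window_width: int = 10
    sentence_bounded_window: bool = False
    # behaviour switches
    paper_faithful_mode: bool = False   # trailing modals demote status unconditionally
    emit_uncertain: bool = False        # reserved: the shipped rules never emit it
    heuristic_k: int = 2                # >=k true mentions to flag a service user
    distinct_documents: bool = False    # require the k mentions in distinct notes
    span_match_mode: str = "exact"      # exact | overlap
    seed: int = 0                       # synthetic-corpus generation

    def __post_init__(self) -> None:
        if self.window_width < 0:
            raise ValueError("window_width must be non-negative")
        if self.heuristic_k < 1:
            raise ValueError("heuristic_k must be positive")
        if self.span_match_mode not in {"exact", "overlap"}:
            raise ValueError("span_match_mode must be 'exact' or 'overlap'")
        for name in ("lexicon_dir", "rules_file", "exceptions_file", "headers_file"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name} does not exist: {p}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {', '.join(sorted(unknown))}")
        return cls(**data)
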