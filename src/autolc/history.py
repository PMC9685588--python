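"""Run-history persistence and progress reporting.

A run's history is one record per method-development iteration: the
program that ran, how it scored, and bookkeeping (tracked/modeled analyte
counts, whether a retrack happened).  Histories serialize to a directory
with ``history.jsonl`` plus per-MDI CSV tables, and stream to any sink as
JSON lines while the loop runs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

from .optimize_bo import BOMDIRecord
from .optimize_rm import MDIRecord

__all__ = ["RunHistory", "report_progress"]

log = logging.getLogger("autolc")


@dataclass
class RunHistory:
    """Per-MDI records plus the immutable run context."""

    records: list[dict] = field(default_factory=list)
    config_snapshot: dict = field(default_factory=dict)
    master_seed: int | None = None
    strategy: str = ""

    def append(self, record: dict) -> None:
        expected = len(self.records) + 1
        if record.get("mdi") != expected:
            raise ValueError(f"MDI indices must be contiguous: expected {expected}")
        self.records.append(record)

    @classmethod
    def from_rm(
        cls, mdi_records: Sequence[MDIRecord], config_snapshot: dict, master_seed: int
    ) -> "RunHistory":
        hist = cls(config_snapshot=config_snapshot, master_seed=master_seed, strategy="rm")
        for rec in mdi_records:
            entry = {
                "mdi": rec.index,
                "kind": rec.kind,
                "program": rec.program.to_dict(),
                "achieved": rec.achieved.to_dict(),
                "n_tracked": rec.n_tracked,
                "n_modeled": rec.n_modeled,
                "retracked": rec.retracked,
            }
            if rec.predicted is not None:
                entry["predicted"] = rec.predicted.to_dict()
            hist.append(entry)
        return hist

    @classmethod
    def from_bo(
        cls, mdi_records: Sequence[BOMDIRecord], config_snapshot: dict, master_seed: int
    ) -> "RunHistory":
        hist = cls(config_snapshot=config_snapshot, master_seed=master_seed, strategy="bo")
        for rec in mdi_records:
            hist.append(
                {
                    "mdi": rec.index,
                    "kind": "bo",
                    "program": rec.program.to_dict(),
                    "params": {
                        "phi_A": rec.params.phi_A,
                        "phi_B": rec.params.phi_B,
                        "t_A": rec.params.t_A,
                        "t_B": rec.params.t_B,
                    },
                    "n_peaks": rec.n_peaks,
                    "connected_components": rec.n_connected_components,
                    "product_rs": rec.prod_rs,
                    "objective": rec.objective,
                }
            )
        return hist

    def to_jsonl(self) -> str:
        return "\n".join(json.dumps(r) for r in self.records) + ("\n" if self.records else "")

    def save(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "history.jsonl").write_text(self.to_jsonl())
        meta = {
            "strategy": self.strategy,
            "master_seed": self.master_seed,
            "config": self.config_snapshot,
        }
        (out / "run.json").write_text(json.dumps(meta, indent=2))
        return out


def report_progress(history: RunHistory, sink: Callable[[str], None] | Path | str) -> None:
    """Emit one JSON line per MDI to ``sink`` (callable, path, or file-like).

    Sink failures are logged and swallowed: reporting must never kill a
    running optimization.
    """
    if not history.records:
        raise ValueError("history is empty")
    lines = [json.dumps(r) for r in history.records]
    try:
        if callable(sink):
            for line in lines:
                sink(line)
        elif isinstance(sink, (str, Path)):
            Path(sink).write_text("\n".join(lines) + "\n")
        else:
            for line in lines:
                sink.write(line + "\n")
    except Exception as exc:
        log.warning("progress sink failed: %r", exc)
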