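"""Build-report bookkeeping shared by every pipeline stage.

Each stage increments named counters and records skipped/rejected items
with a reason; the pipeline serializes the whole report as JSON so a run
is auditable without re-parsing logs.
"""
from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field


@dataclass
class BuildReport:
    counts: Counter = field(default_factory=Counter)
    entries: list[tuple[str, str, str]] = field(default_factory=list)
    _once: set[tuple[str, str]] = field(default_factory=set)

    def count(self, stage: str, n: int = 1) -> None:
        self.counts[stage] += n

    def skip(self, stage: str, item: str, reason: str) -> None:
        """Record a skipped/rejected item and bump the stage's skip counter."""
        self.entries.append((stage, item, reason))
        self.counts[stage] += 1

    def skip_once(self, stage: str, item: str, reason: str) -> None:
        """Like :meth:`skip` but at most one entry per (stage, item)."""
        key = (stage, item)
        if key in self._once:
            return
        self._once.add(key)
        self.skip(stage, item, reason)

    def to_dict(self) -> dict:
        return {
            "counts": dict(sorted(self.counts.items())),
            "entries": [list(e) for e in self.entries],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n"

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for stage, item, reason in self.entries:
                fh.write(f"{stage}\t{item}\t{reason}\n")
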