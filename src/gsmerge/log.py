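"""Replayable decision log.

Every change made to a consensus model — automatic or user-chosen — is
recorded as an ordered action entry.  Replaying the log on the same input
models re-applies exactly the same actions in the same order, reproducing
the refined model bit-for-bit.  Entries are ordered by sequence number, not
wall clock, so replay is deterministic.

The log stores a digest of the input models' entity ids; replay refuses to
run against inputs that do not match (stale-log protection).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, TYPE_CHECKING

if TYPE_CHECKING:  # pragma: no cover
    from .model import Model


@dataclass
class LogEntry:
    seq: int
    op: str
    args: dict
    origin: str = "auto"  # auto | user

    def to_json(self) -> str:
        return json.dumps(
            {"seq": self.seq, "op": self.op, "args": self.args,
             "origin": self.origin},
            sort_keys=True,
        )


class StaleLogError(RuntimeError):
    """The log was recorded against different input models."""


@dataclass
class DecisionLog:
    input_digests: list[str] = field(default_factory=list)
    entries: list[LogEntry] = field(default_factory=list)

    def record(self, op: str, args: dict, origin: str = "auto") -> LogEntry:
        entry = LogEntry(seq=len(self.entries), op=op, args=args, origin=origin)
        self.entries.append(entry)
        return entry

    # -- persistence (line-delimited JSON) -----------------------------------

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(json.dumps({"input_digests": self.input_digests}) + "\n")
            for entry in self.entries:
                fh.write(entry.to_json() + "\n")

    @staticmethod
    def load(path: str | Path) -> "DecisionLog":
        with open(path) as fh:
            header = json.loads(fh.readline())
            log = DecisionLog(input_digests=header.get("input_digests", []))
            for line in fh:
                if not line.strip():
                    continue
                d = json.loads(line)
                log.entries.append(
                    LogEntry(seq=d["seq"], op=d["op"], args=d["args"],
                             origin=d.get("origin", "auto")))
        log.entries.sort(key=lambda e: e.seq)
        return log


# ---------------------------------------------------------------------------
# Action registry: op name -> mutator(Model, args).  Modules that implement
# model mutations register them here so the log can be replayed without the
# log module depending on them.
# ---------------------------------------------------------------------------

ACTIONS: dict[str, Callable[["Model", dict], None]] = {}


def action(name: str) -> Callable:
    def deco(fn: Callable[["Model", dict], None]) -> Callable:
        ACTIONS[name] = fn
        return fn
    return deco


def apply_entry(model: "Model", entry: LogEntry) -> None:
    try:
        fn = ACTIONS[entry.op]
    except KeyError:
        raise KeyError(f"unknown logged operation {entry.op!r}") from None
    fn(model, entry.args)


def check_inputs(log: DecisionLog, models: list["Model"]) -> None:
    digests = [m.entity_digest() for m in models]
    if digests != log.input_digests:
        raise StaleLogError(
            "decision log was recorded against different inputs "
            f"(expected digests {log.input_digests}, got {digests})")
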