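"""Inconsistency records shared by the detection modules."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path


@dataclass
class InconsistencyRecord:
    """One detected inconsistency instance.

    ``klass`` names the inconsistency class (identical_net, alt_stoich,
    redox, nested, similar, lumped, alt_transport, invalid_transport,
    alt_compartment, unknown_compartment, invalid_boundary, met_conflict).
    ``members`` are the involved reaction ids (or metabolite keys rendered
    as ``id@compartment``).  ``status`` tracks the resolution lifecycle.
    """

    klass: str
    members: tuple[str, ...]
    resolution: str = ""
    status: str = "pending"   # pending | auto-resolved | user-resolved
    detail: dict = field(default_factory=dict)


def write_report(records: list[InconsistencyRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("class\tmember_ids\tstatus\tresolution\n")
        for rec in records:
            fh.write(f"{rec.klass}\t{';'.join(rec.members)}\t"
                     f"{rec.status}\t{rec.resolution}\n")
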