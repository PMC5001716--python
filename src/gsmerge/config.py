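"""Run configuration: every tunable in one serialisable place.

Defaults follow the published method settings where those exist (growth
cutoffs 1e-6 absolute / 30% relative, lumped-set size cap 5, redox
co-occurrence threshold 0.8); the rest are this tool's own documented
choices.  The configuration used for a run is written next to its outputs
so the run is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .namespace import DEFAULT_COMPARTMENT_ALIASES
from .reactions import DEFAULT_PROTON_WATER_IDS, DEFAULT_REDOX_PAIRS


@dataclass
class Config:
    match_percentile: float = 5.0          # threshold percentile for matching
    wt_growth_cutoff: float = 1e-6         # absolute wild-type growth cutoff
    mutant_relative_cutoff: float = 0.30   # minimal relative mutant growth
    max_lumped_size: int = 5               # lumped-set size cap
    redox_suggest_threshold: float = 0.8   # co-occurrence fraction
    gpr_mode: str = "union"                # union | strict
    direction_mode: str = "consensus-then-reversible"
    proton_water_ids: list[str] = field(
        default_factory=lambda: sorted(DEFAULT_PROTON_WATER_IDS))
    redox_pairs: list[list[str]] = field(
        default_factory=lambda: [sorted(p) for p in DEFAULT_REDOX_PAIRS])
    compartment_aliases: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_COMPARTMENT_ALIASES))
    overlap_convention: str = "union"      # union | min
    auto_confirm_matches: bool = False
    seed: int = 0

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @staticmethod
    def load(path: str | Path) -> "Config":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return Config(**data)

    def merge_policy(self):
        from .reactions import MergePolicy
        return MergePolicy(gpr_mode=self.gpr_mode,
                           direction_mode=self.direction_mode,
                           proton_water_ids=frozenset(self.proton_water_ids))

    def redox_pair_list(self):
        from .reactions import RedoxPairList
        return RedoxPairList([frozenset(p) for p in self.redox_pairs])
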