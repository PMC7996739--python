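"""Pipeline configuration: every filter threshold, with defaults.

Defaults implement the published filter cascade for canonical animal
miRNA precursors: E-value <= 0.01, coverage >= 70%, HSP length >= 20 nt,
precursor length <= 200 nt, MFE <= -10 kcal/mol, tree edit distance <= 7,
CM bitscore > log2(2N) with the nBit >= 0.32*ge rescue, and a per-family
candidate cap of 100 by bitscore.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class Thresholds:
    """Numeric cutoffs of the filter cascade (units in field names)."""

    evalue_max: float = 0.01              # all engines
    coverage_min: float = 0.70            # blast (query) and cm (model) hits
    hsp_min_length: int = 20              # nt, blast hits
    nbit_factor: float = 0.32             # bitscore / gathering-cutoff rescue
    candidate_cap: int = 100              # per family, by best bitscore
    precursor_max_length: int = 200       # nt
    mfe_max: float = -10.0                # kcal/mol; accept iff mfe <= mfe_max
    mfe_inclusive: bool = True            # boundary behaviour of the MFE test
    ted_max: int = 7                      # tree edit distance for High confidence
    loop_overlap_tolerance: int = 3       # nt a mature may reach into the loop
    mature_score_fraction: float = 0.6    # score floor = fraction * mature length
    match_score: float = 1.0              # mature anchoring alignment scores
    mismatch_score: float = -1.0
    gap_score: float = -2.0
    trim_flank: int = 10                  # nt kept either side of miR/miR*
    consensus_min_pair_fraction: float = 1.0   # row support needed to keep a pair
    css_pair_retention_min: float = 0.5   # fraction of default pairs for valid CSS
    candidate_flank: int = 30             # nt of genomic context excised per region


@dataclass
class PipelineConfig:
    thresholds: Thresholds = field(default_factory=Thresholds)
    genome_size: int | None = None        # override; default = total FASTA length
    modes: tuple[str, ...] = ("blast", "hmm", "cm")
    engine_args: dict = field(default_factory=dict)  # free-form extra CLI args

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        thr = Thresholds(**raw.get("thresholds", {}))
        return cls(
            thresholds=thr,
            genome_size=raw.get("genome_size"),
            modes=tuple(raw.get("modes", ("blast", "hmm", "cm"))),
            engine_args=raw.get("engine_args", {}),
        )

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "thresholds": dataclasses.asdict(self.thresholds),
            "genome_size": self.genome_size,
            "modes": list(self.modes),
            "engine_args": self.engine_args,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)
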