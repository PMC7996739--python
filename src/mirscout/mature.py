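"""Mature miR / miR* placement on candidate precursors.

Each family's annotated mature sequences are anchored on the candidate
precursor by semi-global alignment (the mature aligned end-to-end, free
end gaps on the precursor).  The precursor is then trimmed to the span
of miR and miR* plus a flank, and placements inconsistent with a single
stem-loop (loop overlap, multi-loop, both matures on one arm) are
rejected by the structural arm check.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

from Bio import Align

from .config import Thresholds
from .homology import FamilyCutoffs
from .intervals import GenomicInterval
from .formats_io import StockholmAlignment
from .structure import check_arm_consistency, fold_mfe, pair_table

__all__ = [
    "MatureSequence",
    "MirnaFamily",
    "MaturePlacement",
    "locate_mature",
    "trim_precursor",
    "check_arm_consistency",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class MatureSequence:
    """One annotated mature product; arm parsed from -5p/-3p id suffixes."""

    mature_id: str
    sequence: str  # RNA
    arm: str = "unknown"  # 5p | 3p | unknown

    @staticmethod
    def from_fasta_record(name: str, seq: str) -> "MatureSequence":
        arm = "unknown"
        lowered = name.lower()
        if lowered.endswith("-5p"):
            arm = "5p"
        elif lowered.endswith("-3p"):
            arm = "3p"
        return MatureSequence(name, seq.upper().replace("T", "U"), arm)


@dataclass
class MirnaFamily:
    """Query bundle for one miRNA family: structure-annotated precursor
    alignment, mature miR/miR* sequences and score cutoffs."""

    family_id: str
    precursor_alignment: StockholmAlignment
    mature_sequences: list[MatureSequence]
    cutoffs: FamilyCutoffs | None = None

    def __post_init__(self) -> None:
        if not self.mature_sequences:
            raise ValueError(f"family {self.family_id}: needs >= 1 mature sequence")
        for m in self.mature_sequences:
            if not 15 <= len(m.sequence) <= 30:
                raise ValueError(
                    f"mature {m.mature_id}: length {len(m.sequence)} outside [15, 30]"
                )

    @property
    def precursor_sequences(self) -> list[tuple[str, str]]:
        """Degapped alignment rows — the homology-search queries."""
        return [(name, row.replace("-", "")) for name, row in self.precursor_alignment.rows.items()]


@dataclass
class MaturePlacement:
    """Positions of miR and miR* on a candidate precursor (0-based
    half-open on the oriented precursor sequence)."""

    precursor_sequence: str
    mir_interval: tuple[int, int]
    mirstar_interval: tuple[int, int] | None
    mir_arm: str  # 5p | 3p
    alignment_score: float
    source_mature_id: str

    def __post_init__(self) -> None:
        n = len(self.precursor_sequence)
        for iv in (self.mir_interval, self.mirstar_interval):
            if iv is None:
                continue
            if not (0 <= iv[0] < iv[1] <= n):
                raise ValueError(f"interval {iv} outside precursor bounds [0, {n})")
        if self.mirstar_interval is not None:
            a, b = sorted([self.mir_interval, self.mirstar_interval])
            if a[1] > b[0]:
                raise ValueError("miR and miR* intervals must be disjoint")


def _semi_global_aligner(thr: Thresholds) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = thr.match_score
    aligner.mismatch_score = thr.mismatch_score
    aligner.open_gap_score = thr.gap_score
    aligner.extend_gap_score = thr.gap_score
    # free end gaps on the precursor: the mature aligns end-to-end
    # (an end "deletion" leaves precursor characters unaligned)
    aligner.end_deletion_score = 0.0
    return aligner


def _best_placement(
    precursor: str, mature: str, aligner: Align.PairwiseAligner
) -> tuple[float, tuple[int, int]]:
    """Best semi-global placement; the 5'-most among equal-scoring ones."""
    alignments = aligner.align(precursor, mature)
    score = alignments.score
    # inspect a bounded number of co-optimal placements for determinism
    best_iv: tuple[int, int] | None = None
    for aln in itertools.islice(alignments, 16):
        blocks = aln.aligned[0]
        if len(blocks) == 0:
            continue
        iv = (int(blocks[0][0]), int(blocks[-1][1]))
        if best_iv is None or iv < best_iv:
            best_iv = iv
    if best_iv is None:
        return float("-inf"), (0, 0)
    return float(score), best_iv


def locate_mature(
    precursor: str,
    family: MirnaFamily,
    thresholds: Thresholds | None = None,
) -> MaturePlacement | None:
    """Place the family's mature sequences on a candidate precursor.

    Every mature is aligned semi-globally (match +1, mismatch -1, gap
    -2 by default); the best placement wins if its score reaches
    0.6 x mature length, else the candidate has no mature anchor and is
    rejected downstream.  When no annotated miR* aligns, the miR*
    interval is predicted as the base-paired window on the opposite arm
    of the MFE structure.  Ties between arms resolve to the 5' arm.
    """
    thr = thresholds or Thresholds()
    if len(precursor) < 40:
        return None
    precursor = precursor.upper().replace("T", "U")
    aligner = _semi_global_aligner(thr)

    scored: list[tuple[float, tuple[int, int], MatureSequence]] = []
    for mat in family.mature_sequences:
        score, iv = _best_placement(precursor, mat.sequence, aligner)
        if score >= thr.mature_score_fraction * len(mat.sequence):
            scored.append((score, iv, mat))
    if not scored:
        return None

    # best score; ties resolve to the 5'-most placement (5p arm)
    scored.sort(key=lambda t: (-t[0], t[1]))
    best_score, mir_iv, mir_mat = scored[0]
    if len(scored) > 1 and scored[1][0] == best_score and scored[1][1] != mir_iv:
        log.debug(
            "mature placement tie for %s on candidate; keeping 5'-most", mir_mat.mature_id
        )

    fold = fold_mfe(precursor)
    pt = pair_table(fold.dotbracket)
    mir_mid = sum(mir_iv) / 2
    mir_arm = "5p" if mir_mid < len(precursor) / 2 else "3p"

    # an annotated mature on the opposite arm, non-overlapping, is the miR*
    mirstar_iv = None
    star_id = None
    for score, iv, mat in scored[1:]:
        opposite = (sum(iv) / 2 < len(precursor) / 2) != (mir_arm == "5p")
        if opposite and (iv[1] <= mir_iv[0] or iv[0] >= mir_iv[1]):
            mirstar_iv, star_id = iv, mat.mature_id
            break

    if mirstar_iv is None:
        partners = [pt[i] for i in range(*mir_iv) if 0 <= i < len(pt) and pt[i] >= 0]
        partners = [p for p in partners if p < mir_iv[0] or p >= mir_iv[1]]
        if partners:
            candidate_iv = (min(partners), max(partners) + 1)
            # keep only if it forms a clean window on one side of the miR
            if candidate_iv[1] <= mir_iv[0] or candidate_iv[0] >= mir_iv[1]:
                mirstar_iv = candidate_iv

    return MaturePlacement(
        precursor_sequence=precursor,
        mir_interval=mir_iv,
        mirstar_interval=mirstar_iv,
        mir_arm=mir_arm,
        alignment_score=best_score,
        source_mature_id=mir_mat.mature_id + (f"+{star_id}" if star_id else ""),
    )


def trim_precursor(
    candidate_interval: GenomicInterval,
    placement: MaturePlacement,
    flank: int = 10,
    sequence_length: int | None = None,
    opposite_arm_reach: int = 70,
) -> GenomicInterval:
    """Trim/extend the genomic candidate to span miR and miR* + flank.

    Placement coordinates live on the oriented (5'->3') excised
    precursor; minus-strand candidates map back through the reverse
    complement.  With no miR*, the span reaches ``opposite_arm_reach`` +
    flank nt from the miR toward the predicted opposite arm.  Clipped to
    the chromosome; idempotent once the span is stable.
    """
    mir = placement.mir_interval
    if placement.mirstar_interval is not None:
        lo = min(mir[0], placement.mirstar_interval[0]) - flank
        hi = max(mir[1], placement.mirstar_interval[1]) + flank
    elif placement.mir_arm == "5p":
        lo, hi = mir[0] - flank, mir[1] + opposite_arm_reach + flank
    else:
        lo, hi = mir[0] - opposite_arm_reach - flank, mir[1] + flank
    lo = max(0, lo)
    hi = min(hi, len(placement.precursor_sequence))

    iv = candidate_interval
    if iv.strand == "+":
        start, end = iv.start + lo, iv.start + hi
    else:
        start, end = iv.end - hi, iv.end - lo
    start = max(0, start)
    if sequence_length is not None:
        end = min(end, sequence_length)
    return GenomicInterval(iv.sequence_id, start, end, iv.strand)
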