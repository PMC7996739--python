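"""Homology stage: hit filtering, region aggregation, strand resolution.

Raw hits from the three search engines (blastn pairwise search, nhmmer
profile-HMM search, cmsearch covariance-model search) are filtered with
engine-specific score cutoffs, aggregated into extended candidate regions
by transitive interval overlap, disambiguated between strands, merged
across engines, and capped per family at the best bitscores.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .config import Thresholds
from .intervals import GenomicInterval

log = logging.getLogger(__name__)

ENGINES = ("blast", "hmm", "cm")


@dataclass(frozen=True)
class HomologyHit:
    """One raw hit from a homology search engine.

    ``coverage`` is the aligned fraction of the query sequence (blast) or
    of the profile/model (hmm, cm); ``None`` when the query/model length
    was unavailable at parse time, in which case coverage filters do not
    evaluate it.
    """

    interval: GenomicInterval
    family_id: str
    engine: str
    evalue: float
    bitscore: float
    hsp_length: int
    coverage: float | None = None

    def __post_init__(self) -> None:
        if self.engine not in ENGINES:
            raise ValueError(f"unknown engine {self.engine!r}")
        if self.hsp_length < 1:
            raise ValueError("hsp_length must be >= 1")
        if self.coverage is not None and not 0.0 <= self.coverage <= 1.0:
            raise ValueError(f"coverage must lie in [0, 1], got {self.coverage}")


@dataclass(frozen=True)
class FamilyCutoffs:
    """Per-family score context: Rfam-style gathering cutoff and genome size.

    The gathering cutoff (ge) is the curated bitscore separating family
    members from non-members; the genome size N sets the uniform
    log2(2N) bitscore threshold for CM hits.
    """

    genome_size: int
    gathering_cutoff: float | None = None

    def __post_init__(self) -> None:
        if self.genome_size <= 0:
            raise ValueError("genome_size must be positive")
        if self.gathering_cutoff is not None and self.gathering_cutoff <= 0:
            raise ValueError("gathering cutoff must be positive when present")

    @property
    def bitscore_threshold(self) -> float:
        return math.log2(2 * self.genome_size)


@dataclass
class CandidateRegion:
    """A merged, strand-resolved candidate precursor locus."""

    interval: GenomicInterval
    family_id: str
    supporting_hits: list[HomologyHit] = field(default_factory=list)
    status: str = "candidate"  # candidate | potential | rejected_strand

    @property
    def best_bitscore(self) -> float:
        return max(h.bitscore for h in self.supporting_hits)

    @property
    def best_evalue(self) -> float:
        return min(h.evalue for h in self.supporting_hits)

    @property
    def best_coverage(self) -> float:
        covs = [h.coverage for h in self.supporting_hits if h.coverage is not None]
        return max(covs) if covs else 0.0

    @property
    def engines(self) -> tuple[str, ...]:
        return tuple(sorted({h.engine for h in self.supporting_hits}))


def filter_sequence_hits(
    hits: Iterable[HomologyHit], thresholds: Thresholds | None = None
) -> list[HomologyHit]:
    """Sequence-homology filter for pairwise (blast) hits.

    Keeps exactly the hits with E-value <= 0.01, HSP length >= 20 nt and
    query coverage >= 70% (boundaries inclusive; thresholds from config).
    """
    thr = thresholds or Thresholds()
    kept = []
    for h in hits:
        if h.evalue > thr.evalue_max:
            continue
        if h.hsp_length < thr.hsp_min_length:
            continue
        if h.coverage is not None and h.coverage < thr.coverage_min:
            continue
        kept.append(h)
    return kept


def filter_hmm_hits(
    hits: Iterable[HomologyHit], thresholds: Thresholds | None = None
) -> list[HomologyHit]:
    """Filter for nhmmer hits: the engine's own inclusion threshold is
    assumed applied upstream; here only E-value <= 0.01 is enforced (no
    coverage test for the HMM path)."""
    thr = thresholds or Thresholds()
    return [h for h in hits if h.evalue <= thr.evalue_max]


def filter_cm_hits(
    hits: Iterable[HomologyHit],
    cutoffs: FamilyCutoffs,
    thresholds: Thresholds | None = None,
) -> list[HomologyHit]:
    """Alignment-score filter for covariance-model hits.

    A hit is kept iff E-value <= 0.01 AND model coverage >= 70% AND its
    bitscore clears the uniform log2(2N) genome-size threshold, OR —
    when a family gathering cutoff ge is available — the normalised
    bitscore nBit = bitscore/ge reaches 0.32, rescuing candidates below
    the uniform cutoff that plausibly represent valid miRNAs.
    """
    thr = thresholds or Thresholds()
    uniform = cutoffs.bitscore_threshold
    kept = []
    for h in hits:
        if h.evalue > thr.evalue_max:
            continue
        if h.coverage is not None and h.coverage < thr.coverage_min:
            continue
        ok = h.bitscore > uniform
        if not ok and cutoffs.gathering_cutoff is not None:
            ok = h.bitscore / cutoffs.gathering_cutoff >= thr.nbit_factor
        if ok:
            kept.append(h)
    return kept


def merge_hits_to_regions(hits: Sequence[HomologyHit]) -> list[CandidateRegion]:
    """Aggregate overlapping same-strand hits into extended regions.

    Hits on the same sequence and strand whose intervals share >= 1 nt
    (after transitive closure) form one region spanning their union.
    Output is sorted by (sequence_id, start); the result is independent
    of the input order.
    """
    by_key: dict[tuple[str, str, str], list[HomologyHit]] = {}
    for h in hits:
        by_key.setdefault(
            (h.family_id, h.interval.sequence_id, h.interval.strand), []
        ).append(h)

    regions: list[CandidateRegion] = []
    for (family_id, seq_id, strand), group in by_key.items():
        group = sorted(group, key=lambda h: (h.interval.start, h.interval.end))
        current: list[HomologyHit] = []
        cur_start = cur_end = None
        for h in group:
            if current and h.interval.start < cur_end:  # half-open overlap
                current.append(h)
                cur_end = max(cur_end, h.interval.end)
            else:
                if current:
                    regions.append(
                        CandidateRegion(
                            GenomicInterval(seq_id, cur_start, cur_end, strand),
                            family_id,
                            current,
                        )
                    )
                current = [h]
                cur_start, cur_end = h.interval.start, h.interval.end
        if current:
            regions.append(
                CandidateRegion(
                    GenomicInterval(seq_id, cur_start, cur_end, strand),
                    family_id,
                    current,
                )
            )
    regions.sort(key=lambda r: (r.interval.sequence_id, r.interval.start, r.interval.strand))
    return regions


def disambiguate_strand(
    region_plus: CandidateRegion, region_minus: CandidateRegion
) -> tuple[CandidateRegion, CandidateRegion]:
    """Pick the reading direction for a locus detected on both strands.

    The winner is chosen lexicographically by (higher best bitscore,
    lower best E-value, higher best coverage) — the quality measures the
    covariance-model engine reports.  The loser is kept with status
    ``rejected_strand`` so it still appears in the reports.  An exact tie
    on all three keeps the + strand and logs a warning.
    """
    plus, minus = region_plus, region_minus
    if plus.interval.strand == "-" and minus.interval.strand == "+":
        plus, minus = minus, plus
    key_plus = (plus.best_bitscore, -plus.best_evalue, plus.best_coverage)
    key_minus = (minus.best_bitscore, -minus.best_evalue, minus.best_coverage)
    if key_plus == key_minus:
        log.warning(
            "strand tie for %s at %s:%d-%d; keeping + strand",
            plus.family_id, plus.interval.sequence_id,
            plus.interval.start, plus.interval.end,
        )
        winner, loser = plus, minus
    elif key_plus > key_minus:
        winner, loser = plus, minus
    else:
        winner, loser = minus, plus
    loser = replace_status(loser, "rejected_strand")
    return winner, loser


def replace_status(region: CandidateRegion, status: str) -> CandidateRegion:
    return CandidateRegion(region.interval, region.family_id, list(region.supporting_hits), status)


def resolve_strands(regions: Sequence[CandidateRegion]) -> tuple[list[CandidateRegion], list[CandidateRegion]]:
    """Apply strand disambiguation to every pair of opposite-strand
    overlapping same-family regions; returns (kept, rejected)."""
    kept: list[CandidateRegion] = []
    rejected: list[CandidateRegion] = []
    pool = sorted(regions, key=lambda r: (r.interval.sequence_id, r.interval.start, r.interval.strand))
    used = [False] * len(pool)
    for i, a in enumerate(pool):
        if used[i]:
            continue
        partner = None
        for j in range(i + 1, len(pool)):
            b = pool[j]
            if used[j] or b.family_id != a.family_id:
                continue
            if a.interval.overlaps(b.interval, stranded=False) and a.interval.strand != b.interval.strand:
                partner = j
                break
        if partner is None:
            kept.append(a)
            used[i] = True
        else:
            b = pool[partner]
            pa, pb = (a, b) if a.interval.strand == "+" else (b, a)
            winner, loser = disambiguate_strand(pa, pb)
            kept.append(winner)
            rejected.append(loser)
            used[i] = used[partner] = True
    return kept, rejected


def merge_engines(*region_lists: Sequence[CandidateRegion]) -> list[CandidateRegion]:
    """Merge strand-resolved candidate lists from the different engines.

    Same-family regions overlapping on the same strand are unified: the
    interval becomes the union and supporting hits are concatenated, so
    best bitscore/E-value/coverage follow as max/min/max.  Loci found by
    only one engine are retained.
    """
    all_hits: list[HomologyHit] = []
    for regions in region_lists:
        for r in regions:
            all_hits.extend(r.supporting_hits)
    # re-merging all supporting hits reproduces union intervals and is
    # independent of engine order — but hits from distinct regions may not
    # themselves overlap even when the regions do, so merge region spans.
    merged = merge_hits_to_regions(all_hits)
    return _coalesce_regions(merged)


def _coalesce_regions(regions: list[CandidateRegion]) -> list[CandidateRegion]:
    out: list[CandidateRegion] = []
    for r in regions:
        if out:
            prev = out[-1]
            if (
                prev.family_id == r.family_id
                and prev.interval.overlaps(r.interval)
            ):
                out[-1] = CandidateRegion(
                    prev.interval.union(r.interval),
                    prev.family_id,
                    prev.supporting_hits + r.supporting_hits,
                    prev.status,
                )
                continue
        out.append(r)
    return out


def cap_candidates(
    regions: Sequence[CandidateRegion], limit: int = 100
) -> tuple[list[CandidateRegion], list[CandidateRegion]]:
    """Limit a family's candidate list to the ``limit`` best bitscores.

    The overflow is flagged ``potential`` and reported for manual
    inspection rather than evaluated — the guard against highly
    repetitive families flooding the mature-annotation stage.  Ties are
    broken by lower E-value, then genomic order, so the outcome is
    deterministic.
    """
    ranked = sorted(
        regions,
        key=lambda r: (
            -r.best_bitscore,
            r.best_evalue,
            r.interval.sequence_id,
            r.interval.start,
            r.interval.strand,
        ),
    )
    processed = list(ranked[:limit])
    potential = [replace_status(r, "potential") for r in ranked[limit:]]
    return processed, potential
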