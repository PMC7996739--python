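"""Comparison of pipeline output against a reference annotation.

Loci are classified with strand-aware >= 1 nt overlap (the bedtools
intersect default): a reference locus overlapped by a same-strand
candidate is a *Match*, a reference locus with no overlapping candidate
a *Miss*, and a candidate overlapping no reference locus an
*Additional*.  Additional candidates can further be categorized against
an auxiliary annotation under the strict hierarchy
different-miRNA > repeat > other.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from .formats_io import Feature


@dataclass
class ComparisonSummary:
    """Per-run locus accounting in the style of a benchmark summary row."""

    n_homology: int = 0
    n_final: int = 0
    n_filtered: int = 0
    n_annotation: int = 0
    n_match: int = 0
    n_miss: int = 0
    ratio_match: float = math.nan
    ratio_miss: float = math.nan
    n_additional: int = 0

    def as_row(self) -> dict:
        def fmt(x):
            return "NA" if isinstance(x, float) and math.isnan(x) else x

        return {
            "Homology": self.n_homology,
            "Final": self.n_final,
            "Filtered": self.n_filtered,
            "Ann.": self.n_annotation,
            "Match": self.n_match,
            "Miss": self.n_miss,
            "Ratio Match": fmt(round(self.ratio_match, 3) if not math.isnan(self.ratio_match) else self.ratio_match),
            "Ratio Miss": fmt(round(self.ratio_miss, 3) if not math.isnan(self.ratio_miss) else self.ratio_miss),
            "Add.": self.n_additional,
        }


@dataclass
class LocusLabels:
    """Per-locus classification produced by :func:`classify_loci`."""

    reference: dict[str, str] = field(default_factory=dict)   # ref id -> Match|Miss
    candidates: dict[str, str] = field(default_factory=dict)  # cand id -> Match|Additional


def _build_tree(features: Sequence[Feature]) -> dict[tuple[str, str], IntervalTree]:
    trees: dict[tuple[str, str], IntervalTree] = {}
    for ft in features:
        iv = ft.interval
        trees.setdefault((iv.sequence_id, iv.strand), IntervalTree()).addi(
            iv.start, iv.end, ft
        )
    return trees


def _overlap_ok(a, b, min_fraction: float) -> bool:
    ov = max(0, min(a.end, b.end) - max(a.start, b.start))
    if ov < 1:
        return False
    if min_fraction > 0.0:
        return ov / len(a) >= min_fraction
    return True


def classify_loci(
    candidates: Sequence[Feature],
    reference: Sequence[Feature],
    min_fraction: float = 0.0,
    n_homology: int | None = None,
    n_filtered: int | None = None,
) -> tuple[LocusLabels, ComparisonSummary]:
    """Strand-aware Match / Miss / Additional classification.

    ``min_fraction`` optionally requires the overlap to cover that
    fraction of the reference locus (0.0 = any >= 1 nt overlap).  With an
    empty reference the ratios are undefined and reported as NaN
    (serialized as NA).
    """
    labels = LocusLabels()
    cand_trees = _build_tree(candidates)
    ref_trees = _build_tree(reference)

    for ref in sorted(reference, key=lambda f: (f.interval.sequence_id, f.interval.start)):
        iv = ref.interval
        tree = cand_trees.get((iv.sequence_id, iv.strand))
        hit = False
        if tree:
            for entry in sorted(tree.overlap(iv.start, iv.end)):
                if _overlap_ok(iv, entry.data.interval, min_fraction):
                    hit = True
                    break
        labels.reference[ref.feature_id] = "Match" if hit else "Miss"

    for cand in sorted(candidates, key=lambda f: (f.interval.sequence_id, f.interval.start)):
        iv = cand.interval
        tree = ref_trees.get((iv.sequence_id, iv.strand))
        hit = False
        if tree:
            for entry in sorted(tree.overlap(iv.start, iv.end)):
                if _overlap_ok(entry.data.interval, iv, min_fraction):
                    hit = True
                    break
        labels.candidates[cand.feature_id] = "Match" if hit else "Additional"

    n_ann = len(reference)
    n_match = sum(1 for v in labels.reference.values() if v == "Match")
    n_miss = n_ann - n_match
    n_additional = sum(1 for v in labels.candidates.values() if v == "Additional")
    summary = ComparisonSummary(
        n_homology=n_homology if n_homology is not None else len(candidates),
        n_final=len(candidates),
        n_filtered=n_filtered if n_filtered is not None else 0,
        n_annotation=n_ann,
        n_match=n_match,
        n_miss=n_miss,
        ratio_match=n_match / n_ann if n_ann else math.nan,
        ratio_miss=n_miss / n_ann if n_ann else math.nan,
        n_additional=n_additional,
    )
    return labels, summary


def classify_family_overlap(
    per_family_matches: Mapping[str, tuple[int, int]]
) -> dict[str, str]:
    """Per family: Perfect iff every annotated locus matched, Partial iff
    some but not all, Without iff none.

    Input maps family id -> (n_matched, n_annotated).
    """
    out = {}
    for family, (matched, annotated) in per_family_matches.items():
        if annotated > 0 and matched == annotated:
            out[family] = "Perfect"
        elif matched > 0:
            out[family] = "Partial"
        else:
            out[family] = "Without"
    return out


_CATEGORY_RANK = {"miRNA": 0, "repeat": 1, "other": 2}
_CATEGORY_NAME = {0: "different-miRNA", 1: "repeat", 2: "other"}


def annotate_additional(
    additional: Sequence[Feature],
    aux_annotation: Sequence[Feature] | None,
) -> dict[str, str]:
    """Categorize Additional candidates under the hierarchy d > r > o.

    Auxiliary features declare their category via ``feature_type`` (or an
    ``annotation_class`` attribute): ``miRNA``-like types beat
    ``repeat``-like types beat everything else; candidates overlapping
    nothing are ``intergenic``.  Missing auxiliary annotation leaves all
    candidates uncategorized.
    """
    if aux_annotation is None:
        return {c.feature_id: "uncategorized" for c in additional}
    trees = _build_tree(aux_annotation)
    out = {}
    for cand in additional:
        iv = cand.interval
        best: int | None = None
        tree = trees.get((iv.sequence_id, iv.strand))
        if tree:
            for entry in sorted(tree.overlap(iv.start, iv.end)):
                rank = _aux_rank(entry.data)
                if best is None or rank < best:
                    best = rank
        out[cand.feature_id] = _CATEGORY_NAME[best] if best is not None else "intergenic"
    return out


def _aux_rank(feature: Feature) -> int:
    cls = feature.attributes.get("annotation_class", feature.feature_type).lower()
    if "mirna" in cls or "mir" in cls:
        return _CATEGORY_RANK["miRNA"]
    if "repeat" in cls or "transposon" in cls:
        return _CATEGORY_RANK["repeat"]
    return _CATEGORY_RANK["other"]


def summary_table(rows: Mapping[str, ComparisonSummary]) -> "pandas.DataFrame":  # noqa: F821
    """One summary row per family/run, with the standard column set."""
    import pandas as pd

    records = []
    for name, summ in rows.items():
        rec = {"Family": name}
        rec.update(summ.as_row())
        records.append(rec)
    return pd.DataFrame.from_records(records)
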