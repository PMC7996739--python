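"""Secondary-structure evaluation of candidate precursors.

This module holds the structural half of the filter cascade: MFE folding
(via a pluggable engine, default ViennaRNA), conversion of dot-bracket
strings to ordered labeled trees, the Zhang–Shasha tree edit distance
used to measure how much a new candidate deforms the family consensus
structure, and the final accept/discard decision with its High/Medium
confidence call.

Tree encoding: every matched base pair becomes an internal ``P`` node
containing its enclosed region, every unpaired base a ``U`` leaf, and
all top-level elements hang under a virtual root ``R``.  The full
expansion makes the distance sensitive to bulge and loop size changes,
which is the scale the ted <= 7 acceptance threshold operates on.
"""

from __future__ import annotations

import functools
import re
import subprocess
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from numba import njit

from .config import Thresholds

# ---------------------------------------------------------------------------
# Folding

@dataclass(frozen=True)
class FoldResult:
    """A minimum-free-energy structure: dot-bracket + energy (kcal/mol)."""

    dotbracket: str
    mfe: float


FoldEngine = Callable[[str], tuple[str, float]]


def _vienna_fold(sequence: str) -> tuple[str, float]:
    import RNA

    db, mfe = RNA.fold(sequence)
    return db, float(mfe)


_FOLD_ENGINE: FoldEngine = _vienna_fold


def set_fold_engine(engine: FoldEngine | None) -> None:
    """Install a different MFE folding engine (None restores the default).

    Engines take an RNA sequence and return (dot-bracket, mfe).  The
    default delegates to the ViennaRNA bindings; :class:`RNAfoldCommand`
    adapts any RNAfold-compatible executable.
    """
    global _FOLD_ENGINE
    _FOLD_ENGINE = engine or _vienna_fold
    _fold_cached.cache_clear()


class RNAfoldCommand:
    """Adapter for an RNAfold-compatible command-line folder.

    Parses the second output line ``<structure> ( -12.30)`` bit-exactly.
    """

    _ENERGY_RE = re.compile(r"^([.()]+)\s+\(\s*(-?\d+(?:\.\d+)?)\s*\)\s*$")

    def __init__(self, executable: str = "RNAfold"):
        self.executable = executable

    def __call__(self, sequence: str) -> tuple[str, float]:
        proc = subprocess.run(
            [self.executable, "--noPS"],
            input=sequence + "\n",
            capture_output=True,
            text=True,
            check=True,
        )
        for line in proc.stdout.splitlines():
            m = self._ENERGY_RE.match(line.strip())
            if m:
                return m.group(1), float(m.group(2))
        raise RuntimeError(f"could not parse {self.executable} output:\n{proc.stdout}")


@functools.lru_cache(maxsize=65536)
def _fold_cached(sequence: str) -> FoldResult:
    db, mfe = _FOLD_ENGINE(sequence)
    return FoldResult(db, mfe)


def fold_mfe(sequence: str) -> FoldResult:
    """Fold an RNA sequence; results are cached by sequence."""
    seq = sequence.upper().replace("T", "U")
    if len(seq) < 10:
        raise ValueError(f"sequence too short to fold ({len(seq)} nt)")
    return _fold_cached(seq)


# ---------------------------------------------------------------------------
# Dot-bracket utilities

def pair_table(dotbracket: str) -> list[int]:
    """Partner index per position (-1 = unpaired); raises on imbalance."""
    pt = [-1] * len(dotbracket)
    stack: list[int] = []
    for i, c in enumerate(dotbracket):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {i}")
            j = stack.pop()
            pt[i], pt[j] = j, i
        elif c != ".":
            raise ValueError(f"unexpected character {c!r} at position {i}")
    if stack:
        raise ValueError(f"unbalanced '(' at position {stack[-1]}")
    return pt


def hairpin_loops(dotbracket: str) -> list[tuple[int, int]]:
    """Half-open intervals of hairpin loops (unpaired stretches directly
    closed by a pair with no pairs inside)."""
    pt = pair_table(dotbracket)
    loops = []
    for i, j in enumerate(pt):
        if j > i:  # each pair once, i < j
            inner = range(i + 1, j)
            if inner and all(pt[k] == -1 for k in inner):
                loops.append((i + 1, j))
    return loops


def base_pairs(dotbracket: str) -> set[tuple[int, int]]:
    pt = pair_table(dotbracket)
    return {(i, j) for i, j in enumerate(pt) if j > i}


# ---------------------------------------------------------------------------
# Structure trees

LABEL_R, LABEL_P, LABEL_U = 0, 1, 2
_LABEL_NAMES = {LABEL_R: "R", LABEL_P: "P", LABEL_U: "U"}


@dataclass
class StructureTree:
    """Ordered rooted tree over labels R (virtual root), P (pair), U
    (unpaired base); children follow 5'->3' order."""

    label: int
    children: list["StructureTree"] = field(default_factory=list)

    @property
    def label_name(self) -> str:
        return _LABEL_NAMES[self.label]

    def size(self) -> int:
        return 1 + sum(c.size() for c in self.children)

    def __repr__(self) -> str:  # compact, e.g. R(P(U,U))
        if not self.children:
            return self.label_name
        return f"{self.label_name}({','.join(map(repr, self.children))})"


def dotbracket_to_tree(dotbracket: str) -> StructureTree:
    """Parse a balanced dot-bracket string into its structure tree."""
    root = StructureTree(LABEL_R)
    stack = [root]
    open_positions: list[int] = []
    for i, c in enumerate(dotbracket):
        if c == "(":
            node = StructureTree(LABEL_P)
            stack[-1].children.append(node)
            stack.append(node)
            open_positions.append(i)
        elif c == ")":
            if len(stack) == 1:
                raise ValueError(f"unbalanced ')' at position {i}")
            stack.pop()
            open_positions.pop()
        elif c == ".":
            stack[-1].children.append(StructureTree(LABEL_U))
        else:
            raise ValueError(f"unexpected character {c!r} at position {i}")
    if len(stack) != 1:
        raise ValueError(f"unbalanced '(' at position {open_positions[-1]}")
    return root


def _postorder_arrays(tree: StructureTree) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Postorder labels, leftmost-leaf indices and LR-keyroots for the
    Zhang–Shasha dynamic program (all 0-based postorder positions)."""
    labels: list[int] = []
    lml: list[int] = []

    def visit(node: StructureTree) -> int:
        first_leaf = None
        for child in node.children:
            cl = visit(child)
            if first_leaf is None:
                first_leaf = cl
        idx = len(labels)
        labels.append(node.label)
        lml.append(first_leaf if first_leaf is not None else idx)
        return lml[idx]

    visit(tree)
    lml_arr = np.asarray(lml, dtype=np.int64)
    n = len(labels)
    # keyroots: highest postorder index for each distinct leftmost leaf
    seen: dict[int, int] = {}
    for i in range(n):
        seen[lml_arr[i]] = i
    keyroots = np.asarray(sorted(seen.values()), dtype=np.int64)
    return np.asarray(labels, dtype=np.int64), lml_arr, keyroots


@njit(cache=True)
def _zs_core(l1, lml1, kr1, l2, lml2, kr2):  # pragma: no cover - jitted
    n, m = len(l1), len(l2)
    td = np.zeros((n, m), dtype=np.int64)
    fd = np.zeros((n + 2, m + 2), dtype=np.int64)
    for ki in range(len(kr1)):
        i_root = kr1[ki]
        li = lml1[i_root]
        for kj in range(len(kr2)):
            j_root = kr2[kj]
            lj = lml2[j_root]
            fd[li, lj] = 0
            for di in range(li, i_root + 1):
                fd[di + 1, lj] = fd[di, lj] + 1
            for dj in range(lj, j_root + 1):
                fd[li, dj + 1] = fd[li, dj] + 1
            for di in range(li, i_root + 1):
                for dj in range(lj, j_root + 1):
                    if lml1[di] == li and lml2[dj] == lj:
                        cost = 0 if l1[di] == l2[dj] else 1
                        fd[di + 1, dj + 1] = min(
                            fd[di, dj + 1] + 1,
                            fd[di + 1, dj] + 1,
                            fd[di, dj] + cost,
                        )
                        td[di, dj] = fd[di + 1, dj + 1]
                    else:
                        fd[di + 1, dj + 1] = min(
                            fd[di, dj + 1] + 1,
                            fd[di + 1, dj] + 1,
                            fd[lml1[di], lml2[dj]] + td[di, dj],
                        )
    return td[n - 1, m - 1]


def tree_edit_distance(t1: StructureTree, t2: StructureTree) -> int:
    """Zhang–Shasha ordered tree edit distance with unit costs.

    Insertions, deletions and relabelings all cost 1; the distance is
    symmetric and zero iff the trees are isomorphic with equal labels.
    """
    l1, lml1, kr1 = _postorder_arrays(t1)
    l2, lml2, kr2 = _postorder_arrays(t2)
    return int(_zs_core(l1, lml1, kr1, l2, lml2, kr2))


def structure_distance(db1: str, db2: str) -> int:
    """Tree edit distance between two dot-bracket strings."""
    return tree_edit_distance(dotbracket_to_tree(db1), dotbracket_to_tree(db2))


# ---------------------------------------------------------------------------
# Arm-consistency check (mature placement vs. hairpin geometry)

def check_arm_consistency(
    mir_interval: tuple[int, int],
    mirstar_interval: tuple[int, int] | None,
    dotbracket: str,
    loop_overlap_tolerance: int = 3,
) -> str:
    """Classify mature placements against the folded precursor.

    A canonical precursor places miR and miR* on opposite arms of a
    single stem-loop.  The check therefore requires exactly one hairpin
    loop between the two matures (zero means both sit on the same arm,
    two or more means the region branches into a multi-loop), and
    neither mature may reach more than ``loop_overlap_tolerance`` nt
    into that loop.  Structure outside the miR/miR* span (retained
    genomic flanks) is not held against the candidate; with no miR* the
    whole structure must be a single hairpin.

    Returns one of ``valid``, ``multiloop``, ``same_arm``,
    ``loop_overlap``.
    """
    loops = hairpin_loops(dotbracket)
    if mirstar_interval is None:
        if len(loops) != 1:
            return "multiloop"
        relevant = loops
    else:
        span = (
            min(mir_interval[0], mirstar_interval[0]),
            max(mir_interval[1], mirstar_interval[1]),
        )
        relevant = [l for l in loops if span[0] <= l[0] and l[1] <= span[1]]
        if len(relevant) == 0:
            return "same_arm"
        if len(relevant) > 1:
            return "multiloop"
    loop_start, loop_end = relevant[0]

    def loop_overlap(iv: tuple[int, int]) -> int:
        return max(0, min(iv[1], loop_end) - max(iv[0], loop_start))

    intervals = [mir_interval] + ([mirstar_interval] if mirstar_interval else [])
    for iv in intervals:
        if loop_overlap(iv) > loop_overlap_tolerance:
            return "loop_overlap"
    if mirstar_interval is not None:
        mid = (loop_start + loop_end) / 2
        if ((mir_interval[0] + mir_interval[1]) / 2 < mid) == (
            (mirstar_interval[0] + mirstar_interval[1]) / 2 < mid
        ):
            return "same_arm"
    return "valid"


# ---------------------------------------------------------------------------
# Consensus structure with / without the candidate

_PAIRABLE = {
    ("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G"),
}


def _can_pair(a: str, b: str) -> bool:
    return (a, b) in _PAIRABLE


def _consensus_from_rows(
    rows: Sequence[str],
    anchor_pairs: Sequence[tuple[int, int]],
    length: int,
    min_pair_fraction: float,
) -> str:
    """Consensus dot-bracket: an anchor pair survives iff the fraction of
    distinct rows with two non-gap, pairable bases at its columns reaches
    ``min_pair_fraction`` (and at least one row supports it)."""
    distinct = list(dict.fromkeys(rows))  # order-preserving dedup
    out = ["."] * length
    for i, j in anchor_pairs:
        informative = 0
        compatible = 0
        for row in distinct:
            a, b = row[i], row[j]
            if a == "-" or b == "-":
                continue
            informative += 1
            if _can_pair(a, b):
                compatible += 1
        if informative and compatible / informative >= min_pair_fraction:
            out[i], out[j] = "(", ")"
    return "".join(out)


def align_candidate_to_columns(
    candidate: str, rows: Sequence[str], thresholds: Thresholds | None = None
) -> str:
    """Place a (degapped) candidate sequence into the alignment columns.

    The candidate is globally aligned against the column-majority
    sequence; candidate bases that fall into insertions relative to the
    column system are dropped, so the returned row has alignment length.
    """
    from Bio import Align

    thr = thresholds or Thresholds()
    length = len(rows[0])
    majority = []
    for col in range(length):
        counts: dict[str, int] = {}
        for row in rows:
            c = row[col]
            if c != "-":
                counts[c] = counts.get(c, 0) + 1
        majority.append(max(counts, key=counts.get) if counts else "N")
    ref = "".join(majority)

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = thr.match_score
    aligner.mismatch_score = thr.mismatch_score
    aligner.open_gap_score = thr.gap_score
    aligner.extend_gap_score = thr.gap_score
    aln = aligner.align(ref, candidate)[0]
    row = ["-"] * length
    for (r0, r1), (c0, c1) in zip(*aln.aligned):
        for k in range(r1 - r0):
            row[r0 + k] = candidate[c0 + k]
    return "".join(row)


def consensus_with_candidate(
    alignment,  # StockholmAlignment
    candidate_sequence: str,
    thresholds: Thresholds | None = None,
) -> tuple[str, str]:
    """Consensus structures of the family alignment without and with the
    candidate, in the alignment's column coordinates.

    Candidate pairs considered are the anchor pairs of the family's
    SS_cons; duplicate rows are collapsed first, so a candidate identical
    to an existing member can never change the consensus.
    """
    thr = thresholds or Thresholds()
    if not alignment.rows:
        raise ValueError("empty family alignment")
    rows = [r.upper().replace("T", "U") for r in alignment.rows.values()]
    anchors = sorted(base_pairs(alignment.consensus_structure))
    length = alignment.length
    css_default = _consensus_from_rows(
        rows, anchors, length, thr.consensus_min_pair_fraction
    )
    cand = candidate_sequence.upper().replace("T", "U").replace("-", "")
    cand_row = align_candidate_to_columns(cand, rows, thr)
    css_with = _consensus_from_rows(
        rows + [cand_row], anchors, length, thr.consensus_min_pair_fraction
    )
    return css_default, css_with


# ---------------------------------------------------------------------------
# Final evaluation

@dataclass
class EvaluationResult:
    """Per-filter verdicts and the final accept/discard decision."""

    length_ok: bool = False
    mfe_ok: bool = False
    arm_verdict: str | None = None
    ted: int | None = None
    css_valid: bool | None = None
    confidence: str | None = None           # High | Medium, iff accepted
    final_status: str = "discarded"         # accepted | discarded
    reject_reason: str = ""
    mfe: float | None = None
    dotbracket: str | None = None


def evaluate_candidate(
    sequence: str,
    placement,  # MaturePlacement | None
    alignment,  # StockholmAlignment
    thresholds: Thresholds | None = None,
) -> EvaluationResult:
    """Run the structural filter cascade on one candidate precursor.

    Discards on: failed mature placement, precursor length > 200 nt,
    MFE above -10 kcal/mol, or an arm verdict other than ``valid``.
    Surviving candidates are compared against the family consensus: the
    tree edit distance between the consensus structure with and without
    the candidate yields confidence High (valid consensus and ted <= 7)
    or Medium.
    """
    thr = thresholds or Thresholds()
    res = EvaluationResult()

    if placement is None:
        res.reject_reason = "no mature anchor"
        return res

    res.length_ok = len(sequence) <= thr.precursor_max_length
    if not res.length_ok:
        res.reject_reason = "length"
        return res

    fold = fold_mfe(sequence)
    res.mfe, res.dotbracket = fold.mfe, fold.dotbracket
    res.mfe_ok = fold.mfe <= thr.mfe_max if thr.mfe_inclusive else fold.mfe < thr.mfe_max
    if not res.mfe_ok:
        res.reject_reason = "mfe"
        return res

    res.arm_verdict = check_arm_consistency(
        placement.mir_interval,
        placement.mirstar_interval,
        fold.dotbracket,
        thr.loop_overlap_tolerance,
    )
    if res.arm_verdict != "valid":
        res.reject_reason = f"arm:{res.arm_verdict}"
        return res

    css_default, css_with = consensus_with_candidate(alignment, sequence, thr)
    res.ted = structure_distance(css_default, css_with)
    default_pairs = base_pairs(css_default)
    with_pairs = base_pairs(css_with)
    retention = (
        len(default_pairs & with_pairs) / len(default_pairs) if default_pairs else 1.0
    )
    res.css_valid = bool(hairpin_loops(css_with)) and retention >= thr.css_pair_retention_min

    res.final_status = "accepted"
    res.confidence = "High" if (res.css_valid and res.ted <= thr.ted_max) else "Medium"
    return res
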