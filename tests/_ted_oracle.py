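"""Independent brute-force oracle for the ordered tree edit distance.

Memoized recursion on forests (the textbook decomposition on the
rightmost roots), written without reference to the package's
Zhang–Shasha implementation so the two can cross-check each other.
"""

from __future__ import annotations

import functools

from mirscout.structure import StructureTree

Forest = tuple  # tuple of tuple-trees; tuple-tree = (label, (children...))


def to_tuple_tree(tree: StructureTree):
    return (tree.label, tuple(to_tuple_tree(c) for c in tree.children))


def _forest_size(forest: Forest) -> int:
    return sum(1 + _forest_size(t[1]) for t in forest)


@functools.lru_cache(maxsize=None)
def _fed(f1: Forest, f2: Forest) -> int:
    if not f1 and not f2:
        return 0
    if not f1:
        return _forest_size(f2)
    if not f2:
        return _forest_size(f1)
    v = f1[-1]
    w = f2[-1]
    f1_minus_v = f1[:-1] + v[1]          # delete v, promote its children
    f2_minus_w = f2[:-1] + w[1]          # insert w symmetrically
    return min(
        _fed(f1_minus_v, f2) + 1,
        _fed(f1, f2_minus_w) + 1,
        _fed(f1[:-1], f2[:-1]) + _fed(v[1], w[1]) + (0 if v[0] == w[0] else 1),
    )


def oracle_distance(t1: StructureTree, t2: StructureTree) -> int:
    return _fed((to_tuple_tree(t1),), (to_tuple_tree(t2),))


def random_tree(rng, n_nodes: int, n_labels: int = 3) -> StructureTree:
    """Uniform-ish random ordered tree with ``n_nodes`` nodes and random
    labels: nodes are attached to a random existing node in creation
    order (preserving child order)."""
    nodes = [StructureTree(int(rng.integers(0, n_labels)))]
    for _ in range(n_nodes - 1):
        parent = nodes[int(rng.integers(0, len(nodes)))]
        child = StructureTree(int(rng.integers(0, n_labels)))
        parent.children.append(child)
        nodes.append(child)
    return nodes[0]


def all_balanced_strings(max_len: int) -> list[str]:
    """Every dot-bracket string over {(, ), .} of length <= max_len."""
    out = [""]
    frontier = [("", 0)]
    for _ in range(max_len):
        nxt = []
        for s, depth in frontier:
            for c in "(.)":
                if c == ")" and depth == 0:
                    continue
                d = depth + (1 if c == "(" else -1 if c == ")" else 0)
                nxt.append((s + c, d))
        frontier = nxt
        out.extend(s for s, d in frontier if d == 0)
    return out
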