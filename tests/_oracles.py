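"""Independent brute-force oracles used by the unit and acceptance suites.

Everything here is deliberately naive — nested loops, breadth-first
search, exhaustive enumeration — and shares no code with the package's
implementations.
"""

from __future__ import annotations

from collections import deque
from itertools import combinations


def bf_ancestors(edges: list[tuple[str, str]], term: str) -> set[str]:
    """Reflexive ancestor closure by breadth-first reachability over
    child->parent edges."""
    parents: dict[str, list[str]] = {}
    for c, p in edges:
        parents.setdefault(c, []).append(p)
    seen = {term}
    queue = deque([term])
    while queue:
        t = queue.popleft()
        for p in parents.get(t, []):
            if p not in seen:
                seen.add(p)
                queue.append(p)
    return seen


def bf_depth(edges: list[tuple[str, str]], root: str, term: str) -> int:
    """Shortest path length root -> term over parent->child direction."""
    children: dict[str, list[str]] = {}
    for c, p in edges:
        children.setdefault(p, []).append(c)
    dist = {root: 0}
    queue = deque([root])
    while queue:
        t = queue.popleft()
        for c in children.get(t, []):
            if c not in dist:
                dist[c] = dist[t] + 1
                queue.append(c)
    return dist[term]


def bf_depth_difference(edges, roots: set[str], namespace: dict[str, str],
                        i: str, j: str):
    """Enumerative re-derivation of the signed depth difference."""
    if namespace[i] != namespace[j]:
        return None
    if i in roots or j in roots:
        return None
    if j not in bf_ancestors(edges, i) and i not in bf_ancestors(edges, j):
        return None
    root = next(r for r in roots if namespace[r] == namespace[i])
    return bf_depth(edges, root, i) - bf_depth(edges, root, j)


def bf_term_counts(annotations: dict[str, set[str]],
                   edges: list[tuple[str, str]]) -> dict[str, int]:
    """Per-protein deduplicated ancestor-propagated counts."""
    counts: dict[str, int] = {}
    for protein, terms in annotations.items():
        closure: set[str] = set()
        for t in terms:
            closure |= bf_ancestors(edges, t)
        for t in closure:
            counts[t] = counts.get(t, 0) + 1
    return counts


def bf_cooccurrence(annotations: dict[str, set[str]],
                    edges: list[tuple[str, str]]) -> set[tuple[str, str]]:
    pairs: set[tuple[str, str]] = set()
    for protein, terms in annotations.items():
        closure: set[str] = set()
        for t in terms:
            closure |= bf_ancestors(edges, t)
        for a, b in combinations(sorted(closure), 2):
            pairs.add((a, b))
    return pairs


def bf_group_by_max(rows: list[tuple[str, str, float]]) -> dict[tuple[str, str], float]:
    """(target, term, score) rows -> per-key maximum score."""
    best: dict[tuple[str, str], float] = {}
    for target, term, score in rows:
        key = (target, term)
        if key not in best or score > best[key]:
            best[key] = score
    return best


def bf_propagate(precisions: dict[str, float], depth_diff) -> dict[str, float]:
    """Snapshot upward propagation: nested loops over the update rule."""
    out = {}
    for i in precisions:
        p = precisions[i]
        for j in precisions:
            if j == i:
                continue
            d = depth_diff(i, j)
            if d is not None and d < 0:
                p = 1.0 - (1.0 - p) * (1.0 - precisions[j])
        out[i] = p
    return out


def bf_filter(precisions: dict[str, float], cooccurring, depth_diff) -> set[str]:
    """Single-pass incompatibility deletions against the original vector."""
    doomed = set()
    for a, b in combinations(sorted(precisions), 2):
        if depth_diff(a, b) is None:
            continue
        if (a, b) in cooccurring or (b, a) in cooccurring:
            continue
        if precisions[a] < precisions[b]:
            doomed.add(a)
        elif precisions[b] < precisions[a]:
            doomed.add(b)
    return set(precisions) - doomed


def enumerate_alignments(la: int, lb: int):
    """All global alignments as op strings over M (match), X (gap in b),
    Y (gap in a)."""

    def rec(i, j):
        if i == la and j == lb:
            yield ""
            return
        if i < la and j < lb:
            for rest in rec(i + 1, j + 1):
                yield "M" + rest
        if i < la:
            for rest in rec(i + 1, j):
                yield "X" + rest
        if j < lb:
            for rest in rec(i, j + 1):
                yield "Y" + rest

    yield from rec(0, 0)


def score_alignment(ops: str, S, gap_open: float, gap_extend: float) -> float:
    """Affine score of one explicit alignment: each maximal gap run of
    length k costs gap_open + (k-1)*gap_extend."""
    i = j = 0
    score = 0.0
    prev = None
    for op in ops:
        if op == "M":
            score += S[i][j]
            i += 1
            j += 1
        else:
            score -= gap_open if op != prev else gap_extend
            if op == "X":
                i += 1
            else:
                j += 1
        prev = op
    return score


def exhaustive_best_score(S, gap_open: float, gap_extend: float) -> float:
    la, lb = len(S), len(S[0])
    return max(
        score_alignment(ops, S, gap_open, gap_extend)
        for ops in enumerate_alignments(la, lb)
    )
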