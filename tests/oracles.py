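"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a result by direct enumeration, deliberately
avoiding the implementation path it is checked against.
"""

from __future__ import annotations

import math
import re


def brute_moving_average(values, k, edge_policy="shrink"):
    """Centered moving average by explicit window loops."""
    n = len(values)
    half = (k - 1) // 2
    out = []
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n - 1, i + half)
        if edge_policy == "drop" and (i - half < 0 or i + half > n - 1):
            out.append(0.0)
        else:
            window = values[lo : hi + 1]
            out.append(sum(window) / len(window))
    return out


def brute_call_regions(ma, seed_threshold=2.0, merge_gap=9, bridge=True):
    """Region calling by exhaustive run enumeration and transitive closure
    of the bridging relation.  Returns (start, end, n_seeds) 1-based tuples."""
    n = len(ma)
    runs = []
    i = 0
    while i < n:
        if ma[i] > 0:
            j = i
            while j + 1 < n and ma[j + 1] > 0:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1
    # Transitive closure of "separated by < merge_gap" via union-find.
    parent = list(range(len(runs)))

    def find(a):
        while parent[a] != a:
            a = parent[a]
        return a

    if bridge:
        for a in range(len(runs)):
            for b in range(a + 1, len(runs)):
                gap = runs[b][0] - runs[a][1] - 1
                if gap < merge_gap:
                    parent[find(b)] = find(a)
    clusters = {}
    for idx, (s, e) in enumerate(runs):
        root = find(idx)
        cs, ce = clusters.get(root, (s, e))
        clusters[root] = (min(cs, s), max(ce, e))
    out = []
    for s, e in sorted(clusters.values()):
        n_seeds = sum(1 for i in range(s, e + 1) if ma[i] >= seed_threshold)
        if n_seeds:
            out.append((s + 1, e + 1, n_seeds))
    return out


def _parse(pattern):
    """Minimal independent parser for the PROSITE-like dialect."""
    elements = []
    for token in pattern.split("-"):
        m = re.fullmatch(r"(x|\[[A-Z]+\]|[A-Z]+)(?:\((\d+)(?:,(\d+))?\))?", token)
        body, lo, hi = m.group(1), m.group(2), m.group(3)
        rep = (1, 1)
        if lo is not None:
            rep = (int(lo), int(hi) if hi is not None else int(lo))
        if body == "x":
            elements.append((None, *rep))
        elif body.startswith("["):
            elements.append((set(body[1:-1]), *rep))
        elif len(body) > 1:
            elements.extend((set(ch), 1, 1) for ch in body)
        else:
            elements.append((set(body), *rep))
    return elements


def _match_lengths(seq, i, elements):
    """All total match lengths of the element list anchored at position i."""
    if not elements:
        return {0}
    (allowed, lo, hi), rest = elements[0], elements[1:]
    lengths = set()
    for reps in range(lo, hi + 1):
        if i + reps > len(seq):
            break
        if allowed is not None and any(ch not in allowed for ch in seq[i : i + reps]):
            break
        for tail in _match_lengths(seq, i + reps, rest):
            lengths.add(reps + tail)
    return lengths


def brute_scan(seq, pattern):
    """Leftmost-longest non-overlapping matches by recursive enumeration.
    Returns (start, end) 1-based tuples."""
    elements = _parse(pattern)
    hits = []
    i = 0
    while i < len(seq):
        lengths = [l for l in _match_lengths(seq, i, elements) if l > 0]
        if lengths:
            best = max(lengths)
            hits.append((i + 1, i + best))
            i += best
        else:
            i += 1
    return hits


def jsd_bits(p, q):
    """Jensen-Shannon divergence in bits by the direct KL formula."""

    def kl(a, b):
        return sum(
            ai * math.log2(ai / bi) for ai, bi in zip(a, b) if ai > 0
        )

    m = [(ai + bi) / 2 for ai, bi in zip(p, q)]
    return 0.5 * kl(p, m) + 0.5 * kl(q, m)
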