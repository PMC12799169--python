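"""Naive brute-force re-implementations used as independent oracles.

Everything here is written as plain row-by-row scans with no shared code
with the package (beyond the canonicalization convention, which is part of
the measured quantity's definition), so agreement is a genuine dual-route
check.
"""

from __future__ import annotations

import math
from collections import Counter


def canon(token: str) -> str:
    token = token.strip()
    if token.startswith("#"):
        token = token[1:]
    return token.strip().casefold()


def rows_of(transcript) -> list[dict]:
    df = transcript.records if hasattr(transcript, "records") else transcript
    return df.to_dict(orient="records")


def naive_dominant_proportion(transcript, trial: int) -> float:
    responses = [canon(r["response"]) for r in rows_of(transcript) if r["trial"] == trial]
    counts = Counter(responses)
    return max(counts.values()) / len(responses)


def naive_entropy(transcript, trial: int, normalized: bool = False) -> float:
    responses = [canon(r["response"]) for r in rows_of(transcript) if r["trial"] == trial]
    counts = Counter(responses)
    n = len(responses)
    h = -sum((c / n) * math.log2(c / n) for c in counts.values())
    if normalized and n > 1:
        h /= math.log2(n)
    return h


def naive_classify(transcript, agent: int, trial: int) -> str:
    if trial == 1:
        return "new"
    rows = [r for r in rows_of(transcript) if r["agent"] == agent]
    by_trial = {r["trial"]: r for r in rows}
    current = canon(by_trial[trial]["response"])
    prev = by_trial[trial - 1]
    if current == canon(prev["response"]):
        return "repeat_self"
    if current == canon(prev["partner_response"]):
        return "repeat_partner"
    earlier = set()
    for t in range(1, trial - 1):
        earlier.add(canon(by_trial[t]["response"]))
        earlier.add(canon(by_trial[t]["partner_response"]))
    if current in earlier:
        return "earlier_context"
    return "new"


def naive_coordination_rates(transcript) -> dict[str, tuple[float, int]]:
    produced: Counter = Counter()
    matched: Counter = Counter()
    for r in rows_of(transcript):
        token = canon(r["response"])
        produced[token] += 1
        if r["matched"]:
            matched[token] += 1
    return {t: (matched[t] / produced[t], produced[t]) for t in produced}


def naive_partner_entropy(transcript, agent: int) -> float:
    received = [
        canon(r["partner_response"])
        for r in rows_of(transcript)
        if r["agent"] == agent
    ]
    counts = Counter(received)
    n = len(received)
    return -sum((c / n) * math.log2(c / n) for c in counts.values())


def enumerate_perfect_matchings(nodes: list[int], edges: set[frozenset]) -> set[frozenset]:
    """All perfect matchings of a small graph, by exhaustive recursion."""
    out: set[frozenset] = set()

    def recurse(remaining: tuple[int, ...], chosen: frozenset) -> None:
        if not remaining:
            out.add(chosen)
            return
        i = remaining[0]
        rest = remaining[1:]
        for j in rest:
            if frozenset((i, j)) in edges:
                recurse(
                    tuple(x for x in rest if x != j),
                    chosen | {frozenset((i, j))},
                )

    recurse(tuple(sorted(nodes)), frozenset())
    return out


def bfs_diameter(n: int, edges: set[frozenset]) -> int:
    adj: dict[int, list[int]] = {i: [] for i in range(n)}
    for e in edges:
        i, j = sorted(e)
        adj[i].append(j)
        adj[j].append(i)
    diam = 0
    for src in range(n):
        dist = {src: 0}
        frontier = [src]
        while frontier:
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if v not in dist:
                        dist[v] = dist[u] + 1
                        nxt.append(v)
            frontier = nxt
        assert len(dist) == n, "graph disconnected"
        diam = max(diam, max(dist.values()))
    return diam
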