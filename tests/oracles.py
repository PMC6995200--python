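"""Independent brute-force oracles used by the test suite.

Each oracle re-derives an expected result by exhaustive enumeration or
direct definition, sharing no code path with the package implementation.
"""
from __future__ import annotations

from itertools import permutations
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from Bio.Seq import Seq

BASES = "ACGT"


# ---------------------------------------------------------------------------
# codon-level Nei-Gojobori oracle (translation via Biopython, not the package)


def aa_of(codon: str) -> str:
    return str(Seq(codon).translate())  # '*' for stops


def is_stop(codon: str) -> bool:
    return aa_of(codon) == "*"


def oracle_syn_fraction(codon: str) -> float:
    total = 0.0
    for pos in range(3):
        alts = [codon[:pos] + b + codon[pos + 1 :] for b in BASES if b != codon[pos]]
        alts = [a for a in alts if not is_stop(a)]
        if alts:
            total += sum(aa_of(a) == aa_of(codon) for a in alts) / len(alts)
    return total


def oracle_count_pair(ca: str, cb: str) -> Tuple[float, float]:
    diffs = [i for i in range(3) if ca[i] != cb[i]]
    if not diffs:
        return 0.0, 0.0
    tallies_ok: List[Tuple[int, int]] = []
    tallies_all: List[Tuple[int, int]] = []
    for order in permutations(diffs):
        cur, sd, nd, stop_seen = ca, 0, 0, False
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
            if is_stop(nxt):
                stop_seen = True
            if not is_stop(cur) and aa_of(cur) == aa_of(nxt):
                sd += 1
            else:
                nd += 1
            cur = nxt
        tallies_all.append((sd, nd))
        if not stop_seen:
            tallies_ok.append((sd, nd))
    use = tallies_ok or tallies_all
    return (sum(t[0] for t in use) / len(use), sum(t[1] for t in use) / len(use))


# ---------------------------------------------------------------------------
# exhaustive monotone-chain oracle


def _valid_step(a, b, max_gap: int, antiparallel: bool) -> bool:
    da = b[0] - a[0] - 1
    if da < 0 or da > max_gap:
        return False
    db = (a[1] - b[1] if antiparallel else b[1] - a[1]) - 1
    return 0 <= db <= max_gap


def _all_chains(points: Sequence[Tuple[int, int]], max_gap: int, antiparallel: bool):
    """Yield every maximal-extension chain via DFS (all chains, small n only)."""
    pts = sorted(points)
    n = len(pts)

    def extend(chain: List[int]):
        yield [pts[i] for i in chain]
        last = pts[chain[-1]]
        for j in range(n):
            if j in chain:
                continue
            if _valid_step(last, pts[j], max_gap, antiparallel):
                yield from extend(chain + [j])

    for i in range(n):
        yield from extend([i])


def chain_gap(chain: Sequence[Tuple[int, int]]) -> int:
    return sum(
        (b[0] - a[0] - 1) + (abs(b[1] - a[1]) - 1) for a, b in zip(chain, chain[1:])
    )


def oracle_best_chain(points, max_gap: int) -> Tuple[List[Tuple[int, int]], bool]:
    """Best chain over both orientations by (count desc, gap asc, lex asc,
    parallel preferred)."""
    best = None
    for anti in (False, True):
        for chain in _all_chains(points, max_gap, anti):
            key = (-len(chain), chain_gap(chain), tuple(chain), anti)
            if best is None or key < best[0]:
                best = (key, chain, anti)
    assert best is not None
    return best[1], best[2]


def oracle_greedy_blocks(points, max_gap: int, min_anchors: int):
    """Greedy extraction using the exhaustive best-chain oracle."""
    remaining = list(points)
    blocks = []
    while remaining:
        chain, anti = oracle_best_chain(remaining, max_gap)
        if len(chain) < min_anchors:
            break
        blocks.append((tuple(chain), anti if len(chain) > 1 else False))
        remaining = [p for p in remaining if p not in chain]
    return blocks


# ---------------------------------------------------------------------------
# minimum-event loss oracle on the two-level duplication tree


def oracle_classify_loss(pattern: Sequence[bool]) -> Tuple[int, int, int]:
    """Enumerate every placement of loss events on the event tree.

    Events: one pre-beta loss (kills all four leaves), two inter-event
    losses (kill one beta pair each), four post-alpha losses (kill one
    leaf).  Find the smallest event set whose union of killed leaves is
    exactly the absent set.
    """
    absent = frozenset(i for i, present in enumerate(pattern) if not present)
    events = [("e1", frozenset({0, 1, 2, 3}))]
    events += [("e2", frozenset({0, 1})), ("e2", frozenset({2, 3}))]
    events += [("e3", frozenset({i})) for i in range(4)]
    best: Optional[Tuple[int, Tuple[int, int, int]]] = None
    for mask in range(1 << len(events)):
        killed: frozenset = frozenset()
        counts = {"e1": 0, "e2": 0, "e3": 0}
        size = 0
        for k, (kind, leaves) in enumerate(events):
            if mask >> k & 1:
                killed |= leaves
                counts[kind] += 1
                size += 1
        if killed == absent:
            cand = (size, (counts["e1"], counts["e2"], counts["e3"]))
            if best is None or cand[0] < best[0]:
                best = cand
    assert best is not None
    return best[1]


# ---------------------------------------------------------------------------
# simple scan / prefix-sum oracles


def oracle_runs(presence: Sequence[bool]) -> List[int]:
    runs, cur = [], 0
    for v in presence:
        if v:
            if cur:
                runs.append(cur)
            cur = 0
        else:
            cur += 1
    if cur:
        runs.append(cur)
    return runs


def oracle_retention(presence: Sequence[bool], window: int, step: int) -> np.ndarray:
    v = np.asarray(presence, dtype=float)
    out = []
    for start in range(0, len(v) - window + 1, step):
        out.append(v[start : start + window].mean())
    return np.asarray(out)


# ---------------------------------------------------------------------------
# additive tree distances for topology tests


def additive_distances(
    labels: Sequence[str],
    pairs: Tuple[Tuple[str, str], Tuple[str, str]],
    reference: str,
    d_alpha: float,
    d_beta: float,
    d_ref: float,
) -> np.ndarray:
    """Ultrametric distances on the two-tetraploidization gene tree: alpha
    sisters at d_alpha, beta relatives at d_beta, reference at d_ref."""
    pair_of = {}
    for k, (x, y) in enumerate(pairs):
        pair_of[x] = k
        pair_of[y] = k
    n = len(labels)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = labels[i], labels[j]
            if reference in (a, b):
                d = d_ref
            elif pair_of[a] == pair_of[b]:
                d = d_alpha
            else:
                d = d_beta
            D[i, j] = D[j, i] = d
    return D
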