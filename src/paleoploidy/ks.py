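"""Synonymous (Ks) and nonsynonymous (Ka) substitution rates for aligned CDS.

Implements the Nei & Gojobori (1986) counting method: synonymous site
fractions per codon, path-averaged difference counts for codon pairs
differing at multiple positions (uniform over mutational paths that
avoid stop codons), and the Jukes-Cantor multiple-hit correction
ks = -(3/4) ln(1 - (4/3) ps), defined for ps < 3/4.

The standard nuclear genetic code is used throughout; codons containing
gaps or ambiguity characters, and stop codons, are skipped pairwise so
that site totals stay consistent with the compared positions.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations
from typing import Optional, Tuple

from Bio.Data.CodonTable import standard_dna_table

BASES = "ACGT"
_FORWARD = dict(standard_dna_table.forward_table)
STOP_CODONS = frozenset(standard_dna_table.stop_codons)
NONSTOP_CODONS = tuple(sorted(_FORWARD))


def translate_codon(codon: str) -> Optional[str]:
    """Amino acid for a codon; None for a stop codon."""
    return _FORWARD.get(codon)


def _check_codon(codon: str) -> None:
    if len(codon) != 3 or any(b not in BASES for b in codon):
        raise ValueError(f"invalid codon {codon!r}")
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon!r} not allowed here")


@lru_cache(maxsize=None)
def syn_fraction(codon: str) -> float:
    """Number of synonymous sites in a codon (0..3).

    At each position, the fraction of single-nucleotide changes that are
    synonymous, counted over the changes that do not create a stop codon.
    """
    _check_codon(codon)
    aa = _FORWARD[codon]
    total = 0.0
    for pos in range(3):
        syn = 0
        nonstop = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if alt in STOP_CODONS:
                continue
            nonstop += 1
            if _FORWARD[alt] == aa:
                syn += 1
        if nonstop:
            total += syn / nonstop
    return total


@lru_cache(maxsize=None)
def synonymous_neighbors(codon: str) -> Tuple[str, ...]:
    """Non-stop single-nucleotide neighbors encoding the same amino acid."""
    _check_codon(codon)
    aa = _FORWARD[codon]
    out = []
    for pos in range(3):
        for b in BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if alt in _FORWARD and _FORWARD[alt] == aa:
                out.append(alt)
    return tuple(sorted(out))


@lru_cache(maxsize=None)
def count_pair(codon_a: str, codon_b: str) -> Tuple[float, float]:
    """(synonymous, nonsynonymous) difference counts for one codon pair.

    For k differing positions the counts are averaged uniformly over the
    k! single-step mutational paths that avoid stop codons; if every
    path passes through a stop, the average is over all paths.
    """
    _check_codon(codon_a)
    _check_codon(codon_b)
    diffs = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diffs:
        return 0.0, 0.0
    all_paths = []
    valid_paths = []
    for order in permutations(diffs):
        cur = codon_a
        sd = nd = 0
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                through_stop = True
            if _FORWARD.get(cur) is not None and _FORWARD.get(cur) == _FORWARD.get(nxt):
                sd += 1
            else:
                nd += 1
            cur = nxt
        all_paths.append((sd, nd))
        if not through_stop:
            valid_paths.append((sd, nd))
    paths = valid_paths or all_paths
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


def pair_sites(codon_a: str, codon_b: str) -> Tuple[float, float]:
    """(S, N) site counts for a codon pair, averaged between the two codons."""
    s = (syn_fraction(codon_a) + syn_fraction(codon_b)) / 2.0
    return s, 3.0 - s


def jukes_cantor(p: float) -> float:
    """Jukes-Cantor distance for a proportion of differing sites p < 3/4."""
    if p < 0 or p >= 0.75:
        raise ValueError(f"proportion {p} outside [0, 3/4)")
    return -0.75 * math.log(1.0 - (4.0 / 3.0) * p) + 0.0


@dataclass(frozen=True)
class KsValue:
    """Nei-Gojobori estimates for one aligned CDS pair.

    ``flag`` is None for a clean estimate, "saturated" when ps or pn is at
    or beyond the Jukes-Cantor domain boundary (3/4), or "undefined" when
    no codon could be compared.
    """

    ks: float
    ka: float
    ps: float
    pn: float
    syn_sites: float
    nonsyn_sites: float
    syn_diffs: float
    nonsyn_diffs: float
    n_codons: int
    flag: Optional[str] = None


def nei_gojobori(seq_a: str, seq_b: str) -> KsValue:
    """Estimate Ks and Ka for two pre-aligned coding sequences.

    Sequences must have equal length divisible by 3; codons containing
    gaps or ambiguous bases, or that are stop codons in either sequence,
    are skipped pairwise.
    """
    seq_a = seq_a.upper()
    seq_b = seq_b.upper()
    if len(seq_a) != len(seq_b):
        raise ValueError(f"aligned lengths differ: {len(seq_a)} vs {len(seq_b)}")
    if len(seq_a) % 3 != 0:
        raise ValueError(f"alignment length {len(seq_a)} not divisible by 3")
    S = N = Sd = Nd = 0.0
    n_codons = 0
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i : i + 3], seq_b[i : i + 3]
        if any(b not in BASES for b in ca + cb):
            continue
        if ca in STOP_CODONS or cb in STOP_CODONS:
            continue
        s, n = pair_sites(ca, cb)
        sd, nd = count_pair(ca, cb)
        S += s
        N += n
        Sd += sd
        Nd += nd
        n_codons += 1
    nan = float("nan")
    if n_codons == 0 or S <= 0.0:
        return KsValue(nan, nan, nan, nan, S, N, Sd, Nd, n_codons, flag="undefined")
    ps = Sd / S
    pn = Nd / N if N > 0 else 0.0
    if ps >= 0.75 or pn >= 0.75:
        return KsValue(nan, nan, ps, pn, S, N, Sd, Nd, n_codons, flag="saturated")
    return KsValue(jukes_cantor(ps), jukes_cantor(pn), ps, pn, S, N, Sd, Nd, n_codons)
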