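"""Collinear block detection by chaining homologous anchors.

An anchor is a homologous gene pair plotted at its (rank_a, rank_b)
position on the gene-order dotplot of one chromosome pair.  A collinear
block is a chain of anchors strictly monotone on both axes (same
direction: parallel; opposite: antiparallel) in which consecutive
anchors are separated by at most ``max_gap`` intervening genes on each
axis.  Blocks are extracted greedily: the highest-scoring chain (most
anchors, ties broken by smaller total gap, then lexicographically
earliest anchor sequence, then parallel orientation) is removed and the
search repeats until no chain of ``min_anchors`` anchors remains.

Block significance follows a uniform-placement null model: the
probability that at least ``n_anchors`` of the chromosome pair's anchors
fall inside the block's bounding rectangle by chance (binomial tail).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from statistics import median
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import binom


@dataclass(frozen=True)
class Anchor:
    """A homologous gene pair at gene-order position (rank_a, rank_b)."""

    rank_a: int
    rank_b: int
    gene_a: str = ""
    gene_b: str = ""
    ks: Optional[float] = None


@dataclass
class CollinearBlock:
    anchors: List[Anchor]
    orientation: str  # "parallel" | "antiparallel"
    chrom_a: str = ""
    chrom_b: str = ""
    genome_a: str = ""
    genome_b: str = ""
    median_ks: Optional[float] = None
    p_value: float = 1.0

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)

    def span_a(self) -> Tuple[int, int]:
        ranks = [a.rank_a for a in self.anchors]
        return min(ranks), max(ranks)

    def span_b(self) -> Tuple[int, int]:
        ranks = [a.rank_b for a in self.anchors]
        return min(ranks), max(ranks)

    def sort_key(self):
        a0 = self.anchors[0]
        return (self.genome_a, self.genome_b, self.chrom_a, self.chrom_b,
                a0.rank_a, a0.rank_b, self.orientation)

    def __repr__(self) -> str:  # pragma: no cover
        return (f"CollinearBlock({self.chrom_a}~{self.chrom_b}, {self.n_anchors} anchors, "
                f"{self.orientation}, median_ks={self.median_ks}, p={self.p_value:.3g})")


# ---------------------------------------------------------------------------
# chaining


def _chain_total_gap(chain: Sequence[Anchor]) -> int:
    gap = 0
    for prev, cur in zip(chain, chain[1:]):
        gap += (cur.rank_a - prev.rank_a - 1) + (abs(cur.rank_b - prev.rank_b) - 1)
    return gap


def _best_chain(anchors: Sequence[Anchor], antiparallel: bool, max_gap: int) -> List[Anchor]:
    """Best single chain in one orientation.

    Maximizes anchor count, then minimizes total gap, then takes the
    lexicographically smallest (rank_a, rank_b) anchor sequence.
    """
    n = len(anchors)
    if n == 0:
        return []
    sign = -1 if antiparallel else 1
    order = sorted(range(n), key=lambda i: (anchors[i].rank_a, sign * anchors[i].rank_b,
                                            anchors[i].gene_a, anchors[i].gene_b))
    A = np.array([anchors[i].rank_a for i in order])
    B = np.array([sign * anchors[i].rank_b for i in order])
    counts = np.ones(n, dtype=int)
    gaps = np.zeros(n, dtype=int)
    parent = np.full(n, -1, dtype=int)

    def chain_ranks(i: int) -> List[Tuple[int, int]]:
        out = []
        while i >= 0:
            out.append((int(A[i]), sign * int(B[i])))
            i = parent[i]
        return out[::-1]

    for i in range(1, n):
        da = A[i] - A[:i] - 1
        db = B[i] - B[:i] - 1
        mask = (A[:i] < A[i]) & (B[:i] < B[i]) & (da <= max_gap) & (db <= max_gap)
        if not mask.any():
            continue
        idx = np.nonzero(mask)[0]
        c = counts[idx]
        best_c = c.max()
        idx = idx[c == best_c]
        g = gaps[idx] + da[idx] + db[idx]
        best_g = g.min()
        idx = idx[g == best_g]
        j = idx[0]
        if len(idx) > 1:  # rare exact tie: compare full chains lexicographically
            j = min(idx, key=chain_ranks)
        counts[i] = best_c + 1
        gaps[i] = best_g
        parent[i] = j

    best_count = counts.max()
    ends = np.nonzero(counts == best_count)[0]
    best_gap = gaps[ends].min()
    ends = ends[gaps[ends] == best_gap]
    end = ends[0] if len(ends) == 1 else min(ends, key=chain_ranks)
    chain_idx = []
    i = int(end)
    while i >= 0:
        chain_idx.append(i)
        i = parent[i]
    chain_idx.reverse()
    return [anchors[order[i]] for i in chain_idx]


def chain_blocks(
    anchors: Sequence[Anchor],
    max_gap: int = 50,
    min_anchors: int = 4,
    *,
    chrom_a: str = "",
    chrom_b: str = "",
    genome_a: str = "",
    genome_b: str = "",
) -> List[CollinearBlock]:
    """Greedy iterative extraction of collinear blocks from one chromosome pair.

    Both orientations are searched each round; each anchor is used in at
    most one block.  Empty input yields an empty list.
    """
    min_anchors = max(1, int(min_anchors))
    remaining = sorted(anchors, key=lambda a: (a.rank_a, a.rank_b, a.gene_a, a.gene_b))
    blocks: List[CollinearBlock] = []
    while remaining:
        candidates = []
        for anti in (False, True):
            chain = _best_chain(remaining, anti, max_gap)
            if chain:
                key = (
                    -len(chain),
                    _chain_total_gap(chain),
                    tuple((a.rank_a, a.rank_b) for a in chain),
                    anti,  # parallel preferred on full tie
                )
                candidates.append((key, anti, chain))
        if not candidates:
            break
        _, anti, chain = min(candidates)
        if len(chain) < min_anchors:
            break
        if len(chain) >= 2:
            orientation = "antiparallel" if chain[1].rank_b < chain[0].rank_b else "parallel"
        else:
            orientation = "parallel"
        blocks.append(
            CollinearBlock(
                anchors=list(chain), orientation=orientation,
                chrom_a=chrom_a, chrom_b=chrom_b, genome_a=genome_a, genome_b=genome_b,
            )
        )
        used = set(map(id, chain))
        remaining = [a for a in remaining if id(a) not in used]
    return blocks


# ---------------------------------------------------------------------------
# significance and Ks summary


def block_significance(
    block: CollinearBlock, n_genes_a: int, n_genes_b: int, n_anchors_total: int
) -> float:
    """Binomial-tail p-value of the block under uniform anchor placement.

    p = P(X >= n_anchors), X ~ Binomial(n_anchors_total, q) where q is the
    fraction of the (n_genes_a x n_genes_b) dotplot grid covered by the
    block's bounding rectangle.  Returned value lies in (0, 1].
    """
    if n_genes_a <= 0 or n_genes_b <= 0 or n_anchors_total <= 0:
        raise ValueError("gene and anchor counts must be positive")
    lo_a, hi_a = block.span_a()
    lo_b, hi_b = block.span_b()
    rect = (hi_a - lo_a + 1) * (hi_b - lo_b + 1)
    grid = n_genes_a * n_genes_b
    q = rect / grid
    if q <= 0.0:
        return 1.0
    q = min(q, 1.0)
    p = float(binom.sf(block.n_anchors - 1, n_anchors_total, q))
    return min(max(p, np.nextafter(0.0, 1.0)), 1.0)


def block_median_ks(
    block: CollinearBlock, ks_lookup: Optional[Mapping[Tuple[str, str], float]] = None
) -> Optional[float]:
    """Median Ks over anchors with a known Ks; absent (None) when no anchor has one.

    Even counts average the two central values.
    """
    values = []
    for a in block.anchors:
        ks = a.ks
        if ks is None and ks_lookup is not None:
            ks = ks_lookup.get((a.gene_a, a.gene_b), ks_lookup.get((a.gene_b, a.gene_a)))
        if ks is not None and np.isfinite(ks):
            values.append(float(ks))
    if not values:
        return None
    return float(median(values))


# ---------------------------------------------------------------------------
# anchors from gene tables + pair lists


def anchors_from_pairs(
    ranks_a: Mapping[str, Tuple[str, int]],
    ranks_b: Mapping[str, Tuple[str, int]],
    pairs,
    same_genome: bool = False,
) -> Dict[Tuple[str, str], List[Anchor]]:
    """Group pairs into per-chromosome-pair anchor lists.

    ``ranks_*`` map gene_id -> (chrom, rank).  Pairs with a gene missing
    from either table are skipped.  For intra-genome comparisons the
    chromosome pair is ordered so chrom_a <= chrom_b (ranks ordered on
    the same chromosome), which de-duplicates the symmetric dotplot.
    """
    ks_col = "ks" if "ks" in pairs.columns else None
    grouped: Dict[Tuple[str, str], List[Anchor]] = {}
    for row in pairs.itertuples(index=False):
        ga, gb = row.gene_a, row.gene_b
        ks = getattr(row, ks_col) if ks_col else None
        if ks is not None and not np.isfinite(ks):
            ks = None
        pos_a = ranks_a.get(ga)
        pos_b = ranks_b.get(gb)
        if pos_a is None or pos_b is None:
            # canonical storage orders genes lexicographically; try the swap
            alt_a, alt_b = ranks_a.get(gb), ranks_b.get(ga)
            if alt_a is not None and alt_b is not None:
                pos_a, pos_b = alt_a, alt_b
                ga, gb = gb, ga
        if pos_a is None or pos_b is None:
            continue
        (ca, ra), (cb, rb) = pos_a, pos_b
        if same_genome and ((cb, rb, gb) < (ca, ra, ga)):
            ca, ra, ga, cb, rb, gb = cb, rb, gb, ca, ra, ga
        grouped.setdefault((ca, cb), []).append(Anchor(ra, rb, ga, gb, ks))
    return grouped


def detect_blocks(
    table_a,
    table_b,
    pairs,
    max_gap: int = 50,
    min_anchors: int = 4,
) -> List[CollinearBlock]:
    """Chain blocks over every chromosome pair of two genomes (or one genome
    against itself), attach median Ks and binomial significance."""
    same = table_a is table_b or (
        table_a.genome == table_b.genome and table_a.n_genes == table_b.n_genes
    )
    ranks_a = table_a.rank_index()
    ranks_b = table_b.rank_index()
    sizes_a = table_a.chrom_sizes()
    sizes_b = table_b.chrom_sizes()
    grouped = anchors_from_pairs(ranks_a, ranks_b, pairs, same_genome=same)
    blocks: List[CollinearBlock] = []
    for (ca, cb) in sorted(grouped):
        anchors = grouped[(ca, cb)]
        found = chain_blocks(
            anchors, max_gap=max_gap, min_anchors=min_anchors,
            chrom_a=ca, chrom_b=cb, genome_a=table_a.genome, genome_b=table_b.genome,
        )
        for b in found:
            b.median_ks = block_median_ks(b)
            b.p_value = block_significance(b, sizes_a[ca], sizes_b[cb], len(anchors))
        blocks.extend(found)
    blocks.sort(key=CollinearBlock.sort_key)
    return blocks
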