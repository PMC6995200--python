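"""Event-related homology: orthology vs outparalogy, the multi-genome
homology table, gene-loss epochs, ortholog depth and gene-tree topology.

Blocks between two genomes mix true orthologs (separated by the
speciation) with outparalogs (separated by the older shared hexaploidy).
Orthologous blocks have more collinear genes and a smaller median Ks;
here they are identified by the youngest component of the between-genome
Ks mixture, with an anchor-count demotion rule when more candidate
regions survive than the expected ortholog depth (2^d for a target with
d extra duplications).

The event table aligns every reference gene with its two hexaploidy
paralogs, their orthologs in each outgroup genome, and the 2^d target
copies expected per reference column; a dot marks a cell emptied by gene
loss or translocation.  Presence patterns over the four target columns
date each loss to one of three epochs: before the older
tetraploidization (beta), between the two, or after the younger (alpha).
"""
from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .collinearity import CollinearBlock
from .formats import MISSING, EventTable, GenomeTable, event_table_columns
from .peaks import KsMixture, classify_by_event

ORTHOLOGOUS = "orthologous"
OUTPARALOGOUS = "outparalogous"


# ---------------------------------------------------------------------------
# orthology / outparalogy labeling


def _overlap_components(blocks: Sequence[CollinearBlock]) -> List[List[CollinearBlock]]:
    """Connected components of blocks overlapping on the reference axis."""
    items = sorted(blocks, key=lambda b: b.span_a())
    comps: List[List[CollinearBlock]] = []
    cur: List[CollinearBlock] = []
    cur_end = -1
    for b in items:
        lo, hi = b.span_a()
        if cur and lo > cur_end:
            comps.append(cur)
            cur = []
            cur_end = -1
        cur.append(b)
        cur_end = max(cur_end, hi)
    if cur:
        comps.append(cur)
    return comps


def assign_orthology(
    blocks: Sequence[CollinearBlock],
    mixture: Optional[KsMixture],
    max_depth: Optional[int] = None,
) -> List[Tuple[CollinearBlock, str]]:
    """Label blocks orthologous/outparalogous from the between-genome Ks mixture.

    Blocks whose median Ks falls in the youngest mixture component are
    orthologous; older components are outparalogous.  When a mixture is
    unimodal (or absent) every block is labeled orthologous and a warning
    is issued.  If ``max_depth`` is given, each group of reference-
    overlapping orthologous blocks keeps at most that many distinct
    target-chromosome groups; excess groups (fewer total anchors, then
    larger median Ks) are demoted to outparalogous.
    """
    blocks = sorted(blocks, key=CollinearBlock.sort_key)
    labels: Dict[int, str] = {}
    if mixture is None or mixture.k < 2:
        import warnings

        warnings.warn("between-genome Ks mixture is unimodal; labeling all blocks orthologous")
        for b in blocks:
            labels[id(b)] = ORTHOLOGOUS
    else:
        for b in blocks:
            if b.median_ks is None:
                labels[id(b)] = OUTPARALOGOUS
            else:
                comp = classify_by_event(b.median_ks, mixture)
                labels[id(b)] = ORTHOLOGOUS if comp == 0 else OUTPARALOGOUS
    if max_depth is not None:
        by_ref_chrom: Dict[str, List[CollinearBlock]] = defaultdict(list)
        for b in blocks:
            if labels[id(b)] == ORTHOLOGOUS:
                by_ref_chrom[b.chrom_a].append(b)
        for chrom_blocks in by_ref_chrom.values():
            for comp in _overlap_components(chrom_blocks):
                groups: Dict[str, List[CollinearBlock]] = defaultdict(list)
                for b in comp:
                    groups[b.chrom_b].append(b)
                if len(groups) <= max_depth:
                    continue
                ranked = sorted(
                    groups.items(),
                    key=lambda kv: (
                        -sum(b.n_anchors for b in kv[1]),
                        min(b.median_ks if b.median_ks is not None else np.inf for b in kv[1]),
                        kv[0],
                    ),
                )
                for chrom_b, demoted in ranked[max_depth:]:
                    for b in demoted:
                        labels[id(b)] = OUTPARALOGOUS
    return [(b, labels[id(b)]) for b in blocks]


# ---------------------------------------------------------------------------
# hexaploidy paralog triples within the reference


def ech_pairing_from_blocks(
    intra_ref_blocks: Sequence[CollinearBlock],
    mixture: Optional[KsMixture] = None,
    component: Optional[int] = None,
) -> Dict[str, Tuple[Optional[str], Optional[str]]]:
    """Pair each reference gene with up to two hexaploidy paralogs.

    Blocks are used when their median Ks classifies to ``component``
    (default: the oldest component of the mixture, or all blocks when no
    mixture is given).  When a gene has more than two candidate
    partners, those anchored in blocks with more anchors win.
    """
    candidates: Dict[str, List[Tuple[int, str]]] = defaultdict(list)
    for b in sorted(intra_ref_blocks, key=CollinearBlock.sort_key):
        if mixture is not None:
            want = component if component is not None else mixture.k - 1
            if b.median_ks is None or classify_by_event(b.median_ks, mixture) != want:
                continue
        for a in b.anchors:
            candidates[a.gene_a].append((-b.n_anchors, a.gene_b))
            candidates[a.gene_b].append((-b.n_anchors, a.gene_a))
    pairing: Dict[str, Tuple[Optional[str], Optional[str]]] = {}
    for gene, cands in candidates.items():
        seen: List[str] = []
        for _, partner in sorted(cands):
            if partner not in seen and partner != gene:
                seen.append(partner)
            if len(seen) == 2:
                break
        partners = sorted(seen)
        pairing[gene] = (
            partners[0] if partners else None,
            partners[1] if len(partners) > 1 else None,
        )
    return pairing


# ---------------------------------------------------------------------------
# target column pairing (which target chromosomes are alpha partners)


def alpha_chrom_pairs(
    intra_target_blocks: Sequence[CollinearBlock],
    mixture: Optional[KsMixture] = None,
    component: int = 0,
) -> Dict[str, str]:
    """Pair target chromosomes related by the younger tetraploidization.

    Edges are weighted by the total anchors of alpha-component blocks
    between two chromosomes; ambiguity is resolved by maximizing total
    intra-pair anchor count via greedy max-weight matching.  Returns a
    symmetric chromosome -> partner map.
    """
    weight: Dict[Tuple[str, str], int] = defaultdict(int)
    for b in intra_target_blocks:
        if b.chrom_a == b.chrom_b:
            continue
        if mixture is not None:
            if b.median_ks is None or classify_by_event(b.median_ks, mixture) != component:
                continue
        key = tuple(sorted((b.chrom_a, b.chrom_b)))
        weight[key] += b.n_anchors
    pairs: Dict[str, str] = {}
    for (ca, cb), _w in sorted(weight.items(), key=lambda kv: (-kv[1], kv[0])):
        if ca not in pairs and cb not in pairs:
            pairs[ca] = cb
            pairs[cb] = ca
    return pairs


def _slot_map_for_ref_chrom(
    ortho_blocks: Sequence[CollinearBlock],
    alpha_pairs: Mapping[str, str],
    n_slots: int,
) -> Dict[str, int]:
    """Deterministic target-chromosome -> column-slot map for one reference
    chromosome: alpha partners occupy adjacent slots; groups ordered by
    their lexicographically smallest chromosome."""
    anchors_per_chrom: Dict[str, int] = defaultdict(int)
    for b in ortho_blocks:
        anchors_per_chrom[b.chrom_b] += b.n_anchors
    kept = [c for c, _ in sorted(anchors_per_chrom.items(), key=lambda kv: (-kv[1], kv[0]))][
        :n_slots
    ]
    kept_set = set(kept)
    groups: List[List[str]] = []
    used: Set[str] = set()
    for c in sorted(kept_set):
        if c in used:
            continue
        partner = alpha_pairs.get(c)
        if partner in kept_set and partner not in used and partner != c:
            groups.append(sorted([c, partner]))
            used.update((c, partner))
        else:
            groups.append([c])
            used.add(c)
    groups.sort(key=lambda g: g[0])
    slot_map: Dict[str, int] = {}
    slot = 0
    for g in groups:
        for c in g:
            if slot < n_slots:
                slot_map[c] = slot
                slot += 1
    return slot_map


# ---------------------------------------------------------------------------
# event table construction


def build_event_table(
    ref_table: GenomeTable,
    ech_pairing: Mapping[str, Tuple[Optional[str], Optional[str]]],
    target_labeled_blocks: Sequence[Tuple[CollinearBlock, str]],
    outgroup_labeled_blocks: Mapping[str, Sequence[Tuple[CollinearBlock, str]]],
    alpha_pairs: Mapping[str, str],
    target_genome: str,
    n_target_cols: int = 4,
) -> EventTable:
    """Assemble the event-related collinear gene table.

    Rows follow the reference gene order; each of the three reference
    columns heads one ortholog column per outgroup genome and
    ``n_target_cols`` target columns whose slots are tied to alpha-paired
    target chromosomes.  Every outgroup/target gene is used in at most
    one cell: a gene anchoring to several reference genes goes to the
    anchor from the block with the most anchors.
    """
    outgroups = tuple(sorted(outgroup_labeled_blocks))
    columns = event_table_columns(ref_table.genome, target_genome, outgroups, n_target_cols)

    # unique ortholog assignment: non-reference gene -> (ref gene, strength)
    def ortholog_map(labeled: Sequence[Tuple[CollinearBlock, str]]) -> Dict[str, Dict[str, str]]:
        """ref gene -> {chrom_b: partner gene} using each partner at most once."""
        best: Dict[str, Tuple[int, str, str, str]] = {}
        for b, label in labeled:
            if label != ORTHOLOGOUS:
                continue
            for a in b.anchors:
                cand = (-b.n_anchors, a.gene_a, b.chrom_b, a.gene_a)
                prev = best.get(a.gene_b)
                if prev is None or cand < prev:
                    best[a.gene_b] = (-b.n_anchors, a.gene_a, b.chrom_b, a.gene_a)
        out: Dict[str, Dict[str, str]] = defaultdict(dict)
        for gene_b, (_neg, _ga, chrom_b, ref_gene) in sorted(best.items()):
            out[ref_gene].setdefault(chrom_b, gene_b)
        return out

    target_orth = ortholog_map(target_labeled_blocks)
    outgroup_orth = {og: ortholog_map(lb) for og, lb in outgroup_labeled_blocks.items()}

    # per reference chromosome: target chromosome -> slot
    ortho_by_ref_chrom: Dict[str, List[CollinearBlock]] = defaultdict(list)
    for b, label in target_labeled_blocks:
        if label == ORTHOLOGOUS:
            ortho_by_ref_chrom[b.chrom_a].append(b)
    slot_maps = {
        chrom: _slot_map_for_ref_chrom(bl, alpha_pairs, n_target_cols)
        for chrom, bl in ortho_by_ref_chrom.items()
    }

    ref_chrom_of = {g: c for g, (c, _r) in ref_table.rank_index().items()}

    def fill_group(gene: Optional[str], ref_col: int, row: Dict[str, str]) -> None:
        if gene is None:
            return
        for og in outgroups:
            partners = outgroup_orth[og].get(gene, {})
            if partners:
                # a single outgroup column: strongest chromosome's partner
                row[f"{og}_{ref_col}"] = partners[sorted(partners)[0]]
        slot_map = slot_maps.get(ref_chrom_of.get(gene, ""), {})
        for chrom_b, partner in sorted(target_orth.get(gene, {}).items()):
            slot = slot_map.get(chrom_b)
            if slot is not None:
                col = f"{target_genome}_{ref_col}_{slot + 1}"
                if row[col] == MISSING:
                    row[col] = partner

    # each outgroup/target gene carries a single reference assignment (made
    # once in ortholog_map); it appears in its own reference gene's column-1
    # group and again only in the mirror cells of that gene's two partner rows
    rows = []
    ordered = ref_table.df.sort_values(["chrom", "rank"], kind="stable")
    for gene in ordered["gene_id"]:
        row = {c: MISSING for c in columns}
        row[f"{ref_table.genome}_1"] = gene
        p2, p3 = ech_pairing.get(gene, (None, None))
        if p2:
            row[f"{ref_table.genome}_2"] = p2
        if p3:
            row[f"{ref_table.genome}_3"] = p3
        for ref_col, g in ((1, gene), (2, p2), (3, p3)):
            fill_group(g, ref_col, row)
        rows.append(row)
    df = pd.DataFrame(rows, columns=columns) if rows else pd.DataFrame(columns=columns)
    return EventTable(
        df=df,
        ref_genome=ref_table.genome,
        target_genome=target_genome,
        outgroups=outgroups,
        n_target_cols=n_target_cols,
    )


# ---------------------------------------------------------------------------
# loss-epoch classification


def classify_loss(pattern: Sequence) -> Tuple[int, int, int]:
    """Minimum-event epoch assignment for one presence pattern.

    ``pattern`` is the presence 4-tuple over the target columns ordered
    (beta1.alpha1, beta1.alpha2, beta2.alpha1, beta2.alpha2).  Returns
    (losses before beta, losses between beta and alpha, losses after
    alpha): all four absent is one pre-beta loss; a beta pair fully
    absent is one inter-event loss; a single absent gene in a pair is
    one post-alpha loss.  Counts add over the two pairs.
    """
    p = [bool(x) for x in pattern]
    if len(p) != 4:
        raise ValueError("presence pattern must have exactly 4 entries")
    if not any(p):
        return (1, 0, 0)
    e2 = e3 = 0
    for left, right in ((p[0], p[1]), (p[2], p[3])):
        if not left and not right:
            e2 += 1
        elif left != right:
            e3 += 1
    return (0, e2, e3)


def loss_summary(table: EventTable, ref_col: int = 1) -> Dict[str, int]:
    """Aggregate loss-epoch events over the rows of one reference column."""
    presence = table.presence(ref_col)
    head = table.df[f"{table.ref_genome}_{ref_col}"] != MISSING
    totals = np.zeros(3, dtype=int)
    for row_present, ok in zip(presence, head):
        if not ok:
            continue
        totals += np.array(classify_loss(row_present))
    return {
        "before_beta": int(totals[0]),
        "between_beta_alpha": int(totals[1]),
        "after_alpha": int(totals[2]),
    }


# ---------------------------------------------------------------------------
# ortholog depth


@dataclass
class DepthProfile:
    per_window: pd.DataFrame  # chrom, start, depth
    modal_depth: int
    histogram: Dict[int, int]


def ortholog_depth(
    ref_table: GenomeTable,
    labeled_blocks: Sequence[Tuple[CollinearBlock, str]],
    window: int = 100,
    step: int = 1,
) -> DepthProfile:
    """Count distinct orthologous target regions covering each reference window.

    A window is covered by a target chromosome when any orthologous
    block from it overlaps the window's rank interval.  The modal depth
    over all windows summarizes the expected copy number (2^d for a
    target with d extra duplications, 3 for a triplicated target).
    """
    by_chrom: Dict[str, List[Tuple[int, int, str]]] = defaultdict(list)
    for b, label in labeled_blocks:
        if label == ORTHOLOGOUS:
            lo, hi = b.span_a()
            by_chrom[b.chrom_a].append((lo, hi, b.chrom_b))
    rows = []
    for chrom, size in sorted(ref_table.chrom_sizes().items()):
        intervals = by_chrom.get(chrom, [])
        w = min(window, size)
        for start in range(0, size - w + 1, step):
            end = start + w - 1
            covering = {cb for lo, hi, cb in intervals if lo <= end and hi >= start}
            rows.append((chrom, start, len(covering)))
    df = pd.DataFrame(rows, columns=["chrom", "start", "depth"])
    if len(df):
        counts = df["depth"].value_counts()
        top = counts.max()
        modal = int(min(d for d, c in counts.items() if c == top))
        hist = {int(k): int(v) for k, v in sorted(counts.items())}
    else:
        modal, hist = 0, {}
    return DepthProfile(per_window=df, modal_depth=modal, histogram=hist)


# ---------------------------------------------------------------------------
# neighbor-joining topology test


@dataclass(frozen=True)
class TopologyVerdict:
    group_id: str
    verdict: str  # "supports" | "conflicts" | "unresolved"
    newick: str


class _Node:
    __slots__ = ("label", "children")

    def __init__(self, label: Optional[str] = None, children: Optional[list] = None):
        self.label = label
        self.children = children or []

    def leaves(self) -> frozenset:
        if self.label is not None:
            return frozenset([self.label])
        out: Set[str] = set()
        for c, _bl in self.children:
            out |= c.leaves()
        return frozenset(out)

    def newick(self) -> str:
        if self.label is not None:
            return self.label
        inner = ",".join(f"{c.newick()}:{bl:.4g}" for c, bl in self.children)
        return f"({inner})"


def neighbor_joining(dist: np.ndarray, labels: Sequence[str]) -> Tuple[_Node, bool]:
    """Plain neighbor joining; returns (unrooted tree, degenerate flag).

    The degenerate flag is set when a zero off-diagonal distance or an
    exact tie in the Q-matrix makes the agglomeration order arbitrary.
    """
    D = np.array(dist, dtype=float)
    n = len(labels)
    if D.shape != (n, n):
        raise ValueError("distance matrix shape does not match labels")
    if not np.allclose(D, D.T) or np.any(np.diag(D) != 0) or np.any(D < 0):
        raise ValueError("distance matrix must be symmetric, non-negative, zero-diagonal")
    degenerate = bool(np.any(D[np.triu_indices(n, 1)] <= 0))
    nodes: List[_Node] = [_Node(label=l) for l in labels]
    while len(nodes) > 2:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        ties = np.argwhere(np.isclose(Q, qmin, rtol=0, atol=1e-12))
        ties = sorted({tuple(sorted(t)) for t in ties})
        # ties between pairs sharing a taxon make the join order arbitrary;
        # disjoint tied pairs (two equal cherries) join in either order, and
        # with three nodes left every join yields the same unrooted tree
        if m > 3:
            for a in range(len(ties)):
                for b in range(a + 1, len(ties)):
                    if set(ties[a]) & set(ties[b]):
                        degenerate = True
        i, j = ties[0]
        bl_i = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        bl_j = D[i, j] - bl_i
        new = _Node(children=[(nodes[i], bl_i), (nodes[j], bl_j)])
        d_new = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D2 = np.empty((m - 1, m - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = d_new[keep]
        D2[:-1, -1] = d_new[keep]
        D2[-1, -1] = 0.0
        nodes = [nodes[k] for k in keep] + [new]
        D = D2
    root = _Node(children=[(nodes[0], D[0, 1] / 2), (nodes[1], D[0, 1] / 2)])
    return root, degenerate


def _splits(node: _Node, all_leaves: frozenset) -> Set[frozenset]:
    """Non-trivial bipartitions (as the smaller side) of an unrooted tree."""
    out: Set[frozenset] = set()

    def walk(n: _Node) -> None:
        for c, _bl in n.children:
            lv = c.leaves()
            if 1 < len(lv) < len(all_leaves) - 1:
                other = all_leaves - lv
                out.add(lv if len(lv) <= len(other) else other)
            walk(c)

    walk(node)
    return out


def nj_topology(
    dist: np.ndarray,
    labels: Sequence[str],
    reference: Optional[str],
    alpha_pairs: Tuple[Tuple[str, str], Tuple[str, str]],
    group_id: str = "",
) -> TopologyVerdict:
    """Neighbor-joining topology test for one homologous gene group.

    ``labels`` name the reference gene and the four target orthologs;
    ``alpha_pairs`` are the two expected younger-duplication sister
    pairs.  The tree supports the two-tetraploidization history when,
    rooted on the reference gene (midpoint when it is missing), the two
    alpha pairs each form a cherry under the older-duplication split --
    equivalently when both pairs appear as bipartitions of the unrooted
    tree.  Degenerate (tied or zero) distances yield "unresolved".
    """
    tree, degenerate = neighbor_joining(dist, labels)
    if degenerate:
        return TopologyVerdict(group_id, "unresolved", tree.newick())
    found = _splits(tree, frozenset(labels))
    want = {frozenset(alpha_pairs[0]), frozenset(alpha_pairs[1])}
    verdict = "supports" if want <= found else "conflicts"
    return TopologyVerdict(group_id, verdict, tree.newick())
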