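"""Genome-evolution simulator with a known polyploidization history.

Simulates a clade of genomes descending from one ancestral gene order
through a configurable schedule of whole-genome triplications (wgt),
duplications (wgd) and speciations, with per-subgenome biased
fractionation (gene deletion in geometric-length runs) and
lineage-specific evolutionary rates.  The output bundles the final gene
tables with complete ground truth -- the true Ks, separating event and
subgenome of every homologous pair, and every deletion run drawn -- so
each downstream inference stage can be scored against what actually
happened.

Ks model: every event carries a ``ks_depth`` expressed at the reference
(slowest) lineage's substitution rate.  The expected Ks of a pair equals
that depth times the mean of the two genes' lineage rate multipliers
(matching the algebraic-mean cross-lineage correction used for dating),
plus truncated-Gaussian noise with the event's ``ks_sd``.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import ks as ksmod
from .formats import GenomeTable


@dataclass(frozen=True)
class Event:
    """One step of the clade history.

    kind          "wgt" (x3), "wgd" (x2) or "speciation"
    lineage       lineage in which the event happens (parent, for speciation)
    ks_depth      expected Ks from the present, at the reference lineage rate
    label         event name used in ground-truth pair labels
    new_lineage   name of the daughter lineage (speciation only)
    ks_sd         Gaussian spread of the event's Ks peak
    retention     per-subgenome retained fraction applied right after a
                  polyploidy (length 2 for wgd, 3 for wgt; 1.0 = no loss)
    """

    kind: str
    lineage: str
    ks_depth: float
    label: str
    new_lineage: Optional[str] = None
    ks_sd: float = 0.05
    retention: Optional[Tuple[float, ...]] = None


@dataclass
class EvolConfig:
    n_ancestral_genes: int = 500
    n_chromosomes: int = 2
    events: List[Event] = field(default_factory=list)
    rate_multiplier: Dict[str, float] = field(default_factory=dict)
    root_lineage: str = "reference"
    p_geom: float = 0.23
    seed: int = 0

    def validate(self) -> None:
        if self.n_ancestral_genes < 1 or self.n_chromosomes < 1:
            raise ValueError("need at least one ancestral gene and chromosome")
        if not (0.0 < self.p_geom <= 1.0):
            raise ValueError("p_geom must lie in (0, 1]")
        known = {self.root_lineage}
        floor: Dict[str, float] = {self.root_lineage: math.inf}
        labels = set()
        for ev in self.events:
            if ev.kind not in ("wgt", "wgd", "speciation"):
                raise ValueError(f"unknown event kind {ev.kind!r}")
            if ev.lineage not in known:
                raise ValueError(
                    f"event {ev.label!r} applies to lineage {ev.lineage!r} before "
                    "that lineage exists (child predates its parent speciation)"
                )
            if ev.ks_depth <= 0:
                raise ValueError(f"event {ev.label!r}: ks_depth must be positive")
            if ev.ks_depth >= floor[ev.lineage]:
                raise ValueError(
                    f"event {ev.label!r}: ks_depth {ev.ks_depth} not strictly below the "
                    f"previous event depth {floor[ev.lineage]} in lineage {ev.lineage!r}"
                )
            if ev.ks_sd < 0:
                raise ValueError(f"event {ev.label!r}: ks_sd must be non-negative")
            if ev.label in labels:
                raise ValueError(f"duplicate event label {ev.label!r}")
            labels.add(ev.label)
            floor[ev.lineage] = ev.ks_depth
            if ev.kind == "speciation":
                if not ev.new_lineage:
                    raise ValueError(f"speciation {ev.label!r} needs new_lineage")
                if ev.new_lineage in known:
                    raise ValueError(f"lineage {ev.new_lineage!r} already exists")
                known.add(ev.new_lineage)
                floor[ev.new_lineage] = ev.ks_depth
            else:
                mult = 3 if ev.kind == "wgt" else 2
                ret = ev.retention or (1.0,) * mult
                if len(ret) != mult:
                    raise ValueError(
                        f"event {ev.label!r}: retention needs {mult} values, got {len(ret)}"
                    )
                for r in ret:
                    if not (0.0 < r <= 1.0):
                        raise ValueError(
                            f"event {ev.label!r}: retention_target {r} outside (0, 1] "
                            "(0 would delete everything)"
                        )

    def event_by_label(self) -> Dict[str, Event]:
        return {ev.label: ev for ev in self.events}


@dataclass
class SimulatedClade:
    """Simulator output: final genomes plus complete ground truth."""

    genomes: Dict[str, GenomeTable]
    true_pairs: pd.DataFrame  # gene_a, gene_b, true_ks, event_label
    true_runs: Dict[Tuple[str, str], Dict[str, List[int]]]  # (lineage, subgenome branch)
    subgenome_of: Dict[str, str]
    ancestral_of: Dict[str, int]
    config: EvolConfig


# ---------------------------------------------------------------------------
# internal genome state


class _Chrom:
    __slots__ = ("anc", "subg", "genes")

    def __init__(self, anc: int, subg: Tuple[str, ...], genes: List[Tuple[int, Tuple]]):
        self.anc = anc          # ancestral chromosome index
        self.subg = subg        # polyploidy branch labels, oldest first
        self.genes = genes      # [(ancestral gene id, event path), ...]

    def clone(self, extra_path: Tuple) -> "_Chrom":
        return _Chrom(self.anc, self.subg, [(a, p + (extra_path,)) for a, p in self.genes])


def _run_deletion(
    chroms: List[_Chrom], retention: float, p_geom: float, rng: np.random.Generator
) -> Tuple[List[int], List[List[int]]]:
    """Delete genes in geometric-length runs until the retained fraction
    first drops to <= retention.

    Run starts are uniform among surviving genes; a run deletes
    consecutive *surviving* genes, so later runs may abut earlier gaps
    and merge with them.  Returns the raw draws and, per chromosome, the
    observed merged gap lengths relative to the pre-deletion order.
    """
    n0 = sum(len(c.genes) for c in chroms)
    draws: List[int] = []
    if n0 == 0 or retention >= 1.0:
        return draws, [[] for _ in chroms]
    alive = [list(range(len(c.genes))) for c in chroms]  # surviving original indices
    n = n0
    while n / n0 > retention:
        k = int(rng.integers(n))
        length = int(rng.geometric(p_geom))
        for ci, al in enumerate(alive):
            if k < len(al):
                removed = min(length, len(al) - k)
                del al[k : k + removed]
                n -= removed
                break
            k -= len(al)
        draws.append(length)
    observed: List[List[int]] = []
    for c, al in zip(chroms, alive):
        flags = np.ones(len(c.genes), dtype=bool)
        flags[:] = False
        for i in al:
            flags[i] = True
        from .fractionation import deletion_runs  # merged gaps along pre-deletion order

        observed.append(deletion_runs(flags).runs)
        c.genes = [c.genes[i] for i in al]
    return draws, observed


# ---------------------------------------------------------------------------
# simulate_history


def simulate_history(config: EvolConfig) -> SimulatedClade:
    """Run the event schedule and return genomes with full ground truth.

    Without fractionation a lineage with d whole-genome duplications
    after a shared triplication carries exactly 3 * 2^d copies of every
    ancestral gene.  Identical seeds give byte-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    per = [config.n_ancestral_genes // config.n_chromosomes] * config.n_chromosomes
    for i in range(config.n_ancestral_genes % config.n_chromosomes):
        per[i] += 1
    gene_no = 0
    chroms0 = []
    for ci, cnt in enumerate(per):
        genes = [(gene_no + k, ()) for k in range(cnt)]
        gene_no += cnt
        chroms0.append(_Chrom(ci, (), genes))
    lineages: Dict[str, List[_Chrom]] = {config.root_lineage: chroms0}
    true_runs: Dict[Tuple[str, str], Dict[str, List[int]]] = {}

    for ev in config.events:
        chroms = lineages[ev.lineage]
        if ev.kind == "speciation":
            lineages[ev.new_lineage] = [c.clone((ev.label, 1)) for c in chroms]
            lineages[ev.lineage] = [c.clone((ev.label, 0)) for c in chroms]
        else:
            mult = 3 if ev.kind == "wgt" else 2
            retention = ev.retention or (1.0,) * mult
            new_chroms: List[_Chrom] = []
            for b in range(mult):
                branch = [
                    _Chrom(c.anc, c.subg + (f"{ev.label}{b + 1}",),
                           [(a, p + ((ev.label, b),)) for a, p in c.genes])
                    for c in chroms
                ]
                draws, observed = _run_deletion(branch, retention[b], config.p_geom, rng)
                true_runs[(ev.lineage, f"{ev.label}{b + 1}")] = {
                    "draws": draws,
                    "observed": [r for obs in observed for r in obs],
                }
                new_chroms.extend(branch)
            lineages[ev.lineage] = new_chroms

    # final gene tables
    genomes: Dict[str, GenomeTable] = {}
    subgenome_of: Dict[str, str] = {}
    ancestral_of: Dict[str, int] = {}
    copies: Dict[int, List[Tuple[str, str, Tuple]]] = {}
    for lineage in sorted(lineages):
        rows = []
        for c in sorted(lineages[lineage], key=lambda c: (c.anc, c.subg)):
            subg = ".".join(c.subg) if c.subg else "root"
            chrom_name = f"c{c.anc + 1}" + (f".{subg}" if c.subg else "")
            for pos, (anc, path) in enumerate(c.genes):
                gid = f"{lineage}|{subg}|g{anc:05d}"
                rows.append(
                    dict(gene_id=gid, chrom=chrom_name, start=pos * 1000,
                         end=pos * 1000 + 600, strand="+", subgenome=subg, anc=anc)
                )
                subgenome_of[gid] = subg
                ancestral_of[gid] = anc
                copies.setdefault(anc, []).append((lineage, gid, path))
        genomes[lineage] = GenomeTable(lineage, pd.DataFrame(rows))

    # ground-truth homologous pairs
    events = config.event_by_label()
    mult_of = {lin: config.rate_multiplier.get(lin, 1.0) for lin in lineages}
    pair_rows = []
    for anc in sorted(copies):
        group = copies[anc]
        for i in range(len(group)):
            for j in range(i + 1, len(group)):
                lin_a, ga, pa = group[i]
                lin_b, gb, pb = group[j]
                label = None
                for ea, eb in zip(pa, pb):
                    if ea != eb:
                        label = ea[0]
                        break
                if label is None:
                    continue  # identical path: same copy, skip
                ev = events[label]
                scale = (mult_of[lin_a] + mult_of[lin_b]) / 2.0
                ks = ev.ks_depth * scale
                if ev.ks_sd > 0:
                    ks += rng.normal(0.0, ev.ks_sd)
                a, b = (ga, gb) if ga < gb else (gb, ga)
                pair_rows.append((a, b, max(ks, 0.0), label))
    true_pairs = pd.DataFrame(pair_rows, columns=["gene_a", "gene_b", "true_ks", "event_label"])
    return SimulatedClade(
        genomes=genomes,
        true_pairs=true_pairs,
        true_runs=true_runs,
        subgenome_of=subgenome_of,
        ancestral_of=ancestral_of,
        config=config,
    )


# ---------------------------------------------------------------------------
# standalone fractionation of a GenomeTable


def fractionate(
    genome: GenomeTable,
    subgenome: Optional[str],
    retention_target: float,
    p_geom: float,
    seed: int,
) -> Tuple[GenomeTable, List[int]]:
    """Delete genes of one subgenome in geometric-length runs.

    Runs are drawn i.i.d. geometric(p_geom) (support 1, 2, ...), start
    uniformly among surviving genes of the subgenome and delete
    consecutive survivors within a chromosome, until the retained
    fraction first drops to <= retention_target.  Returns the survivor
    table (ranks recomputed) and the realized (pre-overlap) draws.
    """
    if not (0.0 < retention_target <= 1.0):
        raise ValueError("retention_target must lie in (0, 1]; 0 would delete everything")
    if not (0.0 < p_geom <= 1.0):
        raise ValueError("p_geom must lie in (0, 1]")
    df = genome.df
    if subgenome is None:
        member = pd.Series(True, index=df.index)
    else:
        if "subgenome" not in df.columns:
            raise ValueError("gene table has no 'subgenome' column")
        member = df["subgenome"].map(
            lambda s: s == subgenome or subgenome in str(s).split(".")
        )
    rng = np.random.default_rng(seed)
    chrom_members = {
        chrom: list(df.loc[member & (df["chrom"] == chrom), "gene_id"])
        for chrom in genome.chromosomes
    }
    chroms = [
        _Chrom(0, (), [(0, g) for g in genes])  # reuse the run machinery; gene ids as payload
        for chrom, genes in sorted(chrom_members.items())
        if genes
    ]
    draws, _ = _run_deletion(chroms, retention_target, p_geom, rng)
    survivors = {g for c in chroms for _, g in c.genes}
    keep = set(df.loc[~member, "gene_id"]) | survivors
    return genome.subset(keep), draws


# ---------------------------------------------------------------------------
# aligned CDS emission


@dataclass(frozen=True)
class PairSequences:
    pair_id: str
    gene_a: str
    gene_b: str
    seq_a: str
    seq_b: str
    true_ks: float


def emit_sequences(
    pairs: pd.DataFrame, codon_length: int, seed: int
) -> Tuple[List[PairSequences], List[str]]:
    """Emit gap-free aligned CDS pairs whose expected Nei-Gojobori Ks equals
    the pair's true Ks.

    The Jukes-Cantor relation is inverted to choose the number of
    synonymous differences: ps = (3/4)(1 - exp(-(4/3) ks)), and that
    many single-nucleotide synonymous substitutions are placed on
    distinct codons.  Pairs whose implied ps reaches the Jukes-Cantor
    boundary of 3/4 (or that need more substitutions than the sequence
    can host) are flagged and skipped.
    """
    if codon_length < 100:
        raise ValueError("codon_length must be at least 100")
    rng = np.random.default_rng(seed)
    codons = np.array(ksmod.NONSTOP_CODONS)
    mutable = [c for c in ksmod.NONSTOP_CODONS if ksmod.synonymous_neighbors(c)]
    out: List[PairSequences] = []
    flagged: List[str] = []
    for row in pairs.itertuples(index=False):
        pair_id = f"{row.gene_a}__{row.gene_b}"
        ks = float(row.true_ks)
        if not np.isfinite(ks) or ks < 0:
            flagged.append(pair_id)
            continue
        ps = 0.75 * (1.0 - math.exp(-(4.0 / 3.0) * ks))
        if ps >= 0.75:
            flagged.append(pair_id)
            continue
        seq_codons = list(rng.choice(codons, size=codon_length))
        if ks > 0:
            # guarantee enough mutable codons for the required substitutions
            s_sites = sum(ksmod.syn_fraction(c) for c in seq_codons)
            n_sub = int(round(ps * s_sites))
            eligible = [i for i, c in enumerate(seq_codons) if ksmod.synonymous_neighbors(c)]
            if n_sub > len(eligible):
                flagged.append(pair_id)
                continue
        seq_a = "".join(seq_codons)
        other = list(seq_codons)
        if ks > 0 and n_sub > 0:
            chosen = rng.choice(len(eligible), size=n_sub, replace=False)
            for idx in chosen:
                i = eligible[int(idx)]
                nbrs = ksmod.synonymous_neighbors(seq_codons[i])
                other[i] = nbrs[int(rng.integers(len(nbrs)))]
        out.append(PairSequences(pair_id, row.gene_a, row.gene_b, seq_a, "".join(other), ks))
    return out, flagged


# ---------------------------------------------------------------------------
# default clade configuration


def carrot_like_config(
    seed: int = 0,
    n_ancestral_genes: int = 500,
    n_chromosomes: int = 2,
    *,
    ech_sd: float = 0.11,
    beta_sd: float = 0.176,
    alpha_sd: float = 0.06,
    speciation_sd: float = 0.05,
    ech_retention: Tuple[float, float, float] = (0.85, 0.70, 0.60),
    beta_retention: Tuple[float, float] = (0.80, 0.55),
    alpha_retention: Tuple[float, float] = (0.75, 0.60),
) -> EvolConfig:
    """Three-genome clade emulating the grape/coffee/carrot configuration.

    A shared hexaploidy (depth 1.053 at the reference rate) precedes two
    speciations; the target lineage then undergoes two tetraploidizations
    (depths 0.715 and 0.417).  With rate multipliers 1.33 (outgroup) and
    1.32 (target) the observed intra-target peaks sit near 0.551, 0.944
    and 1.390 and the outgroup hexaploidy peak near 1.400, i.e. relative
    rates of ~32-33% and ~41% would follow for faster configurations.
    """
    events = [
        Event("wgt", "reference", 1.053, "ech", ks_sd=ech_sd, retention=ech_retention),
        Event("speciation", "reference", 0.935, "split_ref", new_lineage="outgroup",
              ks_sd=speciation_sd),
        Event("speciation", "outgroup", 0.80, "split_out", new_lineage="target",
              ks_sd=speciation_sd),
        Event("wgd", "target", 0.715, "beta", ks_sd=beta_sd, retention=beta_retention),
        Event("wgd", "target", 0.417, "alpha", ks_sd=alpha_sd, retention=alpha_retention),
    ]
    return EvolConfig(
        n_ancestral_genes=n_ancestral_genes,
        n_chromosomes=n_chromosomes,
        events=events,
        rate_multiplier={"reference": 1.0, "outgroup": 1.33, "target": 1.32},
        root_lineage="reference",
        p_geom=0.23,
        seed=seed,
    )
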