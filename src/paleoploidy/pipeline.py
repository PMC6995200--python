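"""End-to-end pipeline: simulate (optional) -> collinearity -> Ks -> peaks ->
rate-corrected dating -> event table -> fractionation.

A single seed fans out to per-stage seeds through a stage-name hash so
any stage can be rerun independently; rerunning with the same
configuration is bit-identical.  Every output file carries a provenance
header (seed, config hash, package version).
"""
from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .collinearity import CollinearBlock, detect_blocks
from .dating import correction_coefficient, date_event, relative_rate
from .events import (
    ORTHOLOGOUS,
    alpha_chrom_pairs,
    assign_orthology,
    build_event_table,
    ech_pairing_from_blocks,
    loss_summary,
    ortholog_depth,
)
from .formats import (
    EventTable,
    GenomeTable,
    read_gene_table,
    read_pairs,
    write_blocks,
    write_event_table,
    write_gene_table,
    write_pairs,
)
from .fractionation import (
    RunLengthSample,
    compare_subgenomes,
    deletion_runs,
    fit_geometric,
    retention_windows,
)
from .peaks import KsMixture, fit_mixture
from .simulate import EvolConfig, SimulatedClade, carrot_like_config, simulate_history


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    return (int(seed) ^ zlib.crc32(stage.encode())) & 0x7FFFFFFF


@dataclass
class PipelineConfig:
    """Flat configuration for one pipeline run."""

    seed: int = 17
    # roles
    reference: str = "reference"
    outgroup: str = "outgroup"
    target: str = "target"
    # inputs: simulate a clade, or read genome tables + a pair list with Ks
    simulate: bool = True
    n_ancestral_genes: int = 500
    n_chromosomes: int = 2
    genome_tables: Dict[str, str] = field(default_factory=dict)
    pairs_path: Optional[str] = None
    # stage parameters
    max_gap: int = 50
    min_anchors: int = 4
    ks_min: float = 0.0
    ks_max: float = 2.0
    k_max: int = 4
    t_low: float = 115.0
    t_high: float = 130.0
    window: int = 100
    step: int = 1
    delta: float = 0.05
    alpha: float = 0.05
    n_target_cols: int = 4

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]

    @classmethod
    def from_mapping(cls, mapping: Dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**mapping)


def demo_config(seed: int = 17, n_ancestral_genes: int = 500, n_chromosomes: int = 2) -> PipelineConfig:
    return PipelineConfig(
        seed=seed, n_ancestral_genes=n_ancestral_genes, n_chromosomes=n_chromosomes
    )


# ---------------------------------------------------------------------------


def _mixture_dict(m: Optional[KsMixture]) -> Optional[Dict]:
    if m is None:
        return None
    return {
        "components": [
            {"mu": round(c.mu, 6), "sigma": round(c.sigma, 6), "weight": round(c.weight, 6)}
            for c in m.components
        ],
        "ks_range": list(m.ks_range),
        "n_points": m.n_points,
        "bic": round(m.bic, 3),
    }


def _anchor_ks(blocks: Sequence[CollinearBlock]) -> np.ndarray:
    vals = [a.ks for b in blocks for a in b.anchors if a.ks is not None]
    return np.asarray(vals, dtype=float)


def _try_fit(values, k_range, ks_range, seed) -> Optional[KsMixture]:
    try:
        return fit_mixture(values, k_range=k_range, ks_range=ks_range, seed=seed)
    except ValueError:
        return None


def run_pipeline(config: PipelineConfig, outdir) -> Dict:
    """Execute every stage and write a machine-readable JSON report.

    Stage failures abort with the stage name and offending input in the
    error message.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"seed": config.seed, "config_hash": config.config_hash(), "version": __version__}
    report: Dict = {"meta": dict(meta)}
    ref, og, tgt = config.reference, config.outgroup, config.target

    # -- stage: inputs -----------------------------------------------------
    clade: Optional[SimulatedClade] = None
    if config.simulate:
        evo = carrot_like_config(
            seed=stage_seed(config.seed, "simulate"),
            n_ancestral_genes=config.n_ancestral_genes,
            n_chromosomes=config.n_chromosomes,
        )
        clade = simulate_history(evo)
        genomes = clade.genomes
        pairs = clade.true_pairs.rename(columns={"true_ks": "ks"})
        for name, gt in genomes.items():
            write_gene_table(gt, out / f"genome_{name}.tsv", meta)
        write_pairs(pairs, out / "pairs.tsv", meta)
    else:
        genomes = {}
        for name, path in config.genome_tables.items():
            if not Path(path).exists():
                raise FileNotFoundError(f"stage inputs: genome table not found: {path}")
            genomes[name] = read_gene_table(path)
        if not config.pairs_path or not Path(config.pairs_path).exists():
            raise FileNotFoundError(f"stage inputs: pair list not found: {config.pairs_path}")
        pairs = read_pairs(config.pairs_path)
    for role, name in (("reference", ref), ("outgroup", og), ("target", tgt)):
        if name not in genomes:
            raise ValueError(f"stage inputs: {role} genome {name!r} not among {sorted(genomes)}")

    # -- stage: collinearity ----------------------------------------------
    combos = [(ref, ref), (og, og), (tgt, tgt), (ref, og), (ref, tgt), (og, tgt)]
    blocks: Dict[Tuple[str, str], List[CollinearBlock]] = {}
    for ga, gb in combos:
        blocks[(ga, gb)] = detect_blocks(
            genomes[ga], genomes[gb], pairs,
            max_gap=config.max_gap, min_anchors=config.min_anchors,
        )
        write_blocks(blocks[(ga, gb)], out / f"blocks_{ga}_{gb}.tsv", meta)
    report["block_counts"] = {f"{ga}~{gb}": len(b) for (ga, gb), b in blocks.items()}

    # -- stage: Ks peaks ----------------------------------------------------
    ks_range = (config.ks_min, config.ks_max)
    k_range = tuple(range(1, config.k_max + 1))
    mixtures: Dict[Tuple[str, str], Optional[KsMixture]] = {}
    for combo in combos:
        seed = stage_seed(config.seed, f"peaks:{combo[0]}~{combo[1]}")
        mixtures[combo] = _try_fit(_anchor_ks(blocks[combo]), k_range, ks_range, seed)
    report["ks_components"] = {
        f"{ga}~{gb}": _mixture_dict(m) for (ga, gb), m in mixtures.items()
    }
    m_tgt = mixtures[(tgt, tgt)]
    m_ref = mixtures[(ref, ref)]
    m_og = mixtures[(og, og)]
    if m_tgt is None or m_ref is None:
        raise RuntimeError("stage peaks: too few collinear Ks values for the intra-genome fits")

    # -- stage: rate correction + dating ------------------------------------
    mu_ref_ech = m_ref.components[-1].mu
    mu_tgt_ech = m_tgt.components[-1].mu
    rc_tgt = correction_coefficient(mu_tgt_ech, mu_ref_ech)
    rates = {tgt: {"r": rc_tgt.r, "lambda": rc_tgt.lambda_i}}
    if m_og is not None:
        rc_og = correction_coefficient(m_og.components[-1].mu, mu_ref_ech)
        rates[og] = {"r": rc_og.r, "lambda": rc_og.lambda_i}
    report["rates"] = {"reference_ech_peak": mu_ref_ech, "lineages": rates}
    dated = []
    labels = {0: "alpha", 1: "beta"}
    for idx in range(m_tgt.k - 1):
        comp = m_tgt.components[idx]
        ev = date_event(comp.mu, mu_tgt_ech, config.t_low, config.t_high,
                        label=labels.get(idx, f"event_{idx}"))
        dated.append(ev)
    ech_date = date_event(mu_tgt_ech, mu_tgt_ech, config.t_low, config.t_high, label="ech")
    report["dated_events"] = [
        {"label": e.label, "ks_peak": round(e.ks_peak, 4),
         "age_low": e.age_low, "age_high": e.age_high}
        for e in dated + [ech_date]
    ]

    # -- stage: orthology + event table -------------------------------------
    labeled_tgt = assign_orthology(
        blocks[(ref, tgt)], mixtures[(ref, tgt)], max_depth=config.n_target_cols
    )
    labeled_og = assign_orthology(blocks[(ref, og)], mixtures[(ref, og)], max_depth=1)
    ech_pairing = ech_pairing_from_blocks(blocks[(ref, ref)], m_ref)
    apairs = alpha_chrom_pairs(blocks[(tgt, tgt)], m_tgt, component=0)
    table = build_event_table(
        genomes[ref], ech_pairing, labeled_tgt, {og: labeled_og}, apairs,
        target_genome=tgt, n_target_cols=config.n_target_cols,
    )
    write_event_table(table, out / "event_table.tsv", meta)
    report["event_table"] = {"rows": table.n_rows, "columns": table.n_columns}
    report["loss_epochs"] = loss_summary(table)
    depth = ortholog_depth(genomes[ref], labeled_tgt, window=config.window, step=config.step)
    report["ortholog_depth"] = {"modal": depth.modal_depth, "histogram": depth.histogram}

    # -- stage: fractionation ------------------------------------------------
    presence = table.presence(1)
    ref_order = genomes[ref].df.sort_values(["chrom", "rank"], kind="stable")
    chrom_of_row = ref_order["chrom"].to_numpy()
    runs = RunLengthSample()
    profiles: List[np.ndarray] = []
    for slot in range(config.n_target_cols):
        slot_profiles = []
        for chrom in genomes[ref].chromosomes:
            vec = presence[chrom_of_row == chrom, slot]
            runs.extend(deletion_runs(vec))
            prof = retention_windows(vec, window=min(config.window, len(vec)), step=config.step)
            slot_profiles.append(prof)
        profiles.append(np.concatenate(slot_profiles) if slot_profiles else np.empty(0))
    try:
        fit = fit_geometric(runs)
        report["geometric_fit"] = {
            "p_hat": round(fit.p_hat, 4), "goodness_p": round(fit.goodness_p, 4),
            "frac_runs_le2": round(fit.frac_runs_le2, 4), "n_runs": fit.n_runs,
        }
    except ValueError as exc:
        report["geometric_fit"] = {"error": str(exc)}
    comparisons = {}
    slot_names = [f"slot{s + 1}" for s in range(config.n_target_cols)]
    pairs_to_test = []
    if config.n_target_cols == 4:
        pairs_to_test = [(0, 1, "alpha"), (2, 3, "alpha"), (0, 2, "beta"),
                         (0, 3, "beta"), (1, 2, "beta"), (1, 3, "beta")]
    for i, j, kind in pairs_to_test:
        cmp = compare_subgenomes(
            profiles[i], profiles[j], window=config.window,
            delta=config.delta, alpha=config.alpha,
            labels=(slot_names[i], slot_names[j]),
        )
        comparisons[f"{slot_names[i]}~{slot_names[j]}"] = {
            "event": kind,
            "frac_divergent": round(cmp.frac_divergent, 4),
            "mean_diff": round(cmp.mean_diff, 4),
            "dominant": cmp.dominant,
        }
    report["subgenome_dominance"] = comparisons

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
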