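import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from paleoploidy.formats import write_gene_table
from paleoploidy.simulate import (
    EvolConfig,
    Event,
    carrot_like_config,
    emit_sequences,
    fractionate,
    simulate_history,
)


def _noloss_config(**kwargs):
    return carrot_like_config(
        ech_retention=(1.0, 1.0, 1.0), beta_retention=(1.0, 1.0), alpha_retention=(1.0, 1.0),
        **kwargs,
    )


class TestSimulateHistory:
    def test_triplication_only_yields_three_copies(self):
        cfg = EvolConfig(
            n_ancestral_genes=50, n_chromosomes=1,
            events=[Event("wgt", "reference", 1.39, "hex")], seed=0,
        )
        clade = simulate_history(cfg)
        counts = pd.Series(list(clade.ancestral_of.values())).value_counts()
        assert (counts == 3).all()

    def test_copy_number_conservation(self, noloss_clade):
        """A shared triplication plus two target duplications give 12 target
        copies and 3 reference copies per ancestral gene."""
        for lineage, expected in [("reference", 3), ("outgroup", 3), ("target", 12)]:
            gt = noloss_clade.genomes[lineage]
            per_anc = gt.df.groupby("anc").size()
            assert (per_anc == expected).all()

    def test_seeded_determinism_is_byte_identical(self, tmp_path):
        paths = []
        for run in range(2):
            clade = simulate_history(carrot_like_config(seed=42, n_ancestral_genes=80))
            path = tmp_path / f"run{run}.tsv"
            write_gene_table(clade.genomes["target"], path)
            paths.append(path)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_child_lineage_before_parent_rejected(self):
        cfg = EvolConfig(
            n_ancestral_genes=10, n_chromosomes=1,
            events=[Event("wgd", "target", 0.5, "dup")],  # 'target' never speciated
        )
        with pytest.raises(ValueError, match="before that lineage exists"):
            simulate_history(cfg)

    def test_event_depths_must_decrease(self):
        cfg = EvolConfig(
            n_ancestral_genes=10, n_chromosomes=1,
            events=[
                Event("wgd", "reference", 0.5, "old"),
                Event("wgd", "reference", 0.9, "young"),
            ],
        )
        with pytest.raises(ValueError, match="strictly below"):
            simulate_history(cfg)

    def test_pair_event_labels_match_divergence(self, noloss_clade):
        """A same-subgenome cross-lineage pair separates at the speciation;
        same-lineage pairs separate at their most recent shared duplication."""
        tp = noloss_clade.true_pairs
        cross = tp[
            tp["gene_a"].str.startswith("reference") & tp["gene_b"].str.startswith("target")
        ]
        same_ech_branch = cross[
            cross["gene_a"].str.contains("ech1") & cross["gene_b"].str.contains("ech1")
        ]
        assert (same_ech_branch["event_label"] == "split_ref").all()
        within_target = tp[
            tp["gene_a"].str.startswith("target") & tp["gene_b"].str.startswith("target")
        ]
        alpha_pairs = within_target[within_target["event_label"] == "alpha"]
        # alpha pairs share everything except the alpha branch
        subg = noloss_clade.subgenome_of
        for a, b in zip(alpha_pairs["gene_a"], alpha_pairs["gene_b"]):
            sa, sb = subg[a].split("."), subg[b].split(".")
            assert sa[:-1] == sb[:-1] and sa[-1] != sb[-1]

    def test_ks_modes_sit_at_configured_depths(self, noloss_clade):
        """Per-event Ks distributions are unimodal at depth x rate scaling."""
        cfg = noloss_clade.config
        events = cfg.event_by_label()
        tp = noloss_clade.true_pairs
        tgt = tp[tp["gene_a"].str.startswith("target") & tp["gene_b"].str.startswith("target")]
        for label, scale in [("alpha", 1.32), ("beta", 1.32), ("ech", 1.32)]:
            vals = tgt.loc[tgt["event_label"] == label, "true_ks"]
            ev = events[label]
            assert abs(vals.mean() - ev.ks_depth * scale) < 2 * ev.ks_sd


class TestFractionate:
    @pytest.fixture
    def genome(self):
        cfg = EvolConfig(
            n_ancestral_genes=2000, n_chromosomes=2,
            events=[Event("wgd", "reference", 0.5, "dup")], seed=1,
        )
        return simulate_history(cfg).genomes["reference"]

    def test_full_retention_deletes_nothing(self, genome):
        out, runs = fractionate(genome, "dup1", 1.0, 0.23, seed=0)
        assert out.n_genes == genome.n_genes
        assert runs == []

    def test_degenerate_geometric_gives_unit_runs(self, genome):
        _, runs = fractionate(genome, "dup2", 0.8, 1.0, seed=0)
        assert runs and all(r == 1 for r in runs)

    def test_zero_retention_rejected(self, genome):
        with pytest.raises(ValueError, match="retention_target"):
            fractionate(genome, "dup1", 0.0, 0.23, seed=0)

    def test_mean_run_length_matches_geometric(self, genome):
        _, runs = fractionate(genome, "dup1", 0.5, 0.23, seed=1)
        assert len(runs) > 100
        assert np.mean(runs) == pytest.approx(1 / 0.23, rel=0.15)

    def test_survivor_order_preserved(self, genome):
        out, _ = fractionate(genome, "dup1", 0.6, 0.23, seed=4)
        for chrom in out.chromosomes:
            starts = out.genes(chrom)["start"].to_numpy()
            assert (np.diff(starts) > 0).all()

    def test_draws_pass_geometric_goodness_of_fit(self):
        """Realized run-length draws fit geometric(p) at alpha = 0.01."""
        cfg = EvolConfig(
            n_ancestral_genes=20000, n_chromosomes=1,
            events=[Event("wgd", "reference", 0.5, "dup")], p_geom=0.25, seed=7,
        )
        genome = simulate_history(cfg).genomes["reference"]
        _, runs = fractionate(genome, "dup1", 0.3, 0.25, seed=7)
        assert len(runs) >= 1000
        runs = np.asarray(runs)
        edges = list(range(1, 10))
        observed = [np.sum(runs == l) for l in edges] + [np.sum(runs >= 10)]
        p = 0.25
        expected = [len(runs) * p * (1 - p) ** (l - 1) for l in edges] + [
            len(runs) * (1 - p) ** 9
        ]
        chi2 = sum((o - e) ** 2 / e for o, e in zip(observed, expected))
        assert stats.chi2.sf(chi2, len(edges)) > 0.01


class TestEmitSequences:
    def _pairs(self, ks_values):
        return pd.DataFrame(
            {"gene_a": [f"a{i}" for i in range(len(ks_values))],
             "gene_b": [f"b{i}" for i in range(len(ks_values))],
             "true_ks": ks_values}
        )

    def test_zero_ks_gives_identical_sequences(self):
        recs, flagged = emit_sequences(self._pairs([0.0]), 150, seed=0)
        assert not flagged
        assert recs[0].seq_a == recs[0].seq_b

    def test_monte_carlo_mean_recovers_target(self):
        from paleoploidy.ks import nei_gojobori

        recs, _ = emit_sequences(self._pairs([0.5] * 200), 300, seed=1)
        est = [nei_gojobori(r.seq_a, r.seq_b).ks for r in recs]
        assert 0.45 <= float(np.mean(est)) <= 0.55

    def test_unrealizable_ks_flagged_and_skipped(self):
        recs, flagged = emit_sequences(self._pairs([np.inf, 0.2]), 120, seed=2)
        assert flagged == ["a0__b0"]
        assert len(recs) == 1 and recs[0].pair_id == "a1__b1"

    def test_short_sequences_rejected(self):
        with pytest.raises(ValueError, match="at least 100"):
            emit_sequences(self._pairs([0.1]), 50, seed=0)

    def test_no_stop_codons_emitted(self):
        from paleoploidy.ks import STOP_CODONS

        recs, _ = emit_sequences(self._pairs([1.2]), 200, seed=3)
        for seq in (recs[0].seq_a, recs[0].seq_b):
            codons = {seq[i : i + 3] for i in range(0, len(seq), 3)}
            assert not (codons & STOP_CODONS)
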