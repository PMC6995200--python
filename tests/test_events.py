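from itertools import product

import numpy as np
import pytest

from oracles import additive_distances, oracle_classify_loss
from paleoploidy.collinearity import Anchor, CollinearBlock, detect_blocks
from paleoploidy.events import (
    ORTHOLOGOUS,
    OUTPARALOGOUS,
    alpha_chrom_pairs,
    assign_orthology,
    build_event_table,
    classify_loss,
    ech_pairing_from_blocks,
    nj_topology,
    ortholog_depth,
)
from paleoploidy.formats import MISSING, GenomeTable
from paleoploidy.peaks import Component, KsMixture, fit_mixture
from paleoploidy.simulate import EvolConfig, Event, simulate_history


def _mixture(*comps):
    total = sum(w for _, _, w in comps)
    return KsMixture(
        components=[Component(mu, sd, w / total) for mu, sd, w in comps],
        ks_range=(0.0, 2.0), n_points=1000, bic=0.0,
    )


def _block(chrom_a, chrom_b, n, median_ks, start=0):
    anchors = [Anchor(start + i, start + i, f"r{chrom_a}_{start + i}", f"t{chrom_b}_{start + i}")
               for i in range(n)]
    return CollinearBlock(anchors=anchors, orientation="parallel",
                          chrom_a=chrom_a, chrom_b=chrom_b, median_ks=median_ks)


def _analyze(clade, n_target_cols=4, min_anchors=4):
    """Run the homology fragment (blocks -> mixtures -> labels -> table) on a
    simulated clade, returning the labeled target blocks and event table."""
    pairs = clade.true_pairs.rename(columns={"true_ks": "ks"})
    ref, og, tgt = (clade.genomes[n] for n in ("reference", "outgroup", "target"))

    def anchor_ks(blocks):
        return [a.ks for b in blocks for a in b.anchors if a.ks is not None]

    def try_fit(blocks):
        vals = anchor_ks(blocks)
        try:
            return fit_mixture(vals, seed=13)
        except ValueError:
            return None

    b_rr = detect_blocks(ref, ref, pairs, min_anchors=min_anchors)
    b_tt = detect_blocks(tgt, tgt, pairs, min_anchors=min_anchors)
    b_rt = detect_blocks(ref, tgt, pairs, min_anchors=min_anchors)
    b_ro = detect_blocks(ref, og, pairs, min_anchors=min_anchors)
    labeled_tgt = assign_orthology(b_rt, try_fit(b_rt), max_depth=n_target_cols)
    labeled_og = assign_orthology(b_ro, try_fit(b_ro), max_depth=1)
    ech_pairing = ech_pairing_from_blocks(b_rr, try_fit(b_rr))
    apairs = alpha_chrom_pairs(b_tt, try_fit(b_tt), component=0)
    table = build_event_table(
        ref, ech_pairing, labeled_tgt, {"outgroup": labeled_og}, apairs,
        target_genome="target", n_target_cols=n_target_cols,
    )
    return table, labeled_tgt, ref


class TestAssignOrthology:
    def test_block_at_speciation_peak_is_orthologous(self):
        mix = _mixture((1.0, 0.05, 1), (1.3, 0.05, 1))
        blocks = [_block("c1", "x1", 10, 1.0), _block("c1", "x2", 10, 1.31)]
        labels = dict((b.chrom_b, lab) for b, lab in assign_orthology(blocks, mix))
        assert labels == {"x1": ORTHOLOGOUS, "x2": OUTPARALOGOUS}

    def test_depth_budget_keeps_stronger_block(self):
        """Two same-component candidates for one region: the 40-anchor block
        survives the depth budget, the 12-anchor block is demoted."""
        mix = _mixture((1.0, 0.05, 1), (1.3, 0.05, 1))
        blocks = [_block("c1", "x1", 40, 1.0), _block("c1", "x2", 12, 1.0)]
        labels = dict((b.chrom_b, lab) for b, lab in assign_orthology(blocks, mix, max_depth=1))
        assert labels == {"x1": ORTHOLOGOUS, "x2": OUTPARALOGOUS}

    def test_unimodal_mixture_labels_all_orthologous(self):
        mix = _mixture((1.0, 0.05, 1))
        blocks = [_block("c1", "x1", 10, 1.0), _block("c1", "x2", 10, 1.4)]
        with pytest.warns(UserWarning, match="unimodal"):
            labeled = assign_orthology(blocks, mix)
        assert all(lab == ORTHOLOGOUS for _, lab in labeled)

    def test_invariant_to_block_order(self):
        mix = _mixture((1.0, 0.05, 1), (1.3, 0.05, 1))
        blocks = [_block("c1", f"x{i}", 10 + i, 1.0 + 0.05 * i) for i in range(6)]
        fwd = assign_orthology(blocks, mix, max_depth=3)
        rev = assign_orthology(blocks[::-1], mix, max_depth=3)
        assert [(b.chrom_b, lab) for b, lab in fwd] == [(b.chrom_b, lab) for b, lab in rev]

    def test_simulated_block_labels_recover_ground_truth(self, sharp_clade):
        """With well-separated peaks, at least 95% of reference-target blocks
        are labeled by their true separating event."""
        _table, labeled, _ref = _analyze(sharp_clade)
        anc = sharp_clade.ancestral_of
        subg = sharp_clade.subgenome_of
        correct = total = 0
        for b, lab in labeled:
            # ground truth: a block is orthologous when its anchors join genes
            # from the same hexaploidy branch (separated by the speciation)
            votes = []
            for a in b.anchors[:10]:
                same_branch = subg[a.gene_a].split(".")[0] == subg[a.gene_b].split(".")[0]
                votes.append(same_branch)
            truth = ORTHOLOGOUS if np.mean(votes) > 0.5 else OUTPARALOGOUS
            total += 1
            correct += truth == lab
        assert total > 20
        assert correct / total >= 0.95


class TestEventTable:
    def test_18_columns_for_one_outgroup_and_four_target_columns(self, noloss_clade):
        table, _, _ = _analyze(noloss_clade)
        assert table.n_columns == 18

    @pytest.mark.parametrize("d,n_outgroups", [(0, 1), (1, 1), (2, 2), (3, 0)])
    def test_column_count_formula(self, d, n_outgroups):
        ref = GenomeTable("ref", __import__("pandas").DataFrame(
            {"gene_id": ["g1"], "chrom": ["c1"], "start": [0], "end": [10], "strand": ["+"]}
        ))
        ogs = {f"og{i}": [] for i in range(n_outgroups)}
        table = build_event_table(ref, {}, [], ogs, {}, target_genome="tgt",
                                  n_target_cols=2 ** d)
        assert table.n_columns == 3 * (1 + n_outgroups + 2 ** d)

    def test_noloss_simulation_has_no_missing_target_cells(self, noloss_clade):
        table, _, _ = _analyze(noloss_clade)
        for ref_col in (1, 2, 3):
            assert table.presence(ref_col).all()

    def test_rows_follow_reference_gene_order(self, noloss_clade):
        table, _, ref = _analyze(noloss_clade)
        expected = list(ref.df.sort_values(["chrom", "rank"])["gene_id"])
        assert list(table.df[f"{ref.genome}_1"]) == expected

    def test_filled_cells_match_ground_truth(self, sharp_clade):
        """At least 90% of filled target cells name a true homolog (same
        ancestral gene) of the column-head reference gene."""
        table, _, _ = _analyze(sharp_clade)
        anc = sharp_clade.ancestral_of
        ok = total = 0
        for ref_col in (1, 2, 3):
            head = table.df[f"reference_{ref_col}"]
            for col in table.target_column_names(ref_col):
                for h, t in zip(head, table.df[col]):
                    if h != MISSING and t != MISSING:
                        total += 1
                        ok += anc[t] == anc[h]
        assert total > 500
        assert ok / total >= 0.90

    def test_target_gene_assigned_to_one_reference_gene(self, sharp_clade):
        """Each target gene anchors to a single reference gene: it appears at
        most once in the column-1 target group, and any mirror occurrence in
        a partner row's group agrees with that single assignment."""
        table, _, _ = _analyze(sharp_clade)
        assigned = {}
        heads = table.df["reference_1"]
        for col in table.target_column_names(1):
            for h, t in zip(heads, table.df[col]):
                if t != MISSING:
                    assert t not in assigned
                    assigned[t] = h
        for ref_col in (2, 3):
            partner_heads = table.df[f"reference_{ref_col}"]
            for col in table.target_column_names(ref_col):
                for p, t in zip(partner_heads, table.df[col]):
                    if t != MISSING:
                        assert assigned.get(t) == p


class TestClassifyLoss:
    def test_intact_pattern_has_no_losses(self):
        assert classify_loss((1, 1, 1, 1)) == (0, 0, 0)

    def test_one_pair_lost_is_one_intermediate_loss(self):
        assert classify_loss((0, 0, 1, 1)) == (0, 1, 0)

    def test_all_absent_is_one_ancestral_loss(self):
        assert classify_loss((0, 0, 0, 0)) == (1, 0, 0)

    @pytest.mark.parametrize("pattern", list(product([0, 1], repeat=4)))
    def test_all_16_patterns_match_minimum_event_oracle(self, pattern):
        assert classify_loss(pattern) == oracle_classify_loss(pattern)


class TestOrthologDepth:
    def test_unfractionated_double_duplication_depth_is_four(self, noloss_clade):
        _, labeled, ref = _analyze(noloss_clade)
        profile = ortholog_depth(ref, labeled, window=50)
        assert profile.modal_depth == 4
        assert set(profile.histogram) == {4}

    def test_triplicated_target_depth_is_three(self):
        cfg = EvolConfig(
            n_ancestral_genes=150, n_chromosomes=1,
            events=[
                Event("speciation", "reference", 0.9, "split", new_lineage="target",
                      ks_sd=0.03),
                Event("wgt", "target", 0.5, "hex", ks_sd=0.04),
            ],
            rate_multiplier={"reference": 1.0, "target": 1.0}, seed=2,
        )
        clade = simulate_history(cfg)
        pairs = clade.true_pairs.rename(columns={"true_ks": "ks"})
        ref, tgt = clade.genomes["reference"], clade.genomes["target"]
        blocks = detect_blocks(ref, tgt, pairs)
        mix = fit_mixture([a.ks for b in blocks for a in b.anchors], seed=3)
        with pytest.warns(UserWarning, match="unimodal"):
            labeled = assign_orthology(blocks, mix, max_depth=3)
        profile = ortholog_depth(ref, labeled, window=50)
        assert profile.modal_depth == 3

    def test_fractionated_depth_at_most_four(self, sharp_clade):
        _, labeled, ref = _analyze(sharp_clade)
        profile = ortholog_depth(ref, labeled, window=50)
        assert profile.modal_depth <= 4
        assert sum(profile.histogram.get(d, 0) for d in (2, 3, 4)) >= 0.8 * sum(
            profile.histogram.values()
        )


class TestNjTopology:
    LABELS = ["ref", "t11", "t12", "t21", "t22"]
    PAIRS = (("t11", "t12"), ("t21", "t22"))

    def test_additive_true_tree_supports(self):
        D = additive_distances(self.LABELS, self.PAIRS, "ref", 0.55, 0.94, 1.08)
        v = nj_topology(D, self.LABELS, "ref", self.PAIRS)
        assert v.verdict == "supports"

    def test_swapped_sister_conflicts(self):
        swapped = (("t11", "t21"), ("t12", "t22"))
        D = additive_distances(self.LABELS, swapped, "ref", 0.55, 0.94, 1.08)
        v = nj_topology(D, self.LABELS, "ref", self.PAIRS)
        assert v.verdict == "conflicts"

    def test_degenerate_distances_unresolved(self):
        D = np.ones((5, 5)) - np.eye(5)
        v = nj_topology(D, self.LABELS, "ref", self.PAIRS)
        assert v.verdict == "unresolved"

    def test_invalid_matrix_rejected(self):
        D = np.zeros((5, 5))
        D[0, 1] = 1.0  # asymmetric
        with pytest.raises(ValueError):
            nj_topology(D, self.LABELS, "ref", self.PAIRS)

    def test_agrees_with_skbio_nj_on_random_additive_matrices(self):
        """Internal NJ recovers the same supports/conflicts verdicts as
        scikit-bio's NJ on noisy additive matrices."""
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(31)
        agree = 0
        trials = 20
        for _ in range(trials):
            D = additive_distances(self.LABELS, self.PAIRS, "ref", 0.5, 0.9, 1.1)
            noise = rng.normal(0, 0.02, D.shape)
            noise = (noise + noise.T) / 2
            np.fill_diagonal(noise, 0)
            Dn = np.abs(D + noise)
            mine = nj_topology(Dn, self.LABELS, "ref", self.PAIRS).verdict
            tree = skbio_nj(DistanceMatrix(Dn, self.LABELS))
            everyone = frozenset(self.LABELS)
            splits = set()
            for node in tree.non_tips(include_self=False):
                s = frozenset(t.name for t in node.tips())
                if 1 < len(s) < len(everyone) - 1:
                    splits.add(s if len(s) <= len(everyone) - len(s) else everyone - s)
            skbio_supports = (
                frozenset(self.PAIRS[0]) in splits and frozenset(self.PAIRS[1]) in splits
            )
            expected = "supports" if skbio_supports else "conflicts"
            agree += mine == expected
        assert agree == trials

    def test_noisy_simulated_groups_mostly_support(self):
        """With peaks separated by >=4 sigma, at least 70% of gene groups
        recover the expected two-cherry topology."""
        rng = np.random.default_rng(17)
        supports = 0
        n_groups = 200
        for _ in range(n_groups):
            D = additive_distances(self.LABELS, self.PAIRS, "ref", 0.551, 0.944, 1.085)
            noise = rng.normal(0, 0.06, D.shape)
            noise = (noise + noise.T) / 2
            np.fill_diagonal(noise, 0)
            v = nj_topology(np.abs(D + noise), self.LABELS, "ref", self.PAIRS)
            supports += v.verdict == "supports"
        assert supports / n_groups >= 0.70
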