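import numpy as np
import pytest

from moltloss.homolog import ScreenConfig, reciprocal_top_hits
from moltloss.io import State
from moltloss.simulate import (
    FOLD_TEMPLATES,
    fold_template,
    gen_expression_timecourse,
    gen_hit_tables,
    gen_orthogroups,
    gen_presence_matrix,
    gen_random_tree,
    gen_structure_pair,
)
from moltloss.structure import lbd_length_filter, tm_score


class TestDeterminism:
    def test_all_generators_reproduce_for_fixed_seed(self, major_taxon_tree):
        tree = gen_random_tree(8, seed=1)
        m1, t1 = gen_presence_matrix(tree, 20, 0.1, 0.1, seed=2)
        m2, t2 = gen_presence_matrix(tree, 20, 0.1, 0.1, seed=2)
        assert m1.data.equals(m2.data) and t1.loss_edges == t2.loss_edges

        probs = {"Nematoda": 0.5, "Rhabditina": 0.5}
        o1, _ = gen_orthogroups(major_taxon_tree, 2, 10, probs, seed=3)
        o2, _ = gen_orthogroups(major_taxon_tree, 2, 10, probs, seed=3)
        assert o1.groups == o2.groups

        e1, _ = gen_expression_timecourse(n_genes=30, seed=4)
        e2, _ = gen_expression_timecourse(n_genes=30, seed=4)
        assert e1.values.equals(e2.values)

        omap = {("A", "B"): {"a1": "b1", "a2": "b2"}}
        h1 = gen_hit_tables(omap, decoy_count=3, seed=5)
        h2 = gen_hit_tables(omap, decoy_count=3, seed=5)
        assert h1[("A", "B")].data.equals(h2[("A", "B")].data)

        s1, _ = gen_structure_pair("meander", 2, seed=6)
        s2, _ = gen_structure_pair("meander", 2, seed=6)
        assert np.array_equal(s1[0].coords, s2[0].coords)


class TestPresenceGenerator:
    def test_zero_loss_rate_gives_all_present(self):
        tree = gen_random_tree(10, seed=7)
        matrix, truth = gen_presence_matrix(tree, 30, loss_rate=0.0, seed=7)
        assert all(
            s is State.PRESENT for s in matrix.data.to_numpy().ravel()
        )
        assert all(not e for e in truth.loss_edges.values())

    def test_full_missing_rate_hides_all_absences(self):
        tree = gen_random_tree(10, seed=8)
        matrix, _ = gen_presence_matrix(tree, 50, loss_rate=0.3, missing_rate=1.0, seed=8)
        assert State.ABSENT not in set(matrix.data.to_numpy().ravel())

    def test_per_edge_loss_frequency_matches_rate(self):
        """Empirical loss frequency on the first root edge is within 3
        binomial SE of the configured rate over 10,000 families."""
        tree = gen_random_tree(6, seed=9)
        rate, n = 0.1, 10_000
        _, truth = gen_presence_matrix(tree, n, loss_rate=rate, seed=9)
        first_edge = next(
            node.name for node in tree.preorder() if node is not tree.root
        )
        freq = sum(first_edge in e for e in truth.loss_edges.values()) / n
        se = np.sqrt(rate * (1 - rate) / n)
        assert abs(freq - rate) < 3 * se


class TestOrthogroupGenerator:
    def test_zero_thinning_preserves_origins(self, major_taxon_tree):
        from moltloss.ancestral import assign_og_origin

        probs = {"Nematoda": 0.3, "Rhabditida": 0.3, "Tylenchina": 0.4}
        table, truth = gen_orthogroups(
            major_taxon_tree, 2, 40, probs, within_taxon_loss=0.0, seed=10
        )
        for og, planted in truth.og_origins.items():
            o = assign_og_origin(table.groups[og], truth.taxon_of, major_taxon_tree)
            assert o.origin == planted

    def test_root_concentrated_origins_cover_all_taxa(self, major_taxon_tree):
        table, _ = gen_orthogroups(major_taxon_tree, 2, 20, {"Nematoda": 1.0}, seed=11)
        taxa = set(major_taxon_tree.leaf_labels)
        for og in table.og_ids:
            covered = {
                sp.rsplit("_sp", 1)[0] for sp in table.species_represented(og)
            }
            assert covered == taxa

    def test_origin_frequencies_match_multinomial(self, major_taxon_tree):
        probs = {"Nematoda": 0.5, "Rhabditina": 0.5}
        n = 2000
        _, truth = gen_orthogroups(major_taxon_tree, 1, n, probs, seed=12)
        count = sum(1 for o in truth.og_origins.values() if o == "Nematoda")
        se = np.sqrt(n * 0.25)
        assert abs(count - n * 0.5) < 3 * se


class TestExpressionGenerator:
    def test_noiseless_planted_peaks_at_offset(self):
        tc, truth = gen_expression_timecourse(n_genes=40, noise_sd=0.0, seed=13)
        molts = tc.molt_times
        for g in truth.planted_genes:
            profile = tc.values.loc[g].to_numpy()
            peak_time = tc.times[profile.argmax()]
            assert any(abs(peak_time - (m - truth.peak_offset)) < 1e-9 for m in molts)

    def test_zero_fraction_plants_nothing(self):
        tc, truth = gen_expression_timecourse(n_genes=30, frac_premolt=0.0, seed=14)
        assert truth.planted_genes == []
        assert tc.values.shape[0] == 30

    def test_artifacts_validate_type_invariants(self):
        tc, _ = gen_expression_timecourse(n_genes=20, seed=15)
        vals = tc.values.to_numpy()
        assert (vals >= 0).all() and np.isfinite(vals).all()
        assert (np.diff(tc.times) > 0).all()


class TestHitGenerator:
    def test_no_decoys_recovers_bijection_exactly(self):
        omap = {("A", "B"): {f"a{i}": f"b{i}" for i in range(10)}}
        tables = gen_hit_tables(omap, decoy_count=0, seed=16)
        pairs = reciprocal_top_hits(tables[("A", "B")], tables[("B", "A")], ScreenConfig())
        assert pairs == set(omap[("A", "B")].items())

    def test_recall_monotone_in_decoy_separation_with_jitter(self):
        """With lognormal jitter undercutting the decoy bound, recall
        improves monotonically as the separation factor grows."""
        omap = {("A", "B"): {f"a{i}": f"b{i}" for i in range(30)}}
        recalls = []
        for factor in (1.01, 3.0, 1e3, 1e8):
            hits = 0
            for seed in range(15):
                tables = gen_hit_tables(
                    omap, decoy_count=60, decoy_evalue_factor=factor,
                    seed=seed, decoy_jitter_sd=6.0,
                )
                pairs = reciprocal_top_hits(
                    tables[("A", "B")], tables[("B", "A")], ScreenConfig()
                )
                hits += len(pairs & set(omap[("A", "B")].items()))
            recalls.append(hits / (30 * 15))
        assert recalls == sorted(recalls)
        assert recalls[0] < 1.0

    def test_factor_must_exceed_one(self):
        with pytest.raises(ValueError):
            gen_hit_tables({("A", "B"): {"a": "b"}}, decoy_evalue_factor=1.0)


class TestStructureGenerator:
    def test_noiseless_copy_scores_one(self):
        for tpl in FOLD_TEMPLATES:
            base = fold_template(tpl)
            chains, truth = gen_structure_pair(tpl, 2, coord_noise=0.0, seed=17)
            pairs = np.column_stack([np.arange(len(base))] * 2)
            for c in chains:
                assert tm_score(c.coords, base.coords, pairs) > 1.0 - 1e-6
                assert truth.template_of[c.source] == tpl

    def test_copies_pass_length_filter(self):
        chains, _ = gen_structure_pair("meander", 4, seed=18)
        assert lbd_length_filter(chains) == chains

    def test_unknown_template_rejected(self):
        with pytest.raises(ValueError):
            fold_template("nope")
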