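import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from moltloss.io import StructureChain
from moltloss.simulate import fold_template, gen_structure_pair
from moltloss.structure import (
    AlignmentFailedError,
    DegenerateInputError,
    align_structures,
    classify_against_references,
    kabsch_superpose,
    lbd_length_filter,
    tm_d0,
    tm_score,
)


def _chain(coords, name="c"):
    coords = np.asarray(coords, float)
    return StructureChain(np.arange(1, len(coords) + 1), coords, "A", name)


def _random_chain(n, seed):
    rng = np.random.default_rng(seed)
    # random walk with ~3.8 A steps, CA-trace-like
    steps = rng.normal(size=(n, 3))
    steps = 3.8 * steps / np.linalg.norm(steps, axis=1, keepdims=True)
    return _chain(np.cumsum(steps, axis=0), f"rw{seed}")


class TestLengthFilter:
    def test_boundary(self):
        keep151 = _random_chain(151, 0)
        drop150 = _random_chain(150, 1)
        out = lbd_length_filter([keep151, drop150])
        assert out == [keep151]

    def test_empty_input(self):
        assert lbd_length_filter([]) == []


class TestKabsch:
    def test_identity_superposition(self):
        P = np.random.default_rng(0).normal(size=(20, 3))
        sup = kabsch_superpose(P, P)
        assert sup.rmsd < 1e-12
        assert np.allclose(sup.rotation, np.eye(3), atol=1e-9)

    def test_construct_and_recover_random_transform(self):
        rng = np.random.default_rng(1)
        for seed in range(10):
            P = rng.normal(size=(30, 3)) * 5
            R = Rotation.random(random_state=rng).as_matrix()
            t = rng.uniform(-10, 10, 3)
            Q = P @ R.T + t
            sup = kabsch_superpose(P, Q)
            assert sup.rmsd < 1e-9
            assert np.allclose(sup.rotation, R, atol=1e-8)
            assert np.allclose(sup.translation, t, atol=1e-8)

    def test_rotation_always_proper(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            P = rng.normal(size=(10, 3))
            Q = rng.normal(size=(10, 3))  # arbitrary, reflection-tempting
            sup = kabsch_superpose(P, Q)
            assert np.isclose(np.linalg.det(sup.rotation), 1.0, atol=1e-9)
            assert np.allclose(sup.rotation @ sup.rotation.T, np.eye(3), atol=1e-9)

    def test_noise_rmsd_matches_theory(self):
        """With isotropic noise sigma, fitted RMSD approaches
        sigma * sqrt(3) * sqrt(1 - 6/N) (6 dof absorbed by the fit)."""
        rng = np.random.default_rng(3)
        N, sigma = 500, 0.7
        rmsds = []
        for _ in range(20):
            P = rng.normal(size=(N, 3)) * 10
            Q = P + rng.normal(0, sigma, size=(N, 3))
            rmsds.append(kabsch_superpose(P, Q).rmsd)
        expected = sigma * np.sqrt(3) * np.sqrt(1 - 6 / N)
        assert abs(np.mean(rmsds) - expected) / expected < 0.10

    def test_too_few_pairs_raises(self):
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_configuration_raises(self):
        line = np.outer(np.arange(10), [1.0, 0.0, 0.0])
        with pytest.raises(DegenerateInputError):
            kabsch_superpose(line, line)


class TestTmScore:
    def test_self_score_is_exactly_one(self):
        chain = fold_template("helix_bundle")
        pairs = np.column_stack([np.arange(len(chain))] * 2)
        assert tm_score(chain.coords, chain.coords, pairs) == 1.0

    def test_rigid_copy_scores_one(self):
        chain = fold_template("meander")
        rng = np.random.default_rng(4)
        R = Rotation.random(random_state=rng).as_matrix()
        moved = chain.coords @ R.T + [3.0, -2.0, 7.0]
        pairs = np.column_stack([np.arange(len(chain))] * 2)
        assert tm_score(moved, chain.coords, pairs) > 1.0 - 1e-9

    def test_d0_closed_form(self):
        assert np.isclose(tm_d0(120), 1.24 * 105 ** (1 / 3) - 1.8)

    def test_d0_clamp_active_for_short_chains(self):
        for L in (3, 10, 15, 18, 21):
            assert tm_d0(L) == 0.5

    def test_too_short_normalization_raises(self):
        with pytest.raises(ValueError):
            tm_d0(2)


class TestAlignStructures:
    def test_identical_chains_align_fully(self):
        chain = fold_template("helix_bundle")
        aln = align_structures(chain, chain)
        assert aln.n_aligned == len(chain)
        assert aln.tm == pytest.approx(1.0, abs=1e-9)

    def test_correspondence_monotone_and_injective(self):
        chains, _ = gen_structure_pair("helix_bundle", 1, coord_noise=0.5, seed=6)
        aln = align_structures(chains[0], fold_template("helix_bundle"))
        assert (np.diff(aln.pairs[:, 0]) > 0).all()
        assert (np.diff(aln.pairs[:, 1]) > 0).all()

    def test_score_invariant_under_rigid_pretransform(self):
        ref = fold_template("helix_bundle")
        chains, _ = gen_structure_pair("helix_bundle", 1, coord_noise=0.5, seed=7)
        base = align_structures(chains[0], ref).tm
        rng = np.random.default_rng(8)
        for _ in range(3):
            R = Rotation.random(random_state=rng).as_matrix()
            moved = StructureChain(
                chains[0].residue_ids,
                chains[0].coords @ R.T + rng.uniform(-30, 30, 3),
                "A",
                "moved",
            )
            assert abs(align_structures(moved, ref).tm - base) < 1e-6

    def test_same_fold_beats_different_fold(self):
        ref = fold_template("helix_bundle")
        same, _ = gen_structure_pair("helix_bundle", 5, coord_noise=0.5, seed=9)
        diff, _ = gen_structure_pair("meander", 5, coord_noise=0.5, seed=10)
        for s, d in zip(same, diff):
            assert align_structures(s, ref).tm > align_structures(d, ref).tm


class TestClassification:
    def test_noisy_copies_classified_to_their_template(self):
        refs = {
            "helix_bundle": fold_template("helix_bundle"),
            "meander": fold_template("meander"),
        }
        queries = {}
        for tpl in refs:
            chains, _ = gen_structure_pair(tpl, 3, coord_noise=0.5, seed=11)
            queries.update({c.source: c for c in chains})
        sm = classify_against_references(queries, refs)
        for qid, ref in sm.assignments.items():
            assert qid.startswith(ref)

    def test_duplicated_reference_ties_break_lexicographically(self):
        tpl = fold_template("helix_bundle")
        refs = {"refB": tpl, "refA": tpl}
        queries = {"q": tpl}
        sm = classify_against_references(queries, refs)
        assert sm.assignments["q"] == "refA"
        assert "q" in sm.ties

    def test_histogram_uses_fixed_bin_width(self):
        refs = {
            "helix_bundle": fold_template("helix_bundle"),
            "meander": fold_template("meander"),
        }
        chains, _ = gen_structure_pair("helix_bundle", 2, coord_noise=0.5, seed=12)
        sm = classify_against_references({c.source: c for c in chains}, refs)
        counts, edges = sm.histogram("helix_bundle")
        assert np.allclose(np.diff(edges), 0.02)
        assert counts.sum() == 2

    def test_requires_two_references(self):
        tpl = fold_template("meander")
        with pytest.raises(ValueError):
            classify_against_references({"q": tpl}, {"r": tpl})
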