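import numpy as np
import pytest

from scduet._nn import MLPClassifier, relu, softmax
from scduet.decomposer import (
    DoubletDecomposer,
    NetworkSpec,
    SelectionResult,
    TrainedDecomposer,
    TrainingConfig,
    select_cells,
)
from scduet.doublet_synthesis import build_training_set, sample_recipes
from scduet.expr_data import ExpressionMatrix

from conftest import tiny_matrix


@pytest.fixture(scope="module")
def trained(small_sim_split_module):
    mat_a, mat_b = small_sim_split_module
    recipes = sample_recipes(mat_a.n_cells, mat_b.n_cells, 600, seed=13)
    dset = build_training_set(mat_a, mat_b, recipes)
    d = dset.mixtures.shape[1]
    model = DoubletDecomposer(
        dset,
        mat_a.cell_ids,
        mat_b.cell_ids,
        spec_a=NetworkSpec(d, mat_a.n_cells, (64, 32)),
        spec_b=NetworkSpec(d, mat_b.n_cells, (64, 32)),
    )
    fitted = model.fit(TrainingConfig(epochs=8, batch_size=64, seed=13))
    return fitted, dset


@pytest.fixture(scope="module")
def small_sim_split_module():
    from conftest import SMALL_CONFIG
    from scduet.synthetic_data import simulate_two_types

    matrix, truth = simulate_two_types(SMALL_CONFIG)
    is_a = truth.cell_type == "A"
    return (
        matrix.subset_cells(np.where(is_a)[0]),
        matrix.subset_cells(np.where(~is_a)[0]),
    )


class TestActivations:
    def test_relu(self):
        np.testing.assert_array_equal(relu(np.array([-3.0, 0.0, 2.0])), [0, 0, 2])

    def test_softmax_closed_form(self):
        np.testing.assert_allclose(
            softmax(np.array([np.log(2), 0.0])), [2 / 3, 1 / 3], atol=1e-12
        )

    def test_softmax_of_constant_is_uniform(self):
        np.testing.assert_allclose(softmax(np.zeros(7)), np.full(7, 1 / 7))

    def test_untrained_forward_is_valid_distribution(self):
        net = MLPClassifier(20, (8,), 5, seed=0)
        proba = net.predict_proba(np.random.default_rng(0).random((10, 20)))
        assert proba.shape == (10, 5)
        assert proba.min() >= 0 and proba.max() <= 1
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-6)

    def test_dimension_mismatch_rejected(self):
        net = MLPClassifier(20, (8,), 5, seed=0)
        with pytest.raises(ValueError):
            net.predict_proba(np.ones(19))


class TestTraining:
    def test_loss_decreases(self, trained):
        fitted, _ = trained
        for hist in fitted.loss_history.values():
            assert hist[-1] < hist[0]

    def test_memorizes_singleton_dataset(self):
        rng = np.random.default_rng(0)
        profile = rng.integers(0, 50, size=120).astype(float)
        mixtures = np.tile(profile, (64, 1))
        from scduet.doublet_synthesis import ArtificialDoubletSet, DoubletRecipe

        dset = ArtificialDoubletSet(
            mixtures=mixtures,
            recipes=[DoubletRecipe(2, 1, 0.5)] * 64,
            gene_ids=np.array([f"g{i}" for i in range(120)], dtype=object),
        )
        model = DoubletDecomposer(
            dset,
            ref_ids_a=[f"A{i}" for i in range(4)],
            ref_ids_b=[f"B{i}" for i in range(4)],
            spec_a=NetworkSpec(120, 4, (16,)),
            spec_b=NetworkSpec(120, 4, (16,)),
        )
        fitted = model.fit(TrainingConfig(epochs=150, batch_size=32, seed=0))
        scores = fitted.score_doublets(dset)
        assert scores.scores_a[0, 2] > 0.99
        assert scores.scores_b[0, 1] > 0.99

    def test_same_seed_reproducible(self, small_sim_split_module):
        mat_a, mat_b = small_sim_split_module
        recipes = sample_recipes(mat_a.n_cells, mat_b.n_cells, 200, seed=5)
        dset = build_training_set(mat_a, mat_b, recipes)
        d = dset.mixtures.shape[1]

        def fit_once():
            model = DoubletDecomposer(
                dset,
                mat_a.cell_ids,
                mat_b.cell_ids,
                spec_a=NetworkSpec(d, mat_a.n_cells, (32,)),
                spec_b=NetworkSpec(d, mat_b.n_cells, (32,)),
            )
            return model.fit(TrainingConfig(epochs=3, batch_size=64, seed=7))

        s1 = fit_once().score_doublets(dset)
        s2 = fit_once().score_doublets(dset)
        np.testing.assert_array_equal(s1.scores_a, s2.scores_a)
        np.testing.assert_array_equal(s1.scores_b, s2.scores_b)

    def test_validation_fraction_tracks_holdout_loss(self, small_sim_split_module):
        mat_a, mat_b = small_sim_split_module
        recipes = sample_recipes(mat_a.n_cells, mat_b.n_cells, 300, seed=6)
        dset = build_training_set(mat_a, mat_b, recipes)
        d = dset.mixtures.shape[1]
        model = DoubletDecomposer(
            dset, mat_a.cell_ids, mat_b.cell_ids,
            spec_a=NetworkSpec(d, mat_a.n_cells, (32,)),
            spec_b=NetworkSpec(d, mat_b.n_cells, (32,)),
        )
        fitted = model.fit(
            TrainingConfig(epochs=4, batch_size=64, seed=6, validation_fraction=0.2)
        )
        assert len(fitted.network_a.val_loss_history_) == 4
        assert all(np.isfinite(v) for v in fitted.network_a.val_loss_history_)

    def test_too_few_doublets_for_batch_rejected(self, small_sim_split_module):
        mat_a, mat_b = small_sim_split_module
        recipes = sample_recipes(mat_a.n_cells, mat_b.n_cells, 10, seed=5)
        dset = build_training_set(mat_a, mat_b, recipes)
        model = DoubletDecomposer(dset, mat_a.cell_ids, mat_b.cell_ids,
                                  spec_a=NetworkSpec(dset.mixtures.shape[1], mat_a.n_cells, (8,)),
                                  spec_b=NetworkSpec(dset.mixtures.shape[1], mat_b.n_cells, (8,)))
        with pytest.raises(ValueError):
            model.fit(TrainingConfig(epochs=1, batch_size=256))

    def test_inconsistent_panel_size_rejected(self, small_sim_split_module):
        mat_a, mat_b = small_sim_split_module
        recipes = sample_recipes(mat_a.n_cells, mat_b.n_cells, 50, seed=5)
        dset = build_training_set(mat_a, mat_b, recipes)
        with pytest.raises(ValueError):
            DoubletDecomposer(dset, mat_a.cell_ids[:3], mat_b.cell_ids)


class TestScoring:
    def test_score_vectors_sum_to_one(self, trained):
        fitted, dset = trained
        scores = fitted.score_doublets(dset)
        np.testing.assert_allclose(scores.scores_a.sum(axis=1), 1.0, atol=1e-5)
        np.testing.assert_allclose(scores.scores_b.sum(axis=1), 1.0, atol=1e-5)

    def test_scoring_is_deterministic(self, trained):
        fitted, dset = trained
        s1 = fitted.score_doublets(dset)
        s2 = fitted.score_doublets(dset)
        np.testing.assert_array_equal(s1.scores_a, s2.scores_a)

    def test_cpm_scale_invariance(self, trained):
        fitted, dset = trained
        scaled = ExpressionMatrix(
            dset.mixtures[:5].astype(np.int64) * 10,
            cell_ids=[f"d{i}" for i in range(5)],
            gene_ids=dset.gene_ids,
        )
        base = ExpressionMatrix(
            dset.mixtures[:5].astype(np.int64),
            cell_ids=[f"d{i}" for i in range(5)],
            gene_ids=dset.gene_ids,
        )
        s10 = fitted.score_doublets(scaled)
        s1 = fitted.score_doublets(base)
        np.testing.assert_allclose(s10.scores_a, s1.scores_a, atol=1e-6)

    def test_low_gene_overlap_rejected(self, trained):
        fitted, dset = trained
        few = ExpressionMatrix(
            np.ones((2, 10), dtype=np.int64),
            cell_ids=["d0", "d1"],
            gene_ids=dset.gene_ids[:10],
        )
        with pytest.raises(ValueError):
            fitted.score_doublets(few)

    def test_checkpoint_round_trip(self, trained, tmp_path):
        fitted, dset = trained
        path = str(tmp_path / "model.npz")
        fitted.save(path)
        back = TrainedDecomposer.load(path)
        s1 = fitted.score_doublets(dset)
        s2 = back.score_doublets(dset)
        np.testing.assert_allclose(s1.scores_a, s2.scores_a, atol=1e-7)
        assert list(back.gene_ids) == list(fitted.gene_ids)


def _selection(scores_a, ref_ids=None):
    scores_a = np.asarray(scores_a, dtype=float)
    k = scores_a.shape[1]
    if ref_ids is None:
        ref_ids = np.array([f"A{i}" for i in range(k)], dtype=object)
    uniform_b = np.full((scores_a.shape[0], 2), 0.5)
    return SelectionResult(
        scores_a=scores_a,
        scores_b=uniform_b,
        ref_ids_a=np.asarray(ref_ids, dtype=object),
        ref_ids_b=np.array(["B0", "B1"], dtype=object),
    )


class TestSelection:
    def test_argmax_and_tie_rule(self):
        sel = _selection([[0.7, 0.2, 0.1], [0.5, 0.5, 0.0]])
        pa, _ = sel.predict_pair()
        np.testing.assert_array_equal(pa, [0, 0])

    def test_permuting_references_permutes_predictions(self):
        rng = np.random.default_rng(3)
        scores = rng.dirichlet(np.ones(6), size=10)
        perm = rng.permutation(6)
        pa, _ = _selection(scores).predict_pair()
        pa_perm, _ = _selection(scores[:, perm]).predict_pair()
        np.testing.assert_array_equal(perm[pa_perm], pa)

    def test_cutoff_selects_strictly_above(self):
        scores = np.zeros((1, 100))
        scores[0, 0] = 0.98
        scores[0, 1] = 0.011
        scores[0, 2] = 0.005
        scores[0, 3:] = 0.004 / 97
        sel = _selection(scores, ref_ids=[f"A{i}" for i in range(100)])
        assert sel.selected("a") == {"A0", "A1"}

    def test_uniform_scores_at_cutoff_select_nothing(self):
        sel = _selection(np.full((3, 100), 0.01),
                         ref_ids=[f"A{i}" for i in range(100)])
        assert sel.selected("a") == set()

    def test_zero_cutoff_selects_every_nonzero(self):
        scores = np.zeros((1, 4))
        scores[0, :2] = 0.5
        sel = _selection(scores, ref_ids=["A0", "A1", "A2", "A3"])
        assert sel.selected("a", cutoff=0.0) == {"A0", "A1"}

    def test_union_aggregates_over_doublets(self):
        scores = np.array([[0.99, 0.005, 0.005], [0.005, 0.99, 0.005]])
        sel = _selection(scores)
        both = select_cells(sel)
        assert both["a"] == {"A0", "A1"}

    def test_per_doublet_mode(self):
        scores = np.array([[0.99, 0.005, 0.005], [0.005, 0.99, 0.005]])
        sel = _selection(scores)
        per = sel.selected("a", mode="per_doublet")
        assert per == [["A0"], ["A1"]]

    def test_malformed_scores_rejected(self):
        with pytest.raises(ValueError):
            _selection([[0.5, 0.1, 0.1]])
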