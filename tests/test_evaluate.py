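import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hmaxga import (
    ExperimentConfig,
    GAConfig,
    LabeledDataset,
    compare_runs,
    eer_performance,
    equilibrium_error,
    population_matrix,
    roc_auc,
    run_experiment,
    selection_percentage,
    split_counts,
    split_three_way,
    train_linear_classifier,
)
from hmaxga.patches import Patch, PatchDictionary
from hmaxga.synthetic import FixtureSpec, generate_dataset

from _oracles import auc_all_pairs, eer_sweep


def dummy_dataset(n_per_class, seed=0):
    rng = np.random.default_rng(seed)
    images, labels, ids = [], [], []
    for label, name in ((1, "pos"), (-1, "neg")):
        for k in range(n_per_class):
            images.append(rng.random((6, 6)))
            labels.append(label)
            ids.append(f"{name}_{k:03d}")
    return LabeledDataset(images=images, labels=np.asarray(labels), ids=ids)


class TestSplits:
    def test_equal_thirds(self):
        ds = dummy_dataset(90)
        split = split_three_way(ds, seed=0)
        assert len(split.train_ids) == len(split.eval_ids) == \
            len(split.test_ids) == 60
        for ids in (split.train_ids, split.eval_ids, split.test_ids):
            labels = [ds.label_of(i) for i in ids]
            assert labels.count(1) == labels.count(-1) == 30

    def test_remainder_dropped(self):
        ds = dummy_dataset(31)
        split = split_three_way(ds, seed=1)
        used = len(split.train_ids) + len(split.eval_ids) + len(split.test_ids)
        assert used == 60  # 10+10+10 per class, 1 dropped per class
        assert len(set(split.train_ids) | set(split.eval_ids)
                   | set(split.test_ids)) == used

    def test_deterministic_from_seed(self):
        ds = dummy_dataset(30)
        a, b = split_three_way(ds, 5), split_three_way(ds, 5)
        c = split_three_way(ds, 6)
        assert a.train_ids == b.train_ids and a.test_ids == b.test_ids
        assert a.train_ids != c.train_ids

    def test_too_few_images_rejected(self):
        with pytest.raises(ValueError):
            split_three_way(dummy_dataset(2), 0)

    @pytest.mark.parametrize("protocol,train_n,test_n",
                             [("graz01", 100, 50), ("graz02", 150, 75)])
    def test_fixed_count_protocols(self, protocol, train_n, test_n):
        ds = dummy_dataset(train_n + test_n + 5)
        split = split_counts(ds, protocol, seed=0)
        for ids, count in ((split.train_ids, train_n), (split.test_ids, test_n)):
            labels = [ds.label_of(i) for i in ids]
            assert labels.count(1) == labels.count(-1) == count
        assert not set(split.train_ids) & set(split.test_ids)

    def test_insufficient_images_named_in_error(self):
        with pytest.raises(ValueError, match="short by"):
            split_counts(dummy_dataset(100), "graz01", seed=0)


class TestLinearClassifier:
    def test_separable_toy_perfectly_fit(self):
        rng = np.random.default_rng(0)
        y = np.array([1] * 20 + [-1] * 20)
        X = (y + rng.normal(0, 0.1, 40)).reshape(-1, 1)
        scorer = train_linear_classifier(X, y)
        pred = np.where(scorer(X) >= 0, 1, -1)
        assert (pred == y).all()

    def test_refitting_same_data_is_deterministic(self):
        rng = np.random.default_rng(1)
        X = rng.random((30, 5))
        y = np.array([1, -1] * 15)
        s1 = train_linear_classifier(X, y)
        s2 = train_linear_classifier(X.copy(), y.copy())
        probe = rng.random((10, 5))
        assert np.array_equal(s1(probe), s2(probe))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_linear_classifier(np.zeros((5, 2)), np.ones(5))

    def test_score_linear_in_features(self):
        rng = np.random.default_rng(2)
        X = rng.random((40, 3))
        y = np.where(X[:, 0] > 0.5, 1, -1)
        scorer = train_linear_classifier(X, y)
        a, b = rng.random((2, 3))
        mid = scorer(np.vstack([a, b, (a + b) / 2]))
        assert abs(mid[2] - (mid[0] + mid[1]) / 2) < 1e-9


class TestEquilibriumError:
    def test_perfect_separation_gives_zero(self):
        scores = np.array([-2.0, -1.0, 1.0, 2.0])
        labels = np.array([-1, -1, 1, 1])
        assert equilibrium_error(scores, labels) == 0.0
        assert eer_performance(scores, labels) == 1.0

    def test_chance_level_near_half(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=400)
        labels = np.array([1, -1] * 200)
        assert abs(equilibrium_error(scores, labels) - 0.5) < 0.1

    def test_matches_threshold_sweep_oracle(self):
        scores = np.array([0.1, 0.4, 0.35, 0.8])
        labels = np.array([-1, -1, 1, 1])
        assert abs(equilibrium_error(scores, labels)
                   - eer_sweep(scores, labels)) < 1e-12

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(seed=st.integers(0, 2**20), n=st.integers(2, 30))
    def test_property_matches_oracle(self, seed, n):
        rng = np.random.default_rng(seed)
        scores = np.round(rng.normal(size=2 * n), 2)  # ties likely
        labels = np.array([1] * n + [-1] * n)
        assert abs(equilibrium_error(scores, labels)
                   - eer_sweep(scores, labels)) < 1e-12

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(size=60)
        labels = np.where(rng.random(60) < 0.5, 1, -1)
        labels[:2] = [1, -1]
        base = equilibrium_error(scores, labels)
        assert abs(equilibrium_error(np.exp(3 * scores), labels) - base) < 1e-12

    def test_degenerate_labels_rejected(self):
        with pytest.raises(ValueError):
            equilibrium_error(np.array([0.1, 0.2]), np.array([1, 1]))


class TestRocAuc:
    def test_perfect_and_reversed(self):
        labels = np.array([-1, -1, 1, 1])
        assert roc_auc(np.array([0.1, 0.2, 0.8, 0.9]), labels) == 1.0
        assert roc_auc(np.array([0.9, 0.8, 0.2, 0.1]), labels) == 0.0

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(seed=st.integers(0, 2**20), n=st.integers(2, 25))
    def test_matches_all_pairs_oracle(self, seed, n):
        rng = np.random.default_rng(seed)
        scores = np.round(rng.normal(size=2 * n), 1)
        labels = np.array([1] * n + [-1] * n)
        assert abs(roc_auc(scores, labels)
                   - auc_all_pairs(scores, labels)) < 1e-12

    def test_reversal_complements(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(size=40)
        labels = np.array([1, -1] * 20)
        assert abs(roc_auc(scores, labels)
                   + roc_auc(-scores, labels) - 1.0) < 1e-12


class TestCompareRuns:
    def test_identical_samples_not_significant(self):
        a = [0.8, 0.82, 0.85, 0.9, 0.7]
        p_rank, p_ks = compare_runs(a, list(a))
        assert p_rank >= 0.9 and p_ks >= 0.9

    def test_well_separated_samples_significant(self):
        rng = np.random.default_rng(6)
        a = rng.normal(0.0, 1.0, 10)
        b = rng.normal(10.0, 1.0, 10)
        p_rank, p_ks = compare_runs(a, b)
        assert p_rank < 0.01 and p_ks < 0.01

    def test_rank_sum_invariant_under_monotone_rescale(self):
        rng = np.random.default_rng(7)
        a, b = rng.normal(0, 1, 8), rng.normal(0.5, 1, 8)
        p1, _ = compare_runs(a, b)
        p2, _ = compare_runs(np.exp(a), np.exp(b))
        assert abs(p1 - p2) < 1e-12

    def test_short_inputs_rejected(self):
        with pytest.raises(ValueError):
            compare_runs([1.0, 2.0], [1.0, 2.0, 3.0])


def toy_dictionary():
    patches = []
    k = 0
    for n, count in ((4, 5), (8, 5), (12, 3), (16, 2)):
        for _ in range(count):
            patches.append(Patch(id=f"p{k}", values=np.zeros((4, n, n)),
                                 size_n=n, source_image="s", position=(0, 0)))
            k += 1
    return PatchDictionary(patches=patches, extraction_seed=0)


class TestSelectionAnalyses:
    def test_selection_percentage_arithmetic(self):
        pdict = toy_dictionary()
        bits = np.zeros(15, dtype=np.uint8)
        bits[:10] = 1  # all size-4 and size-8 patches
        pct = selection_percentage(bits, pdict)
        assert pct == {4: 50.0, 8: 50.0, 12: 0.0, 16: 0.0}

    def test_single_size_selection(self):
        pdict = toy_dictionary()
        bits = np.zeros(15, dtype=np.uint8)
        bits[10:13] = 1  # only size-12 patches
        pct = selection_percentage(bits, pdict)
        assert pct[12] == 100.0

    def test_percentages_sum_to_100(self):
        pdict = toy_dictionary()
        rng = np.random.default_rng(8)
        bits = (rng.random(15) < 0.4).astype(np.uint8)
        bits[0] = 1
        assert abs(sum(selection_percentage(bits, pdict).values()) - 100) < 1e-9

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError):
            selection_percentage(np.zeros(15, dtype=np.uint8), toy_dictionary())

    def test_population_matrix_shape_and_frequencies(self):
        rng = np.random.default_rng(9)
        pop = (rng.random((20, 200)) < 0.5).astype(np.uint8)
        pop[:, 0] = 1
        mat, freq = population_matrix(pop)
        assert mat.shape == (20, 200)
        assert set(np.unique(mat)) <= {0, 1}
        assert freq[0] == 1.0
        assert np.allclose(freq, mat.mean(axis=0))


@pytest.fixture(scope="module")
def tiny_report():
    spec = FixtureSpec(n_pos=12, n_neg=12, seed=21)
    ds, boxes = generate_dataset(spec)
    cfg = ExperimentConfig(
        n_runs=2, seed=3, sizes=(4, 8), count_per_size=15,
        ga=GAConfig(init_density=0.3, max_generations=8,
                    stagnation_patience=4),
    )
    return run_experiment(ds, cfg, boxes=boxes)


class TestRunExperiment:
    def test_one_record_per_run(self, tiny_report):
        assert len(tiny_report.runs) == 2
        assert tiny_report.seeds == [3, 4]
        assert all(r.n_generations >= 1 for r in tiny_report.runs)

    def test_metrics_within_bounds(self, tiny_report):
        for r in tiny_report.runs:
            for v in (r.eer_selected, r.eer_random, r.eer_full):
                assert 0.0 <= v <= 1.0
            for v in (r.auc_selected, r.auc_random, r.auc_full):
                assert 0.0 <= v <= 1.0
            assert 1 <= r.n_selected <= 30
            assert abs(sum(r.selection_pct.values()) - 100) < 1e-9

    def test_summary_reproduces_run_aggregation(self, tiny_report):
        s = tiny_report.summary
        eers = [r.eer_selected for r in tiny_report.runs]
        assert s["mean_eer_selected"] == pytest.approx(np.mean(eers))
        assert s["std_eer_selected"] == pytest.approx(np.std(eers))
        assert s["std_eer_selected"] >= 0
        assert "selected_on_motif_rate" in s

    def test_report_serializes(self, tiny_report):
        import json

        data = tiny_report.to_dict()
        text = json.dumps(data)
        assert json.loads(text)["config"]["n_runs"] == 2
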