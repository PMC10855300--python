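import numpy as np
import pytest

from txsig.datatypes import ExpressionMatrix, GroupAnnotation, METRIC_ORDER, RunConfig, ValidationError
from txsig.simulate import SyntheticConfig, generate_qpcr_like, planted_signature_config
from txsig.supervised import (
    BinaryTask,
    ModelConfig,
    assert_no_leakage,
    build_pairwise_tasks,
    default_model_configs,
    evaluate_model_grid,
    nested_cv_evaluate,
    rfecv_select,
    rfecv_select_per_core,
    stratified_partition,
)


def make_task(n_pos=28, n_neg=14, d=5, gap=0.0, seed=0, name="BPS_vs_Control"):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(gap, 1, (n_pos, d)), rng.normal(0, 1, (n_neg, d))])
    y = np.array(["BPS"] * n_pos + ["Control"] * n_neg)
    return BinaryTask(name, "BPS", "Control",
                      tuple(f"g{i}" for i in range(d)),
                      tuple(f"s{j}" for j in range(n_pos + n_neg)), X, y)


def annotated_matrix(group_sizes, seed=0, n_genes=6):
    rng = np.random.default_rng(seed)
    mapping = {}
    for grp, n in group_sizes.items():
        for i in range(n):
            mapping[f"{grp}{i}"] = grp
    ann = GroupAnnotation(mapping, extensible=True)
    x = ExpressionMatrix(tuple(f"g{i}" for i in range(n_genes)),
                         tuple(mapping), rng.normal(size=(n_genes, len(mapping))),
                         "log2fc")
    return x, ann


class TestPairwiseTasks:
    def test_three_groups_give_study_tasks(self):
        x, ann = annotated_matrix({"Control": 6, "BPS": 6, "DO": 6})
        names = [t.name for t in build_pairwise_tasks(x, ann)]
        assert names == ["BPS_vs_Control", "DO_vs_Control", "BPS_vs_DO"]

    def test_positive_class_is_disease(self):
        x, ann = annotated_matrix({"Control": 6, "BPS": 6, "DO": 6})
        tasks = {t.name: t for t in build_pairwise_tasks(x, ann)}
        assert tasks["BPS_vs_Control"].positive == "BPS"
        assert tasks["BPS_vs_DO"].positive == "BPS"

    def test_two_groups_one_task(self):
        x, ann = annotated_matrix({"Control": 6, "BPS": 6})
        assert len(build_pairwise_tasks(x, ann)) == 1

    def test_four_groups_six_tasks(self):
        x, ann = annotated_matrix({"A": 6, "B": 6, "C": 6, "D": 6})
        assert len(build_pairwise_tasks(x, ann)) == 6  # C(4,2)

    def test_small_group_rejected_for_stratification(self):
        x, ann = annotated_matrix({"Control": 4, "BPS": 8})
        with pytest.raises(ValidationError, match="Control"):
            build_pairwise_tasks(x, ann, cv_folds=3)


class TestStratifiedPartition:
    def test_28_14_counting(self):
        task = make_task(28, 14)
        folds = stratified_partition(task, k=3, seed=0)
        sizes = sorted(len(f) for f in folds)
        assert sizes == [14, 14, 14]
        for f in folds:
            positives = (task.y[f] == "BPS").sum()
            assert positives in (9, 10)
        all_idx = np.sort(np.concatenate(folds))
        np.testing.assert_array_equal(all_idx, np.arange(42))

    def test_class_smaller_than_k_rejected(self):
        task = make_task(5, 2)
        with pytest.raises(ValidationError, match="Control"):
            stratified_partition(task, k=3, seed=0)

    def test_same_seed_identical(self):
        task = make_task()
        a = stratified_partition(task, 3, seed=11)
        b = stratified_partition(task, 3, seed=11)
        for fa, fb in zip(a, b):
            np.testing.assert_array_equal(fa, fb)


class TestRfecv:
    def test_planted_genes_contained(self, fast_config):
        planted = {"TPPP3", "FAT1", "NCALD"}
        hits = 0
        for seed in range(3):
            x, ann, _ = generate_qpcr_like(planted_signature_config(seed=seed))
            task = [t for t in build_pairwise_tasks(x, ann)
                    if t.name == "BPS_vs_Control"][0]
            per_core = rfecv_select_per_core(task, fast_config, seed)
            pool = set().union(*(s.genes for s in per_core.values()))
            hits += planted <= pool
        assert hits >= 2

    def test_pure_noise_floor_and_flag(self, fast_config):
        task = make_task(20, 12, d=8, gap=0.0, seed=5)
        sel = rfecv_select(task, fast_config, seed=5)
        assert sel.low_score
        assert len(sel.genes) == fast_config.min_features

    def test_panel_of_min_features_returned_whole(self, fast_config):
        task = make_task(12, 12, d=3, gap=2.0)
        sel = rfecv_select(task, fast_config, seed=0)
        assert set(sel.genes) == {"g0", "g1", "g2"}

    def test_constant_feature_rejected(self, fast_config):
        task = make_task(8, 8, d=3)
        task = BinaryTask(task.name, task.positive, task.negative,
                          task.gene_ids, task.sample_ids,
                          np.column_stack([task.X[:, :2], np.ones(16)]), task.y)
        with pytest.raises(ValidationError, match="constant"):
            rfecv_select(task, fast_config, seed=0)


class TestModelConfigs:
    def test_default_grid_size(self):
        configs = default_model_configs()
        assert len(configs) == 36  # (11 named + Dummy) x 3 oversamplers
        classifiers = {c.classifier for c in configs}
        assert "Dummy" in classifiers and len(classifiers) == 12

    def test_grids_attached_to_tunable(self):
        configs = {c.classifier: c for c in default_model_configs()}
        assert configs["LR"].grid["C"] == [0.01, 0.1, 1.0, 10.0]
        assert configs["LDA"].grid == {}


SMALL_ROSTER = [ModelConfig("LDA", "RandomOverSampler"),
                ModelConfig("SVM", "RandomOverSampler"),
                ModelConfig("Dummy", "RandomOverSampler")]


class TestEvaluateGrid:
    def test_full_roster_yields_36_results(self, fast_config):
        task = make_task(gap=1.0)
        results = evaluate_model_grid(task, default_model_configs(fast_config),
                                      fast_config, seed=0)
        assert len(results) == 36
        assert all(r.scheme == "repeated_kfold" for r in results)

    def test_separable_lda_perfect_f1(self, fast_config):
        task = make_task(gap=8.0)
        results = evaluate_model_grid(task, [ModelConfig("LDA", "RandomOverSampler")],
                                      fast_config, seed=0)
        assert results[0].metrics_mean["F1"] == pytest.approx(1.0)
        assert results[0].metrics_sd["F1"] == pytest.approx(0.0)

    def test_metrics_in_unit_interval(self, fast_config):
        task = make_task(gap=0.5)
        results = evaluate_model_grid(task, SMALL_ROSTER, fast_config, seed=1)
        for r in results:
            for m in METRIC_ORDER:
                assert 0.0 <= r.metrics_mean[m] <= 1.0
                assert r.metrics_sd[m] >= 0.0

    def test_determinism_bitwise(self, fast_config):
        task = make_task(gap=0.8)
        a = evaluate_model_grid(task, SMALL_ROSTER, fast_config, seed=3)
        b = evaluate_model_grid(task, SMALL_ROSTER, fast_config, seed=3)
        for ra, rb in zip(a, b):
            assert ra.metrics_mean == rb.metrics_mean
            assert ra.metrics_sd == rb.metrics_sd

    def test_no_leakage_audit(self, fast_config):
        task = make_task()
        audit = []
        evaluate_model_grid(task, SMALL_ROSTER, fast_config, seed=0, audit=audit)
        assert audit
        assert_no_leakage(audit)

    def test_planted_best_model_beats_dummy(self):
        # planted signal: best non-dummy mean F1 exceeds Dummy's by >= 0.25
        cfg = RunConfig(cv_repeats=1, random_seed=0)
        x, ann, _ = generate_qpcr_like(planted_signature_config(seed=0))
        task = [t for t in build_pairwise_tasks(x, ann)
                if t.name == "BPS_vs_Control"][0]
        results = evaluate_model_grid(task, default_model_configs(cfg), cfg, 0)
        dummy = np.mean([r.metrics_mean["F1"] for r in results
                         if r.config.classifier == "Dummy"])
        best = max(r.metrics_mean["F1"] for r in results
                   if r.config.classifier != "Dummy")
        assert best - dummy >= 0.25

    def test_permutation_null_close_to_dummy(self):
        # label-permuted data: every model's mean F1 near the Dummy baseline
        cfg = RunConfig(cv_repeats=1, random_seed=0)
        configs = default_model_configs(cfg)
        sums = {c.model_id: 0.0 for c in configs}
        n_seeds = 10
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            task = make_task(24, 12, d=6, gap=1.5, seed=seed)
            permuted = BinaryTask(task.name, task.positive, task.negative,
                                  task.gene_ids, task.sample_ids, task.X,
                                  rng.permutation(task.y))
            for r in evaluate_model_grid(permuted, configs, cfg, seed):
                sums[r.config.model_id] += r.metrics_mean["F1"]
        means = {m: s / n_seeds for m, s in sums.items()}
        dummy = np.mean([v for m, v in means.items() if m.startswith("Dummy")])
        for m, v in means.items():
            if not m.startswith("Dummy"):
                assert abs(v - dummy) < 0.15, (m, v, dummy)


class TestNestedCv:
    def test_trivial_grid_matches_repeated_in_expectation(self):
        cfg = RunConfig(cv_repeats=2, random_seed=0)
        configs = [ModelConfig("LDA", "RandomOverSampler"),
                   ModelConfig("GNB", "RandomOverSampler")]
        diffs = []
        for seed in range(5):
            task = make_task(20, 12, d=4, gap=1.2, seed=seed)
            rep = evaluate_model_grid(task, configs, cfg, seed)
            nest = nested_cv_evaluate(task, configs, cfg, seed)
            for r, n in zip(rep, nest):
                diffs.append(r.metrics_mean["F1"] - n.metrics_mean["F1"])
        assert abs(np.mean(diffs)) < 0.1

    def test_outer_test_never_in_inner_cv(self, fast_config):
        task = make_task(18, 12, d=4, gap=1.0)
        configs = [ModelConfig("KNN", "RandomOverSampler",
                               {"n_neighbors": [3, 5]})]
        audit = []
        nested_cv_evaluate(task, configs, fast_config, seed=0, audit=audit)
        inner_entries = [e for e in audit if "inner_train" in e]
        assert inner_entries  # tuning actually happened
        assert_no_leakage(audit)

    def test_scheme_tag(self, fast_config):
        task = make_task(gap=1.0)
        out = nested_cv_evaluate(task, [ModelConfig("LDA", "RandomOverSampler")],
                                 fast_config, seed=0)
        assert out[0].scheme == "nested_cv"
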