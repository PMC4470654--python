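"""Front filtering, clustering, representatives, final predictors, validation."""

import numpy as np
import pytest

import paretosig as ps
from paretosig.phospho_io import PhosphoMatrix, PhosphoSite, SampleLabels
from paretosig.postprocess import (
    FrontSolution,
    PipelineError,
    Predictor,
    cluster_solutions,
    filter_front,
    impute_validation,
    predict_and_score,
    select_representatives,
    train_final_predictor,
)


def sol(bits, separation=-0.7, size=None, relevance=1.0):
    bits = np.asarray(bits, dtype=np.uint8)
    return FrontSolution(bits=bits,
                         objectives=(size or int(bits.sum()), separation, relevance),
                         sites=[])


class TestFilterFront:
    def test_boundary_value_removed(self):
        front = [sol([1], s) for s in (-0.7, -0.6, -0.65, -0.3)]
        kept = filter_front(front)
        assert [s.separation for s in kept] == [-0.7, -0.65]

    def test_zero_cutoff_keeps_strictly_negative(self):
        front = [sol([1], s) for s in (-0.7, -0.1, -0.01)]
        assert len(filter_front(front, separation_cutoff=0.0)) == 3

    def test_constructed_77_to_53_split(self):
        rng = np.random.default_rng(0)
        good = [sol([1], float(s)) for s in rng.uniform(-0.9, -0.601, size=53)]
        bad = [sol([1], float(s)) for s in rng.uniform(-0.6, -0.1, size=24)]
        assert len(filter_front(good + bad)) == 53

    def test_empty_result_raises_with_advice(self):
        with pytest.raises(ValueError, match="cutoff"):
            filter_front([sol([1], -0.5)])


class TestClustering:
    def test_planted_groups_recovered(self):
        a = [sol([1, 1, 0, 0, 0]), sol([1, 1, 1, 0, 0]), sol([1, 1, 0, 0, 0])]
        b = [sol([0, 0, 0, 1, 1]), sol([0, 0, 1, 1, 1]), sol([0, 0, 0, 1, 1])]
        labels = cluster_solutions(a + b, n_clusters=2)
        assert len(set(labels[:3])) == 1
        assert len(set(labels[3:])) == 1
        assert labels[0] != labels[3]

    def test_singleton_clusters_when_n_equals_solutions(self):
        sols = [sol([1, 0, 0]), sol([0, 1, 0]), sol([0, 0, 1])]
        labels = cluster_solutions(sols, n_clusters=3)
        assert sorted(labels) == [1, 2, 3]

    def test_duplicates_always_co_cluster(self):
        sols = [sol([1, 1, 0, 0]), sol([1, 1, 0, 0]), sol([0, 0, 1, 1]),
                sol([0, 1, 1, 0])]
        labels = cluster_solutions(sols, n_clusters=3)
        assert labels[0] == labels[1]

    def test_too_few_solutions_raises(self):
        with pytest.raises(ValueError, match="cluster"):
            cluster_solutions([sol([1, 0])], n_clusters=2)


class TestRepresentatives:
    def test_singleton_cluster_returns_member(self):
        s = sol([1, 0, 1])
        reps = select_representatives([s], np.array([1]))
        assert reps == [s]
        assert s.is_representative

    def test_closest_to_centroid(self):
        sols = [sol([1, 1, 0, 0, 0]), sol([1, 1, 0, 0, 0]), sol([1, 0, 1, 0, 0])]
        reps = select_representatives(sols, np.array([1, 1, 1]))
        # centroid (1, 2/3, 1/3, 0, 0): 11000 at distance sqrt(2/9) beats 10100
        assert list(reps[0].bits) == [1, 1, 0, 0, 0]

    def test_distance_tie_broken_by_separation(self):
        s1 = sol([1, 0], separation=-0.65)
        s2 = sol([0, 1], separation=-0.70)
        reps = select_representatives([s1, s2], np.array([1, 1]))
        assert reps[0] is s2


def _toy_training():
    sites = [PhosphoSite("a", "PA"), PhosphoSite("b", "PB")]
    samples = [f"c{i}" for i in range(8)]
    values = np.array([
        [1.0, 1.2, 0.9, 1.1, -1.0, -1.1, -0.9, -1.2],
        [0.5, 0.4, 0.6, 0.5, -0.5, -0.6, -0.4, -0.5],
    ])
    matrix = PhosphoMatrix(sites=sites, samples=samples, values=values)
    labels = SampleLabels(samples=samples, y=np.array([1] * 4 + [-1] * 4))
    return matrix, labels


class TestFinalPredictor:
    def test_separable_data_perfect_training_accuracy(self):
        matrix, labels = _toy_training()
        pred = train_final_predictor(matrix.sites, matrix, labels)
        X = matrix.values.T
        assert (pred.predict(X) == labels.y).all()

    def test_hyperplane_probability_half(self):
        matrix, labels = _toy_training()
        pred = train_final_predictor(matrix.sites, matrix, labels)
        # a point exactly on the hyperplane has decision value 0
        X0 = np.zeros((1, 2))
        X0 = X0 - pred.b * pred.w[None, :] / (pred.w @ pred.w)
        assert pred.proba_resistant(X0)[0] == pytest.approx(0.5)

    def test_sample_order_invariance(self):
        matrix, labels = _toy_training()
        pred = train_final_predictor(matrix.sites, matrix, labels)
        perm = np.random.default_rng(0).permutation(len(matrix.samples))
        shuffled = PhosphoMatrix(sites=matrix.sites,
                                 samples=[matrix.samples[j] for j in perm],
                                 values=matrix.values[:, perm])
        pred2 = train_final_predictor(shuffled.sites, shuffled, labels)
        assert np.allclose(pred.w, pred2.w, atol=1e-6)
        assert pred.b == pytest.approx(pred2.b, abs=1e-6)

    def test_round_trip_serialization(self):
        matrix, labels = _toy_training()
        pred = train_final_predictor(matrix.sites, matrix, labels)
        back = Predictor.from_dict(pred.to_dict())
        X = matrix.values.T
        assert np.allclose(pred.proba_resistant(X), back.proba_resistant(X))

    def test_empty_signature_rejected(self):
        matrix, labels = _toy_training()
        with pytest.raises(ValueError, match="empty"):
            train_final_predictor([], matrix, labels)


class TestImputeValidation:
    def _setup(self):
        matrix, labels = _toy_training()
        val = PhosphoMatrix(
            sites=[PhosphoSite("a", "PA")],
            samples=["v1", "v2"],
            values=np.array([[np.nan, 0.7]]),
        )
        return matrix, labels, val

    def test_missing_value_gets_mean_of_class_means(self):
        matrix, labels, val = self._setup()
        X = impute_validation(val, matrix, labels, matrix.sites[:1])
        m_s = matrix.values[0, :4].mean()
        m_r = matrix.values[0, 4:].mean()
        assert X[0, 0] == pytest.approx((m_s + m_r) / 2)

    def test_present_value_untouched(self):
        matrix, labels, val = self._setup()
        X = impute_validation(val, matrix, labels, matrix.sites[:1])
        assert X[1, 0] == 0.7

    def test_absent_site_treated_all_missing_with_warning(self, caplog):
        matrix, labels, val = self._setup()
        with caplog.at_level("WARNING"):
            X = impute_validation(val, matrix, labels, matrix.sites)  # site b absent
        assert "b" in caplog.text
        m_s = matrix.values[1, :4].mean()
        m_r = matrix.values[1, 4:].mean()
        assert np.allclose(X[:, 1], (m_s + m_r) / 2)


class TestPredictAndScore:
    def _predictor(self, probs):
        """Predictor stub whose proba_resistant returns fixed values."""

        class Stub(Predictor):
            def proba_resistant(self, X):
                return np.asarray(probs)

        return Stub(site_ids=[], protein_ids=[], w=np.zeros(1), b=0.0, A=1.0,
                    impute=np.zeros(1))

    def test_direct_arithmetic_example(self):
        labels = SampleLabels(samples=["s", "r"], y=np.array([1, -1]))
        res = predict_and_score(self._predictor([0.2, 0.9]), np.zeros((2, 1)), labels)
        assert res.accuracy == 1.0
        assert res.avg_prob_distance == pytest.approx(0.35)

    def test_all_half_probabilities_score_zero(self):
        labels = SampleLabels(samples=["a", "b"], y=np.array([1, -1]))
        res = predict_and_score(self._predictor([0.5, 0.5]), np.zeros((2, 1)), labels)
        assert res.accuracy == 0.0  # p = 0.5 exactly counts as incorrect
        assert res.avg_prob_distance == 0.0

    def test_perfectly_confident_distance_is_half(self):
        labels = SampleLabels(samples=["a", "b"], y=np.array([1, -1]))
        res = predict_and_score(self._predictor([0.0, 1.0]), np.zeros((2, 1)), labels)
        assert res.accuracy == 1.0
        assert res.avg_prob_distance == pytest.approx(0.5)

    def test_distance_bounds(self):
        rng = np.random.default_rng(0)
        labels = SampleLabels(samples=["a", "b", "c"], y=np.array([1, 1, -1]))
        for _ in range(20):
            p = rng.random(3)
            res = predict_and_score(self._predictor(p), np.zeros((3, 1)), labels)
            assert -0.5 <= res.avg_prob_distance <= 0.5


class TestRunPipeline:
    def test_representatives_belong_to_accepted_front(self, small_result):
        accepted_keys = {s.bits.tobytes() for s in small_result.accepted}
        for rep in small_result.representatives:
            assert rep.bits.tobytes() in accepted_keys
            assert rep.separation < small_result.config.separation_cutoff

    def test_validation_block_present(self, small_result):
        assert small_result.predictions is not None
        for pred in small_result.predictions:
            assert 0.0 <= pred.accuracy <= 1.0
            assert -0.5 <= pred.avg_prob_distance <= 0.5

    def test_no_validation_set_omits_predictions_only(self, small_dataset,
                                                      small_run_config, small_result):
        train, tl, *_ , ppi, _truth = small_dataset
        res = ps.run_pipeline(train, tl, ppi, "TARGET", config=small_run_config)
        assert res.predictions is None
        assert [s.site_ids for s in res.representatives] == \
            [s.site_ids for s in small_result.representatives]
        assert [s.objectives for s in res.front] == \
            [s.objectives for s in small_result.front]

    def test_rerun_is_identical(self, small_dataset, small_run_config, small_result):
        train, tl, val, vl, ppi, _truth = small_dataset
        res = ps.run_pipeline(train, tl, ppi, "TARGET", validation=val,
                              validation_labels=vl, config=small_run_config)
        assert [s.objectives for s in res.front] == \
            [s.objectives for s in small_result.front]
        assert [p.p_resistant.tolist() for p in res.predictions] == \
            [p.p_resistant.tolist() for p in small_result.predictions]

    def test_stage_labelled_errors(self, small_dataset):
        train, tl, *_ , ppi, _truth = small_dataset
        cfg = ps.RunConfig(min_fold=10_000.0)  # nothing survives the prefilter
        with pytest.raises(PipelineError, match=r"\[prefilter\]"):
            ps.run_pipeline(train, tl, ppi, "TARGET", config=cfg)
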