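import numpy as np
import pandas as pd
import pytest

import obscuredgp as og
from obscuredgp.errors import ParameterError, ShapeError, UndefinedCorrelationError
from obscuredgp.evaluation import prepare_fold


class TrainMeanStub:
    """Predicts the training mean for every query (constant predictor)."""

    def fit(self, codes, trait):
        self.mean = float(np.mean(trait))
        return self

    def predict(self, codes):
        return np.full(np.atleast_2d(codes).shape[0], self.mean)


class LookupStub:
    """Perfect oracle: looks each genotype row up in a preset table."""

    def __init__(self, table):
        self.table = table  # bytes(codes row) → standardized target

    def fit(self, codes, trait):
        return self

    def predict(self, codes):
        return np.array([self.table[row.tobytes()] for row in np.atleast_2d(codes)])


class TestMetrics:
    def test_pcc_perfect_and_inverted(self):
        x = np.array([1.0, 2.0, 4.0, 3.0, 5.0])
        assert og.pcc(x, x) == pytest.approx(1.0)
        assert og.pcc(x, -x) == pytest.approx(-1.0)

    def test_pcc_hand_example(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        p = np.array([2.0, 1.0, 4.0, 3.0, 6.0])
        cov = np.mean((a - a.mean()) * (p - p.mean()))
        expected = cov / (a.std() * p.std())
        assert og.pcc(a, p) == pytest.approx(expected, rel=1e-12)

    def test_pcc_constant_input_errors_not_zero(self):
        with pytest.raises(UndefinedCorrelationError):
            og.pcc(np.array([1.0, 1.0, 1.0]), np.array([1.0, 2.0, 3.0]))
        with pytest.raises(UndefinedCorrelationError):
            og.pcc(np.array([1.0, 2.0, 3.0]), np.array([0.5, 0.5, 0.5]))

    def test_mse_examples_and_loop_oracle(self):
        assert og.mse(np.array([1.0, 2.0]), np.array([1.0, 2.0])) == 0.0
        assert og.mse(np.array([0.0, 0.0]), np.array([1.0, 1.0])) == 1.0
        rng = np.random.default_rng(0)
        a, p = rng.normal(size=100), rng.normal(size=100)
        assert og.mse(a, p) == pytest.approx(sum((a[i] - p[i]) ** 2 for i in range(100)) / 100)

    def test_metric_length_mismatch(self):
        with pytest.raises(ShapeError):
            og.mse(np.ones(3), np.ones(4))


class TestFoldPlan:
    def test_balanced_three_folds(self):
        ids = [f"g{i}" for i in range(9)]
        plan = og.make_folds(ids, 3, seed=0)
        sizes = pd.Series(plan.assignments).value_counts()
        assert sorted(sizes) == [3, 3, 3]

    def test_unbalanced_sizes_differ_by_one(self):
        plan = og.make_folds([f"g{i}" for i in range(10)], 3, seed=1)
        sizes = sorted(pd.Series(plan.assignments).value_counts(), reverse=True)
        assert sizes == [4, 3, 3]

    def test_same_seed_identical(self):
        ids = [f"g{i}" for i in range(20)]
        assert og.make_folds(ids, 3, 7).assignments == og.make_folds(ids, 3, 7).assignments

    def test_json_round_trip_byte_identical(self):
        plan = og.make_folds([f"g{i}" for i in range(10)], 3, seed=2)
        back = og.FoldPlan.from_json(plan.to_json())
        assert back.assignments == plan.assignments and back.to_json() == plan.to_json()

    def test_k_exceeding_n_rejected(self):
        with pytest.raises(ParameterError):
            og.make_folds(["a", "b"], 3, seed=0)


class TestRunCV:
    @pytest.fixture()
    def panel(self):
        return og.simulate(og.SimConfig(n_individuals=45, n_markers=60, seed=21))

    def test_constant_predictor_flags_pcc_and_unit_mse(self, panel):
        genos, phenos, _ = panel
        plan = og.make_folds(genos.individual_ids, 3, seed=0)
        rep = og.run_cv({"mean": TrainMeanStub}, genos, phenos, "trait", plan)
        assert (~rep.metrics.pcc_defined).all()  # constant predictions → flagged
        # averaged over folds, MSE ≈ variance of the z-scored trait (≈ 1);
        # individual small folds fluctuate widely
        assert 0.6 < rep.metrics.mse.mean() < 1.4

    def test_perfect_oracle_zero_mse_every_fold(self, panel):
        genos, phenos, _ = panel
        plan = og.make_folds(genos.individual_ids, 3, seed=0)
        y = phenos.trait("trait")

        def factory():
            # standardization is fold-scoped, so build the lookup per fold is
            # impossible here; use raw-scale ranks instead: predict exact
            # z-score by re-deriving it from the training stats is what the
            # harness does, so the lookup stores raw trait and the stub
            # standardizes lazily per fold via closure state set in fit.
            class PerFoldLookup:
                def fit(self, codes, trait):
                    self.table = {row.tobytes(): t for row, t in zip(codes, trait)}
                    self.full = {row.tobytes(): yv for row, yv in zip(genos.codes, y)}
                    tr_raw = np.array([self.full[r.tobytes()] for r in codes])
                    self.stats = og.zscore_fit(tr_raw)
                    return self

                def predict(self, codes):
                    raw = np.array([self.full[r.tobytes()] for r in np.atleast_2d(codes)])
                    return og.zscore_apply(raw, self.stats)

            return PerFoldLookup()

        rep = og.run_cv({"oracle": factory}, genos, phenos, "trait", plan)
        assert (rep.metrics.mse < 1e-20).all()

    def test_report_bookkeeping(self, panel):
        genos, phenos, _ = panel
        plan = og.make_folds(genos.individual_ids, 3, seed=0)
        rep = og.run_cv({"a": TrainMeanStub, "b": TrainMeanStub}, genos, phenos, "trait", plan)
        assert len(rep.metrics) == 3 * 2
        assert {"pcc", "mse"} <= set(rep.metrics.columns)
        per_fold = rep.predictions.groupby(["model", "fold"]).size()
        sizes = pd.Series(plan.assignments).value_counts()
        for (_, fold), count in per_fold.items():
            assert count == sizes[fold]

    def test_model_failure_isolated(self, panel):
        genos, phenos, _ = panel
        plan = og.make_folds(genos.individual_ids, 3, seed=0)

        class Broken:
            def fit(self, codes, trait):
                raise RuntimeError("boom")

        rep = og.run_cv({"broken": Broken, "mean": TrainMeanStub}, genos, phenos, "trait", plan)
        broken = rep.metrics[rep.metrics.model == "broken"]
        assert broken.error.notna().all()
        ok = rep.metrics[rep.metrics.model == "mean"]
        assert ok.error.isna().all() and np.isfinite(ok.mse).all()


class TestSweeps:
    def test_feature_sweep_shape_and_degenerate_single_count(self):
        genos, phenos, _ = og.simulate(og.SimConfig(n_individuals=36, n_markers=50, seed=31))
        plan = og.make_folds(genos.individual_ids, 3, seed=0)
        models = {"mean": TrainMeanStub}
        sweep = og.sweep_feature_counts([8, 16], models, genos, phenos, "trait", plan)
        assert len(sweep.metrics) == 2 * 3 * 1
        single = og.sweep_feature_counts([8], models, genos, phenos, "trait", plan)
        plain = og.run_cv(models, genos, phenos, "trait", plan, dedup_w=8, mi_k=8)
        np.testing.assert_allclose(single.metrics.mse.values, plain.metrics.mse.values)

    def test_ridge_mse_improves_with_more_features(self):
        """Averaged over folds and seeds, ridge at the full marker set beats
        ridge at 8 MI-selected markers on simulated additive traits."""
        from obscuredgp.cli import _RidgeWrapper

        deltas = []
        for seed in (0, 1, 2):
            genos, phenos, _ = og.simulate(
                og.SimConfig(n_individuals=80, n_markers=120, heritability=0.8, seed=seed)
            )
            plan = og.make_folds(genos.individual_ids, 3, seed=seed)
            models = {"ridge": lambda: _RidgeWrapper(1.0)}
            sweep = og.sweep_feature_counts([8, 120], models, genos, phenos, "trait", plan)
            by_count = sweep.metrics.groupby("requested_features").mse.mean()
            deltas.append(by_count[120] - by_count[8])
        assert np.mean(deltas) < 0

    def test_reference_sweep_full_fraction_strategy_invariant(self):
        genos, phenos, _ = og.simulate(og.SimConfig(n_individuals=30, n_markers=40, seed=41))
        plan = og.make_folds(genos.individual_ids, 3, seed=0)
        rep = og.sweep_reference_fractions(
            [1.0], ["random", "targeted"], [0, 1], genos, phenos, "trait", plan,
            net_config={"epochs": 2, "seed": 0}, folds=[0],
        )
        m = rep.metrics
        assert m.mse.nunique() == 1  # full set is unique regardless of strategy/seed
        assert m.n_references.nunique() == 1


class TestMseHeatmap:
    def test_stub_arithmetic(self):
        y_train = np.array([1.0, -1.0])
        y_test = np.array([0.0, 2.0, 1.0])
        codes_tr = np.arange(4).reshape(2, 2)
        codes_te = np.arange(6).reshape(3, 2) + 10

        class ConstStub:
            def predict_batch(self, bits, y_ref):
                return np.full(np.atleast_2d(bits).shape[0], 0.5)

        H = og.mse_heatmap(ConstStub(), codes_tr, y_train, codes_te, y_test)
        expected = np.tile((0.5 - y_test) ** 2, (2, 1))
        np.testing.assert_allclose(H, expected)

    def test_matches_double_loop_oracle_and_profile_consistency(self, tiny_trained_net):
        net, codes, y = tiny_trained_net
        tr, te = np.arange(5), np.arange(5, 9)
        H = og.mse_heatmap(net, codes[tr], y[tr], codes[te], y[te])
        assert H.shape == (5, 4)
        for j in range(5):
            for t in range(4):
                bits = (codes[te][t] == codes[tr][j]).astype(float)
                expected = (net.predict_pair(bits, y[tr][j]) - y[te][t]) ** 2
                assert H[j, t] == pytest.approx(expected, rel=1e-10)


class TestLeakage:
    def test_test_fold_phenotypes_do_not_touch_training_artifacts(self):
        """Altering held-out phenotypes changes nothing fit on the training
        fold: z-score stats, MI selection, or trained network weights."""
        genos, phenos, _ = og.simulate(og.SimConfig(n_individuals=30, n_markers=40, seed=51))
        plan = og.make_folds(genos.individual_ids, 3, seed=0)
        train_idx, test_idx = plan.split(genos.individual_ids, 0)

        tampered = og.PhenotypeTable(
            genos.individual_ids,
            {"trait": phenos.trait("trait").copy()},
        )
        tampered.traits["trait"][test_idx] = -999.0

        art_a = prepare_fold(genos, phenos, "trait", train_idx, dedup_w=8, mi_k=16)
        art_b = prepare_fold(genos, tampered, "trait", train_idx, dedup_w=8, mi_k=16)
        assert art_a[0] == art_b[0]
        np.testing.assert_array_equal(art_a[1], art_b[1])

        def train_net(ph):
            y = og.zscore_apply(ph.trait("trait")[train_idx], art_a[0])
            codes = genos.codes[np.ix_(train_idx, art_a[1])]
            cfg = og.NetConfig(n_features=art_a[1].size, epochs=2, seed=0)
            return og.ObscuredNet(cfg).train(og.build_pair_dataset(codes, y))

        net_a, net_b = train_net(phenos), train_net(tampered)
        assert net_a.training_log == net_b.training_log
        for name in net_a.params:
            np.testing.assert_array_equal(net_a.params[name], net_b.params[name])
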