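import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dualscreen import ise, synth
from dualscreen.ise import Filter, FilterPerformance, Model, PropertyRange


def perf(P, N):
    return FilterPerformance(P=P, N=N, Pf=100 - N, Nf=100 - P, mcc=ise.mcc(P, N, 100 - N, 100 - P))


def simple_filter(*specs):
    """specs: (descriptor, lo, hi) triples; padded to five with wide ranges."""
    ranges = [PropertyRange(d, lo, hi) for d, lo, hi in specs]
    pad_names = [f"pad{i}" for i in range(5 - len(ranges))]
    ranges += [PropertyRange(n, -1e9, 1e9) for n in pad_names]
    return Filter(tuple(ranges))


# ---------------------------------------------------------------------------
# MCC

class TestMCC:
    def test_perfect_and_chance(self):
        assert ise.mcc(100, 100, 0, 0) == pytest.approx(1.0)
        assert ise.mcc(50, 50, 50, 50) == pytest.approx(0.0)

    def test_degenerate_zero_denominator(self):
        # a filter passing nothing: P = Pf = 0
        assert ise.mcc(0, 100, 0, 100) == 0.0

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            ise.mcc(-1, 100, 0, 100)

    def test_equals_point_biserial_correlation(self):
        # 200-molecule set with P = 90, N = 90: MCC from the rates must equal
        # the Pearson correlation of the label/prediction 0-1 vectors
        y = np.array([1] * 100 + [0] * 100)
        pred = np.array([1] * 90 + [0] * 10 + [0] * 90 + [1] * 10)
        oracle = np.corrcoef(y, pred)[0, 1]
        assert ise.mcc(90, 90, 10, 10) == pytest.approx(oracle)

    @given(
        P=st.floats(0, 100, allow_nan=False),
        N=st.floats(0, 100, allow_nan=False),
    )
    @settings(max_examples=100, derandomize=True)
    def test_symmetric_under_class_swap(self, P, N):
        Pf, Nf = 100 - N, 100 - P
        assert ise.mcc(P, N, Pf, Nf) == pytest.approx(ise.mcc(N, P, Nf, Pf), abs=1e-12)
        assert -1 <= ise.mcc(P, N, Pf, Nf) <= 1


# ---------------------------------------------------------------------------
# filter evaluation

@pytest.fixture()
def toy_table():
    rng = np.random.default_rng(3)
    t = pd.DataFrame(
        rng.uniform(0, 10, size=(20, 7)),
        columns=["x", "y", "z", "pad0", "pad1", "pad2", "pad3"],
    )
    labels = (t["x"] > 5).astype(int).to_numpy()
    return t, labels


class TestEvaluateFilter:
    def test_perfect_filter(self, toy_table):
        t, labels = toy_table
        f = simple_filter(("x", 5.0001, 10.0))
        p = ise.evaluate_filter(f, t, labels)
        assert p.P == pytest.approx(100.0)
        assert p.N == pytest.approx(100.0)
        assert p.mcc == pytest.approx(1.0)

    def test_pass_nothing_is_mcc_zero(self, toy_table):
        t, labels = toy_table
        f = simple_filter(("x", 100.0, 200.0))
        p = ise.evaluate_filter(f, t, labels)
        assert (p.P, p.Pf, p.mcc) == (0.0, 0.0, 0.0)

    def test_counts_match_brute_force_row_scan(self, toy_table):
        t, labels = toy_table
        f = simple_filter(("x", 2.0, 8.0), ("y", 1.0, 9.0))
        p = ise.evaluate_filter(f, t, labels)
        passes = [
            2.0 <= row.x <= 8.0 and 1.0 <= row.y <= 9.0 for row in t.itertuples()
        ]
        tp = sum(1 for ok, l in zip(passes, labels) if ok and l == 1)
        tn = sum(1 for ok, l in zip(passes, labels) if not ok and l == 0)
        assert p.P == pytest.approx(100 * tp / labels.sum())
        assert p.N == pytest.approx(100 * tn / (len(labels) - labels.sum()))

    def test_row_order_invariance(self, toy_table):
        t, labels = toy_table
        f = simple_filter(("x", 2.0, 8.0), ("z", 0.0, 7.0))
        p1 = ise.evaluate_filter(f, t, labels)
        order = np.random.default_rng(1).permutation(len(t))
        p2 = ise.evaluate_filter(f, t.iloc[order], labels[order])
        assert p1 == p2

    def test_single_class_is_an_error(self, toy_table):
        t, _ = toy_table
        with pytest.raises(ValueError):
            ise.evaluate_filter(simple_filter(("x", 0, 10)), t, np.ones(len(t), dtype=int))


class TestFilterType:
    def test_five_distinct_descriptors_enforced(self):
        r = [PropertyRange(f"d{i}", 0, 1) for i in range(4)]
        with pytest.raises(ValueError, match="exactly 5"):
            Filter(tuple(r))
        with pytest.raises(ValueError, match="distinct"):
            Filter(tuple(r + [PropertyRange("d0", 0, 1)]))

    def test_inverted_range_rejected(self):
        with pytest.raises(ValueError):
            PropertyRange("x", 2.0, 1.0)


# ---------------------------------------------------------------------------
# molecule index

def model_from(perfs, filters):
    return Model(filters=list(zip(filters, perfs)), index_cap=1.0)


class TestMoleculeIndex:
    def test_pass_all_ratio_one_gives_plus_one(self):
        # P = Pf for every filter -> each pass contributes exactly 1
        m = model_from([perf(50, 50)] * 3, [simple_filter(("x", 0, 10))] * 3)
        row = {"x": 5.0, "pad0": 0.0, "pad1": 0.0, "pad2": 0.0, "pad3": 0.0}
        assert ise.molecule_index(m, row) == pytest.approx(1.0)

    def test_fail_all_symmetric_case_gives_minus_one(self):
        m = model_from([perf(50, 50)] * 3, [simple_filter(("x", 0, 10))] * 3)
        row = {"x": 50.0, "pad0": 0.0, "pad1": 0.0, "pad2": 0.0, "pad3": 0.0}
        assert ise.molecule_index(m, row) == pytest.approx(-1.0)

    def test_hand_computed_three_filter_case(self):
        # filters 1,2 pass; filter 3 fails. cap 1.0, eps 0.5 percentage points
        f_pass = simple_filter(("x", 0.0, 10.0))
        f_fail = simple_filter(("y", 100.0, 200.0))
        perfs = [perf(90, 80), perf(60, 90), perf(95, 70)]
        m = model_from(perfs, [f_pass, f_pass, f_fail])
        row = {"x": 5.0, "y": 5.0, **{f"pad{i}": 0.0 for i in range(4)}}
        # contributions: min(90/20,1)=1; min(60/10,1)=1; -min(5/70,1)=-1/14
        expected = (1.0 + 1.0 - (100 - 95) / 70) / 3
        assert ise.molecule_index(m, row) == pytest.approx(expected)

    def test_epsilon_smoothing_caps_perfect_filter(self):
        # Pf = 0 would divide by zero; eps = 0.5 then cap pins it at 1.0
        m = model_from([perf(100, 100)], [simple_filter(("x", 0, 10))])
        assert ise.molecule_index(m, {"x": 5.0, **{f"pad{i}": 0.0 for i in range(4)}}) == 1.0

    def test_missing_descriptor_is_named(self):
        m = model_from([perf(50, 50)], [simple_filter(("x", 0, 10))])
        with pytest.raises(KeyError, match="pad0"):
            ise.molecule_index(m, {"x": 1.0})

    def test_monotone_in_filter_outcomes(self):
        # flipping one filter from fail to pass never decreases the index
        f_x = simple_filter(("x", 0.0, 10.0))
        f_y = simple_filter(("y", 0.0, 10.0))
        perfs = [perf(80, 70), perf(65, 95)]
        m = model_from(perfs, [f_x, f_y])
        pads = {f"pad{i}": 0.0 for i in range(4)}
        fail_both = ise.molecule_index(m, {"x": 50.0, "y": 50.0, **pads})
        pass_one = ise.molecule_index(m, {"x": 5.0, "y": 50.0, **pads})
        pass_both = ise.molecule_index(m, {"x": 5.0, "y": 5.0, **pads})
        assert fail_both <= pass_one <= pass_both

    def test_screen_table_matches_scalar_path(self, trained_model, canonical_dataset):
        table, _, _ = canonical_dataset
        sub = table.head(25)
        vec = ise.screen_table(trained_model, sub)
        for mol_id, row in sub.iterrows():
            assert vec[mol_id] == pytest.approx(ise.molecule_index(trained_model, row))


# ---------------------------------------------------------------------------
# AUC

class TestModelAUC:
    def test_strong_model_scores_high(self, canonical_dataset, trained_model):
        table, labels, _ = canonical_dataset
        auc = ise.model_auc(trained_model, table, labels)
        assert 0.9 <= auc <= 1.0  # strong separation on its own training data

    def test_all_ties_give_one_half(self, trained_model, canonical_dataset):
        table, _, _ = canonical_dataset
        same = pd.concat([table.iloc[[0]]] * 10, ignore_index=True)
        y = np.array([1] * 5 + [0] * 5)
        assert ise.model_auc(trained_model, same, y) == pytest.approx(0.5)

    def test_equals_mann_whitney_u(self, trained_model, canonical_dataset):
        from scipy.stats import mannwhitneyu

        table, labels, _ = canonical_dataset
        sub = pd.concat([table.head(15), table.tail(15)])
        y = np.concatenate([labels[:15], labels[-15:]])
        auc = ise.model_auc(trained_model, sub, y)
        scores = ise.screen_table(trained_model, sub).to_numpy()
        u = mannwhitneyu(scores[y == 1], scores[y == 0]).statistic
        assert auc == pytest.approx(u / ((y == 1).sum() * (y == 0).sum()))

    def test_single_class_is_an_error(self, trained_model, canonical_dataset):
        table, _, _ = canonical_dataset
        with pytest.raises(ValueError):
            ise.model_auc(trained_model, table.head(5), np.ones(5, dtype=int))


# ---------------------------------------------------------------------------
# training

class TestTrainModel:
    def test_recovers_informative_descriptors(self, trained_model, canonical_dataset):
        _, _, informative = canonical_dataset
        top_filter, top_perf = trained_model.filters[0]
        assert top_perf.mcc >= 0.8
        assert len(set(top_filter.descriptors) & set(informative)) >= 2

    def test_deterministic_under_seed(self, canonical_dataset, fast_config):
        table, labels, _ = canonical_dataset
        m1 = ise.train_model(table, labels, fast_config)
        m2 = ise.train_model(table, labels, fast_config)
        assert m1.to_dict() == m2.to_dict()

    def test_single_class_labels_are_an_error(self, canonical_dataset, fast_config):
        table, _, _ = canonical_dataset
        with pytest.raises(ValueError, match="both classes"):
            ise.train_model(table, np.ones(len(table), dtype=int), fast_config)

    def test_unreachable_mcc_min_reports_best(self, canonical_dataset):
        table, labels, _ = canonical_dataset
        cfg = ise.ISEConfig(seed=0, n_iterations=4, filters_per_iteration=50, mcc_min=0.999)
        with pytest.raises(ValueError, match="best found"):
            ise.train_model(table, labels, cfg)

    def test_label_shuffle_yields_near_zero_mcc(self, canonical_dataset, fast_config):
        # leakage guard: over 20 shuffles the mean held-out MCC stays near 0
        table, labels, _ = canonical_dataset
        rng = np.random.default_rng(0)
        mccs = []
        for i in range(20):
            y = labels.copy()
            rng.shuffle(y)
            cfg = ise.ISEConfig(
                seed=i, n_iterations=fast_config.n_iterations,
                filters_per_iteration=fast_config.filters_per_iteration, mcc_min=-1.0,
            )
            mccs.append(ise.train_model(table, y, cfg).filters[0][1].mcc)
        assert abs(np.mean(mccs)) < 0.15

    def test_model_json_round_trip(self, trained_model, tmp_path):
        path = tmp_path / "model.json"
        trained_model.save(path)
        loaded = ise.Model.load(path)
        assert loaded.to_dict() == trained_model.to_dict()


class TestCrossValidate:
    def test_five_fold_harness_reports_spread(self, fast_config):
        table, labels, _ = synth.make_classification_dataset(
            synth.ClassificationSpec(n_actives=100, n_inactives=100, seed=2)
        )
        rng = np.random.default_rng(0)
        folds = np.array([(i % 5) + 1 for i in range(len(labels))])
        rng.shuffle(folds)
        report = ise.cross_validate(table, labels, folds, fast_config)
        assert len(report) == 5
        assert report["top_filter_mcc"].between(-1, 1).all()
        assert report["auc"].between(0, 1).all()

    def test_merge_models_unions_filters(self, fast_config):
        table, labels, _ = synth.make_classification_dataset(
            synth.ClassificationSpec(n_actives=80, n_inactives=80, seed=3)
        )
        m1 = ise.train_model(table, labels, fast_config)
        cfg2 = ise.ISEConfig(seed=1, n_iterations=8, filters_per_iteration=100, mcc_min=-1.0)
        m2 = ise.train_model(table, labels, cfg2)
        merged = ise.merge_models([m1, m2])
        assert merged.n == m1.n + m2.n
        mccs = [p.mcc for _, p in merged.filters]
        assert mccs == sorted(mccs, reverse=True)


# ---------------------------------------------------------------------------
# cascade

@pytest.fixture(scope="module")
def two_models():
    t1, y1, _ = synth.make_classification_dataset(synth.ClassificationSpec(seed=5))
    cfg = ise.ISEConfig(seed=0, n_iterations=10, filters_per_iteration=150, mcc_min=-1.0)
    m1 = ise.train_model(t1, y1, cfg)
    m2 = ise.train_model(t1.copy(), 1 - y1, cfg)
    return m1, m2, t1


class TestScreenCascade:

    def test_stage_one_failures_not_scored_downstream(self, two_models):
        m1, m2, table = two_models
        out = ise.screen_cascade([m1, m2], table.head(100))
        failed1 = out["failed_stage"] == 1
        assert failed1.any()
        assert out.loc[failed1, "index_2"].isna().all()
        assert (out.loc[failed1, "index_1"] <= 0).all()

    def test_matches_brute_force_on_synthetic_library(self, two_models):
        m1, m2, table = two_models
        lib = table.head(100)
        out = ise.screen_cascade([m1, m2], lib)
        idx1 = ise.screen_table(m1, lib)
        idx2 = ise.screen_table(m2, lib)
        expected_pass = (idx1 > 0) & (idx2 > 0)
        assert (out["passed"] == expected_pass).all()
        survivors = out.index[out["passed"]]
        assert np.allclose(out.loc[survivors, "index_2"], idx2[survivors])

    def test_all_positive_molecule_flagged_pass(self, two_models):
        m1, m2, table = two_models
        out = ise.screen_cascade([m1, m2], table)
        winners = out[(out["index_1"] > 0) & (out["index_2"] > 0)]
        assert (winners["passed"]).all() and (winners["failed_stage"] == 0).all()
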