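import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from motcs.io import DriverCatalog, MotcsError, OmicsMatrix, \
    ProbeAnnotation, SubtypeLabelSet
from motcs.preprocess import (aggregate_methylation, filter_probes,
                              filter_zero_fraction, impute_knn,
                              partition_features, select_l1svc,
                              selection_stability)


def _mat(values, view="mRNA", feats=None):
    values = np.asarray(values, dtype=float)
    samples = [f"s{i}" for i in range(values.shape[0])]
    feats = feats or [f"f{j}" for j in range(values.shape[1])]
    return OmicsMatrix(view, samples, feats, values)


class TestZeroFractionFilter:
    def test_hand_counted_fractions(self):
        # per-feature zeros: 0, 1, 2 of 4 samples -> fractions 0, .25, .5
        m = _mat([[1, 0, 0], [1, 1, 0], [1, 1, 1], [1, 1, 1]])
        out = filter_zero_fraction(m, 0.25)
        assert out.feature_ids == ["f0", "f1"]

    def test_all_nonzero_unchanged(self):
        m = _mat(np.ones((3, 4)))
        assert filter_zero_fraction(m).feature_ids == m.feature_ids

    def test_zero_threshold_boundary(self):
        m = _mat([[1, 0], [1, 1]])
        assert filter_zero_fraction(m, 0.0).feature_ids == ["f0"]

    def test_all_removed_errors(self):
        m = _mat([[0, 0], [0, 0]])
        with pytest.raises(MotcsError):
            filter_zero_fraction(m)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce_recount(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.integers(0, 3, size=(12, 8)).astype(float)
        thr = rng.choice([0.0, 0.25, 0.5])
        expected = [f"f{j}" for j in range(8)
                    if sum(1 for v in vals[:, j] if v == 0) / 12 <= thr]
        if not expected:
            with pytest.raises(MotcsError):
                filter_zero_fraction(_mat(vals), thr)
        else:
            assert filter_zero_fraction(_mat(vals), thr).feature_ids \
                == expected


@settings(max_examples=50, derandomize=True, deadline=None)
@given(st.lists(st.lists(st.sets(st.integers(0, 9)), min_size=2,
                         max_size=5), min_size=1, max_size=1))
def test_stability_overlaps_always_in_unit_interval(fold_sets):
    report = selection_stability([set(s) for s in fold_sets[0]])
    for v in report.pairwise_overlaps.values():
        assert 0.0 <= v <= 1.0
    assert 0.0 <= report.mean_overlap <= 1.0


@settings(max_examples=50, derandomize=True, deadline=None)
@given(st.integers(0, 2**31 - 1), st.floats(0.0, 1.0))
def test_zero_filter_equals_recount_on_random_matrices(seed, thr):
    rng = np.random.default_rng(seed)
    vals = (rng.random((8, 6)) < 0.6).astype(float) * rng.integers(
        1, 5, size=(8, 6))
    expected = [f"f{j}" for j in range(6)
                if (vals[:, j] == 0).sum() / 8 <= thr]
    m = _mat(vals)
    if not expected:
        with pytest.raises(MotcsError):
            filter_zero_fraction(m, thr)
    else:
        assert filter_zero_fraction(m, thr).feature_ids == expected


class TestProbeFilter:
    def test_worked_fixture_counts(self, worked):
        out = filter_probes(worked.views[2], worked.annotation)
        assert out.feature_ids == ["cg01a", "cg01b", "cg02a", "cg02b"]

    def test_unannotated_probe_dropped(self, worked):
        beta = worked.views[2]
        ann = ProbeAnnotation(worked.annotation.table.iloc[1:].copy())
        out = filter_probes(beta, ann)
        assert "cg01a" not in out.feature_ids

    def test_all_flagged_errors(self, worked):
        t = worked.annotation.table.copy()
        t["flagged"] = True
        with pytest.raises(MotcsError):
            filter_probes(worked.views[2], ProbeAnnotation(t))


class TestKnnImpute:
    def test_no_missing_is_identity(self):
        m = _mat(np.arange(12.0).reshape(3, 4), view="methylation")
        out = impute_knn(m, k=2)
        assert np.array_equal(out.values, m.values)

    def test_matches_bruteforce_nearest_neighbour(self):
        # 5x4 toy with one hole; expectation computed by explicit search
        rng = np.random.default_rng(8)
        vals = rng.random((5, 4)).round(2)
        vals[2, 1] = np.nan
        m = _mat(vals, view="methylation")
        out = impute_knn(m, k=1)
        best, best_d = None, np.inf
        for g in [0, 2, 3]:
            shared = [s for s in range(5) if s != 2]
            d = np.sqrt(np.mean([(vals[s, 1] - vals[s, g]) ** 2
                                 for s in shared]))
            if d < best_d:
                best, best_d = g, d
        assert out.values[2, 1] == vals[2, best]

    def test_twin_feature_fills_hole(self):
        base = np.array([0.1, 0.5, 0.9, 0.3])
        vals = np.column_stack([base, base, base + 0.4])
        vals[1, 0] = np.nan
        out = impute_knn(_mat(vals, view="methylation"), k=1)
        assert out.values[1, 0] == 0.5

    def test_feature_missing_everywhere_errors(self):
        vals = np.ones((3, 2))
        vals[:, 1] = np.nan
        with pytest.raises(MotcsError, match="f1"):
            impute_knn(_mat(vals, view="methylation"))


class TestAggregateMethylation:
    def test_worked_fixture_means(self, worked):
        beta = filter_probes(worked.views[2], worked.annotation)
        beta = impute_knn(beta, k=1)
        out = aggregate_methylation(beta, worked.annotation)
        df = out.to_frame()
        assert list(df.columns) == ["MG0001", "MG0002"]
        assert df.loc["S1", "MG0001"] == pytest.approx((0.20 + 0.22) / 2)
        assert df.loc["S2", "MG0001"] == pytest.approx(0.42)
        # MG0002's only in-window probe is cg02b
        assert np.allclose(df["MG0002"], beta.to_frame()["cg02b"])

    def test_out_of_window_probe_excluded(self, worked):
        # cg02a sits 2000 bp upstream: absent at 1500, included at 2500
        beta = impute_knn(worked.views[2], k=1)
        wide = aggregate_methylation(beta, worked.annotation, window_bp=2500)
        narrow = aggregate_methylation(beta, worked.annotation)
        assert not np.allclose(wide.to_frame()["MG0002"],
                               narrow.to_frame()["MG0002"])

    def test_values_within_contributing_probe_range(self):
        rng = np.random.default_rng(0)
        vals = rng.random((6, 5))
        m = _mat(vals, view="methylation",
                 feats=[f"cg{j}" for j in range(5)])
        ann = ProbeAnnotation(pd.DataFrame({
            "probe_id": [f"cg{j}" for j in range(5)],
            "gene": ["g1", "g1", "g1", "g2", "g2"],
            "dist_tss": [100, 700, 1400, 200, 900],
            "chrom": ["1"] * 5, "flagged": [False] * 5}))
        out = aggregate_methylation(m, ann)
        assert np.all(out.to_frame()["g1"] <= vals[:, :3].max(axis=1))
        assert np.all(out.to_frame()["g1"] >= vals[:, :3].min(axis=1))


class TestPartition:
    def test_simple_split(self):
        m = _mat(np.ones((2, 2)), feats=["ERBB2", "GAPDH"])
        d, nd = partition_features(m, DriverCatalog({"ERBB2"}, set()))
        assert (d, nd) == (["ERBB2"], ["GAPDH"])

    def test_empty_catalog(self):
        m = _mat(np.ones((2, 3)))
        d, nd = partition_features(m, DriverCatalog())
        assert d == [] and nd == m.feature_ids

    def test_all_drivers(self):
        m = _mat(np.ones((2, 2)), feats=["a", "b"])
        d, nd = partition_features(m, DriverCatalog({"a", "b"}, set()))
        assert d == ["a", "b"] and nd == []

    @pytest.mark.parametrize("seed", range(5))
    def test_union_and_disjointness(self, seed):
        rng = np.random.default_rng(seed)
        feats = [f"f{j}" for j in range(10)]
        cat = DriverCatalog(set(rng.choice(feats, 4, replace=False)), set())
        m = _mat(np.ones((2, 10)), feats=feats)
        d, nd = partition_features(m, cat)
        assert sorted(d + nd) == sorted(feats)
        assert not set(d) & set(nd)


def _binary_problem(seed, n=200, p=100):
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, size=n)
    X = rng.normal(size=(n, p))
    X[:, 0] = np.where(y == 1, 1.0, -1.0) * np.abs(X[:, 0]) * 2
    m = _mat(X, feats=[f"f{j}" for j in range(p)])
    labels = SubtypeLabelSet(list(m.sample_ids), ["a", "b"], y)
    return m, labels


class TestL1Selection:
    def test_planted_feature_selected_across_replicates(self):
        hits = sum("f0" in select_l1svc(*_binary_problem(seed), C=0.1,
                                        seed=seed)
                   for seed in range(20))
        assert hits >= 19

    def test_constant_features_never_selected(self):
        m, labels = _binary_problem(1)
        vals = m.values.copy()
        vals[:, 5] = 3.0
        m2 = _mat(vals, feats=m.feature_ids)
        assert "f5" not in select_l1svc(m2, labels, C=0.5, seed=0)

    def test_deterministic_given_seed(self):
        m, labels = _binary_problem(2)
        assert select_l1svc(m, labels, seed=7) == \
            select_l1svc(m, labels, seed=7)

    def test_single_class_errors(self):
        m, _ = _binary_problem(3)
        labels = SubtypeLabelSet(list(m.sample_ids), ["a", "b"],
                                 np.zeros(m.n_samples, dtype=int))
        with pytest.raises(MotcsError):
            select_l1svc(m, labels)


class TestSelectionStability:
    def test_identical_sets(self):
        r = selection_stability([{"a", "b"}] * 3)
        assert all(v == 1.0 for v in r.pairwise_overlaps.values())
        assert r.mean_overlap == 1.0

    def test_disjoint_sets(self):
        r = selection_stability([{"a"}, {"b"}, {"c"}])
        assert r.mean_overlap == 0.0

    def test_hand_counted_overlap(self):
        r = selection_stability([{"a", "b", "c"}, {"b", "c", "d"}])
        assert r.mean_overlap == pytest.approx(2 / 3)

    def test_empty_fold_contributes_zero(self):
        r = selection_stability([set(), {"a", "b"}])
        assert r.mean_overlap == 0.0
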