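"""Sliding-window connectivity, state clustering, temporal metrics."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from gradstates import synthetic as syn
from gradstates.dfc import (
    WindowSpec,
    cluster_quality_scan,
    dfc_variability,
    fit_states,
    match_states,
    metrics_table,
    pool_windows,
    sliding_window_fc,
    state_edge_contrast,
    temporal_metrics,
)
from gradstates.gradients import compute_fc
from conftest import make_timeseries


def brute_silhouette(x, labels):
    """Definitional silhouette: mean over points of (b - a)/max(a, b)."""
    n = len(x)
    d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
    vals = []
    for i in range(n):
        own = labels == labels[i]
        if own.sum() < 2:
            vals.append(0.0)
            continue
        a = d[i, own].sum() / (own.sum() - 1)
        b = min(d[i, labels == lab].mean()
                for lab in np.unique(labels) if lab != labels[i])
        vals.append((b - a) / max(a, b))
    return float(np.mean(vals))


def brute_calinski_harabasz(x, labels):
    """Definitional CH index: (B/(k-1)) / (W/(n-k))."""
    n, k = len(x), len(np.unique(labels))
    grand = x.mean(axis=0)
    b = w = 0.0
    for lab in np.unique(labels):
        pts = x[labels == lab]
        c = pts.mean(axis=0)
        b += len(pts) * ((c - grand) ** 2).sum()
        w += ((pts - c) ** 2).sum()
    return (b / (k - 1)) / (w / (n - k))


class TestSlidingWindows:
    @pytest.mark.parametrize("T,L,step,expected", [
        (230, 50, 1, 181),
        (140, 50, 1, 91),
        (50, 50, 1, 1),
        (240, 60, 3, 61),
        (100, 30, 7, 11),
    ])
    def test_window_count_formula(self, T, L, step, expected, rng):
        ts = make_timeseries(rng.standard_normal((T, 14)))
        series = sliding_window_fc(ts, WindowSpec(length=L, step=step))
        assert series.n_windows == expected
        assert series.edges.shape[1] == 14 * 13 // 2

    def test_single_window_equals_static_fc(self, rng):
        ts = make_timeseries(rng.standard_normal((50, 14)))
        series = sliding_window_fc(ts, WindowSpec(length=50))
        static = compute_fc(ts, fisher=True).values
        iu = np.triu_indices(14, 1)
        assert np.allclose(series.edges[0], static[iu], atol=1e-10)

    def test_series_shorter_than_window_rejected(self, rng):
        ts = make_timeseries(rng.standard_normal((40, 14)))
        with pytest.raises(ValueError, match="shorter"):
            sliding_window_fc(ts, WindowSpec(length=50))

    def test_constant_parcel_in_window_named(self, rng):
        data = rng.standard_normal((80, 14))
        data[10:60, 4] = 1.5
        with pytest.raises(ValueError, match="p004"):
            sliding_window_fc(make_timeseries(data), WindowSpec(length=50))

    def test_gaussian_taper_runs(self, rng):
        ts = make_timeseries(rng.standard_normal((80, 14)))
        rect = sliding_window_fc(ts, WindowSpec(length=50))
        gauss = sliding_window_fc(ts, WindowSpec(length=50, taper="gaussian"))
        assert rect.edges.shape == gauss.edges.shape
        assert not np.allclose(rect.edges, gauss.edges)


class TestVariability:
    def test_identical_windows_have_zero_sd(self, rng):
        ts = make_timeseries(np.tile(rng.standard_normal((50, 14)), (3, 1)))
        series = sliding_window_fc(ts, WindowSpec(length=50, step=50))
        assert np.allclose(dfc_variability(series), 0.0, atol=1e-10)

    def test_hand_computed_alternating_sd(self):
        # z alternating {0,1} over 4 windows: sample sd with W-1=3 is 0.57735
        class Stub:
            edges = np.array([[0.0], [1.0], [0.0], [1.0]])
            n_windows = 4
        assert np.isclose(dfc_variability(Stub()), np.sqrt(1.0 / 3.0), atol=1e-6)
        assert np.isclose(dfc_variability(Stub())[0], 0.57735, atol=1e-5)

    def test_order_invariance(self, rng):
        ts = make_timeseries(rng.standard_normal((120, 14)))
        series = sliding_window_fc(ts, WindowSpec(length=50, step=10))
        sd = dfc_variability(series)
        series.edges = series.edges[::-1]
        assert np.allclose(dfc_variability(series), sd)

    def test_single_window_rejected(self, rng):
        ts = make_timeseries(rng.standard_normal((50, 14)))
        series = sliding_window_fc(ts, WindowSpec(length=50))
        with pytest.raises(ValueError):
            dfc_variability(series)


class TestStateFitting:
    def test_k1_sse_is_total_scatter(self, rng):
        pooled = rng.standard_normal((100, 10))
        model = fit_states(pooled, [("s", 100)], k=1, seed=0, n_restarts=3)
        expected = ((pooled - pooled.mean(axis=0)) ** 2).sum()
        assert np.isclose(model.sse, expected, rtol=1e-10)

    def test_planted_separable_clusters_recovered(self, rng):
        centers = rng.standard_normal((4, 20)) * 20
        labels_true = rng.integers(0, 4, 400)
        pooled = centers[labels_true] + rng.standard_normal((400, 20))
        model = fit_states(pooled, [("s", 400)], k=4, seed=0, n_restarts=10)
        assert adjusted_rand_score(labels_true, model.labels["s"]) == 1.0

    def test_same_seed_identical_model(self, rng):
        pooled = rng.standard_normal((200, 12))
        a = fit_states(pooled, [("s", 200)], 3, seed=5, n_restarts=5)
        b = fit_states(pooled, [("s", 200)], 3, seed=5, n_restarts=5)
        assert np.array_equal(a.labels["s"], b.labels["s"])
        assert np.allclose(a.centroids, b.centroids)

    def test_labels_mapped_back_per_subject(self, rng):
        pooled = rng.standard_normal((150, 12))
        counts = [("a", 50), ("b", 60), ("c", 40)]
        model = fit_states(pooled, counts, 2, seed=0, n_restarts=3)
        assert [len(model.labels[s]) for s, _ in counts] == [50, 60, 40]

    def test_more_clusters_than_windows_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_states(rng.standard_normal((3, 5)), [("s", 3)], 10)


class TestQualityScan:
    def test_two_blobs_select_k2(self, rng):
        pooled = np.vstack([rng.standard_normal((60, 5)) - 8,
                            rng.standard_normal((60, 5)) + 8])
        scan = cluster_quality_scan(pooled, [("s", 120)], k_range=(2, 5),
                                    seed=0, n_restarts=5,
                                    silhouette_sample_size=None)
        assert scan.chosen_k == 2
        assert np.argmax(scan.silhouette) == 0

    def test_hand_silhouette_value(self):
        # point at 0 in {0, 0.1} vs {10, 10.1}: a=0.1, b=10.05 -> 0.990050
        x = np.array([[0.0], [0.1], [10.0], [10.1]])
        labels = np.array([0, 0, 1, 1])
        s_all = brute_silhouette(x, labels)
        # point-level value for the first point
        a, b = 0.1, 10.05
        assert np.isclose((b - a) / max(a, b), 0.990050, atol=1e-6)
        from sklearn.metrics import silhouette_score
        assert np.isclose(s_all, silhouette_score(x, labels), atol=1e-10)

    def test_sse_non_increasing_in_k(self, rng):
        pooled = rng.standard_normal((150, 8))
        scan = cluster_quality_scan(pooled, [("s", 150)], k_range=(2, 7),
                                    seed=0, n_restarts=10,
                                    silhouette_sample_size=None)
        assert all(np.diff(scan.sse) <= 1e-6)

    def test_matches_brute_force_quality_indices(self, rng):
        # definitional silhouette / CH oracles on a small instance
        pooled = np.vstack([rng.standard_normal((20, 4)) - 3,
                            rng.standard_normal((20, 4)) + 3])
        model = fit_states(pooled, [("s", 40)], 2, seed=0, n_restarts=5)
        labels = model.labels["s"]
        from sklearn.metrics import calinski_harabasz_score, silhouette_score
        assert np.isclose(silhouette_score(pooled, labels),
                          brute_silhouette(pooled, labels), atol=1e-10)
        assert np.isclose(calinski_harabasz_score(pooled, labels),
                          brute_calinski_harabasz(pooled, labels), atol=1e-8)


class TestTemporalMetrics:
    def test_hand_run_length_example(self):
        m = temporal_metrics(np.array([0, 0, 1, 1, 1, 0]), k=2,
                             spec=WindowSpec(length=50, step=1), tr_seconds=2.0)
        assert np.allclose(m["fo"], [0.5, 0.5])
        assert np.allclose(m["mdt_windows"], [1.5, 3.0])
        assert m["nt"] == 2
        assert np.allclose(m["mdt_seconds"], [3.0, 6.0])

    def test_constant_labels(self):
        m = temporal_metrics(np.zeros(40, dtype=int), k=3)
        assert m["fo"][0] == 1.0 and m["nt"] == 0
        assert m["mdt_windows"][0] == 40
        assert np.isnan(m["mdt_windows"][1])

    def test_fo_partitions_windows(self, rng):
        labels = rng.integers(0, 4, 500)
        m = temporal_metrics(labels, k=4)
        assert np.isclose(m["fo"].sum(), 1.0)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            temporal_metrics(np.array([0, 5, 1]), k=3)

    def test_metrics_table_long_format(self, rng):
        pooled = rng.standard_normal((60, 6))
        model = fit_states(pooled, [("a", 30), ("b", 30)], 2, seed=0,
                           n_restarts=3)
        tbl = metrics_table(model, WindowSpec(length=50, step=1), 2.0)
        assert set(tbl["subject_id"]) == {"a", "b"}
        assert len(tbl) == 4  # 2 subjects x 2 states


class TestStateMatching:
    def test_permuted_reference_recovered(self, rng):
        ref = rng.standard_normal((4, 30))
        perm = np.array([2, 0, 3, 1])
        cents = ref[perm] + 0.05 * rng.standard_normal((4, 30))
        mapping = match_states(cents, ref)
        assert [mapping[i] for i in range(4)] == perm.tolist()


class TestEdgeContrast:
    def _cohort(self, delta, rng, n=10):
        # two groups of window series; group B has one edge shifted in state 0
        series = []
        rows = []
        for g, grp in enumerate(["HC", "AD"]):
            for i in range(n):
                sid = f"{grp}{i}"
                edges = rng.standard_normal((20, 15)) * 0.5
                if grp == "AD":
                    edges[:, 3] += delta
                s = type("S", (), {})()
                s.subject_id = sid
                s.edges = edges
                s.n_windows = 20
                series.append(s)
                rows.append({"subject_id": sid, "group": grp,
                             "age": 70 + rng.normal(), "sex": i % 2})
        return series, pd.DataFrame(rows)

    def test_planted_edge_detected_with_correct_sign(self, rng):
        series, subjects = self._cohort(1.0, rng)
        labels = {s.subject_id: np.zeros(20, dtype=int) for s in series}
        model = type("M", (), {"labels": labels, "k": 1})()
        res = state_edge_contrast(series, model, 0, subjects, baseline="HC")
        assert bool(res.loc[3, "significant"])
        assert res.loc[3, "t"] > 0  # planted increase in the AD group
        others = res.drop(index=3)
        assert not others["significant"].any()

    def test_null_cohort_no_discoveries(self, rng):
        series, subjects = self._cohort(0.0, rng)
        labels = {s.subject_id: np.zeros(20, dtype=int) for s in series}
        model = type("M", (), {"labels": labels, "k": 1})()
        res = state_edge_contrast(series, model, 0, subjects)
        assert not res["significant"].any()

    def test_subject_without_state_excluded(self, rng):
        series, subjects = self._cohort(0.0, rng)
        labels = {s.subject_id: np.zeros(20, dtype=int) for s in series}
        labels[series[0].subject_id] = np.ones(20, dtype=int)
        model = type("M", (), {"labels": labels, "k": 2})()
        res = state_edge_contrast(series, model, 0, subjects)
        assert res.attrs["excluded_subjects"] == [series[0].subject_id]


class TestEndToEndStateRecovery:
    def test_planted_states_recovered_from_windows(self):
        # sticky chain (dwell >> window) so window labels are resolvable
        tm = syn.sticky_transition_matrix(np.full(4, 0.25), 0.95)
        cfg = syn.SyntheticCohortConfig(
            n_per_group=5, n_parcels=40, n_timepoints=400, seed=7,
            transition_matrices={"HC": tm, "AD": tm})
        series, _, truth = syn.simulate_cohort(cfg)
        sw = [sliding_window_fc(s, WindowSpec(length=50, step=2))
              for s in series]
        pooled, counts = pool_windows(sw)
        model = fit_states(pooled, counts, 4, seed=0, n_restarts=10)
        true = np.concatenate([
            syn.true_window_labels(truth.timepoint_labels[sid], 50, 2)
            for sid, _ in counts])
        pred = np.concatenate([model.labels[sid] for sid, _ in counts])
        assert adjusted_rand_score(true, pred) >= 0.8
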