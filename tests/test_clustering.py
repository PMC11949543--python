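"""Pooling, K selection, L1 k-means brain states, and noise-state pruning."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from statedyn import clustering, windows
from statedyn.clustering import (
    NoElbowWarning,
    estimate_k,
    fit_states,
    pool_windows,
    prune_noise_states,
)
from statedyn.synthetic import make_state_covariances, simulate_run, simulate_study

from conftest import small_params


class TestPooling:
    def test_concatenation_count_and_provenance_roundtrip(self, small_analysis):
        pooled = small_analysis["pooled"]
        prov = small_analysis["provenance"]
        series = small_analysis["series"]
        assert pooled.shape[0] == sum(s.n_windows for s in series)
        # provenance row -> original vector equality
        for row_idx in (0, 57, len(prov) - 1):
            run_id = prov.loc[row_idx, "run_id"]
            center = prov.loc[row_idx, "center_tr"]
            s = next(x for x in series if x.run_id == run_id)
            w_idx = int(np.flatnonzero(s.window_center_trs == center)[0])
            assert np.array_equal(pooled[row_idx], s.edge_vectors[w_idx])

    def test_condition_counts_match_manifest(self, small_analysis, small_study):
        prov = small_analysis["provenance"]
        med_windows = (prov["condition"] == "meditation").sum()
        per_run = small_study.runs[0].n_trs - 16 + 1
        assert med_windows == per_run * len(small_study.meditation_runs())

    def test_edge_order_mismatch_hard_error(self, small_analysis):
        series = small_analysis["series"]
        bad = windows.WindowedConnectivitySeries(
            run_id="bad",
            condition="meditation",
            edge_vectors=series[0].edge_vectors.copy(),
            window_center_trs=series[0].window_center_trs.copy(),
            node_labels=list(reversed(series[0].node_labels)),
        )
        with pytest.raises(ValueError, match="edge-label order"):
            pool_windows([series[0], bad])


class TestEstimateK:
    def test_planted_three_clusters_recovered(self, rng):
        centers = rng.normal(0, 5, (3, 50))
        X = np.vstack([c + rng.normal(0, 1, (120, 50)) for c in centers])
        k, curve = estimate_k(X, 2, 8, seed=0, n_replicates=4)
        assert k == 3
        assert len(curve) == 7

    def test_single_gaussian_returns_kmin_with_warning(self, rng):
        X = rng.normal(size=(400, 50))
        with pytest.warns(NoElbowWarning):
            k, _ = estimate_k(X, 2, 8, seed=0, n_replicates=4)
        assert k == 2

    def test_same_seed_identical_curve(self, rng):
        X = rng.normal(size=(100, 10))
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            k1, c1 = estimate_k(X, 2, 5, seed=3, n_replicates=3)
            k2, c2 = estimate_k(X, 2, 5, seed=3, n_replicates=3)
        assert k1 == k2
        assert np.array_equal(c1["dispersion"], c2["dispersion"])

    def test_too_few_rows_rejected(self, rng):
        with pytest.raises(ValueError, match="pooled windows"):
            estimate_k(rng.normal(size=(8, 4)), 2, 10)


class TestFitStates:
    def test_planted_state_recovery_small_study(self, small_study, small_analysis):
        taper = small_analysis["taper"]
        truth, pred = [], []
        for seq in small_analysis["sequences"]:
            gt = small_study.truths[seq.run_id]
            truth.append(windows.window_truth_labels(gt.labels, seq.window_center_trs, taper))
            pred.append(seq.labels)
        ari = adjusted_rand_score(np.concatenate(truth), np.concatenate(pred))
        assert ari >= 0.8

    def test_duplication_invariance(self, rng):
        centers = rng.normal(0, 6, (3, 20))
        X = np.vstack([c + rng.normal(0, 0.5, (60, 20)) for c in centers])
        prov = pd.DataFrame(
            {"run_id": ["r"] * len(X), "center_tr": np.arange(len(X)),
             "condition": ["meditation"] * len(X)}
        )
        prov2 = pd.concat([prov, prov]).reset_index(drop=True)
        prov2["center_tr"] = np.arange(len(prov2))
        m1, _ = fit_states(X, prov, 3, seed=0, n_replicates=8)
        m2, _ = fit_states(np.vstack([X, X]), prov2, 3, seed=0, n_replicates=8)
        # identical centroids up to relabeling
        from scipy.optimize import linear_sum_assignment
        from scipy.spatial.distance import cdist

        D = cdist(m1.centroids, m2.centroids)
        r, c = linear_sum_assignment(D)
        assert D[r, c].max() < 1e-6

    def test_k_one_rejected(self, rng):
        X = rng.normal(size=(50, 5))
        prov = pd.DataFrame(
            {"run_id": ["r"] * 50, "center_tr": np.arange(50), "condition": ["meditation"] * 50}
        )
        with pytest.raises(ValueError, match="k must be"):
            fit_states(X, prov, 1)

    def test_run_order_permutation_only_relabels(self, small_study):
        taper = windows.make_taper()
        series = [windows.windowed_connectivity(tc, taper) for tc in small_study.runs]
        pooled_a, prov_a = pool_windows(series)
        pooled_b, prov_b = pool_windows(series[::-1])
        m_a, seq_a = fit_states(pooled_a, prov_a, 3, seed=0, n_replicates=8)
        m_b, seq_b = fit_states(pooled_b, prov_b, 3, seed=0, n_replicates=8)
        by_id_a = {s.run_id: s.labels for s in seq_a}
        by_id_b = {s.run_id: s.labels for s in seq_b}
        ari = adjusted_rand_score(
            np.concatenate([by_id_a[r] for r in sorted(by_id_a)]),
            np.concatenate([by_id_b[r] for r in sorted(by_id_b)]),
        )
        assert ari == pytest.approx(1.0)


def _pruning_study():
    """3 clean templates everywhere + a rough 4th template present only in
    the last meditation run (which contains nothing else)."""
    rng = np.random.default_rng(99)
    n = 16
    clean_spec = [
        {"description": "a", "baseline_r": 0.45,
         "blocks": [{"nodes": list(range(4)), "within_r": 0.5, "to_rest_r": -0.35}]},
        {"description": "b", "baseline_r": 0.6, "blocks": []},
        {"description": "c", "baseline_r": 0.0, "blocks": []},
    ]
    templates = make_state_covariances(n, structure_spec=clean_spec)
    # rough template: random near-PD correlation with erratic structure
    A = rng.uniform(-1, 1, (n, n))
    rough = A @ A.T
    d = np.sqrt(np.diag(rough))
    rough = rough / np.outer(d, d)
    from statedyn.synthetic import StateTemplate, nearest_pd_correlation

    templates = templates + [StateTemplate(4, nearest_pd_correlation(rough), "noise")]

    plan = [("J1", 120)]
    runs, truths = [], {}
    for i in range(6):
        sched = {"J1": np.array([0.34, 0.33, 0.33, 0.0])}
        tc, gt = simulate_run(templates, plan, sched, stickiness=0.95, seed=i,
                              run_id=f"med-{i:02d}", condition="meditation")
        runs.append(tc)
        truths[tc.run_id] = gt
    # the noise run: only the rough state
    tc, gt = simulate_run(templates, plan, {"J1": np.array([0, 0, 0, 1.0])},
                          stickiness=0.95, seed=100, run_id="med-99",
                          condition="meditation")
    runs.append(tc)
    truths[tc.run_id] = gt
    return runs


class TestPruning:
    def test_constructed_noise_state_pruned_and_run_excluded(self):
        runs = _pruning_study()
        taper = windows.make_taper()
        series = [windows.windowed_connectivity(tc, taper) for tc in runs]
        pooled, prov = pool_windows(series)
        model, seqs = fit_states(pooled, prov, 4, seed=1, n_replicates=10)
        pruned, new_seqs, excluded = prune_noise_states(
            model, seqs, series_by_run={s.run_id: s for s in series}
        )
        assert excluded == ["med-99"]
        assert len(pruned.retained_ids) == 3
        assert len(pruned.pruning_log) == 1
        # surviving runs keep gapless full-length sequences over retained ids
        for s in new_seqs:
            assert len(s) == series[0].n_windows
            assert set(np.unique(s.labels)) <= set(pruned.retained_ids)

    def test_state_in_two_runs_never_pruned(self, small_analysis):
        model = small_analysis["model"]
        seqs = small_analysis["sequences"]
        # all three planted states appear in many runs: pruning is a no-op
        pruned, new_seqs, excluded = prune_noise_states(model, seqs)
        assert pruned.retained_ids == model.retained_ids
        assert excluded == []
        for a, b in zip(seqs, new_seqs):
            assert np.array_equal(a.labels, b.labels)

    def test_prune_all_states_errors(self, rng):
        from statedyn.clustering import BrainStateModel
        from statedyn.core import StateSequence

        # single state, single run, rough centroid: rule would remove everything
        model = BrainStateModel(
            centroids=rng.normal(size=(1, 10)), k_selected=1,
            distance_metric="cityblock", seed=0, n_replicates=1, retained_ids=[1],
        )
        seq = StateSequence("med-01", "meditation", np.ones(5, dtype=int),
                            np.arange(5), [None] * 5)
        with pytest.raises(ValueError, match="remove all"):
            prune_noise_states(model, [seq], roughness_factor=0.0)
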