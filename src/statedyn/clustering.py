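"""Brain-state clustering of pooled window edge vectors.

Windows from all runs and both conditions are pooled, the number of states
K is selected by an elbow criterion on the within-cluster dispersion curve
(ratio of successive dispersion drops), and states are fit by k-means with L1
(city-block) distance — the dynamic-connectivity toolbox convention — using
best-of-replicates seeded initialization.  A post-fit pruning rule removes
"noise" states: states whose meditation windows all come from exactly one
meditation run *and* whose centroid is unusually rough (SD of first
differences along the canonical edge ordering above a configurable multiple
of the median roughness).  Runs left with no retained windows are excluded;
removed-state windows in surviving runs are reassigned to the nearest
retained centroid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .core import MEDITATION, StateSequence, WindowedConnectivitySeries
from .windows import window_stages


@dataclass
class BrainStateModel:
    centroids: np.ndarray            # K×E Fisher-z edge vectors
    k_selected: int
    distance_metric: str
    seed: int
    n_replicates: int
    retained_ids: list[int]          # 1-based state ids still in play
    pruning_log: dict[int, str] = field(default_factory=dict)
    inertia: float = float("nan")

    def retained_centroids(self) -> np.ndarray:
        return self.centroids[[i - 1 for i in self.retained_ids]]


class NoElbowWarning(UserWarning):
    pass


# ---------------------------------------------------------------------------
# pooling


def pool_windows(
    series_list: list[WindowedConnectivitySeries],
) -> tuple[np.ndarray, pd.DataFrame]:
    """Concatenate window edge vectors across runs (both conditions).

    Returns the pooled rows×E matrix and a provenance table mapping each row
    to (run_id, center TR, condition).  The edge-label order must be identical
    across series.
    """
    if not series_list:
        raise ValueError("no series to pool")
    ref = series_list[0].edge_labels()
    for s in series_list[1:]:
        if s.edge_labels() != ref:
            raise ValueError(
                f"edge-label order mismatch between runs "
                f"{series_list[0].run_id!r} and {s.run_id!r}"
            )
    pooled = np.vstack([s.edge_vectors for s in series_list])
    prov = pd.DataFrame(
        {
            "run_id": np.concatenate(
                [[s.run_id] * s.n_windows for s in series_list]
            ),
            "center_tr": np.concatenate([s.window_center_trs for s in series_list]),
            "condition": np.concatenate(
                [[s.condition] * s.n_windows for s in series_list]
            ),
        }
    )
    return pooled, prov


# ---------------------------------------------------------------------------
# k-means with L1 / squared-Euclidean metric


def _point_costs(X: np.ndarray, C: np.ndarray, metric: str) -> np.ndarray:
    if metric == "cityblock":
        return cdist(X, C, "cityblock")
    if metric == "sqeuclidean":
        return cdist(X, C, "sqeuclidean")
    raise ValueError(f"unknown metric {metric!r}")


def _update_centroids(X, labels, k, metric, rng):
    C = np.empty((k, X.shape[1]))
    for j in range(k):
        members = X[labels == j]
        if len(members) == 0:
            C[j] = X[rng.integers(len(X))]  # re-seed empty cluster
        elif metric == "cityblock":
            C[j] = np.median(members, axis=0)
        else:
            C[j] = members.mean(axis=0)
    return C


def _seed_centroids(X, k, metric, rng):
    """Greedy spread-out seeding: next center sampled proportionally to the
    distance to the nearest already-chosen center."""
    idx = [int(rng.integers(len(X)))]
    d = _point_costs(X, X[idx[-1]][None, :], metric)[:, 0]
    for _ in range(1, k):
        p = d / d.sum() if d.sum() > 0 else None
        nxt = int(rng.choice(len(X), p=p))
        idx.append(nxt)
        d = np.minimum(d, _point_costs(X, X[nxt][None, :], metric)[:, 0])
    return X[idx].copy()


def _kmeans_once(X, k, metric, rng, max_iter=100):
    C = _seed_centroids(X, k, metric, rng)
    labels = np.full(len(X), -1)
    for _ in range(max_iter):
        D = _point_costs(X, C, metric)
        new_labels = D.argmin(axis=1)
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        C = _update_centroids(X, labels, k, metric, rng)
    D = _point_costs(X, C, metric)
    labels = D.argmin(axis=1)
    cost = float(D[np.arange(len(X)), labels].sum())
    return C, labels, cost


def _kmeans(X, k, metric, seed, n_replicates, max_iter=100):
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_replicates):
        C, labels, cost = _kmeans_once(X, k, metric, rng, max_iter)
        if best is None or cost < best[2]:
            best = (C, labels, cost)
    return best


# ---------------------------------------------------------------------------
# K selection


def elbow_point(ks: np.ndarray, dispersions: np.ndarray, flat_threshold: float = 0.1):
    """Elbow of a decreasing dispersion curve.

    The elbow is the k maximizing the ratio of successive dispersion drops,
    i.e. the point where a large drop is followed by a small one.  Returns
    ``(k_opt, drop_ratios, flat)``; a near-flat curve (total relative drop
    below ``flat_threshold``) has no elbow and reports ``flat=True`` with
    ``k_opt`` = the smallest k.
    """
    ks = np.asarray(ks, dtype=float)
    y = np.asarray(dispersions, dtype=float)
    total_drop = (y[0] - y[-1]) / y[0] if y[0] > 0 else 0.0
    if total_drop < flat_threshold or len(ks) < 3:
        return int(ks[0]), np.zeros_like(y), True
    drops = np.maximum(-np.diff(y), 1e-12 * max(y[0], 1.0))  # drop into ks[i+1]
    ratios = np.zeros_like(y)
    ratios[1:-1] = drops[:-1] / drops[1:]
    return int(ks[int(np.argmax(ratios))]), ratios, False


def estimate_k(
    pooled: np.ndarray,
    k_min: int = 2,
    k_max: int = 10,
    seed: int = 0,
    n_replicates: int = 5,
    metric: str = "cityblock",
    flat_threshold: float = 0.1,
) -> tuple[int, pd.DataFrame]:
    """Elbow selection of the number of brain states.

    For each k in [k_min, k_max] the best-of-replicates within-cluster
    dispersion is computed; the elbow of the dispersion curve picks k.
    Returns ``(k_opt, curve)`` where the curve table carries k, dispersion,
    and the successive drop ratio, for audit.  A flat curve falls back to
    k_min with a :class:`NoElbowWarning`.
    """
    if pooled.shape[0] <= k_max:
        raise ValueError(f"need more than k_max={k_max} pooled windows")
    ks = np.arange(k_min, k_max + 1)
    disp = np.empty(len(ks))
    for i, k in enumerate(ks):
        _, _, cost = _kmeans(pooled, int(k), metric, seed + i, n_replicates)
        disp[i] = cost
    k_opt, dist, flat = elbow_point(ks, disp, flat_threshold)
    if flat:
        warnings.warn(
            f"dispersion curve has no elbow; falling back to k_min={k_min}",
            NoElbowWarning,
            stacklevel=2,
        )
    curve = pd.DataFrame({"k": ks, "dispersion": disp, "drop_ratio": dist})
    return k_opt, curve


# ---------------------------------------------------------------------------
# fitting and sequences


def fit_states(
    pooled: np.ndarray,
    provenance: pd.DataFrame,
    k: int,
    seed: int = 0,
    n_replicates: int = 20,
    metric: str = "cityblock",
    series_list: list[WindowedConnectivitySeries] | None = None,
    runs_by_id: dict | None = None,
) -> tuple[BrainStateModel, list[StateSequence]]:
    """Fit K brain states on the pooled windows and split assignments back
    into per-run state sequences via the provenance index.

    State ids are 1-based.  If ``runs_by_id`` (run_id -> RoiTimecourse) is
    given, each sequence also carries the stage label at each window center.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    C, labels, cost = _kmeans(pooled, k, metric, seed, n_replicates)
    model = BrainStateModel(
        centroids=C,
        k_selected=k,
        distance_metric=metric,
        seed=seed,
        n_replicates=n_replicates,
        retained_ids=list(range(1, k + 1)),
        inertia=cost,
    )
    sequences = _split_sequences(labels + 1, provenance, runs_by_id)
    return model, sequences


def _split_sequences(labels_1based, provenance, runs_by_id):
    sequences = []
    for run_id in provenance["run_id"].unique():
        mask = (provenance["run_id"] == run_id).to_numpy()
        centers = provenance.loc[mask, "center_tr"].to_numpy()
        condition = provenance.loc[mask, "condition"].iloc[0]
        if runs_by_id and run_id in runs_by_id:
            stages = window_stages(runs_by_id[run_id], centers)
        else:
            stages = [None] * mask.sum()
        sequences.append(
            StateSequence(
                run_id=run_id,
                condition=condition,
                labels=labels_1based[mask],
                window_center_trs=centers,
                stages=stages,
            )
        )
    return sequences


def centroid_roughness(centroids: np.ndarray) -> np.ndarray:
    """Per-state SD of first differences along the canonical edge ordering —
    high for noise-like centroids with erratic adjacent edge values."""
    return np.diff(centroids, axis=1).std(axis=1)


def prune_noise_states(
    model: BrainStateModel,
    sequences: list[StateSequence],
    meditation_run_ids: list[str] | None = None,
    roughness_factor: float = 1.5,
    series_by_run: dict[str, WindowedConnectivitySeries] | None = None,
) -> tuple[BrainStateModel, list[StateSequence], list[str]]:
    """Remove noise states and the runs that only contained them.

    A state is pruned iff (a) all of its meditation windows come from exactly
    one meditation run and (b) its centroid roughness exceeds
    ``roughness_factor`` × the median roughness of all states.  Windows of
    pruned states in surviving runs are reassigned to the nearest retained
    centroid; runs whose windows all belonged to pruned states are excluded.
    Returns (pruned model, updated sequences, excluded run ids).
    """
    if meditation_run_ids is None:
        meditation_run_ids = [s.run_id for s in sequences if s.condition == MEDITATION]
    med_ids = set(meditation_run_ids)
    rough = centroid_roughness(model.centroids)
    med_runs_per_state: dict[int, set] = {i: set() for i in model.retained_ids}
    for s in sequences:
        if s.run_id in med_ids:
            for lab in np.unique(s.labels):
                med_runs_per_state[int(lab)].add(s.run_id)

    median_rough = float(np.median(rough))
    to_remove = [
        sid
        for sid in model.retained_ids
        if len(med_runs_per_state[sid]) == 1
        and rough[sid - 1] > roughness_factor * median_rough
    ]
    if not to_remove:
        return model, sequences, []
    retained = [i for i in model.retained_ids if i not in to_remove]
    if not retained:
        raise ValueError("pruning would remove all states")

    log = dict(model.pruning_log)
    for sid in to_remove:
        only_run = next(iter(med_runs_per_state[sid]))
        log[sid] = (
            f"single-run state (only in {only_run}) with rough centroid "
            f"(SD of first differences {rough[sid - 1]:.3f} > "
            f"{roughness_factor} x median {median_rough:.3f})"
        )
    pruned_model = BrainStateModel(
        centroids=model.centroids,
        k_selected=model.k_selected,
        distance_metric=model.distance_metric,
        seed=model.seed,
        n_replicates=model.n_replicates,
        retained_ids=retained,
        pruning_log=log,
        inertia=model.inertia,
    )

    retained_centroids = model.centroids[[i - 1 for i in retained]]
    new_sequences, excluded = [], []
    for s in sequences:
        removed_mask = np.isin(s.labels, to_remove)
        if removed_mask.all():
            excluded.append(s.run_id)
            continue
        labels = s.labels.copy()
        if removed_mask.any():
            if series_by_run is not None and s.run_id in series_by_run:
                # exact: nearest retained centroid of the actual window vector
                X = series_by_run[s.run_id].edge_vectors[removed_mask]
                D = _point_costs(X, retained_centroids, model.distance_metric)
                labels[removed_mask] = np.array(retained)[D.argmin(axis=1)]
            else:
                # fallback without window vectors: nearest retained centroid
                # to the removed centroid (exact when windows sit at it)
                for sid in to_remove:
                    d = cdist(
                        model.centroids[sid - 1][None, :],
                        retained_centroids,
                        model.distance_metric,
                    )
                    labels[labels == sid] = retained[int(d.argmin())]
        new_sequences.append(
            StateSequence(s.run_id, s.condition, labels, s.window_center_trs, s.stages)
        )
    return pruned_model, new_sequences, excluded


def reassign_windows(
    model: BrainStateModel,
    sequences: list[StateSequence],
    series_by_run: dict[str, WindowedConnectivitySeries],
) -> list[StateSequence]:
    """Re-derive every sequence label as the nearest *retained* centroid of the
    actual window vectors (exact reassignment after pruning)."""
    retained_centroids = model.retained_centroids()
    out = []
    for s in sequences:
        X = series_by_run[s.run_id].edge_vectors
        D = _point_costs(X, retained_centroids, model.distance_metric)
        labels = np.array([model.retained_ids[j] for j in D.argmin(axis=1)])
        out.append(
            StateSequence(s.run_id, s.condition, labels, s.window_center_trs, s.stages)
        )
    return out
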