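"""Stage-resolved trajectory analyses.

Three layers:

* dominant-state trajectory table — per meditation run and jhana stage
  (J1..J5, merged J6-8; access concentration and afterglow excluded), the
  modal brain state over that stage's windows, ties broken by earliest
  first occurrence within the stage;
* k-modes clustering of the categorical trajectories (simple-matching
  dissimilarity, seeded Huang-style initialization, best-of-replicates,
  elbow on the mismatch-cost curve);
* mixed-effects logistic models of state presence across stages (stage
  ordinal 1-6 or form/formless contrast as the fixed effect, run as the
  random intercept), with BH-FDR across the retained states.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .core import FORM_STAGES, JHANA_STAGES, StateSequence
from .glmm import MixedLogitResult, SeparationError, fit_mixed_logit


# ---------------------------------------------------------------------------
# dominant-state trajectories


def dominant_state_table(
    sequences: list[StateSequence], stages: tuple[str, ...] = JHANA_STAGES
) -> pd.DataFrame:
    """Most prevalent state per (run, stage); NaN for stages with no windows.

    Ties are broken by the state occurring earliest within the stage (logged
    via a UserWarning listing the tied cells).
    """
    rows = {}
    ties = []
    for seq in sequences:
        stage_arr = np.array([s if s is not None else "" for s in seq.stages])
        row = {}
        for stage in stages:
            labels = seq.labels[stage_arr == stage]
            if len(labels) == 0:
                row[stage] = np.nan
                continue
            states, counts = np.unique(labels, return_counts=True)
            winners = states[counts == counts.max()]
            if len(winners) > 1:
                # earliest first occurrence within the stage wins
                first = {int(s): int(np.argmax(labels == s)) for s in winners}
                winner = min(first, key=first.get)
                ties.append((seq.run_id, stage, sorted(int(s) for s in winners)))
            else:
                winner = int(winners[0])
            row[stage] = winner
        rows[seq.run_id] = row
    if ties:
        warnings.warn(
            f"dominant-state ties broken by first occurrence: {ties[:5]}",
            stacklevel=2,
        )
    table = pd.DataFrame.from_dict(rows, orient="index", columns=list(stages))
    table.index.name = "run_id"
    return table


# ---------------------------------------------------------------------------
# k-modes clustering of categorical trajectories


@dataclass
class KModesResult:
    labels: np.ndarray
    modes: np.ndarray           # k × n_stages modal trajectories
    cost: float                 # total simple-matching mismatches
    k: int
    cost_curve: pd.DataFrame | None = field(default=None)


def _matching_dissimilarity(rows: np.ndarray, modes: np.ndarray) -> np.ndarray:
    return (rows[:, None, :] != modes[None, :, :]).sum(axis=2)


def _kmodes_once(X: np.ndarray, k: int, rng: np.random.Generator, max_iter: int = 50):
    # Huang-style init: seed modes with distinct observed rows
    unique_rows = np.unique(X, axis=0)
    pick = rng.choice(len(unique_rows), size=min(k, len(unique_rows)), replace=False)
    modes = unique_rows[pick]
    if len(modes) < k:  # fewer distinct rows than clusters: duplicate
        extra = X[rng.choice(len(X), size=k - len(modes))]
        modes = np.vstack([modes, extra])
    labels = np.full(len(X), -1)
    for _ in range(max_iter):
        D = _matching_dissimilarity(X, modes)
        new_labels = D.argmin(axis=1)
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for j in range(k):
            members = X[labels == j]
            if len(members) == 0:
                modes[j] = X[rng.integers(len(X))]
                continue
            for col in range(X.shape[1]):
                vals, counts = np.unique(members[:, col], return_counts=True)
                modes[j, col] = vals[counts.argmax()]
    D = _matching_dissimilarity(X, modes)
    labels = D.argmin(axis=1)
    cost = float(D[np.arange(len(X)), labels].sum())
    return labels, modes, cost


def kmodes_fit(X: np.ndarray, k: int, seed: int = 0, n_replicates: int = 10) -> KModesResult:
    """Best-of-replicates k-modes on integer category rows."""
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_replicates):
        labels, modes, cost = _kmodes_once(X, k, rng)
        if best is None or cost < best[2]:
            best = (labels, modes, cost)
    return KModesResult(labels=best[0], modes=best[1], cost=best[2], k=k)


def kmodes_cluster(
    table: pd.DataFrame,
    k_range: tuple[int, int] = (2, 5),
    seed: int = 0,
    n_replicates: int = 10,
    flat_threshold: float = 0.1,
) -> KModesResult:
    """Elbow-selected k-modes clustering of the dominant-state table.

    Rows with missing cells are dropped.  If every complete row is identical
    the result degenerates to a single cluster with a warning.
    """
    from .clustering import elbow_point  # local import to avoid cycle at import time

    complete = table.dropna()
    X = complete.to_numpy(dtype=int)
    if len(np.unique(X, axis=0)) == 1:
        warnings.warn("all trajectories identical; degenerate single cluster", stacklevel=2)
        return KModesResult(
            labels=np.zeros(len(X), dtype=int), modes=X[:1].copy(), cost=0.0, k=1
        )
    k_min, k_max = k_range
    if len(X) < k_max:
        raise ValueError(f"need at least k_max={k_max} complete rows, have {len(X)}")
    ks = np.arange(k_min, k_max + 1)
    fits = {int(k): kmodes_fit(X, int(k), seed=seed + int(k), n_replicates=n_replicates) for k in ks}
    costs = np.array([fits[int(k)].cost for k in ks], dtype=float)
    if costs[0] <= 0:
        k_opt, dist = int(ks[0]), np.zeros_like(costs)
    else:
        k_opt, dist, _flat = elbow_point(ks, costs, flat_threshold)
    result = fits[k_opt]
    result.cost_curve = pd.DataFrame({"k": ks, "cost": costs, "drop_ratio": dist})
    return result


# ---------------------------------------------------------------------------
# state presence and mixed logistic models


def state_presence(
    sequences: list[StateSequence],
    retained_ids: list[int],
    stages: tuple[str, ...] = JHANA_STAGES,
) -> pd.DataFrame:
    """Long presence table: one row per (run, stage, state) with a 0/1
    ``present`` indicator (state occupies >= 1 window in that run-stage),
    the stage ordinal 1..6, and the form/formless flag."""
    rows = []
    for seq in sequences:
        stage_arr = np.array([s if s is not None else "" for s in seq.stages])
        for ordinal, stage in enumerate(stages, start=1):
            labels = seq.labels[stage_arr == stage]
            for state in retained_ids:
                rows.append(
                    {
                        "run_id": seq.run_id,
                        "stage": stage,
                        "stage_ordinal": ordinal,
                        "state_id": state,
                        "present": int(bool(len(labels)) and bool((labels == state).any())),
                        "form_flag": "form" if stage in FORM_STAGES else "formless",
                    }
                )
    return pd.DataFrame(rows)


def trajectory_glmm(
    presence: pd.DataFrame, state_id: int, predictor: str = "stage"
) -> MixedLogitResult:
    """Mixed logistic model of one state's presence across stages.

    ``predictor='stage'`` uses the ordinal 1..6 (merged J6-8 coded 6);
    ``predictor='form'`` codes formless = 1 vs. form = 0.  Run is the random
    intercept.  Raises :class:`SeparationError` on degenerate outcomes.
    """
    sub = presence[presence["state_id"] == state_id]
    if sub["run_id"].nunique() < 10:
        raise ValueError("need at least 10 runs")
    if predictor == "stage":
        x = sub["stage_ordinal"].to_numpy(dtype=float)
    elif predictor == "form":
        x = (sub["form_flag"] == "formless").to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown predictor {predictor!r}")
    return fit_mixed_logit(x, sub["present"].to_numpy(dtype=float), sub["run_id"].to_numpy())


def trajectory_glmm_table(
    presence: pd.DataFrame, retained_ids: list[int], predictor: str = "stage"
) -> pd.DataFrame:
    """Fit one model per retained state; BH-FDR across states.  Separated or
    failed fits carry an error code instead of estimates."""
    rows = []
    for state in retained_ids:
        row = {"state_id": state, "predictor": predictor, "error": ""}
        try:
            res = trajectory_glmm(presence, state, predictor)
            row.update(res.summary_row())
        except SeparationError as exc:
            row.update({"B": np.nan, "SE": np.nan, "p_raw": np.nan, "converged": False,
                        "error": f"separation: {exc}"})
        rows.append(row)
    table = pd.DataFrame(rows)
    ok = table["p_raw"].notna()
    adj = np.full(len(table), np.nan)
    if ok.any():
        adj[ok.to_numpy()] = multipletests(table.loc[ok, "p_raw"], method="fdr_bh")[1]
    table["p_fdr"] = adj
    return table
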