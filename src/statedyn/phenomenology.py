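"""Coupling self-report ratings to brain-state dynamics.

Three correlation levels, mirroring how intensive-sampling meditation
studies relate experience reports to state dynamics:

* global — run-mean ratings (stability, width, intensity) vs. run-level
  state proportions;
* local — per-stage ratings vs. per-(run, stage) state occupancy and dwell;
* form — per-run form/formless ratings (sensations, narrative) vs.
  category-restricted state dwell.

All cells are Pearson r with two-sided p and no multiplicity correction
(the states' proportions are not independent — a decrease in one is an
increase in the others); an optional BH flag is available for reuse beyond
replication-style reporting.  Canonical correlation analysis (CCA) gives
the multivariate association between global ratings and state proportions,
with Hotelling's trace and its F approximation for joint significance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import FORM_STAGES, FORMLESS_STAGES, JHANA_STAGES, StateSequence
from .dynamics import episodes_and_dwell, occupancy
from .synthetic import PhenoRatings

GLOBAL_ITEMS = ("stability", "width", "intensity")
LOCAL_ITEMS = ("stability", "intensity", "width", "bliss", "joy", "equanimity")
FORM_ITEMS = ("sensations", "narrative")


def _pearson(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)


def stage_restricted_measures(
    sequences: list[StateSequence], retained_ids: list[int]
) -> pd.DataFrame:
    """Per-(run, stage) occupancy and dwell of each retained state."""
    rows = []
    for seq in sequences:
        stage_arr = np.array([s if s is not None else "" for s in seq.stages])
        for stage in JHANA_STAGES:
            labels = seq.labels[stage_arr == stage]
            if len(labels) == 0:
                continue
            occ = occupancy(labels, retained_ids)
            epd = episodes_and_dwell(labels, retained_ids)
            row = {"run_id": seq.run_id, "stage": stage}
            for s in retained_ids:
                row[f"state{s}_occupancy"] = occ[s]
                row[f"state{s}_dwell"] = epd[s][1]
            rows.append(row)
    return pd.DataFrame(rows)


def category_restricted_dwell(
    sequences: list[StateSequence], retained_ids: list[int]
) -> pd.DataFrame:
    """Per-(run, form/formless category) mean dwell and occupancy per state."""
    rows = []
    for seq in sequences:
        stage_arr = np.array([s if s is not None else "" for s in seq.stages])
        for category, members in (("form", FORM_STAGES), ("formless", FORMLESS_STAGES)):
            labels = seq.labels[np.isin(stage_arr, members)]
            if len(labels) == 0:
                continue
            occ = occupancy(labels, retained_ids)
            epd = episodes_and_dwell(labels, retained_ids)
            row = {"run_id": seq.run_id, "category": category}
            for s in retained_ids:
                row[f"state{s}_dwell"] = epd[s][1]
                row[f"state{s}_occupancy"] = occ[s]
            rows.append(row)
    return pd.DataFrame(rows)


def _correlate_frames(
    left: pd.DataFrame,
    right: pd.DataFrame,
    keys: list[str],
    items: tuple[str, ...],
    measures: list[str],
    level: str,
) -> pd.DataFrame:
    merged = left.merge(right, on=keys, how="inner")
    rows = []
    for item in items:
        for measure in measures:
            pair = merged[[item, measure]].dropna()
            n = len(pair)
            row = {"level": level, "item": item, "measure": measure, "n": n, "df": n - 2}
            if n < 4:
                row.update({"r": np.nan, "p": np.nan, "flag": "insufficient-n"})
            elif pair[item].std() == 0 or pair[measure].std() == 0:
                row.update({"r": np.nan, "p": np.nan, "flag": "zero-variance"})
            else:
                r, p = _pearson(pair[item].to_numpy(), pair[measure].to_numpy())
                row.update({"r": r, "p": p, "flag": ""})
            rows.append(row)
    return pd.DataFrame(rows)


def rating_dynamics_correlations(
    ratings: PhenoRatings,
    sequences: list[StateSequence],
    retained_ids: list[int],
    level: str = "global",
    run_measures_table: pd.DataFrame | None = None,
    apply_fdr: bool = False,
) -> pd.DataFrame:
    """Pearson correlation report between ratings and dynamic measures.

    ``level`` is one of ``global`` (run-mean ratings vs. run proportions),
    ``local`` (per-stage ratings vs. per-stage occupancy/dwell), or ``form``
    (form/formless ratings vs. category-restricted dwell).  Raw p only by
    default; ``apply_fdr`` adds a BH-adjusted column.
    """
    med_sequences = [s for s in sequences if s.condition == "meditation"]
    if level == "global":
        if run_measures_table is None:
            from .dynamics import measures_table

            run_measures_table = measures_table(med_sequences, retained_ids)
        measures = [f"state{s}_proportion" for s in retained_ids]
        report = _correlate_frames(
            ratings.global_items, run_measures_table, ["run_id"],
            GLOBAL_ITEMS, measures, "global",
        )
    elif level == "local":
        stage_tab = stage_restricted_measures(med_sequences, retained_ids)
        measures = [f"state{s}_{m}" for s in retained_ids for m in ("occupancy", "dwell")]
        report = _correlate_frames(
            ratings.local_items, stage_tab, ["run_id", "stage"],
            LOCAL_ITEMS, measures, "local",
        )
    elif level == "form":
        cat_tab = category_restricted_dwell(med_sequences, retained_ids)
        measures = [f"state{s}_dwell" for s in retained_ids]
        report = _correlate_frames(
            ratings.form_items, cat_tab, ["run_id", "category"],
            FORM_ITEMS, measures, "form",
        )
    else:
        raise ValueError(f"unknown level {level!r}")
    if apply_fdr:
        ok = report["p"].notna()
        adj = np.full(len(report), np.nan)
        if ok.any():
            adj[ok.to_numpy()] = multipletests(report.loc[ok, "p"], method="fdr_bh")[1]
        report["p_fdr"] = adj
    return report


# ---------------------------------------------------------------------------
# canonical correlation analysis


@dataclass
class CcaResult:
    correlations: np.ndarray        # canonical correlations, descending, in [0, 1]
    x_loadings: np.ndarray          # corr of X columns with the first canonical variate
    y_loadings: np.ndarray
    hotelling_trace: float
    f_stat: float
    df1: float
    df2: float
    p_value: float

    @property
    def first_rc2(self) -> float:
        """Squared first canonical correlation (shared variance of factor 1)."""
        return float(self.correlations[0] ** 2)


def _orthonormal_basis(M: np.ndarray, name: str) -> np.ndarray:
    Mc = M - M.mean(axis=0)
    U, s, _ = np.linalg.svd(Mc, full_matrices=False)
    tol = max(Mc.shape) * np.finfo(float).eps * (s[0] if len(s) else 0.0)
    rank = int((s > tol).sum())
    if rank < M.shape[1]:
        warnings.warn(
            f"{name} side is rank-deficient ({rank} of {M.shape[1]}); "
            "redundant dimensions dropped",
            stacklevel=3,
        )
    return U[:, :rank]


def cca(ratings_matrix: np.ndarray, proportions_matrix: np.ndarray) -> CcaResult:
    """Canonical correlations via SVD of the whitened cross-covariance.

    Rows are runs (aligned across the two sides).  Returns the canonical
    correlations (non-increasing, clipped to [0, 1]), first-factor structure
    loadings for each side, and Hotelling's trace with its F-approximation
    p-value.
    """
    X = np.asarray(ratings_matrix, dtype=float)
    Y = np.asarray(proportions_matrix, dtype=float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("the two sides must have the same number of rows (runs)")
    n = X.shape[0]
    if n <= X.shape[1] + Y.shape[1]:
        warnings.warn(
            f"n={n} rows is small for p+q={X.shape[1] + Y.shape[1]} variables",
            stacklevel=2,
        )
    Ux = _orthonormal_basis(X, "ratings")
    Uy = _orthonormal_basis(Y, "proportions")
    P, svals, Qt = np.linalg.svd(Ux.T @ Uy)
    rho = np.clip(svals, 0.0, 1.0)

    vx = Ux @ P[:, 0]
    vy = Uy @ Qt.T[:, 0]

    def loadings(M, v):
        Mc = M - M.mean(axis=0)
        sd = Mc.std(axis=0)
        out = np.zeros(M.shape[1])
        ok = sd > 0
        vv = (v - v.mean())
        vs = vv.std()
        if vs > 0:
            out[ok] = (Mc[:, ok] * vv[:, None]).mean(axis=0) / (sd[ok] * vs)
        return out

    p_dim, q_dim = X.shape[1], Y.shape[1]
    s = min(p_dim, q_dim)
    rho2 = np.minimum(rho[:s] ** 2, 1.0 - 1e-12)
    trace = float(np.sum(rho2 / (1.0 - rho2)))
    m = (abs(p_dim - q_dim) - 1) / 2.0
    n_h = (n - p_dim - q_dim - 2) / 2.0
    df1 = s * (2 * m + s + 1)
    df2 = 2 * (s * n_h + 1)
    if df2 > 0 and trace >= 0:
        f_stat = 2 * (s * n_h + 1) * trace / (s * s * (2 * m + s + 1))
        p_value = float(stats.f.sf(f_stat, df1, df2))
    else:
        f_stat, p_value = float("nan"), float("nan")
    return CcaResult(
        correlations=rho,
        x_loadings=loadings(X, vx),
        y_loadings=loadings(Y, vy),
        hotelling_trace=trace,
        f_stat=float(f_stat),
        df1=float(df1),
        df2=float(df2),
        p_value=p_value,
    )
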