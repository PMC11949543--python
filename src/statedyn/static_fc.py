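"""Whole-run (static) functional connectivity and the edgewise contrast.

Per run: Pearson correlation between every node pair over the entire run,
Fisher-z transformed (correlations clamped at ±(1 - 1e-7) so duplicated
columns yield a finite z ≈ 8.4 rather than infinity).

Contrast: control-run matrices are averaged into one reference value per
edge; meditation-run values are tested against that reference with a
one-sample t test (two-sided, df = n_meditation - 1) and Bonferroni
correction over the N(N-1)/2 unique edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import RoiTimecourse, edge_pairs, fisher_z, n_edges, vectorize_upper


@dataclass
class ConnectivityMatrix:
    values: np.ndarray          # N×N symmetric Fisher-z matrix; diagonal non-informative
    run_id: str
    condition: str
    node_labels: list[str]

    def edge_vector(self) -> np.ndarray:
        return vectorize_upper(self.values)


def run_connectivity(tc: RoiTimecourse) -> ConnectivityMatrix:
    """Fisher-z whole-run correlation matrix for one run."""
    if tc.n_trs < 3:
        raise ValueError(f"run {tc.run_id}: need at least 3 TRs")
    sds = tc.values.std(axis=0)
    if (sds == 0).any():
        bad = tc.node_labels[int(np.flatnonzero(sds == 0)[0])]
        raise ValueError(f"run {tc.run_id}: zero-variance node {bad!r}")
    r = np.corrcoef(tc.values, rowvar=False)
    z = np.asarray(fisher_z(r))
    np.fill_diagonal(z, 0.0)  # non-informative; excluded from all statistics
    return ConnectivityMatrix(z, tc.run_id, tc.condition, list(tc.node_labels))


def edgewise_contrast(
    meditation_mats: list[ConnectivityMatrix],
    control_mats: list[ConnectivityMatrix],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-sample t per edge of meditation values vs. the averaged control
    reference, Bonferroni-corrected over all unique edges.

    Returns a table with one row per edge (i<j): node_i, node_j, mean
    meditation z, control reference z, t, df, p_raw, p_bonf, sign, and a
    ``zero_variance`` flag where the t statistic is undefined.
    """
    if len(meditation_mats) < 3:
        raise ValueError("need at least 3 meditation matrices")
    if len(control_mats) < 1:
        raise ValueError("need at least 1 control matrix")
    labels = meditation_mats[0].node_labels
    n_nodes = len(labels)
    med = np.array([m.edge_vector() for m in meditation_mats])   # runs × E
    ref = np.array([m.edge_vector() for m in control_mats]).mean(axis=0)

    n_run = med.shape[0]
    mean = med.mean(axis=0)
    sd = med.std(axis=0, ddof=1)
    zero_var = sd == 0
    t = np.full(med.shape[1], np.nan)
    np.divide(mean - ref, sd / np.sqrt(n_run), out=t, where=~zero_var)
    df = n_run - 1
    p_raw = np.where(zero_var, np.nan, 2.0 * stats.t.sf(np.abs(t), df))
    exact_null = zero_var & np.isclose(mean, ref)
    t[exact_null], p_raw[exact_null], zero_var[exact_null] = 0.0, 1.0, False

    m = n_edges(n_nodes)
    table = pd.DataFrame(
        {
            "node_i": [labels[i] for i, _ in edge_pairs(n_nodes)],
            "node_j": [labels[j] for _, j in edge_pairs(n_nodes)],
            "mean_meditation_z": mean,
            "control_reference_z": ref,
            "t": t,
            "df": df,
            "p_raw": p_raw,
            "p_bonf": np.minimum(1.0, p_raw * m),
            "sign": np.sign(mean - ref).astype(int),
            "zero_variance": zero_var,
            "significant": np.minimum(1.0, p_raw * m) < alpha,
        }
    )
    return table
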