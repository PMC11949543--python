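"""Dynamic measures of brain-state sequences and the meditation-vs-control
contrast.

Measures per run (window positions equated with TRs, valid because the
window step is 1):

* proportion — fraction of window positions spent in each state;
* episodes — number of maximal constant runs of each state;
* dwell time — mean episode length per state (undefined, not 0, for states
  with no episodes);
* switch proportion — fraction of successive positions at which the state
  changes (denominator = length - 1 by default; ``/length`` available);
* transition matrix — row-stochastic empirical step probabilities with
  self-transitions on the diagonal; rows with no outgoing steps are NaN.

The contrast averages control runs into a single reference per measure and
applies one-sample t tests over meditation runs with Benjamini-Hochberg FDR
across the measure family.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import StateSequence


def occupancy(seq: np.ndarray | StateSequence, retained_ids: list[int]) -> dict[int, float]:
    """Per-state fraction of window positions; absent states report 0."""
    labels = seq.labels if isinstance(seq, StateSequence) else np.asarray(seq)
    if len(labels) == 0:
        raise ValueError("empty sequence")
    unknown = set(np.unique(labels)) - set(retained_ids)
    if unknown:
        raise ValueError(f"labels outside retained_ids: {sorted(unknown)}")
    return {s: float(np.mean(labels == s)) for s in retained_ids}


def episodes_and_dwell(
    seq: np.ndarray | StateSequence, retained_ids: list[int] | None = None
) -> dict[int, tuple[int, float | None]]:
    """Per-state (episode count, mean dwell in window positions).

    An episode is a maximal constant run.  States with zero episodes report
    dwell ``None`` (missing, never 0).
    """
    labels = seq.labels if isinstance(seq, StateSequence) else np.asarray(seq)
    if len(labels) == 0:
        raise ValueError("empty sequence")
    if retained_ids is None:
        retained_ids = sorted(int(s) for s in np.unique(labels))
    boundaries = np.flatnonzero(np.diff(labels) != 0)
    starts = np.concatenate([[0], boundaries + 1])
    ends = np.concatenate([boundaries + 1, [len(labels)]])
    out: dict[int, tuple[int, float | None]] = {}
    for s in retained_ids:
        mask = labels[starts] == s
        if not mask.any():
            out[s] = (0, None)
        else:
            lengths = (ends - starts)[mask]
            out[s] = (int(mask.sum()), float(lengths.mean()))
    return out


def switch_proportion(
    seq: np.ndarray | StateSequence, denominator: str = "transitions"
) -> float:
    """Fraction of successive positions with a state change.

    ``denominator='transitions'`` divides by length - 1 (default);
    ``denominator='length'`` divides by the sequence length.
    """
    labels = seq.labels if isinstance(seq, StateSequence) else np.asarray(seq)
    if len(labels) < 2:
        raise ValueError("switch proportion undefined for length < 2")
    switches = int(np.sum(np.diff(labels) != 0))
    denom = len(labels) - 1 if denominator == "transitions" else len(labels)
    return switches / denom


def transition_matrix(
    seq: np.ndarray | StateSequence, retained_ids: list[int]
) -> np.ndarray:
    """Row-stochastic K×K empirical transition matrix (self-transitions
    included); rows with zero outgoing steps are NaN."""
    labels = seq.labels if isinstance(seq, StateSequence) else np.asarray(seq)
    if len(labels) < 2:
        raise ValueError("transition matrix undefined for length < 2")
    k = len(retained_ids)
    index = {s: i for i, s in enumerate(retained_ids)}
    counts = np.zeros((k, k))
    for a, b in zip(labels[:-1], labels[1:]):
        counts[index[int(a)], index[int(b)]] += 1
    out = np.full((k, k), np.nan)
    totals = counts.sum(axis=1)
    nz = totals > 0
    out[nz] = counts[nz] / totals[nz, None]
    return out


def run_measures(
    seq: StateSequence, retained_ids: list[int], switch_denominator: str = "transitions"
) -> dict[str, float | None]:
    """Flat measure dict for one run (proportion/episodes/dwell per state +
    switch proportion), suitable for tabulation."""
    occ = occupancy(seq, retained_ids)
    epd = episodes_and_dwell(seq, retained_ids)
    row: dict[str, float | None] = {}
    for s in retained_ids:
        row[f"state{s}_proportion"] = occ[s]
        row[f"state{s}_episodes"] = float(epd[s][0])
        row[f"state{s}_dwell"] = epd[s][1]
    row["switch_proportion"] = switch_proportion(seq, switch_denominator)
    return row


def measures_table(
    sequences: list[StateSequence],
    retained_ids: list[int],
    switch_denominator: str = "transitions",
) -> pd.DataFrame:
    rows = []
    for s in sequences:
        row = {"run_id": s.run_id, "condition": s.condition}
        row.update(run_measures(s, retained_ids, switch_denominator))
        rows.append(row)
    return pd.DataFrame(rows)


def contrast_dynamics(
    meditation_measures: pd.DataFrame, control_measures: pd.DataFrame
) -> pd.DataFrame:
    """Table-style contrast of dynamic measures: meditation runs vs. the
    averaged-control reference, one-sample t per measure, BH-FDR across the
    measure family.

    Input frames carry one row per run and one column per measure (non-measure
    columns ``run_id``/``condition`` are ignored).  Measures missing for a run
    (undefined dwell) are dropped pairwise and the effective n is reported.
    """
    measure_cols = [
        c for c in meditation_measures.columns if c not in ("run_id", "condition")
    ]
    if len(meditation_measures) < 3:
        raise ValueError("need at least 3 meditation runs")
    rows = []
    for col in measure_cols:
        med = meditation_measures[col].dropna().to_numpy(dtype=float)
        ref = float(control_measures[col].dropna().mean())
        n = len(med)
        mean = med.mean()
        sd = med.std(ddof=1) if n > 1 else 0.0
        if sd == 0:
            t, p = (0.0, 1.0) if np.isclose(mean, ref) else (np.nan, np.nan)
            flag = not np.isclose(mean, ref)
        else:
            t = (mean - ref) / (sd / np.sqrt(n))
            p = float(2.0 * stats.t.sf(abs(t), n - 1))
            flag = False
        rows.append(
            {
                "measure": col,
                "meditation_mean": mean,
                "control_mean": ref,
                "difference": mean - ref,
                "t": t,
                "df": n - 1,
                "n": n,
                "p_raw": p,
                "zero_variance": flag,
            }
        )
    table = pd.DataFrame(rows)
    ok = table["p_raw"].notna()
    adj = np.full(len(table), np.nan)
    if ok.any():
        adj[ok.to_numpy()] = multipletests(table.loc[ok, "p_raw"], method="fdr_bh")[1]
    table["p_fdr"] = adj
    return table
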