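"""Tapered sliding-window connectivity.

The taper is the dynamic-connectivity convention: a rectangle of the window
length convolved with a Gaussian (default scale 3 TRs), truncated to the
window and peak-normalized.  With the default 16-TR window at TR = 2.9 s a
window spans 46.4 s.  Per window, a weighted Pearson correlation (weights =
taper) is computed for every node pair, Fisher-z transformed, and the strict
upper triangle is vectorized in the canonical edge order.  Windows advance
by ``step`` TRs (default 1) and never span runs; each window is indexed by
its center TR (start + length // 2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import RoiTimecourse, WindowedConnectivitySeries, fisher_z


@dataclass
class TaperedWindow:
    length_trs: int
    sigma_trs: float
    weights: np.ndarray     # max-normalized, symmetric, strictly positive


def make_taper(length_trs: int = 16, sigma_trs: float = 3.0) -> TaperedWindow:
    """Rectangle-of-window-length ⊛ Gaussian(sigma), truncated, peak-normalized."""
    if length_trs < 4:
        raise ValueError("window length must be >= 4 TRs")
    if sigma_trs <= 0:
        raise ValueError("sigma must be positive")
    center = (length_trs - 1) / 2.0
    x = np.arange(length_trs) - center
    half = length_trs / 2.0
    w = stats.norm.cdf((x + half) / sigma_trs) - stats.norm.cdf((x - half) / sigma_trs)
    w = w / w.max()
    return TaperedWindow(length_trs, sigma_trs, w)


def _weighted_corr(window: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, bool]:
    """Weighted Pearson correlation matrix; flags zero weighted variance."""
    wn = w / w.sum()
    mu = wn @ window
    xc = window - mu
    cov = (xc * wn[:, None]).T @ xc
    var = np.diag(cov).copy()
    degenerate = bool((var <= 0).any())
    var[var <= 0] = 1.0  # affected edges forced to r = 0 below
    denom = np.sqrt(np.outer(var, var))
    r = cov / denom
    if degenerate:
        bad = np.flatnonzero(np.diag(cov) <= 0)
        r[bad, :] = 0.0
        r[:, bad] = 0.0
    return r, degenerate


def windowed_connectivity(
    tc: RoiTimecourse, taper: TaperedWindow | None = None, step: int = 1,
    fisher: bool = True,
) -> WindowedConnectivitySeries:
    """Sliding tapered-window connectivity series for one run (W×E matrix)."""
    taper = taper or make_taper()
    L = taper.length_trs
    if tc.n_trs < L:
        raise ValueError(f"run {tc.run_id}: {tc.n_trs} TRs < window length {L}")
    starts = np.arange(0, tc.n_trs - L + 1, step)
    n = tc.n_nodes
    iu = np.triu_indices(n, k=1)
    vectors = np.empty((len(starts), len(iu[0])))
    degenerate = []
    for w_idx, t0 in enumerate(starts):
        r, bad = _weighted_corr(tc.values[t0 : t0 + L], taper.weights)
        if bad:
            degenerate.append(w_idx)
        edge = r[iu]
        vectors[w_idx] = fisher_z(edge) if fisher else edge
    centers = starts + L // 2
    return WindowedConnectivitySeries(
        run_id=tc.run_id,
        condition=tc.condition,
        edge_vectors=vectors,
        window_center_trs=centers,
        node_labels=list(tc.node_labels),
        degenerate_windows=degenerate,
    )


def window_stages(tc: RoiTimecourse, centers: np.ndarray) -> list[str | None]:
    """Stage label per window, assigned by the window's center TR."""
    return [tc.stage_at(int(c)) for c in centers]


def window_truth_labels(
    latent_labels: np.ndarray, centers: np.ndarray, taper: TaperedWindow
) -> np.ndarray:
    """Ground-truth state per window: taper-weighted modal latent label.

    The window's label is the latent state carrying the most taper weight
    inside the window span — the state that dominates the signal the window
    actually measures.
    """
    L = taper.length_trs
    out = np.empty(len(centers), dtype=int)
    for i, c in enumerate(centers):
        start = int(c) - L // 2
        seg = latent_labels[start : start + L]
        w = taper.weights[: len(seg)]
        states = np.unique(seg)
        mass = [w[seg == s].sum() for s in states]
        out[i] = states[int(np.argmax(mass))]
    return out
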