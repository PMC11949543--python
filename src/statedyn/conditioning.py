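"""Per-run denoising operators: nuisance regression, band-pass, despiking.

These mirror a standard BOLD denoising chain applied to already-extracted
node timecourses: (1) linear regression of nuisance regressors (e.g., tissue
components, motion parameters, linear trend) with an intercept always
included; (2) a separate zero-phase Butterworth band-pass (default
0.01-0.1 Hz); (3) soft despiking via a scaled tanh that is essentially
linear within ``clip_sd`` standard deviations of the mean and bounded
beyond.  All three are optional and identity-safe for clean synthetic data.
"""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np
from scipy import signal

from .core import RoiTimecourse


def regress_nuisance(tc: RoiTimecourse, nuisance: np.ndarray) -> RoiTimecourse:
    """OLS-remove nuisance columns (plus intercept) from every node timecourse.

    Residuals are orthogonal to every regressor column.  A rank-deficient
    design (after adding the intercept) is rejected, naming dependent columns.
    """
    nuisance = np.atleast_2d(np.asarray(nuisance, dtype=float))
    if nuisance.shape[0] != tc.n_trs:
        raise ValueError(
            f"nuisance rows ({nuisance.shape[0]}) != timecourse TRs ({tc.n_trs})"
        )
    design = np.column_stack([np.ones(tc.n_trs), nuisance])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify columns not adding rank, for the error message
        dependent = []
        running = design[:, :1]
        for j in range(1, design.shape[1]):
            trial = np.column_stack([running, design[:, j]])
            if np.linalg.matrix_rank(trial) == running.shape[1]:
                dependent.append(j - 1)
            else:
                running = trial
        raise ValueError(f"rank-deficient nuisance design; dependent columns {dependent}")
    beta, *_ = np.linalg.lstsq(design, tc.values, rcond=None)
    residual = tc.values - design @ beta
    return replace(tc, values=residual)


def bandpass(
    tc: RoiTimecourse, low_hz: float = 0.01, high_hz: float = 0.1, order: int = 4
) -> RoiTimecourse:
    """Zero-phase (forward-backward) Butterworth band-pass per node."""
    fs = 1.0 / tc.tr_seconds
    nyquist = fs / 2.0
    if not (0 < low_hz < high_hz < nyquist):
        raise ValueError(
            f"band ({low_hz}, {high_hz}) Hz invalid for Nyquist {nyquist:.4f} Hz"
        )
    min_len = 3 * (2 * order + 1)
    if tc.n_trs < min_len:
        raise ValueError(
            f"run of {tc.n_trs} TRs too short for order-{order} band-pass; "
            f"need at least {min_len} TRs"
        )
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")
    filtered = signal.sosfiltfilt(sos, tc.values, axis=0)
    return replace(tc, values=np.ascontiguousarray(filtered))


def despike(tc: RoiTimecourse, clip_sd: float = 3.0) -> RoiTimecourse:
    """Soft-clip each column with y' = mu + c*sigma*tanh((y-mu)/(c*sigma)).

    Essentially linear within ``clip_sd`` SDs of the column mean, bounded in
    ``(mu - c*sigma, mu + c*sigma)`` outside, and strictly monotone.
    Zero-variance columns pass through unchanged with a warning.
    """
    if clip_sd <= 0:
        raise ValueError("clip_sd must be positive")
    values = tc.values.copy()
    mu = values.mean(axis=0)
    sd = values.std(axis=0)
    flat = sd == 0
    if flat.any():
        labels = [tc.node_labels[i] for i in np.flatnonzero(flat)[:5]]
        warnings.warn(f"zero-variance columns passed through unchanged: {labels}", stacklevel=2)
    ok = ~flat
    scale = clip_sd * sd[ok]
    values[:, ok] = mu[ok] + scale * np.tanh((values[:, ok] - mu[ok]) / scale)
    return replace(tc, values=values)


def condition_run(
    tc: RoiTimecourse,
    nuisance: np.ndarray | None = None,
    low_hz: float = 0.01,
    high_hz: float = 0.1,
    clip_sd: float = 3.0,
) -> RoiTimecourse:
    """Full chain in the canonical order: regress -> band-pass -> despike."""
    if nuisance is not None:
        tc = regress_nuisance(tc, nuisance)
    tc = bandpass(tc, low_hz, high_hz)
    return despike(tc, clip_sd)
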