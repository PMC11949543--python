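"""Core data containers shared across the pipeline.

Conventions used throughout:

* TR indices are 0-based; stage segments are half-open ``[start, end)``.
* Connectivity edges are the strict upper triangle ``(i < j)`` of the node-by-node
  matrix, vectorized in row-major order.  :func:`edge_pairs` is the single source
  of truth for that ordering.
* Edge values are Fisher-z transformed correlations; correlations are clamped to
  ``±(1 - CLAMP_EPS)`` before ``atanh`` so degenerate inputs stay finite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: correlation clamp applied before the Fisher z transform
CLAMP_EPS = 1e-7

MEDITATION = "meditation"
CONTROL_CONDITIONS = ("control-memory", "control-count")

#: canonical stage labels of a meditation run, in temporal order
MEDITATION_STAGES = ("AC", "J1", "J2", "J3", "J4", "J5", "J6-8", "afterglow")
#: stages entering trajectory analyses (access concentration and afterglow excluded)
JHANA_STAGES = ("J1", "J2", "J3", "J4", "J5", "J6-8")
FORM_STAGES = ("J1", "J2", "J3", "J4")
FORMLESS_STAGES = ("J5", "J6-8")


class ValidationError(ValueError):
    """Raised when an input artifact violates the format contracts."""


def edge_pairs(n_nodes: int) -> list[tuple[int, int]]:
    """Upper-triangle node index pairs in the canonical (row-major, i<j) order."""
    return [(i, j) for i in range(n_nodes) for j in range(i + 1, n_nodes)]


def n_edges(n_nodes: int) -> int:
    return n_nodes * (n_nodes - 1) // 2


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """Variance-stabilizing atanh transform with clamping at ±(1 - 1e-7)."""
    return np.arctanh(np.clip(r, -1.0 + CLAMP_EPS, 1.0 - CLAMP_EPS))


def vectorize_upper(mat: np.ndarray) -> np.ndarray:
    """Strict upper triangle of a square matrix in canonical edge order."""
    n = mat.shape[0]
    iu = np.triu_indices(n, k=1)
    return np.asarray(mat)[iu]


def matrix_from_upper(vec: np.ndarray, n_nodes: int, diag: float = 0.0) -> np.ndarray:
    """Inverse of :func:`vectorize_upper`; fills a symmetric matrix."""
    mat = np.full((n_nodes, n_nodes), float(diag))
    iu = np.triu_indices(n_nodes, k=1)
    mat[iu] = vec
    mat[(iu[1], iu[0])] = vec
    return mat


@dataclass
class RoiTimecourse:
    """One run's node-by-time BOLD signal with acquisition metadata.

    ``values`` is a T×N float matrix (TRs as rows, nodes as columns).
    ``stage_segments`` is an ordered list of ``(stage_label, start_tr, end_tr)``
    with half-open TR ranges that tile ``[0, T)`` without overlap.
    """

    values: np.ndarray
    node_labels: list[str]
    tr_seconds: float
    condition: str
    run_id: str
    stage_segments: list[tuple[str, int, int]] = field(default_factory=list)

    @property
    def n_trs(self) -> int:
        return self.values.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.values.shape[1]

    def validate(self) -> "RoiTimecourse":
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2:
            raise ValidationError(f"run {self.run_id}: values must be 2-D (T×N)")
        if not np.isfinite(vals).all():
            bad = np.argwhere(~np.isfinite(vals))[0]
            raise ValidationError(
                f"run {self.run_id}: non-finite value at TR {bad[0]}, column "
                f"{self.node_labels[bad[1]]!r}"
            )
        if len(self.node_labels) != vals.shape[1]:
            raise ValidationError(
                f"run {self.run_id}: {len(self.node_labels)} labels for "
                f"{vals.shape[1]} columns"
            )
        if len(set(self.node_labels)) != len(self.node_labels):
            raise ValidationError(f"run {self.run_id}: duplicate node labels")
        prev_end = None
        for label, start, end in self.stage_segments:
            if not (0 <= start < end <= self.n_trs):
                raise ValidationError(
                    f"run {self.run_id}: segment {label!r} [{start}, {end}) outside "
                    f"[0, {self.n_trs})"
                )
            if prev_end is not None and start < prev_end:
                raise ValidationError(
                    f"run {self.run_id}: segment {label!r} overlaps previous segment"
                )
            prev_end = end
        return self

    def stage_at(self, tr: int) -> str | None:
        """Stage label covering a TR index, or None outside all segments."""
        for label, start, end in self.stage_segments:
            if start <= tr < end:
                return label
        return None


@dataclass
class WindowedConnectivitySeries:
    """Per-run sliding-window connectivity: W windows × E Fisher-z edges."""

    run_id: str
    condition: str
    edge_vectors: np.ndarray
    window_center_trs: np.ndarray
    node_labels: list[str]
    degenerate_windows: list[int] = field(default_factory=list)

    @property
    def n_windows(self) -> int:
        return self.edge_vectors.shape[0]

    def edge_labels(self) -> list[str]:
        return [
            f"{self.node_labels[i]}--{self.node_labels[j]}"
            for i, j in edge_pairs(len(self.node_labels))
        ]


@dataclass
class StateSequence:
    """Assigned brain-state label per window position for one run."""

    run_id: str
    condition: str
    labels: np.ndarray
    window_center_trs: np.ndarray
    stages: list[str | None]

    def __len__(self) -> int:
        return len(self.labels)
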