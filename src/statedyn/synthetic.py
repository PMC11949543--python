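"""Synthetic multi-run study generator with planted brain states.

The generator emulates an intensive single-subject fMRI meditation study:
49-node BOLD timecourses at TR = 2.9 s, 27 meditation runs of 176 TRs
(~512 s) traversing ordered stages (access concentration AC, jhana stages
J1..J5, merged J6-8, afterglow), plus control runs, with

* latent brain states: each stage-conditioned, sticky first-order Markov
  chain over K connectivity templates (symmetric PD correlation matrices);
* observations: zero-mean multivariate normal draws from the active
  template's covariance plus isotropic observation noise;
* self-report ratings statistically coupled to the latent state dynamics
  (width of attention decreases with state-2 occupancy; physical-sensation
  ratings increase with state-2 dwell time during the formless stages).

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import (
    CONTROL_CONDITIONS,
    FORMLESS_STAGES,
    MEDITATION,
    MEDITATION_STAGES,
    RoiTimecourse,
)

CONTROL_STAGE = "control"


class InfeasibleCorrelationPattern(ValueError):
    """Requested block pattern is not close to any PD correlation matrix."""


@dataclass
class StateTemplate:
    """One latent brain state: a unit-diagonal PD correlation matrix."""

    state_id: int
    covariance: np.ndarray
    description: str

    def validate(self) -> "StateTemplate":
        cov = np.asarray(self.covariance, dtype=float)
        if not np.allclose(cov, cov.T, atol=1e-10):
            raise ValueError(f"template {self.description!r}: covariance not symmetric")
        if not np.allclose(np.diag(cov), 1.0, atol=1e-8):
            raise ValueError(f"template {self.description!r}: diagonal not unit")
        if np.linalg.eigvalsh(cov).min() <= 0:
            raise ValueError(f"template {self.description!r}: not positive definite")
        return self


@dataclass
class RatingCoupling:
    """Coefficients linking self-report ratings to latent state dynamics.

    width = width_intercept - width_slope * (run occupancy of state 2) + noise
    physical sensations (formless) = sens_intercept + sens_slope * (state-2
    mean dwell in formless TRs) + noise.  All ratings are clipped to [1, 10].
    """

    width_intercept: float = 8.0
    width_slope: float = 6.0
    sens_intercept: float = 2.0
    sens_slope: float = 0.15
    noise_sd: float = 0.75


@dataclass
class RunGroundTruth:
    """Latent truth for one simulated run."""

    run_id: str
    labels: np.ndarray                      # per-TR latent state id (1-based)
    occupancy: dict[int, float]             # per-state fraction of TRs
    rating_expectations: dict[str, float] = field(default_factory=dict)


def default_stage_plan(run_length_trs: int = 176) -> list[tuple[str, int]]:
    """Equal-length stage segments tiling the run (8 stages; 176 -> 22 TRs each)."""
    n = len(MEDITATION_STAGES)
    base, extra = divmod(run_length_trs, n)
    return [(s, base + (1 if i < extra else 0)) for i, s in enumerate(MEDITATION_STAGES)]


def default_occupancy_schedule(k_states: int = 3) -> dict[str, np.ndarray]:
    """Stage-conditioned target state weights.

    State 1 rises and state 2 falls across the jhana stages, emulating the
    reported monotone prevalence trajectories; state 3 absorbs the rest.
    The control stage is dominated by the sparse state 3.
    """
    if k_states != 3:
        raise ValueError("default occupancy schedule is defined for 3 states")
    sched: dict[str, np.ndarray] = {
        "AC": np.array([0.15, 0.45, 0.40]),
        "afterglow": np.array([0.15, 0.15, 0.70]),
        CONTROL_STAGE: np.array([0.05, 0.05, 0.90]),
    }
    for t, stage in enumerate(("J1", "J2", "J3", "J4", "J5", "J6-8"), start=1):
        s1 = 0.07 + 0.13 * t
        s2 = 0.62 - 0.098 * t
        sched[stage] = np.array([s1, s2, 1.0 - s1 - s2])
    return sched


def default_structure_spec(n_nodes: int = 49) -> list[dict]:
    """Block-correlation recipes for the three canonical brain states.

    1. DMN-anticorrelated: a coherent sub-network anticorrelated with an
       otherwise well-connected cortex.
    2. Hyperconnected: uniformly elevated correlations.
    3. Sparsely connected: weak background with one small weak block.
    """
    dmn = list(range(min(10, n_nodes // 4)))
    sparse_block = list(range(n_nodes - max(4, n_nodes // 8), n_nodes))
    return [
        {
            "description": "dmn-anticorrelated",
            "baseline_r": 0.5,
            "blocks": [{"nodes": dmn, "within_r": 0.5, "to_rest_r": -0.35}],
        },
        {
            "description": "hyperconnected",
            "baseline_r": 0.6,
            "blocks": [],
        },
        {
            "description": "sparse",
            "baseline_r": 0.1,
            "blocks": [{"nodes": sparse_block, "within_r": 0.25, "to_rest_r": None}],
        },
    ]


@dataclass
class SynthStudyParams:
    """Full configuration of a synthetic study; defaults mirror the study design."""

    n_nodes: int = 49
    tr_seconds: float = 2.9
    n_meditation_runs: int = 27
    n_control_runs: int = 4
    run_length_trs: int = 176
    control_length_trs: int = 166
    stage_plan: list[tuple[str, int]] | None = None
    occupancy_schedule: dict[str, np.ndarray] | None = None
    transition_stickiness: float = 0.98
    noise_sd: float = 0.2
    rating_coupling: RatingCoupling = field(default_factory=RatingCoupling)
    structure_spec: list[dict] | None = None
    separation_floor: float = 1.0
    seed: int = 0

    def resolved(self) -> "SynthStudyParams":
        p = replace(self)
        if p.stage_plan is None:
            p.stage_plan = default_stage_plan(p.run_length_trs)
        if p.structure_spec is None:
            p.structure_spec = default_structure_spec(p.n_nodes)
        if p.occupancy_schedule is None:
            p.occupancy_schedule = default_occupancy_schedule(len(p.structure_spec))
        p.validate()
        return p

    def validate(self) -> None:
        if not (0.0 <= self.transition_stickiness < 1.0):
            raise ValueError("transition_stickiness must be in [0, 1)")
        if sum(n for _, n in self.stage_plan) != self.run_length_trs:
            raise ValueError("stage_plan segment lengths must sum to run_length_trs")
        k = len(self.structure_spec)
        for stage, w in self.occupancy_schedule.items():
            w = np.asarray(w, dtype=float)
            if len(w) != k:
                raise ValueError(f"stage {stage!r}: {len(w)} weights for {k} states")
            if (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
                raise ValueError(f"stage {stage!r}: weights must be >=0 and sum to 1")


@dataclass
class PhenoRatings:
    """Per-run self-report ratings on the 1-10 scale, keyed by run_id."""

    global_items: pd.DataFrame     # run_id, stability, width, intensity
    local_items: pd.DataFrame      # run_id, stage, stability, intensity, width, bliss, joy, equanimity
    form_items: pd.DataFrame       # run_id, category (form|formless), sensations, narrative

    def validate(self) -> "PhenoRatings":
        for name, df in (
            ("global", self.global_items),
            ("local", self.local_items),
            ("form", self.form_items),
        ):
            vals = df.select_dtypes("number").to_numpy(dtype=float)
            if vals.size and ((vals < 1.0 - 1e-9) | (vals > 10.0 + 1e-9)).any():
                raise ValueError(f"{name} ratings outside the 1-10 scale")
        return self


@dataclass
class StudyDataset:
    """A complete simulated study: runs, latent truth, and coupled ratings."""

    runs: list[RoiTimecourse]
    truths: dict[str, RunGroundTruth]
    ratings: PhenoRatings
    templates: list[StateTemplate]
    params: SynthStudyParams

    def meditation_runs(self) -> list[RoiTimecourse]:
        return [r for r in self.runs if r.condition == MEDITATION]

    def control_runs(self) -> list[RoiTimecourse]:
        return [r for r in self.runs if r.condition != MEDITATION]


# ---------------------------------------------------------------------------
# covariance templates


def nearest_pd_correlation(
    target: np.ndarray, eig_floor: float = 1e-6, max_iter: int = 200
) -> np.ndarray:
    """Nearest-PD repair: eigenvalue clipping at ``eig_floor`` then unit-diagonal
    rescaling, iterated to convergence."""
    mat = np.asarray(target, dtype=float).copy()
    mat = (mat + mat.T) / 2.0
    for _ in range(max_iter):
        vals, vecs = np.linalg.eigh(mat)
        if vals.min() >= eig_floor and np.allclose(np.diag(mat), 1.0, atol=1e-12):
            return mat
        vals = np.clip(vals, eig_floor, None)
        mat = (vecs * vals) @ vecs.T
        d = np.sqrt(np.diag(mat))
        mat = mat / np.outer(d, d)
        np.fill_diagonal(mat, 1.0)
    return mat


def _pattern_from_spec(n_nodes: int, spec: dict) -> np.ndarray:
    mat = np.full((n_nodes, n_nodes), float(spec.get("baseline_r", 0.0)))
    np.fill_diagonal(mat, 1.0)
    for block in spec.get("blocks", ()):
        nodes = np.asarray(block["nodes"], dtype=int)
        rest = np.setdiff1d(np.arange(n_nodes), nodes)
        within = float(block["within_r"])
        sub = np.ix_(nodes, nodes)
        mat[sub] = within
        mat[nodes, nodes] = 1.0
        if block.get("to_rest_r") is not None and len(rest):
            to_rest = float(block["to_rest_r"])
            mat[np.ix_(nodes, rest)] = to_rest
            mat[np.ix_(rest, nodes)] = to_rest
    return mat


def make_state_covariances(
    n_nodes: int,
    k_states: int | None = None,
    structure_spec: list[dict] | None = None,
    seed: int | None = None,
    separation_floor: float = 1.0,
    repair_tolerance: float | None = None,
) -> list[StateTemplate]:
    """Build K pairwise-distinguishable PD correlation templates from block recipes.

    Each recipe names block memberships and target within/between-block
    correlation levels; the returned covariance is the nearest-PD unit-diagonal
    repair of the requested pattern.  Templates closer than ``separation_floor``
    (Frobenius) or needing repair beyond ``repair_tolerance`` raise.
    """
    if n_nodes < 4:
        raise ValueError("n_nodes must be >= 4")
    if structure_spec is None:
        if k_states is None:
            k_states = 3
        if k_states == 3:
            structure_spec = default_structure_spec(n_nodes)
        else:
            rng = np.random.default_rng(seed)
            width = max(2, n_nodes // k_states)
            structure_spec = []
            for m in range(k_states):
                start = (m * width) % max(1, n_nodes - width)
                structure_spec.append(
                    {
                        "description": f"block-{m + 1}",
                        "baseline_r": 0.05,
                        "blocks": [
                            {
                                "nodes": list(range(start, start + width)),
                                "within_r": float(rng.uniform(0.45, 0.65)),
                                "to_rest_r": None,
                            }
                        ],
                    }
                )
    if len(structure_spec) < 2:
        raise ValueError("k_states must be >= 2")
    if repair_tolerance is None:
        repair_tolerance = 0.2 * n_nodes

    templates = []
    for sid, spec in enumerate(structure_spec, start=1):
        pattern = _pattern_from_spec(n_nodes, spec)
        cov = nearest_pd_correlation(pattern)
        dist = float(np.linalg.norm(cov - pattern))
        if dist > repair_tolerance:
            raise InfeasibleCorrelationPattern(
                f"template {spec.get('description', sid)!r}: nearest-PD repair moved "
                f"the pattern by Frobenius {dist:.3f} > tolerance {repair_tolerance:.3f}"
            )
        templates.append(
            StateTemplate(sid, cov, spec.get("description", f"state-{sid}")).validate()
        )

    for a in range(len(templates)):
        for b in range(a + 1, len(templates)):
            d = np.linalg.norm(templates[a].covariance - templates[b].covariance)
            if d < separation_floor:
                raise ValueError(
                    f"templates {templates[a].description!r} and "
                    f"{templates[b].description!r} are not separable "
                    f"(Frobenius {d:.3f} < floor {separation_floor})"
                )
    return templates


# ---------------------------------------------------------------------------
# run and study simulation


def _simulate_labels(
    stage_plan: list[tuple[str, int]],
    occupancy_schedule: dict[str, np.ndarray],
    k_states: int,
    stickiness: float,
    rng: np.random.Generator,
    initial_state: int | None = None,
) -> np.ndarray:
    """Stage-conditioned sticky Markov chain with minimal-switching stage
    transitions.

    Within a stage the chain stays with probability ``stickiness`` and
    otherwise redraws from the stage's target weights, whose stationary
    distribution they are.  At a stage boundary the state is updated by the
    maximal coupling of the two stages' weight vectors: the chain switches
    only with probability equal to the total-variation distance between
    successive stage distributions, so stage marginals track the schedule
    exactly while transitions stay gradual (no wholesale resets).  An
    explicit ``initial_state`` overrides the first draw; a single-stage run
    with stickiness 1 then never leaves it.
    """
    total = sum(n for _, n in stage_plan)
    labels = np.empty(total, dtype=int)
    t = 0
    current = initial_state
    prev_w: np.ndarray | None = None
    for stage_idx, (stage, length) in enumerate(stage_plan):
        if length <= 0:
            raise ValueError(f"empty stage {stage!r}")
        if stage not in occupancy_schedule:
            raise ValueError(f"stage {stage!r} missing from occupancy schedule")
        w = np.asarray(occupancy_schedule[stage], dtype=float)
        if len(w) != k_states:
            raise ValueError(f"stage {stage!r}: weight/state-count mismatch")
        if current is None:
            current = int(rng.choice(k_states, p=w)) + 1
        elif stage_idx > 0 and not np.array_equal(w, prev_w):
            # maximal coupling of prev_w -> w given current ~ prev_w
            i = current - 1
            stay_p = 1.0 if prev_w[i] <= 0 else min(1.0, w[i] / prev_w[i])
            if rng.random() >= stay_p:
                excess = np.maximum(w - prev_w, 0.0)
                excess[i] = 0.0
                if excess.sum() > 0:
                    current = int(rng.choice(k_states, p=excess / excess.sum())) + 1
        labels[t] = current
        t += 1
        for _ in range(length - 1):
            if rng.random() >= stickiness:
                current = int(rng.choice(k_states, p=w)) + 1
            labels[t] = current
            t += 1
        prev_w = w
    return labels


def simulate_run(
    templates: list[StateTemplate],
    stage_plan: list[tuple[str, int]],
    occupancy_schedule: dict[str, np.ndarray],
    stickiness: float = 0.98,
    noise_sd: float = 0.2,
    seed: int | np.random.Generator = 0,
    tr_seconds: float = 2.9,
    run_id: str = "run-01",
    condition: str = MEDITATION,
    initial_state: int | None = None,
) -> tuple[RoiTimecourse, RunGroundTruth]:
    """Simulate one run: latent sticky Markov labels, then per-TR multivariate
    normal observations from the active template plus isotropic noise."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    k = len(templates)
    n_nodes = templates[0].covariance.shape[0]
    labels = _simulate_labels(
        stage_plan, occupancy_schedule, k, stickiness, rng, initial_state
    )
    T = len(labels)

    chols = [
        np.linalg.cholesky(t.covariance + noise_sd**2 * np.eye(n_nodes))
        for t in templates
    ]
    z = rng.standard_normal((T, n_nodes))
    values = np.empty_like(z)
    for s in range(1, k + 1):
        idx = labels == s
        if idx.any():
            values[idx] = z[idx] @ chols[s - 1].T

    segments = []
    t = 0
    for stage, length in stage_plan:
        segments.append((stage, t, t + length))
        t += length

    tc = RoiTimecourse(
        values=values,
        node_labels=[f"node{i:03d}" for i in range(n_nodes)],
        tr_seconds=tr_seconds,
        condition=condition,
        run_id=run_id,
        stage_segments=segments,
    ).validate()
    occ = {s: float(np.mean(labels == s)) for s in range(1, k + 1)}
    return tc, RunGroundTruth(run_id=run_id, labels=labels, occupancy=occ)


def _dwell_in_mask(labels: np.ndarray, state: int, mask: np.ndarray) -> float:
    """Mean episode length (TRs) of ``state`` restricted to masked TRs; 0 if absent."""
    sel = (labels == state) & mask
    if not sel.any():
        return 0.0
    runs = []  # lengths of maximal True runs
    start = None
    for t, v in enumerate(sel):
        if v and start is None:
            start = t
        elif not v and start is not None:
            runs.append(t - start)
            start = None
    if start is not None:
        runs.append(len(sel) - start)
    return float(np.mean(runs))


def _clip_rating(x: np.ndarray | float) -> np.ndarray | float:
    return np.clip(x, 1.0, 10.0)


def simulate_study(params: SynthStudyParams | None = None) -> StudyDataset:
    """Generate the full study: meditation + control runs with ground truth and
    ratings coupled to state-2 dynamics (see :class:`RatingCoupling`)."""
    params = (params or SynthStudyParams()).resolved()
    ss = np.random.SeedSequence(params.seed)
    templates = make_state_covariances(
        params.n_nodes,
        structure_spec=params.structure_spec,
        separation_floor=params.separation_floor,
    )
    k = len(templates)

    n_total = params.n_meditation_runs + params.n_control_runs
    child_seeds = ss.spawn(n_total + 1)
    runs: list[RoiTimecourse] = []
    truths: dict[str, RunGroundTruth] = {}

    for i in range(params.n_meditation_runs):
        run_id = f"med-{i + 1:02d}"
        tc, gt = simulate_run(
            templates,
            params.stage_plan,
            params.occupancy_schedule,
            params.transition_stickiness,
            params.noise_sd,
            seed=np.random.default_rng(child_seeds[i]),
            tr_seconds=params.tr_seconds,
            run_id=run_id,
            condition=MEDITATION,
        )
        runs.append(tc)
        truths[run_id] = gt

    control_plan = [(CONTROL_STAGE, params.control_length_trs)]
    for i in range(params.n_control_runs):
        run_id = f"ctl-{i + 1:02d}"
        condition = CONTROL_CONDITIONS[i % len(CONTROL_CONDITIONS)]
        tc, gt = simulate_run(
            templates,
            control_plan,
            params.occupancy_schedule,
            params.transition_stickiness,
            params.noise_sd,
            seed=np.random.default_rng(child_seeds[params.n_meditation_runs + i]),
            tr_seconds=params.tr_seconds,
            run_id=run_id,
            condition=condition,
        )
        runs.append(tc)
        truths[run_id] = gt

    ratings = _generate_ratings(
        runs, truths, params, np.random.default_rng(child_seeds[-1])
    )
    return StudyDataset(runs, truths, ratings, templates, params)


def _generate_ratings(
    runs: list[RoiTimecourse],
    truths: dict[str, RunGroundTruth],
    params: SynthStudyParams,
    rng: np.random.Generator,
) -> PhenoRatings:
    cpl = params.rating_coupling
    g_rows, l_rows, f_rows = [], [], []
    clipped = []
    for tc in runs:
        if tc.condition != MEDITATION:
            continue
        gt = truths[tc.run_id]
        occ2 = gt.occupancy.get(2, 0.0)
        formless_mask = np.zeros(tc.n_trs, dtype=bool)
        for stage, start, end in tc.stage_segments:
            if stage in FORMLESS_STAGES:
                formless_mask[start:end] = True
        dwell2 = _dwell_in_mask(gt.labels, 2, formless_mask)

        exp_width = cpl.width_intercept - cpl.width_slope * occ2
        exp_sens = cpl.sens_intercept + cpl.sens_slope * dwell2
        gt.rating_expectations = {"width": exp_width, "sensations_formless": exp_sens}
        for name, val in gt.rating_expectations.items():
            if not (1.0 <= val <= 10.0):
                clipped.append((tc.run_id, name, val))

        noise = lambda: rng.normal(0.0, cpl.noise_sd)  # noqa: E731
        g_rows.append(
            {
                "run_id": tc.run_id,
                "stability": _clip_rating(7.0 + noise()),
                "width": _clip_rating(exp_width + noise()),
                "intensity": _clip_rating(6.0 + noise()),
            }
        )
        for ordinal, stage in enumerate(("J1", "J2", "J3", "J4", "J5", "J6-8"), 1):
            l_rows.append(
                {
                    "run_id": tc.run_id,
                    "stage": stage,
                    "stability": _clip_rating(6.0 + 0.3 * ordinal + noise()),
                    "intensity": _clip_rating(6.0 + noise()),
                    "width": _clip_rating(4.0 + 0.5 * ordinal + noise()),
                    "bliss": _clip_rating(5.0 + noise()),
                    "joy": _clip_rating(5.0 + noise()),
                    "equanimity": _clip_rating(5.0 + noise()),
                }
            )
        f_rows.append(
            {
                "run_id": tc.run_id,
                "category": "form",
                "sensations": _clip_rating(6.0 + noise()),
                "narrative": _clip_rating(3.0 + noise()),
            }
        )
        f_rows.append(
            {
                "run_id": tc.run_id,
                "category": "formless",
                "sensations": _clip_rating(exp_sens + noise()),
                "narrative": _clip_rating(2.0 + noise()),
            }
        )
    if clipped:
        warnings.warn(
            "noiseless rating expectations outside [1, 10] were clipped: "
            + ", ".join(f"{r}/{n}={v:.2f}" for r, n, v in clipped[:5]),
            stacklevel=2,
        )
    return PhenoRatings(
        pd.DataFrame(g_rows), pd.DataFrame(l_rows), pd.DataFrame(f_rows)
    ).validate()
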