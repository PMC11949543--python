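"""Validation experiments on synthetic studies with known ground truth.

These are the package's built-in parameter-recovery and calibration
experiments: planted-state recovery of the full pipeline, mixed-logistic
slope recovery, rating-coupling detection power, and type-I calibration of
the meditation-vs-control contrasts under a shared generative covariance.
Each function runs the pipeline machinery from scratch on freshly simulated
data and returns plain measured numbers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import adjusted_rand_score

from . import clustering, dynamics, static_fc, windows
from .core import MEDITATION, fisher_z, vectorize_upper
from .glmm import fit_mixed_logit, simulate_presence
from .synthetic import SynthStudyParams, make_state_covariances, simulate_run, simulate_study


@dataclass
class RecoveryResult:
    k_selected: int
    ari: float
    centroid_cosines: list[float]
    max_occupancy_error: float       # worst per-run, per-state |est - truth|
    mean_occupancy_error: float
    n_windows: int


def planted_recovery(
    seed: int = 0,
    k_min: int = 2,
    k_max: int = 8,
    estimate_replicates: int = 5,
    fit_replicates: int = 20,
    params: SynthStudyParams | None = None,
) -> RecoveryResult:
    """Full-pipeline recovery of the default planted three-state study.

    Simulates the study, runs tapered-window connectivity, elbow K selection,
    and L1 k-means, then scores window-label ARI against the taper-weighted
    modal latent labels, centroid/template cosine similarity after Hungarian
    matching, and per-run occupancy error after label matching.
    """
    study = simulate_study(params or SynthStudyParams(seed=seed))
    taper = windows.make_taper()
    series = [windows.windowed_connectivity(tc, taper) for tc in study.runs]
    pooled, prov = clustering.pool_windows(series)
    k_opt, _curve = clustering.estimate_k(
        pooled, k_min, k_max, seed=seed, n_replicates=estimate_replicates
    )
    model, seqs = clustering.fit_states(
        pooled, prov, 3, seed=seed, n_replicates=fit_replicates,
        runs_by_id={tc.run_id: tc for tc in study.runs},
    )

    truth, pred = [], []
    for s in seqs:
        gt = study.truths[s.run_id]
        truth.append(windows.window_truth_labels(gt.labels, s.window_center_trs, taper))
        pred.append(s.labels)
    truth = np.concatenate(truth)
    pred = np.concatenate(pred)
    ari = float(adjusted_rand_score(truth, pred))

    tvecs = np.array(
        [fisher_z(vectorize_upper(t.covariance)) for t in study.templates]
    )
    C = model.centroids
    sim = (C @ tvecs.T) / np.outer(
        np.linalg.norm(C, axis=1), np.linalg.norm(tvecs, axis=1)
    )
    rows, cols = linear_sum_assignment(-sim)
    cosines = [float(sim[r, c]) for r, c in zip(rows, cols)]
    fitted_for_template = {c + 1: r + 1 for r, c in zip(rows, cols)}

    occ_errors = []
    for s in seqs:
        gt = study.truths[s.run_id]
        est = dynamics.occupancy(s, model.retained_ids)
        for template_id, fitted_id in fitted_for_template.items():
            occ_errors.append(abs(est[fitted_id] - gt.occupancy[template_id]))
    return RecoveryResult(
        k_selected=int(k_opt),
        ari=ari,
        centroid_cosines=cosines,
        max_occupancy_error=float(np.max(occ_errors)),
        mean_occupancy_error=float(np.mean(occ_errors)),
        n_windows=int(len(truth)),
    )


def glmm_recovery_simulation(
    n_reps: int = 100,
    slope: float = 0.5,
    n_runs: int = 27,
    sigma_u: float = 0.5,
    seed: int = 0,
) -> dict:
    """Parameter recovery of the mixed logistic fitter on presence data drawn
    from the model itself (stage ordinals 1..6, intercept centering the
    planted slope)."""
    rng = np.random.default_rng(seed)
    ordinals = np.arange(1, 7)
    intercept = -slope * 3.5  # mid-range presence probability
    recovered, significant, estimates = [], [], []
    for _ in range(n_reps):
        x, y, g = simulate_presence(n_runs, slope, intercept, sigma_u, ordinals, rng)
        if y.min() == y.max():
            continue
        res = fit_mixed_logit(x, y, g)
        estimates.append(res.slope)
        recovered.append(abs(res.slope - slope) <= 0.25)
        significant.append(res.p_value < 0.05)
    return {
        "n_reps": len(estimates),
        "mean_estimate": float(np.mean(estimates)),
        "median_estimate": float(np.median(estimates)),
        "recovered_and_significant": float(
            np.mean(np.asarray(recovered) & np.asarray(significant))
        ),
        "rejection_rate": float(np.mean(significant)),
    }


def coupling_detection_simulation(n_reps: int = 100, seed: int = 0, **param_overrides) -> dict:
    """Power to detect the generator's negative width <-> state-2-occupancy
    coupling with a Pearson test at the study's n."""
    detected, rs = [], []
    base = np.random.SeedSequence(seed).generate_state(1)[0] % (2**31)
    for rep in range(n_reps):
        study = simulate_study(
            SynthStudyParams(seed=int(base + rep) % (2**31), **param_overrides)
        )
        g = study.ratings.global_items
        occ2 = np.array([study.truths[r].occupancy[2] for r in g["run_id"]])
        r, p = stats.pearsonr(g["width"].to_numpy(), occ2)
        rs.append(r)
        detected.append((r < 0) and (p < 0.05))
    return {
        "n_reps": n_reps,
        "mean_r": float(np.mean(rs)),
        "detection_rate": float(np.mean(detected)),
    }


def _null_study_runs(
    rng: np.random.Generator,
    n_meditation: int,
    n_control: int,
    run_length: int,
    control_length: int,
    n_nodes: int,
):
    """Runs for both conditions drawn from one covariance (the exact null)."""
    templates = make_state_covariances(
        n_nodes,
        structure_spec=[
            {"description": "shared", "baseline_r": 0.3, "blocks": []},
            {"description": "unused", "baseline_r": 0.0, "blocks": []},
        ],
        separation_floor=0.5,
    )
    sched = {"control": np.array([1.0, 0.0])}
    runs = []
    for i in range(n_meditation):
        tc, _ = simulate_run(
            templates, [("control", run_length)], sched, stickiness=0.98,
            noise_sd=0.2, seed=rng, run_id=f"med-{i:02d}", condition=MEDITATION,
        )
        runs.append(tc)
    for i in range(n_control):
        tc, _ = simulate_run(
            templates, [("control", control_length)], sched, stickiness=0.98,
            noise_sd=0.2, seed=rng, run_id=f"ctl-{i:02d}", condition="control-memory",
        )
        runs.append(tc)
    return runs


def static_type1_simulation(
    n_reps: int = 50,
    n_meditation: int = 12,
    n_control: int = 1000,
    run_length: int = 176,
    n_nodes: int = 16,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Raw edgewise false-positive rate of the static contrast under the null.

    Control runs have the same length as meditation runs, so the small-sample
    bias of the Fisher z estimate cancels between the conditions, and there
    are many of them, so the averaged-control reference is effectively
    noise-free (the one-sample contrast treats it as fixed; its residual
    variance inflates t by sqrt(1 + n_meditation/n_control)).  Returns the
    per-rep raw-p<alpha fractions and their mean.
    """
    rng = np.random.default_rng(seed)
    fracs = []
    for _ in range(n_reps):
        runs = _null_study_runs(
            rng, n_meditation, n_control, run_length, run_length, n_nodes
        )
        mats = [static_fc.run_connectivity(tc) for tc in runs]
        med = [m for m in mats if m.condition == MEDITATION]
        ctl = [m for m in mats if m.condition != MEDITATION]
        table = static_fc.edgewise_contrast(med, ctl, alpha=alpha)
        fracs.append(float((table["p_raw"] < alpha).mean()))
    fracs = np.asarray(fracs)
    return {
        "n_reps": n_reps,
        "mean_fraction": float(fracs.mean()),
        "sd_fraction": float(fracs.std(ddof=1)),
        "fractions": fracs.tolist(),
    }


def dynamics_type1_simulation(
    n_reps: int = 50,
    n_meditation: int = 27,
    n_control: int = 216,
    run_length: int = 176,
    n_nodes: int = 16,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """FDR-corrected false positives of the dynamic-measure contrast under
    the null: both conditions from one covariance, equal run lengths, k-means
    forced to 3 states.  Returns the fraction of reps with any p_FDR < alpha."""
    rng = np.random.default_rng(seed)
    any_rejection = []
    taper = windows.make_taper()
    for rep in range(n_reps):
        runs = _null_study_runs(
            rng, n_meditation, n_control, run_length, run_length, n_nodes
        )
        series = [windows.windowed_connectivity(tc, taper) for tc in runs]
        pooled, prov = clustering.pool_windows(series)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model, seqs = clustering.fit_states(
                pooled, prov, 3, seed=rep, n_replicates=3,
                runs_by_id={tc.run_id: tc for tc in runs},
            )
        meas = dynamics.measures_table(seqs, model.retained_ids)
        med = meas[meas["condition"] == MEDITATION]
        ctl = meas[meas["condition"] != MEDITATION]
        table = dynamics.contrast_dynamics(med, ctl)
        any_rejection.append(bool((table["p_fdr"].dropna() < alpha).any()))
    return {
        "n_reps": n_reps,
        "clean_fraction": float(1.0 - np.mean(any_rejection)),
        "n_with_rejections": int(np.sum(any_rejection)),
    }
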