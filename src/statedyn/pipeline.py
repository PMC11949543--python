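"""End-to-end pipeline driver.

``run_pipeline`` executes the full analysis on a study directory (or a
freshly simulated synthetic study): conditioning (optional) → static FC →
tapered windows → pooled clustering (elbow K, L1 k-means) → noise-state
pruning → dynamic measures and contrast → trajectory models → phenomenology
coupling.  Every intermediate table is written as TSV, and a JSON manifest
records seeds, configuration, and per-stage status, so identical config +
seeds reproduce identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clustering, dynamics, io, phenomenology, static_fc, trajectories, windows
from .core import MEDITATION
from .synthetic import SynthStudyParams, simulate_study

log = logging.getLogger("statedyn")

PIPELINE_STAGES = (
    "load", "condition", "static_fc", "windows", "estimate_k", "fit_states",
    "prune", "dynamics", "trajectories", "phenomenology",
)


@dataclass
class PipelineConfig:
    study_dir: str | None = None          # None -> simulate a synthetic study
    out_dir: str = "statedyn-out"
    parcellation: str | None = None       # targeted | wholebrain | None (trust files)
    condition_data: bool = False          # band-pass + despike before analysis
    window_length_trs: int = 16
    window_sigma_trs: float = 3.0
    window_step: int = 1
    k_min: int = 2
    k_max: int = 8
    k_fixed: int | None = None            # skip elbow selection if set
    n_replicates: int = 20
    estimate_replicates: int = 5
    metric: str = "cityblock"
    pruning_factor: float = 1.5
    switch_denominator: str = "transitions"
    seed: int = 0
    synth: dict = field(default_factory=dict)   # overrides for SynthStudyParams

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]


def run_pipeline(config: PipelineConfig, study=None) -> Path:
    """Execute every stage; returns the artifact directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "config_hash": config.config_hash(),
        "stages": {},
    }
    t_start = time.time()

    def stage_done(name, **info):
        manifest["stages"][name] = {"status": "ok", "elapsed_s": round(time.time() - t_start, 2), **info}
        log.info("stage %s done (%.1fs)", name, time.time() - t_start)

    try:
        # ---- load / simulate -------------------------------------------------
        if study is None:
            if config.study_dir is not None:
                parc = None
                if config.parcellation:
                    from .parcellation import default_parcellation

                    parc = default_parcellation(config.parcellation)
                runs = io.load_study_runs(config.study_dir, parcellation=parc)
                ratings = None
                try:
                    ratings = io.load_ratings(config.study_dir)
                except FileNotFoundError:
                    pass
                study = None
            else:
                params = SynthStudyParams(seed=config.seed, **config.synth)
                study = simulate_study(params)
                io.save_study(study, out / "study")
                runs = study.runs
                ratings = study.ratings
        else:
            runs = study.runs
            ratings = study.ratings
        stage_done("load", n_runs=len(runs))

        # ---- conditioning ----------------------------------------------------
        if config.condition_data:
            from .conditioning import condition_run

            runs = [condition_run(tc) for tc in runs]
        stage_done("condition", applied=config.condition_data)

        # ---- static FC -------------------------------------------------------
        mats = [static_fc.run_connectivity(tc) for tc in runs]
        med_mats = [m for m in mats if m.condition == MEDITATION]
        ctl_mats = [m for m in mats if m.condition != MEDITATION]
        contrast = static_fc.edgewise_contrast(med_mats, ctl_mats)
        contrast.to_csv(out / "static_contrast.tsv", sep="\t", index=False)
        stage_done("static_fc", n_edges=len(contrast))

        # ---- windows ---------------------------------------------------------
        taper = windows.make_taper(config.window_length_trs, config.window_sigma_trs)
        series = [windows.windowed_connectivity(tc, taper, config.window_step) for tc in runs]
        stage_done("windows", n_windows=sum(s.n_windows for s in series))

        # ---- clustering ------------------------------------------------------
        pooled, prov = clustering.pool_windows(series)
        if config.k_fixed is not None:
            k_opt = config.k_fixed
            curve = None
        else:
            k_opt, curve = clustering.estimate_k(
                pooled, config.k_min, config.k_max, seed=config.seed,
                n_replicates=config.estimate_replicates, metric=config.metric,
            )
            curve.to_csv(out / "k_selection_curve.tsv", sep="\t", index=False)
        stage_done("estimate_k", k_opt=int(k_opt))

        runs_by_id = {tc.run_id: tc for tc in runs}
        model, sequences = clustering.fit_states(
            pooled, prov, k_opt, seed=config.seed,
            n_replicates=config.n_replicates, metric=config.metric,
            runs_by_id=runs_by_id,
        )
        stage_done("fit_states", k=model.k_selected, inertia=model.inertia)

        model, sequences, excluded = clustering.prune_noise_states(
            model, sequences, roughness_factor=config.pruning_factor,
            series_by_run={s.run_id: s for s in series},
        )
        pd.DataFrame(model.centroids).to_csv(out / "centroids.tsv", sep="\t", index=False)
        (out / "model.json").write_text(
            json.dumps(
                {
                    "k_selected": model.k_selected,
                    "retained_ids": model.retained_ids,
                    "pruning_log": model.pruning_log,
                    "excluded_runs": excluded,
                    "distance_metric": model.distance_metric,
                },
                indent=1,
            )
        )
        seq_rows = []
        for s in sequences:
            for lab, c, st in zip(s.labels, s.window_center_trs, s.stages):
                seq_rows.append({"run_id": s.run_id, "center_tr": int(c), "stage": st, "state": int(lab)})
        pd.DataFrame(seq_rows).to_csv(out / "state_sequences.tsv", sep="\t", index=False)
        stage_done("prune", retained=model.retained_ids, excluded_runs=excluded)

        # ---- dynamics --------------------------------------------------------
        meas = dynamics.measures_table(sequences, model.retained_ids, config.switch_denominator)
        meas.to_csv(out / "dynamic_measures.tsv", sep="\t", index=False)
        med = meas[meas["condition"] == MEDITATION]
        ctl = meas[meas["condition"] != MEDITATION]
        dyn_contrast = dynamics.contrast_dynamics(med, ctl)
        dyn_contrast.to_csv(out / "dynamics_contrast.tsv", sep="\t", index=False)
        for cond_name, cond_seqs in (
            ("meditation", [s for s in sequences if s.condition == MEDITATION]),
            ("control", [s for s in sequences if s.condition != MEDITATION]),
        ):
            if cond_seqs:
                mats = np.stack(
                    [dynamics.transition_matrix(s, model.retained_ids) for s in cond_seqs]
                )
                with np.errstate(invalid="ignore"):
                    mean_mat = np.nanmean(mats, axis=0)
                pd.DataFrame(
                    mean_mat,
                    index=[f"state{i}" for i in model.retained_ids],
                    columns=[f"state{i}" for i in model.retained_ids],
                ).to_csv(out / f"transition_matrix_{cond_name}.tsv", sep="\t")
        stage_done("dynamics", n_measures=len(dyn_contrast))

        # ---- trajectories ----------------------------------------------------
        med_seqs = [s for s in sequences if s.condition == MEDITATION]
        traj = trajectories.dominant_state_table(med_seqs)
        traj.to_csv(out / "trajectory_table.tsv", sep="\t")
        km = None
        if traj.dropna().shape[0] >= 5 and len(model.retained_ids) > 1:
            km = trajectories.kmodes_cluster(traj, seed=config.seed)
            pd.DataFrame(
                {"run_id": traj.dropna().index, "trajectory_cluster": km.labels}
            ).to_csv(out / "trajectory_clusters.tsv", sep="\t", index=False)
        presence = trajectories.state_presence(med_seqs, model.retained_ids)
        presence.to_csv(out / "state_presence.tsv", sep="\t", index=False)
        glmm_stage = trajectories.trajectory_glmm_table(presence, model.retained_ids, "stage")
        glmm_form = trajectories.trajectory_glmm_table(presence, model.retained_ids, "form")
        pd.concat([glmm_stage, glmm_form]).to_csv(
            out / "trajectory_models.tsv", sep="\t", index=False
        )
        stage_done("trajectories", k_modes=None if km is None else km.k)

        # ---- phenomenology ---------------------------------------------------
        if ratings is not None:
            reports = []
            for level in ("global", "local", "form"):
                reports.append(
                    phenomenology.rating_dynamics_correlations(
                        ratings, sequences, model.retained_ids, level=level,
                        run_measures_table=med if level == "global" else None,
                    )
                )
            pd.concat(reports).to_csv(out / "phenomenology_correlations.tsv", sep="\t", index=False)

            merged = ratings.global_items.merge(med, on="run_id")
            X = merged[list(phenomenology.GLOBAL_ITEMS)].to_numpy()
            Y = merged[[f"state{s}_proportion" for s in model.retained_ids]].to_numpy()
            cca_res = phenomenology.cca(X, Y)
            (out / "cca.json").write_text(
                json.dumps(
                    {
                        "canonical_correlations": cca_res.correlations.tolist(),
                        "first_rc2": cca_res.first_rc2,
                        "hotelling_trace": cca_res.hotelling_trace,
                        "p_value": cca_res.p_value,
                    },
                    indent=1,
                )
            )
        stage_done("phenomenology", with_ratings=ratings is not None)

    except Exception as exc:
        failed = next((s for s in PIPELINE_STAGES if s not in manifest["stages"]), "?")
        manifest["stages"][failed] = {"status": "failed", "error": str(exc)}
        (Path(config.out_dir) / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise RuntimeError(f"pipeline stage {failed!r} failed: {exc}") from exc

    manifest["elapsed_s"] = round(time.time() - t_start, 2)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out


def make_report(artifact_dir: str | Path) -> dict[str, pd.DataFrame]:
    """Collect the summary tables of a completed pipeline run."""
    artifact_dir = Path(artifact_dir)
    if not (artifact_dir / "manifest.json").exists():
        raise FileNotFoundError(f"no pipeline manifest in {artifact_dir}")
    tables = {}
    for name in (
        "dynamics_contrast", "phenomenology_correlations", "trajectory_models",
        "trajectory_clusters", "k_selection_curve",
    ):
        path = artifact_dir / f"{name}.tsv"
        if path.exists():
            tables[name] = pd.read_csv(path, sep="\t")
    if not tables:
        raise FileNotFoundError(f"no pipeline outputs found in {artifact_dir}")
    return tables
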