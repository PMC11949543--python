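"""Reading and writing study artifacts.

Formats (all plain text):

* timecourse: TSV, TRs as rows, header row of node labels;
* sidecar: JSON with ``tr_seconds``, ``condition``, ``run_id`` (all required)
  and optionally ``seed``;
* events: BIDS-style TSV with ``onset``/``duration`` in seconds and
  ``trial_type`` carrying the stage label;
* ratings: three TSVs (global / local / form-formless) keyed by ``run_id``;
* ground truth (synthetic studies only): TSV of per-TR latent labels.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import RoiTimecourse, ValidationError
from .parcellation import ParcellationConfig
from .synthetic import PhenoRatings, RunGroundTruth, StudyDataset

_SIDE_REQUIRED = ("tr_seconds", "condition", "run_id")


def _segments_from_events(events: pd.DataFrame, tr_seconds: float, n_trs: int):
    required = {"onset", "duration", "trial_type"}
    if not required.issubset(events.columns):
        raise ValidationError(f"events table missing columns {sorted(required - set(events.columns))}")
    segs = []
    for idx, row in events.iterrows():
        start = int(round(float(row["onset"]) / tr_seconds))
        end = start + int(round(float(row["duration"]) / tr_seconds))
        if end <= start or start < 0 or end > n_trs:
            raise ValidationError(f"events row {idx}: segment [{start}, {end}) invalid for T={n_trs}")
        segs.append((str(row["trial_type"]), start, end))
    segs.sort(key=lambda s: s[1])
    for (la, sa, ea), (lb, sb, eb) in zip(segs, segs[1:]):
        if sb < ea:
            raise ValidationError(f"events: segments {la!r} and {lb!r} overlap")
        if sb > ea:
            raise ValidationError(f"events: gap between segments {la!r} and {lb!r}")
    return segs


def load_run(
    timecourse_path: str | Path,
    sidecar_path: str | Path,
    events_path: str | Path | None = None,
    parcellation: ParcellationConfig | None = None,
) -> RoiTimecourse:
    """Load and validate one run.

    If a parcellation is given, the timecourse columns must carry exactly its
    labels (any order); columns are re-ordered to the config order.
    """
    df = pd.read_csv(timecourse_path, sep="\t")
    if df.isna().any().any():
        col = df.columns[df.isna().any()][0]
        row = int(df[df[col].isna()].index[0])
        raise ValidationError(f"{timecourse_path}: NaN at row {row}, column {col!r}")

    with open(sidecar_path) as fh:
        side = json.load(fh)
    missing = [k for k in _SIDE_REQUIRED if k not in side]
    if missing:
        raise ValidationError(f"{sidecar_path}: missing sidecar fields {missing}")

    if parcellation is not None:
        want = parcellation.node_labels
        have = list(df.columns)
        if set(want) != set(have):
            extra = sorted(set(have) - set(want))
            absent = sorted(set(want) - set(have))
            raise ValidationError(
                f"{timecourse_path}: column labels do not match parcellation "
                f"{parcellation.name!r} (unexpected {extra[:3]}, missing {absent[:3]})"
            )
        df = df[want]

    segments = []
    if events_path is not None:
        events = pd.read_csv(events_path, sep="\t")
        segments = _segments_from_events(events, float(side["tr_seconds"]), len(df))

    return RoiTimecourse(
        values=df.to_numpy(dtype=float),
        node_labels=list(df.columns),
        tr_seconds=float(side["tr_seconds"]),
        condition=str(side["condition"]),
        run_id=str(side["run_id"]),
        stage_segments=segments,
    ).validate()


def save_run(tc: RoiTimecourse, out_dir: str | Path, seed: int | None = None) -> dict[str, Path]:
    """Write timecourse TSV + JSON sidecar + events TSV; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "timecourse": out_dir / f"{tc.run_id}_timecourse.tsv",
        "sidecar": out_dir / f"{tc.run_id}_sidecar.json",
        "events": out_dir / f"{tc.run_id}_events.tsv",
    }
    pd.DataFrame(tc.values, columns=tc.node_labels).to_csv(
        paths["timecourse"], sep="\t", index=False, float_format="%.10g"
    )
    side = {"tr_seconds": tc.tr_seconds, "condition": tc.condition, "run_id": tc.run_id}
    if seed is not None:
        side["seed"] = seed
    paths["sidecar"].write_text(json.dumps(side, indent=1))
    events = pd.DataFrame(
        [
            {
                "onset": start * tc.tr_seconds,
                "duration": (end - start) * tc.tr_seconds,
                "trial_type": label,
            }
            for label, start, end in tc.stage_segments
        ]
    )
    events.to_csv(paths["events"], sep="\t", index=False)
    return paths


def save_ratings(ratings: PhenoRatings, out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ratings.global_items.to_csv(out_dir / "ratings_global.tsv", sep="\t", index=False)
    ratings.local_items.to_csv(out_dir / "ratings_local.tsv", sep="\t", index=False)
    ratings.form_items.to_csv(out_dir / "ratings_form.tsv", sep="\t", index=False)


def load_ratings(in_dir: str | Path) -> PhenoRatings:
    in_dir = Path(in_dir)
    return PhenoRatings(
        pd.read_csv(in_dir / "ratings_global.tsv", sep="\t"),
        pd.read_csv(in_dir / "ratings_local.tsv", sep="\t"),
        pd.read_csv(in_dir / "ratings_form.tsv", sep="\t"),
    ).validate()


def save_study(study: StudyDataset, out_dir: str | Path, with_truth: bool = True) -> Path:
    """Write a full synthetic study (runs, ratings, optional latent truth)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for tc in study.runs:
        save_run(tc, out_dir, seed=study.params.seed)
        if with_truth and tc.run_id in study.truths:
            gt = study.truths[tc.run_id]
            pd.DataFrame({"tr": np.arange(len(gt.labels)), "state": gt.labels}).to_csv(
                out_dir / f"{tc.run_id}_truth.tsv", sep="\t", index=False
            )
    save_ratings(study.ratings, out_dir)
    manifest = {
        "run_ids": [tc.run_id for tc in study.runs],
        "conditions": {tc.run_id: tc.condition for tc in study.runs},
        "seed": study.params.seed,
        "n_nodes": study.params.n_nodes,
    }
    (out_dir / "study.json").write_text(json.dumps(manifest, indent=1))
    return out_dir


def load_study_runs(
    in_dir: str | Path, parcellation: ParcellationConfig | None = None
) -> list[RoiTimecourse]:
    """Load every run listed in a study directory's manifest."""
    in_dir = Path(in_dir)
    manifest = json.loads((in_dir / "study.json").read_text())
    runs = []
    for run_id in manifest["run_ids"]:
        runs.append(
            load_run(
                in_dir / f"{run_id}_timecourse.tsv",
                in_dir / f"{run_id}_sidecar.json",
                in_dir / f"{run_id}_events.tsv",
                parcellation=parcellation,
            )
        )
    return runs


def load_truth(in_dir: str | Path, run_id: str) -> RunGroundTruth:
    df = pd.read_csv(Path(in_dir) / f"{run_id}_truth.tsv", sep="\t")
    labels = df["state"].to_numpy(dtype=int)
    occ = {int(s): float(np.mean(labels == s)) for s in np.unique(labels)}
    return RunGroundTruth(run_id=run_id, labels=labels, occupancy=occ)


def validate_study(in_dir: str | Path) -> dict:
    """Validate every artifact in a study directory; returns a summary dict."""
    runs = load_study_runs(in_dir)
    summary = {
        "n_runs": len(runs),
        "n_meditation": sum(r.condition == "meditation" for r in runs),
        "n_control": sum(r.condition != "meditation" for r in runs),
        "n_nodes": runs[0].n_nodes if runs else 0,
        "run_lengths": {r.run_id: r.n_trs for r in runs},
    }
    try:
        load_ratings(in_dir)
        summary["ratings"] = "ok"
    except FileNotFoundError:
        summary["ratings"] = "absent"
    return summary


def save_windows(series, out_dir: str | Path) -> None:
    """Per-run windowed-connectivity TSV (W×E) plus a JSON sidecar carrying the
    window centers and the canonical edge-label order."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for s in series:
        pd.DataFrame(s.edge_vectors).to_csv(
            out_dir / f"{s.run_id}_windows.tsv", sep="\t", index=False,
            float_format="%.8g",
        )
        (out_dir / f"{s.run_id}_windows.json").write_text(
            json.dumps(
                {
                    "run_id": s.run_id,
                    "condition": s.condition,
                    "window_center_trs": [int(c) for c in s.window_center_trs],
                    "node_labels": s.node_labels,
                    "edge_labels": s.edge_labels(),
                    "degenerate_windows": s.degenerate_windows,
                },
            )
        )


def load_windows(in_dir: str | Path):
    """Load every windowed-connectivity series in a directory."""
    from .core import WindowedConnectivitySeries

    in_dir = Path(in_dir)
    series = []
    for sidecar in sorted(in_dir.glob("*_windows.json")):
        meta = json.loads(sidecar.read_text())
        values = pd.read_csv(
            in_dir / f"{meta['run_id']}_windows.tsv", sep="\t"
        ).to_numpy(dtype=float)
        series.append(
            WindowedConnectivitySeries(
                run_id=meta["run_id"],
                condition=meta["condition"],
                edge_vectors=values,
                window_center_trs=np.asarray(meta["window_center_trs"]),
                node_labels=meta["node_labels"],
                degenerate_windows=meta.get("degenerate_windows", []),
            )
        )
    return series


def save_sequences(sequences, path: str | Path) -> None:
    """State sequences as long TSV (run_id, center_tr, stage, state)."""
    rows = []
    for s in sequences:
        for lab, c, st in zip(s.labels, s.window_center_trs, s.stages):
            rows.append(
                {"run_id": s.run_id, "condition": s.condition,
                 "center_tr": int(c), "stage": st, "state": int(lab)}
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_sequences(path: str | Path):
    """Inverse of :func:`save_sequences`."""
    from .core import StateSequence

    df = pd.read_csv(path, sep="\t")
    sequences = []
    for run_id, sub in df.groupby("run_id", sort=False):
        stages = [None if pd.isna(s) else str(s) for s in sub["stage"]]
        sequences.append(
            StateSequence(
                run_id=str(run_id),
                condition=str(sub["condition"].iloc[0]),
                labels=sub["state"].to_numpy(dtype=int),
                window_center_trs=sub["center_tr"].to_numpy(dtype=int),
                stages=stages,
            )
        )
    return sequences
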