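"""Readers, writers, configuration, and the end-to-end pipeline.

All artifacts are plain text: spikes, units, bouts and pose as CSV, the run
configuration as YAML, and the run report as JSON.  A KiloSort/phy-style
sorted-output directory can be read in place of the CSV bundle; only units
curated as 'good' are kept.

The pipeline executes simulate → detect-grooming → classify → responses →
ensembles → characterize → trajectories with per-stage artifacts on disk and
a deterministic JSON report.  A single global seed fans out to per-stage
child seeds, so each stage is independently reproducible.
"""

from __future__ import annotations

import ast
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify as _classify
from . import ensemble_stats as es
from . import ensembles as ens
from . import grooming as gr
from . import responses as resp
from . import synthetic as syn
from . import trajectories as traj
from .core import GroomingBouts, SpikeData

logger = logging.getLogger(__name__)

__all__ = [
    "SessionBundle",
    "read_session",
    "write_session",
    "read_phy_dir",
    "read_bouts_csv",
    "write_bouts_csv",
    "read_pose_csv",
    "write_pose_csv",
    "load_config",
    "save_config",
    "default_config",
    "run_pipeline",
]


@dataclass
class SessionBundle:
    """Everything one session's analysis needs, on one clock."""

    spikes: SpikeData
    units: pd.DataFrame
    bouts: GroomingBouts
    pose: gr.Pose3DTrack | None = None
    ground_truth: syn.GroundTruth | None = None
    provenance: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# CSV bundle
# ---------------------------------------------------------------------------

def write_bouts_csv(bouts: GroomingBouts, path) -> None:
    pd.DataFrame(bouts.intervals, columns=["start_s", "end_s"]).to_csv(
        path, index=False
    )


def read_bouts_csv(path) -> GroomingBouts:
    df = pd.read_csv(path)
    bad = df.index[df["end_s"] <= df["start_s"]].tolist()
    if bad:
        raise ValueError(f"bout rows with end <= start: {bad}")
    iv = df[["start_s", "end_s"]].to_numpy(dtype=float)
    return GroomingBouts(iv[np.argsort(iv[:, 0])])


def write_spikes_csv(spikes: SpikeData, path) -> None:
    times = np.concatenate(spikes.times) if spikes.n_units else np.empty(0)
    units = np.concatenate(
        [np.full(len(t), u) for u, t in zip(spikes.unit_ids, spikes.times)]
    ) if spikes.n_units else np.empty(0, dtype=int)
    order = np.argsort(times, kind="stable")
    pd.DataFrame({"time_s": times[order], "unit_id": units[order]}).to_csv(
        path, index=False, float_format="%.6f"
    )


def read_spikes_csv(path, units: pd.DataFrame, duration_s: float) -> SpikeData:
    df = pd.read_csv(path)
    ids = units["unit_id"].to_numpy()
    grouped = df.groupby("unit_id")["time_s"]
    times = [
        np.sort(grouped.get_group(u).to_numpy()) if u in grouped.groups else np.empty(0)
        for u in ids
    ]
    pos = None
    if {"x_um", "depth_um"}.issubset(units.columns):
        pos = units[["x_um", "depth_um"]].to_numpy(dtype=float)
    return SpikeData(ids, times, duration_s, pos)


def write_pose_csv(track: gr.Pose3DTrack, path, fmt: str = "wide") -> None:
    """Write a pose track as CSV, wide (one row per frame) or long."""
    if fmt == "wide":
        cols = {"frame": track.frames}
        for k, name in enumerate(track.keypoints):
            for d, ax in enumerate("xyz"):
                cols[f"{name}_{ax}"] = track.coords[:, k, d]
        pd.DataFrame(cols).to_csv(path, index=False, float_format="%.4f")
    elif fmt == "long":
        n, kps = track.n_frames, len(track.keypoints)
        pd.DataFrame(
            {
                "frame": np.repeat(track.frames, kps),
                "keypoint": list(track.keypoints) * n,
                "x": track.coords[:, :, 0].ravel(),
                "y": track.coords[:, :, 1].ravel(),
                "z": track.coords[:, :, 2].ravel(),
            }
        ).to_csv(path, index=False, float_format="%.4f")
    else:
        raise ValueError("fmt must be 'wide' or 'long'")


def read_pose_csv(path, frame_rate_hz: float) -> gr.Pose3DTrack:
    """Read a pose CSV in either wide or long layout (autodetected)."""
    df = pd.read_csv(path)
    if "keypoint" in df.columns:  # long
        keypoints = tuple(df["keypoint"].unique())
        frames = np.sort(df["frame"].unique())
        coords = np.empty((len(frames), len(keypoints), 3))
        pivot = df.set_index(["frame", "keypoint"])
        for k, name in enumerate(keypoints):
            sub = pivot.xs(name, level="keypoint").loc[frames]
            coords[:, k, :] = sub[["x", "y", "z"]].to_numpy()
    else:  # wide
        frames = df["frame"].to_numpy()
        keypoints = tuple(
            dict.fromkeys(c.rsplit("_", 1)[0] for c in df.columns if c != "frame")
        )
        coords = np.empty((len(frames), len(keypoints), 3))
        for k, name in enumerate(keypoints):
            coords[:, k, :] = df[[f"{name}_x", f"{name}_y", f"{name}_z"]].to_numpy()
    return gr.Pose3DTrack(
        frame_rate_hz=frame_rate_hz,
        frames=frames,
        keypoints=keypoints,
        coords=coords,
    )


def write_session(bundle: SessionBundle, out_dir, save_pose: bool = False) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_spikes_csv(bundle.spikes, out / "spikes.csv")
    bundle.units.to_csv(out / "units.csv", index=False, float_format="%.4f")
    write_bouts_csv(bundle.bouts, out / "bouts.csv")
    meta = {
        "duration_s": float(bundle.spikes.duration_s),
        **{k: v for k, v in bundle.provenance.items()},
    }
    if bundle.pose is not None:
        meta["pose_frame_rate_hz"] = float(bundle.pose.frame_rate_hz)
        if save_pose:
            write_pose_csv(bundle.pose, out / "pose.csv")
    save_config(meta, out / "session.yaml")


def read_session(path, fmt: str = "csv_bundle") -> SessionBundle:
    """Load a session from a CSV bundle directory or a phy-style directory."""
    path = Path(path)
    if fmt == "csv_bundle":
        meta = load_config(path / "session.yaml")
        units = pd.read_csv(path / "units.csv")
        spikes = read_spikes_csv(path / "spikes.csv", units, float(meta["duration_s"]))
        bouts = read_bouts_csv(path / "bouts.csv")
        pose = None
        if (path / "pose.csv").exists():
            pose = read_pose_csv(path / "pose.csv", float(meta["pose_frame_rate_hz"]))
        return SessionBundle(
            spikes=spikes, units=units, bouts=bouts, pose=pose, provenance=meta
        )
    if fmt == "kilosort_phy_dir":
        spikes, units = read_phy_dir(path)
        bouts_path = path / "bouts.csv"
        bouts = read_bouts_csv(bouts_path) if bouts_path.exists() else GroomingBouts.empty()
        return SessionBundle(spikes=spikes, units=units, bouts=bouts)
    raise ValueError("fmt must be 'csv_bundle' or 'kilosort_phy_dir'")


def read_phy_dir(path) -> tuple[SpikeData, pd.DataFrame]:
    """Read a KiloSort/phy sorted-output directory, keeping 'good' units.

    Consumes ``spike_times.npy`` (samples), ``spike_clusters.npy``,
    ``cluster_group.tsv`` and the ``sample_rate`` entry of ``params.py``.
    """
    path = Path(path)
    params = {}
    for line in (path / "params.py").read_text().splitlines():
        if "=" in line:
            k, v = line.split("=", 1)
            try:
                params[k.strip()] = ast.literal_eval(v.strip())
            except (ValueError, SyntaxError):
                pass
    fs = float(params["sample_rate"])
    samples = np.load(path / "spike_times.npy").ravel()
    clusters = np.load(path / "spike_clusters.npy").ravel()
    groups = pd.read_csv(path / "cluster_group.tsv", sep="\t")
    good = groups.loc[groups["group"] == "good", "cluster_id"].to_numpy()
    t = samples / fs
    duration = float(params.get("duration_s", np.ceil(t.max()) if len(t) else 1.0))
    times = [np.sort(t[clusters == c]) for c in good]
    spikes = SpikeData(good, times, duration)
    units = pd.DataFrame({"unit_id": good, "mean_rate_hz": spikes.mean_rates()})
    return spikes, units


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def save_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def default_config() -> dict:
    """Baseline pipeline configuration for a synthetic session."""
    return {
        "seed": 0,
        "simulate": {
            "session_duration_s": 7200.0,
            "n_spn": 55,
            "n_fsi": 5,
            "n_ensembles": 5,
            "ensemble_sizes": [6, 6, 6, 6, 6],
            "response_profiles": [
                "step_up",
                "transient_start",
                "step_down",
                "transient_end",
                "step_up",
            ],
            "modulation_gain": 5.0,
        },
        "pose": {"simulate": True, "frame_rate_hz": 125.0, "jitter_sd": 0.05,
                 "save_csv": False},
        "detection": {},
        "responses": {},
        "ensembles": {"n_shuffles": 5000, "n_kmeans_runs": 1000, "pair_threshold": 0.8},
        "characterization": {"n_bootstrap_windows": 1000},
        "trajectories": {"k": 3},
    }


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return round(float(obj), 10)
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, float):
        return round(obj, 10)
    return obj


def _write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(_jsonable(report), fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_pipeline(config: dict, out_dir) -> dict:
    """Run the full analysis and return the report dict (also written to
    ``out_dir/report.json``).

    Stage artifacts are written as they complete, so a failing stage leaves
    the earlier results on disk.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config_seed": int(config["seed"])}
    try:
        _run_stages(config, out, report)
    finally:
        _write_report(report, out / "report.json")
    return report


def _child_rngs(seed: int, n: int) -> list:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _run_stages(config: dict, out: Path, report: dict) -> None:
    seed = int(config["seed"])
    # fixed stream allocation: slot 0 is reserved for the simulation stage,
    # which draws its own children from the same seed inside simulate_session
    _, rng_eig, rng_km, rng_boot = _child_rngs(seed, 4)

    # --- simulate ------------------------------------------------------
    sim_cfg = dict(config.get("simulate") or {})
    scfg = syn.SessionConfig(seed=seed, **sim_cfg)
    pose_cfg = config.get("pose") or {}
    session = syn.simulate_session(
        scfg,
        make_pose=bool(pose_cfg.get("simulate", False)),
        pose_frame_rate_hz=float(pose_cfg.get("frame_rate_hz", 125.0)),
        pose_jitter_sd=float(pose_cfg.get("jitter_sd", 0.0)),
    )
    bundle = SessionBundle(
        spikes=session.spikes,
        units=session.units,
        bouts=session.bouts,
        pose=session.pose,
        ground_truth=session.ground_truth,
        provenance={"seed": seed},
    )
    write_session(bundle, out / "session", save_pose=bool(pose_cfg.get("save_csv")))
    bouts = session.bouts
    report["simulate"] = {
        "n_units": session.spikes.n_units,
        "n_bouts": len(bouts),
        "groom_fraction": bouts.total_time() / scfg.session_duration_s,
        "mean_bout_s": float(bouts.durations.mean()) if len(bouts) else 0.0,
        "mean_ibi_s": (
            float(bouts.inter_bout_intervals().mean()) if len(bouts) > 1 else 0.0
        ),
    }

    # --- detect grooming ----------------------------------------------
    det_cfg = config.get("detection") or {}
    if session.pose is not None:
        thr = gr.DEFAULT_THRESHOLDS.with_(**det_cfg.get("thresholds", {}))
        feats = gr.compute_postural_features(session.pose)
        detected = gr.detect_grooming(feats, thr)
        write_bouts_csv(detected, out / "bouts_detected.csv")
        report["detection"] = {
            "n_bouts_detected": len(detected),
            "jaccard_vs_annotation": gr.jaccard_agreement(
                detected, bouts, scfg.session_duration_s
            ),
        }
    else:
        report["detection"] = {"skipped": "no pose track available"}

    # --- classify ------------------------------------------------------
    units = bundle.units.copy()
    units["label"] = _classify.classify_units(units)
    units.to_csv(out / "units_labeled.csv", index=False, float_format="%.4f")
    counts = units["label"].value_counts().to_dict()
    report["classification"] = {
        "n_spn": int(counts.get("SPN", 0)),
        "n_fsi": int(counts.get("FSI", 0)),
        "n_other": int(counts.get("other", 0)),
    }
    keep = units["label"].isin(["SPN", "FSI"]).to_numpy()
    spikes = bundle.spikes.subset(keep)
    kept_units = units.loc[keep].reset_index(drop=True)

    # --- responses -----------------------------------------------------
    merged = gr.merge_close_bouts(bouts, 3.0)
    isolated = resp.select_isolated_bouts(merged)
    report["responses"] = {"n_isolated_bouts": len(isolated)}
    if len(isolated):
        for cell_type in ("SPN", "FSI"):
            sel = (kept_units["label"] == cell_type).to_numpy()
            if sel.sum() < 3:
                report["responses"][cell_type] = {"skipped": "fewer than 3 units"}
                continue
            sub = spikes.subset(sel)
            ct_report = {}
            for alignment, events in (("start", isolated.starts), ("end", isolated.ends)):
                profile = resp.event_triggered_average(
                    sub, events, alignment=alignment
                )
                typing = resp.pca_response_types(profile)
                prefix = f"responses_{cell_type}_{alignment}"
                pd.DataFrame(
                    profile.mean_response,
                    index=pd.Index(profile.unit_ids, name="unit_id"),
                    columns=[f"t{o:+.2f}" for o in profile.bin_offsets_s],
                ).to_csv(out / f"{prefix}_eta.csv", float_format="%.5f")
                pd.DataFrame(
                    {
                        "unit_id": typing.unit_ids,
                        "group": typing.group,
                        "sign": typing.sign,
                        "w_pc1": typing.weights[:, 0],
                        "w_pc2": typing.weights[:, 1],
                    }
                ).to_csv(out / f"{prefix}_pca.csv", index=False, float_format="%.5f")
                ct_report[alignment] = {
                    "pc1_pos": int(np.sum((typing.group == "PC1") & (typing.sign == "+"))),
                    "pc1_neg": int(np.sum((typing.group == "PC1") & (typing.sign == "-"))),
                    "pc2_pos": int(np.sum((typing.group == "PC2") & (typing.sign == "+"))),
                    "pc2_neg": int(np.sum((typing.group == "PC2") & (typing.sign == "-"))),
                    "explained_variance": typing.explained_variance_fraction,
                }
            report["responses"][cell_type] = ct_report
        n_mod = sum(
            resp.flag_grooming_modulated(t, isolated, "start")
            or resp.flag_grooming_modulated(t, isolated, "end")
            for t in spikes.times
        )
        report["responses"]["n_flagged_2sd"] = int(n_mod)

    # --- ensembles -----------------------------------------------------
    ens_cfg = config.get("ensembles") or {}
    if spikes.n_units < ens.MIN_UNITS:
        report["ensembles"] = {
            "skipped": f"fewer than {ens.MIN_UNITS} SPN+FSI units"
        }
        report["characterization"] = {"skipped": "no ensembles"}
        report["trajectories"] = {"skipped": "no ensembles"}
        return
    gm = ens.build_grooming_matrix(spikes, merged)
    estimate = ens.estimate_ensemble_count(
        gm, n_shuffles=int(ens_cfg.get("n_shuffles", 5000)), rng=rng_eig
    )
    assignment = ens.meta_kmeans(
        gm,
        rng=rng_km,
        n_runs=int(ens_cfg.get("n_kmeans_runs", 1000)),
        pair_threshold=float(ens_cfg.get("pair_threshold", 0.8)),
    )
    pd.DataFrame(
        {"unit_id": assignment.unit_ids, "cluster_id": assignment.labels}
    ).to_csv(out / "ensemble_assignment.csv", index=False)
    pd.DataFrame(
        assignment.coassignment,
        index=pd.Index(assignment.unit_ids, name="unit_id"),
        columns=assignment.unit_ids,
    ).to_csv(out / "coassignment.csv", float_format="%.4f")
    pd.DataFrame(
        {"eigenvalue": estimate.eigenvalues}
    ).to_csv(out / "eigenvalues.csv", index=False, float_format="%.5f")
    sizes = assignment.cluster_sizes()
    report["ensembles"] = {
        "n_significant_eigenvalues": estimate.n_significant,
        "null_threshold": estimate.null_threshold,
        "n_clusters": assignment.n_clusters,
        "cluster_sizes": sizes,
        "pct_clustered": 100.0 * float(np.mean(assignment.labels >= 0)),
    }

    # --- characterization ---------------------------------------------
    char_cfg = config.get("characterization") or {}
    char: dict = {}
    if assignment.n_clusters == 0:
        report["characterization"] = {"skipped": "no clusters found"}
    else:
        w_g, b_g = es.pairwise_correlation_split(gm, assignment)
        sm = ens.build_session_matrix(spikes)
        w_s, b_s = es.pairwise_correlation_split(sm, assignment)
        char["auc_grooming"] = es.distribution_auc(w_g, b_g)
        char["auc_whole_session"] = es.distribution_auc(w_s, b_s)
        positions = kept_units[["x_um", "depth_um"]].to_numpy(dtype=float)
        d_w, d_b = es.pairwise_distance_split(positions, assignment)
        char["median_within_dist_um"] = float(np.median(d_w)) if len(d_w) else None
        char["median_between_dist_um"] = float(np.median(d_b)) if len(d_b) else None

        iso_for_warp = resp.select_isolated_bouts(merged)
        if len(iso_for_warp):
            gmw = ens.build_grooming_matrix(spikes, iso_for_warp)
            traces = es.ensemble_traces(gmw, assignment)
            warped = es.timewarp_bout_activity(gmw, traces)
            avg = warped.bout_average()
            peaks = es.ensemble_peak_times(avg)
            pd.DataFrame(
                avg,
                index=pd.Index(range(assignment.n_clusters), name="cluster_id"),
            ).to_csv(out / "warped_ensemble_activity.csv", float_format="%.5f")
            n_boot = int(char_cfg.get("n_bootstrap_windows", 1000))
            n_sig = 0
            for c in range(assignment.n_clusters):
                members = assignment.members(c)
                null = es.bootstrap_null(
                    spikes.subset(members),
                    iso_for_warp.durations,
                    gmw.norm_min[members],
                    gmw.norm_max[members],
                    warped.target_len_bins,
                    n_windows=n_boot,
                    rng=rng_boot,
                )
                if es.is_significant_ensemble(avg[c], null):
                    n_sig += 1
            char.update(
                {
                    "target_len_bins": warped.target_len_bins,
                    "peak_bins": peaks,
                    "n_significant_ensembles": n_sig,
                }
            )
        report["characterization"] = char

    # --- trajectories --------------------------------------------------
    k = int((config.get("trajectories") or {}).get("k", 3))
    inputs = traj.split_trajectory_inputs(spikes, merged, assignment)
    traj_report = {}
    for mode, mat in (
        ("all_units", inputs.all_units),
        ("clustered_units", inputs.clustered_units),
        ("unclustered_units", inputs.unclustered_units),
        ("ensemble_means", inputs.ensemble_means),
    ):
        if min(mat.shape) < k:
            traj_report[mode] = {"skipped": "matrix smaller than k"}
            continue
        factors = traj.nmf_trajectories(
            mat, k=k, bout_segmentation=inputs.bout_segmentation
        )
        pd.DataFrame(factors.basis).to_csv(
            out / f"nmf_basis_{mode}.csv", index=False, float_format="%.5f"
        )
        pd.DataFrame(factors.scores.T).to_csv(
            out / f"nmf_scores_{mode}.csv", index=False, float_format="%.5f"
        )
        traj_report[mode] = {
            "relative_reconstruction_error": factors.reconstruction_error,
            "n_iterations": len(factors.loss_history) - 1,
            "converged": factors.converged,
        }
    report["trajectories"] = traj_report
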