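"""End-to-end orchestration of the two analyses.

``run_behavior_pipeline`` chains featurization -> discriminative SVM
ensemble -> balanced k-means state discovery -> epoch/transition
analytics for a set of two-fly sessions grouped by condition.
``run_persistence_pipeline`` chains baseline z-scoring -> ICA drift
removal -> 3-sigma response classification -> response-type clustering ->
decay profiles for a set of ROI traces.

Every random stage draws its seed from a master seed through
``numpy.random.SeedSequence`` spawning, so inserting a stage does not
shift the streams of the others, and the full run is deterministic given
(inputs, configs, master seed). Reports carry a configuration hash and
the package version.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, is_dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .calcium import (RoiTrace, ResponseWindows, baseline_and_zscore,
                      classify_response, cluster_response_types,
                      decay_profile, ica_clean, DegenerateRoiError)
from .discriminative import EnsembleConfig, train_svm_ensemble
from .ethogram import epochs_from_labels, behavior_time_course, transition_matrix
from .kinematics import FEATURE_NAMES, Trajectory, compute_frame_features
from .stateclust import (ClusterConfig, occupancy_and_coverage,
                         run_clustering_repeats)


def _config_hash(*cfgs) -> str:
    payload = []
    for c in cfgs:
        if is_dataclass(c):
            payload.append({k: (v.tolist() if isinstance(v, np.ndarray)
                                else repr(v) if not isinstance(
                                    v, (int, float, str, bool, list, dict,
                                        tuple, type(None))) else v)
                            for k, v in asdict(c).items()})
        else:
            payload.append(repr(c))
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=repr).encode()
    ).hexdigest()[:16]


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def run_behavior_pipeline(
    sessions: Dict[str, Sequence[Trajectory]],
    ensemble_cfg: Optional[EnsembleConfig] = None,
    cluster_cfg: Optional[ClusterConfig] = None,
    seed: int = 0,
    top_n: int = 7,
    control_condition: str = "control",
    min_bout: int = 5,
) -> dict:
    """Behavioral-state discovery over sessions grouped by condition.

    Stages: per-frame featurization; SVM-ensemble selection of
    discriminative parameters (control vs all experimental conditions
    pooled); repeated condition-balanced k-means on the significant
    parameters (all 17 if none reach significance); occupancy/coverage;
    and epoch/transition/time-course statistics for the cluster most
    enriched in experimental conditions (frames assigned by nearest
    reference centroid).
    """
    ss = np.random.SeedSequence(seed)
    s_ens, s_clu = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(2)]

    try:
        frames, conds, session_ids, session_bounds = [], [], [], []
        pos = 0
        for cond, trajs in sessions.items():
            for si, traj in enumerate(trajs):
                f = compute_frame_features(traj)[FEATURE_NAMES]
                frames.append(f)
                conds.append(np.full(len(f), cond, dtype=object))
                session_ids.append((cond, si, pos, pos + len(f)))
                pos += len(f)
        features = pd.concat(frames, ignore_index=True)
        conditions = np.concatenate(conds)
    except Exception as e:
        raise StageError(f"featurize: {e}") from e

    try:
        ensemble_cfg = ensemble_cfg or EnsembleConfig()
        ensemble_cfg.seed = s_ens
        labels = np.where(conditions == control_condition,
                          "control", "experimental")
        ens = train_svm_ensemble(features.to_numpy(), labels, ensemble_cfg,
                                 feature_names=list(features.columns))
    except Exception as e:
        raise StageError(f"discriminative: {e}") from e

    try:
        cluster_cfg = cluster_cfg or ClusterConfig()
        cluster_cfg.seed = s_clu
        cluster_cfg.params = ens.significant or list(features.columns)
        repeats = run_clustering_repeats(features, conditions, cluster_cfg)
        matched = occupancy_and_coverage(repeats, top_n=top_n)
    except Exception as e:
        raise StageError(f"stateclust: {e}") from e

    try:
        # enrichment: mean occupancy in experimental minus control per cluster
        occ = matched.occupancy.copy()
        occ["group"] = np.where(occ["condition"] == control_condition,
                                "control", "experimental")
        mean_occ = (occ.groupby(["cluster", "group"])["probability"]
                    .mean().unstack(fill_value=0.0))
        if "experimental" in mean_occ and "control" in mean_occ:
            enrichment = mean_occ["experimental"] - mean_occ["control"]
        else:
            enrichment = mean_occ.iloc[:, 0] * 0.0
        focus_cluster = int(enrichment.idxmax())

        # assign every frame to its nearest reference centroid
        ref = repeats[matched.reference]
        xz = (features[cluster_cfg.params].to_numpy() - ref.z_mean) / ref.z_sd
        d2 = ((xz[:, None, :] - ref.centroids[None, :, :]) ** 2).sum(axis=2)
        frame_clusters = d2.argmin(axis=1)
        in_focus = frame_clusters == focus_cluster

        epoch_stats, courses = {}, {}
        labels_by_session: Dict[str, List[np.ndarray]] = {}
        for cond, si, a, b in session_ids:
            labels_by_session.setdefault(cond, []).append(in_focus[a:b])
        for cond, labs in labels_by_session.items():
            eps = [epochs_from_labels(l, min_bout=min_bout,
                                      state="focus", condition=cond)
                   for l in labs]
            epoch_stats[cond] = {
                "n_epochs": int(sum(len(e.intervals) for e in eps)),
                "mean_duration_s": float(np.mean(
                    np.concatenate([e.durations_s for e in eps])
                )) if any(len(e.intervals) for e in eps) else 0.0,
                "frame_fraction": float(np.mean(
                    [l.mean() for l in labs])),
            }
            fps = next(iter(sessions[cond])).fps
            t, p = behavior_time_course(labs, fps=fps)
            courses[cond] = {"time_s": t.tolist(), "probability": p.tolist()}
    except Exception as e:
        raise StageError(f"ethogram: {e}") from e

    return {
        "version": __version__,
        "config_hash": _config_hash(ensemble_cfg, cluster_cfg, seed),
        "significant_parameters": ens.significant,
        "mean_test_accuracy": float(ens.test_accuracy.mean()),
        "p_values": dict(zip(ens.feature_names, ens.p_values.tolist())),
        "coverage_top_n": matched.coverage,
        "top_n": matched.top_n,
        "occupancy": matched.occupancy,
        "cluster_enrichment": enrichment.to_dict(),
        "focus_cluster": focus_cluster,
        "epoch_stats": epoch_stats,
        "time_courses": courses,
    }


def run_persistence_pipeline(
    traces: Sequence[RoiTrace],
    seed: int = 0,
    use_ica: bool = True,
    threshold: float = 3.0,
    post_s: float = 300.0,
    split_type2: bool = False,
) -> dict:
    """Persistent-activity mapping over a set of ROI traces.

    Stages: ICA drift removal (optional), baseline z-scoring, 3-sigma
    transient/persistent classification, consensus response-type
    clustering of the responsive traces, and group decay profiles at
    0/3/6 min after stimulus offset.
    """
    ss = np.random.SeedSequence(seed)
    s_ica, s_clu = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(2)]

    per_roi = []
    z_rows, excluded = [], []
    for trace in traces:
        try:
            flags: List[str] = []
            signal = None
            if use_ica:
                signal, ica_flags = ica_clean(trace, seed=s_ica)
                flags += ica_flags
            stats, z, dff = baseline_and_zscore(trace, signal=signal)
            win = ResponseWindows.from_trace(
                z, trace.timebase, trace.stim_on, trace.stim_off, post_s)
            rc = classify_response(z, win, threshold)
            per_roi.append({
                "fly_id": trace.fly_id, "roi_id": trace.roi_id,
                "f0": stats.f0, "sigma0": stats.sigma0,
                "ft1": rc.ft1, "ft2": rc.ft2, "class": rc.label,
                "flags": ";".join(flags + rc.flags)})
            z_rows.append(z)
        except DegenerateRoiError as e:
            excluded.append({"fly_id": trace.fly_id, "roi_id": trace.roi_id,
                             "reason": str(e)})
        except Exception as e:
            raise StageError(f"classify(roi {trace.roi_id}): {e}") from e

    table = pd.DataFrame(per_roi)
    counts = {c: int((table["class"] == c).sum())
              for c in ("nonresponsive", "transient", "persistent")} \
        if len(table) else {"nonresponsive": 0, "transient": 0,
                            "persistent": 0}

    types = np.zeros(len(table), dtype=int)
    type_info: dict = {}
    responsive = table.index[table["class"] != "nonresponsive"].to_numpy() \
        if len(table) else np.array([], dtype=int)
    if len(responsive) >= 4:
        try:
            z_resp = np.stack([z_rows[i] for i in responsive])
            pers = (table.loc[responsive, "class"] == "persistent").to_numpy()
            t_lab, type_info = cluster_response_types(
                z_resp, pers, table.loc[responsive, "ft1"].to_numpy(),
                table.loc[responsive, "ft2"].to_numpy(),
                split_type2=split_type2, seed=s_clu)
            types[responsive] = t_lab
        except Exception as e:
            raise StageError(f"cluster_types: {e}") from e
    if len(table):
        table["response_type"] = types

    decay = None
    if len(responsive):
        t0 = traces[0].timebase
        decay = decay_profile(np.stack([z_rows[i] for i in responsive]),
                              t0, traces[0].stim_off)

    return {
        "version": __version__,
        "config_hash": _config_hash(seed, use_ica, threshold, post_s),
        "n_rois": len(traces),
        "n_excluded": len(excluded),
        "class_counts": counts,
        "per_roi": table,
        "type_info": type_info,
        "decay_profile": decay,
    }
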