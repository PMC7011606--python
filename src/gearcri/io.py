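"""File formats, annotation processing, and session-level metrics.

Plain-text formats shared by the pipeline stages:

* annotation CSV — one row per frame: ``frame`` (0-based, strictly
  increasing), ``label`` (action class or empty), ``visible_view_<v>``
  flags, optional ``event`` column with interaction events
  (``look``, ``move_toward``, ``ascend_complete``);
* feature table CSV — ``instance_id, view_id, label, f0..f{D-1}``;
* embedding matrix (``.npy``-free: whitespace text matrix) with a JSON
  sidecar manifest;
* episode CSV — ``timestamp_s, robot_action, child_state`` with ``TA``
  serializing the slashed state name;
* MDP model JSON — states, actions, counts, estimator settings, utilities
  and (optionally) a policy.

Parsers validate eagerly and name the offending row in errors.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from . import cri_mdp
from .cri_mdp import (
    ACTIONS,
    STATES,
    Episode,
    EpisodeRecord,
    Policy,
    TransitionCounts,
)
from .multiview_classify import ACTION_CLASSES, MultiViewActionInstance

INTERACTION_EVENTS = ("look", "move_toward", "ascend_complete")

PathLike = Union[str, Path]


# ---------------------------------------------------------------- annotations


def write_annotations(table: pd.DataFrame, path: PathLike) -> None:
    table.to_csv(path, index=False)


def read_annotations(path: PathLike, n_views: Optional[int] = None) -> pd.DataFrame:
    """Read and validate a per-frame annotation table."""
    df = pd.read_csv(path)
    if "frame" not in df.columns or "label" not in df.columns:
        raise ValueError(f"{path}: annotation CSV needs 'frame' and 'label' columns")
    frames = df["frame"].to_numpy()
    bad = np.nonzero(np.diff(frames) <= 0)[0]
    if bad.size:
        raise ValueError(
            f"{path}: frame indices must be strictly increasing (row {bad[0] + 2})"
        )
    for i, label in enumerate(df["label"]):
        if not _is_missing(label) and label not in ACTION_CLASSES:
            raise ValueError(f"{path}: unknown action label {label!r} (row {i + 2})")
    if "event" in df.columns:
        for i, ev in enumerate(df["event"]):
            if not _is_missing(ev) and ev not in INTERACTION_EVENTS:
                raise ValueError(f"{path}: unknown event {ev!r} (row {i + 2})")
    if n_views is not None:
        missing = [
            f"visible_view_{v}"
            for v in range(n_views)
            if f"visible_view_{v}" not in df.columns
        ]
        if missing:
            raise ValueError(f"{path}: missing visibility columns {missing}")
    return df


def _is_missing(value) -> bool:
    return value is None or (isinstance(value, float) and np.isnan(value)) or value == ""


def segment_instances(annotations: pd.DataFrame) -> list[tuple[str, int, int]]:
    """Run-length segmentation of per-frame labels into action instances.

    Maximal runs of one label become ``(label, start, end)`` with a
    half-open frame interval ``[start, end)``; unlabeled frames (and gaps
    in the frame index) break runs.
    """
    instances: list[tuple[str, int, int]] = []
    current: Optional[str] = None
    start = 0
    prev_frame: Optional[int] = None
    for frame, label in zip(annotations.get("frame", []), annotations.get("label", [])):
        frame = int(frame)
        if _is_missing(label):
            label = None
        contiguous = prev_frame is not None and frame == prev_frame + 1
        if label != current or not contiguous:
            if current is not None:
                instances.append((current, start, prev_frame + 1))
            current, start = label, frame
        prev_frame = frame
    if current is not None:
        instances.append((current, start, prev_frame + 1))
    return instances


def session_metrics(
    annotations: pd.DataFrame, trial_duration_s: float
) -> tuple[float, float, int]:
    """Interaction indicators from an annotated trial.

    Returns (looks per minute, moves toward the robot per minute,
    completed ascents as a raw count). The trial duration is in seconds;
    the free-play protocol's trials are 3 minutes.
    """
    if trial_duration_s <= 0:
        raise ValueError("trial duration must be positive")
    events = annotations["event"] if "event" in annotations.columns else []
    n = {ev: 0 for ev in INTERACTION_EVENTS}
    for ev in events:
        if not _is_missing(ev):
            n[ev] += 1
    minutes = trial_duration_s / 60.0
    return n["look"] / minutes, n["move_toward"] / minutes, n["ascend_complete"]


# ------------------------------------------------------------- feature tables


def write_feature_table(
    instances: Sequence[MultiViewActionInstance], path: PathLike
) -> None:
    rows = []
    for inst in instances:
        for v in inst.views:
            rows.append(
                {"instance_id": inst.instance_id, "view_id": v, "label": inst.label}
                | {f"f{i}": x for i, x in enumerate(inst.embeddings[v])}
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_feature_table(
    path: PathLike, n_views: Optional[int] = 5
) -> list[MultiViewActionInstance]:
    """Read per-view features back into labeled multi-view instances."""
    df = pd.read_csv(path)
    required = {"instance_id", "view_id", "label"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: feature table needs columns {sorted(required)}")
    feat_cols = [c for c in df.columns if c.startswith("f") and c[1:].isdigit()]
    feat_cols.sort(key=lambda c: int(c[1:]))
    if not feat_cols:
        raise ValueError(f"{path}: no feature columns f0..fN found")
    instances = []
    for iid, group in df.groupby("instance_id", sort=False):
        labels = set(group["label"])
        if len(labels) > 1:
            raise ValueError(f"{path}: instance {iid!r} has conflicting labels {labels}")
        label = labels.pop()
        embeddings = {}
        for _, row in group.iterrows():
            v = int(row["view_id"])
            if n_views is not None and not 0 <= v < n_views:
                raise ValueError(
                    f"{path}: view_id {v} out of range 0..{n_views - 1} "
                    f"for instance {iid!r}"
                )
            embeddings[v] = row[feat_cols].to_numpy(dtype=float)
        instances.append(
            MultiViewActionInstance(
                str(iid), embeddings, None if _is_missing(label) else str(label)
            )
        )
    return instances


def write_embedding_matrix(
    matrix: np.ndarray, manifest: list[dict], path: PathLike
) -> None:
    """Text matrix (rows = videos) with a JSON sidecar manifest."""
    path = Path(path)
    np.savetxt(path, np.atleast_2d(matrix))
    manifest_path = path.with_suffix(path.suffix + ".manifest.json")
    manifest_path.write_text(json.dumps(manifest, indent=1))


def read_embedding_matrix(path: PathLike) -> tuple[np.ndarray, list[dict]]:
    path = Path(path)
    matrix = np.atleast_2d(np.loadtxt(path))
    manifest_path = path.with_suffix(path.suffix + ".manifest.json")
    manifest = json.loads(manifest_path.read_text())
    if len(manifest) != len(matrix):
        raise ValueError(
            f"{path}: manifest has {len(manifest)} entries for {len(matrix)} rows"
        )
    return matrix, manifest


# ------------------------------------------------------------------ episodes

_STATE_TOKENS = {"T/A": "TA"}
_TOKEN_STATES = {"TA": "T/A"}


def write_episode(episode: Episode, path: PathLike) -> None:
    rows = [
        {
            "timestamp_s": r.timestamp_s,
            "robot_action": r.robot_action,
            "child_state": _STATE_TOKENS.get(r.child_state, r.child_state),
        }
        for r in episode.records
    ]
    df = pd.DataFrame(rows, columns=["timestamp_s", "robot_action", "child_state"])
    with open(path, "w") as fh:
        fh.write(f"# duration_s={episode.duration_s} start_state="
                 f"{_STATE_TOKENS.get(episode.start_state, episode.start_state)}\n")
        df.to_csv(fh, index=False)


def read_episode(path: PathLike, duration_s: Optional[float] = None) -> Episode:
    """Read an episode log CSV (header mandatory; 'TA' spells the T/A state)."""
    path = Path(path)
    start_state = "NL"
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            meta = dict(kv.split("=") for kv in first[1:].split())
            duration_s = float(meta.get("duration_s", duration_s or 0))
            start_state = _TOKEN_STATES.get(
                meta.get("start_state", "NL"), meta.get("start_state", "NL")
            )
            df = pd.read_csv(fh)
        else:
            fh.seek(0)
            df = pd.read_csv(fh)
    required = {"timestamp_s", "robot_action", "child_state"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: episode CSV needs columns {sorted(required)}")
    records = []
    for i, row in df.iterrows():
        action = str(row["robot_action"])
        token = str(row["child_state"])
        state = _TOKEN_STATES.get(token, token)
        if action not in ACTIONS:
            raise ValueError(f"{path}: unknown robot action {action!r} (row {i + 2})")
        if state not in STATES:
            raise ValueError(f"{path}: unknown child state {token!r} (row {i + 2})")
        records.append(EpisodeRecord(float(row["timestamp_s"]), action, state))
    if duration_s is None or duration_s <= 0:
        duration_s = records[-1].timestamp_s if records else 0.0
    return Episode(records, duration_s, start_state=start_state)


# -------------------------------------------------------------- model files


def write_mdp_model(
    path: PathLike,
    counts: TransitionCounts,
    estimator: str,
    lam: Optional[float] = None,
    gamma: float = 0.95,
    utilities: Sequence[float] = cri_mdp.DEFAULT_UTILITIES,
    policy: Optional[Policy] = None,
) -> None:
    payload = {
        "states": list(STATES),
        "actions": list(ACTIONS),
        "counts": counts.counts.tolist(),
        "estimator": estimator,
        "lambda": lam,
        "gamma": gamma,
        "utilities": list(utilities),
        "policy": dict(policy.mapping) if policy else None,
        "policy_provenance": policy.provenance if policy else None,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_mdp_model(path: PathLike) -> dict:
    payload = json.loads(Path(path).read_text())
    if payload.get("states") != list(STATES) or payload.get("actions") != list(ACTIONS):
        raise ValueError(f"{path}: model state/action sets do not match this MDP")
    payload["counts"] = TransitionCounts(np.array(payload["counts"]))
    if payload.get("policy"):
        payload["policy"] = Policy(
            payload["policy"], provenance=payload.get("policy_provenance") or "custom"
        )
    return payload


def write_policy(policy: Policy, path: PathLike) -> None:
    Path(path).write_text(
        json.dumps({"mapping": dict(policy.mapping), "provenance": policy.provenance})
    )


def read_policy(path: PathLike) -> Policy:
    payload = json.loads(Path(path).read_text())
    return Policy(payload["mapping"], provenance=payload.get("provenance", "custom"))


# ------------------------------------------------------------------- config


@dataclasses.dataclass
class RunConfig:
    """Resolved configuration for a pipeline run; unknown keys are rejected."""

    trajectory_length: int = 15
    sampling_stride: int = 5
    min_displacement: float = 1.0
    patch_size: int = 16
    codebook_k: int = 64
    projected_dim: Optional[int] = None
    svm_c: float = 1.0
    n_splits: int = 5
    train_frac: float = 0.8
    smoothing_lambda: float = 1.0
    gamma: float = 0.95
    tol: float = 1e-8
    seed: int = 0

    @classmethod
    def from_file(cls, path: PathLike) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
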