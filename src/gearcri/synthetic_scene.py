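"""Seeded synthetic multi-view scenes for the classification stack.

The study's videos of children cannot be shared, so this module provides
two substitutes:

* :func:`render_session` — renders small grayscale multi-view clips of a
  single child agent performing one of four motion archetypes per scripted
  segment, with per-view occlusions and optional distractor agents, plus a
  per-frame annotation table. The archetypes mirror how the four actions
  differ kinematically: crawling and walking are translating gaits at low
  and tall body profiles, while sitting and standing are near-static
  postures whose residual sway is deliberately subtle — so, as with real
  trajectory features, the static classes are the hard pair.
* :func:`make_feature_bags` — skips rendering and draws per-view feature
  vectors directly from class-specific Gaussians, with occluded views
  replaced by draws from a shared background distribution. This is the
  fast benchmark for the SVM-MV / MI-SVM comparison: label transfer puts
  background views into training with class labels, which is exactly the
  failure mode multiple-instance learning avoids.

All outputs are reproducible from the script/seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd

from .multiview_classify import ACTION_CLASSES, MultiViewActionInstance
from .video_features import VideoClip

# per-class instance counts of the recorded sessions' annotation harvest,
# used as the default class proportions of the synthetic benchmark
DEFAULT_CLASS_COUNTS: dict[str, int] = {
    "crawling": 166,
    "sitting": 228,
    "standing": 406,
    "walking": 248,
}


@dataclass
class SceneScript:
    """Script for one rendered session.

    ``segments`` is a sequence of ``(action_class, duration_frames)``
    pairs; every segment must be at least ``min_segment_frames`` long so
    that trajectory extraction (default length 15) can operate on it.
    """

    segments: Sequence[tuple[str, int]]
    n_views: int = 5
    fps: float = 15.0
    occlusion_rate: float = 0.0
    n_distractors: int = 0
    seed: int = 0
    frame_height: int = 48
    frame_width: int = 64
    min_segment_frames: int = 15

    def __post_init__(self) -> None:
        if self.n_views < 1:
            raise ValueError("need at least one view")
        if not 0 <= self.occlusion_rate < 1:
            raise ValueError("occlusion_rate must lie in [0, 1)")
        for label, dur in self.segments:
            if label not in ACTION_CLASSES:
                raise ValueError(f"unknown action class {label!r}")
            if dur < self.min_segment_frames:
                raise ValueError(
                    f"segment ({label!r}, {dur}) shorter than the minimum "
                    f"{self.min_segment_frames} frames"
                )

    @property
    def n_frames(self) -> int:
        return sum(d for _, d in self.segments)


# archetype kinematics: (width, height, elevation above ground,
#                        horiz amplitude, horiz period, vert amplitude, vert period)
_ARCHETYPES = {
    "crawling": dict(w=7.0, h=3.5, lift=0.0, ax=14.0, px=56.0, ay=1.0, py=14.0),
    "sitting": dict(w=4.5, h=4.5, lift=0.0, ax=1.5, px=30.0, ay=0.5, py=30.0),
    "standing": dict(w=3.0, h=8.0, lift=0.0, ax=0.5, px=24.0, ay=1.5, py=16.0),
    "walking": dict(w=3.0, h=8.0, lift=0.0, ax=16.0, px=48.0, ay=1.5, py=12.0),
}


def _agent_position(label: str, t: int, x_center: float, ground_y: float):
    a = _ARCHETYPES[label]
    x = x_center + a["ax"] * np.sin(2 * np.pi * t / a["px"])
    y = ground_y - a["h"] - a["lift"] - a["ay"] * (0.5 + 0.5 * np.sin(2 * np.pi * t / a["py"]))
    return x, y, a["w"], a["h"]


def _draw_blob(img: np.ndarray, x: float, y: float, w: float, h: float, peak: float) -> None:
    """Additively draw a soft elliptical blob centered at (x, y)."""
    H, W = img.shape
    yy, xx = np.mgrid[0:H, 0:W]
    d2 = ((xx - x) / w) ** 2 + ((yy - y) / h) ** 2
    img += peak * np.exp(-0.5 * d2 * 4.0)


def render_session(script: SceneScript) -> tuple[list[VideoClip], pd.DataFrame]:
    """Render one session: frame-synchronized clips per view + annotations.

    The child agent follows each segment's archetype; with probability
    ``occlusion_rate`` a (view, segment) pair is occluded — the child is
    hidden behind a static mask and the view's visibility flag goes false
    for those frames. Distractor agents re-use archetype motions at other
    positions in every view. The annotation table has one row per frame:
    ``frame``, ``label``, and ``visible_view_<v>`` flags.
    """
    rng = np.random.default_rng(script.seed)
    H, W = script.frame_height, script.frame_width
    T = script.n_frames
    ground_y = H - 6.0
    child_x = W / 2.0

    # static per-view background texture (static content yields no trajectories)
    backgrounds = [
        0.15 + 0.05 * rng.random((H, W)) for _ in range(script.n_views)
    ]
    view_shift = [3.0 * (v - (script.n_views - 1) / 2.0) for v in range(script.n_views)]

    occluded = rng.random((script.n_views, len(script.segments))) < script.occlusion_rate

    distractors = []
    for _ in range(script.n_distractors):
        distractors.append(
            {
                "labels": [
                    ACTION_CLASSES[rng.integers(len(ACTION_CLASSES))]
                    for _ in script.segments
                ],
                "x": float(rng.uniform(8, W - 8)),
                "phase": int(rng.integers(0, 60)),
            }
        )

    frames = np.zeros((script.n_views, T, H, W))
    rows = []
    t0 = 0
    for seg_idx, (label, dur) in enumerate(script.segments):
        for dt in range(dur):
            t = t0 + dt
            cx, cy, cw, ch = _agent_position(label, dt, child_x, ground_y)
            visible = []
            for v in range(script.n_views):
                img = backgrounds[v].copy()
                shift = view_shift[v]
                for d in distractors:
                    dl = d["labels"][seg_idx]
                    dx, dy, dw, dh = _agent_position(
                        dl, dt + d["phase"], d["x"], ground_y
                    )
                    _draw_blob(img, dx + shift, dy, dw, dh, 0.5)
                if occluded[v, seg_idx]:
                    # static occluder mask over the child's neighborhood
                    r0 = int(max(cy - 14, 0))
                    c0 = int(max(child_x - 18 + shift, 0))
                    img[r0 : min(r0 + 28, H), c0 : min(c0 + 36, W)] = 0.35
                    visible.append(False)
                else:
                    _draw_blob(img, cx + shift, cy, cw, ch, 1.0)
                    visible.append(True)
                frames[v, t] = img
            rows.append(
                {"frame": t, "label": label}
                | {f"visible_view_{v}": visible[v] for v in range(script.n_views)}
            )
        t0 += dur
    clips = [
        VideoClip(np.clip(frames[v], 0.0, 1.0), fps=script.fps, view_id=v)
        for v in range(script.n_views)
    ]
    return clips, pd.DataFrame(rows)


def make_feature_bags(
    n_per_class: Union[int, Mapping[str, int], None] = None,
    dim: int = 20,
    n_views: int = 5,
    occlusion_rate: float = 0.4,
    class_separation: float = 3.0,
    noise_scale: float = 1.0,
    seed: int = 0,
) -> list[MultiViewActionInstance]:
    """Draw labeled multi-view bags directly in feature space.

    Per class, a mean vector of norm ``class_separation`` is drawn once;
    each informative view is that mean plus isotropic noise. With
    probability ``occlusion_rate`` a view is *occluded*: drawn from the
    shared zero-mean background distribution instead, and recorded in the
    instance's ``info["informative_views"]`` metadata. ``n_per_class``
    defaults to the benchmark's class counts
    (crawling 166, sitting 228, standing 406, walking 248).
    """
    if class_separation <= 0:
        raise ValueError("class_separation must be positive")
    if n_per_class is None:
        counts = dict(DEFAULT_CLASS_COUNTS)
    elif isinstance(n_per_class, int):
        if n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        counts = {c: n_per_class for c in ACTION_CLASSES}
    else:
        counts = {c: int(n) for c, n in n_per_class.items()}
        if any(n < 1 for n in counts.values()):
            raise ValueError("every class needs at least one instance")
    rng = np.random.default_rng(seed)
    means = {}
    for c in ACTION_CLASSES:
        if c in counts:
            v = rng.standard_normal(dim)
            means[c] = class_separation * v / np.linalg.norm(v)
    instances = []
    for c in sorted(counts, key=lambda c: ACTION_CLASSES.index(c)):
        for i in range(counts[c]):
            embeddings = {}
            informative = []
            for v in range(n_views):
                if rng.random() < occlusion_rate:
                    embeddings[v] = noise_scale * rng.standard_normal(dim)
                else:
                    embeddings[v] = means[c] + noise_scale * rng.standard_normal(dim)
                    informative.append(v)
            instances.append(
                MultiViewActionInstance(
                    instance_id=f"{c}_{i:04d}",
                    embeddings=embeddings,
                    label=c,
                    info={"informative_views": informative},
                )
            )
    return instances
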