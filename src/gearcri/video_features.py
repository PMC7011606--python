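"""Fixed-length video embeddings via dense trajectories and Fisher vectors.

A clip is represented by (1) extracting spatially dense, temporally short
trajectories that follow moving points for about a second, (2) attaching to
each trajectory a descriptor capturing its shape together with the motion
and appearance of a small spatio-temporal tube around it, and (3)
aggregating the descriptor set into one fixed-length vector with a Fisher
encoding against a Gaussian-mixture codebook fitted on training
descriptors.

The extractor is a simplified dense-trajectory scheme: points seeded on a
regular grid wherever no track is active, advected by median-filtered dense
optical flow, and discarded when (near-)static. Camera-motion compensation
is omitted — the camera network this pipeline targets is static.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from skimage.registration import optical_flow_ilk
from sklearn.decomposition import PCA
from sklearn.mixture import GaussianMixture

logger = logging.getLogger(__name__)

N_ORIENT_BINS = 8
TUBE_SPATIAL = 2  # 2x2 spatial cells
TUBE_TEMPORAL = 3  # 3 temporal cells


@dataclass
class VideoClip:
    """An ordered frame sequence from one camera view.

    ``frames`` may be (T, H, W) grayscale or (T, H, W, 3) RGB; internally
    everything runs on float grayscale. Optical flow between consecutive
    frames is computed lazily and cached on the clip.
    """

    frames: np.ndarray
    fps: float = 15.0
    view_id: int = 0
    frame_offset: int = 0
    _flow: Optional[np.ndarray] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim not in (3, 4) or len(self.frames) == 0:
            raise ValueError("frames must be a non-empty (T, H, W[, 3]) array")
        if self.fps <= 0:
            raise ValueError("fps must be positive")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    def gray(self) -> np.ndarray:
        """Frames as float grayscale in [0, 1] (ITU-R 601 luma for RGB)."""
        f = self.frames.astype(np.float64)
        if f.ndim == 4:
            f = f @ np.array([0.299, 0.587, 0.114])
        if np.issubdtype(self.frames.dtype, np.integer):
            f = f / 255.0
        return f

    def flow(self) -> np.ndarray:
        """Dense flow fields, shape (T-1, 2, H, W) in (row, col) order.

        ``flow()[t]`` maps a pixel of frame ``t`` to its position in frame
        ``t + 1`` via ``new = old + flow``. Each component is median-filtered
        (3x3) to suppress flow outliers before points are advected.
        """
        if self._flow is None:
            g = self.gray()
            flows = np.empty((len(g) - 1, 2, *g[0].shape)) if len(g) > 1 else np.empty(
                (0, 2, *g[0].shape)
            )
            for t in range(len(g) - 1):
                f = optical_flow_ilk(g[t], g[t + 1], radius=5)
                flows[t, 0] = ndimage.median_filter(f[0], size=3)
                flows[t, 1] = ndimage.median_filter(f[1], size=3)
            self._flow = flows
        return self._flow


@dataclass(frozen=True)
class Trajectory:
    """One tracked point: ``points`` is (L, 2) in (x, y) image coordinates."""

    points: np.ndarray
    start_frame: int

    @property
    def length(self) -> int:
        return len(self.points)

    def displacements(self) -> np.ndarray:
        return np.diff(self.points, axis=0)

    def total_displacement(self) -> float:
        return float(np.linalg.norm(self.displacements(), axis=1).sum())


@dataclass(frozen=True)
class TrajectoryDescriptor:
    """Shape, motion and appearance blocks for one trajectory.

    ``shape`` is the displacement sequence L1-normalized by the total
    displacement magnitude; ``motion`` holds orientation histograms of
    optical flow and ``appearance`` orientation histograms of image
    gradients, both over a 2x2x3-cell spatio-temporal tube and each
    L2-normalized (blocks with no signal stay zero).
    """

    shape: np.ndarray
    motion: np.ndarray
    appearance: np.ndarray

    @property
    def vector(self) -> np.ndarray:
        return np.concatenate([self.shape, self.motion, self.appearance])


def extract_trajectories(
    clip: VideoClip,
    sampling_stride: int = 5,
    L: int = 15,
    min_displacement: float = 1.0,
) -> list[Trajectory]:
    """Track densely seeded points for exactly ``L`` frames each.

    Every frame, grid cells of size ``sampling_stride`` that contain no
    active track are re-seeded at their center. Points are advected by the
    clip's median-filtered dense flow; tracks leaving the image are dropped,
    and finished tracks whose total displacement is below
    ``min_displacement`` (static points) are discarded.
    """
    if L < 2:
        raise ValueError("trajectory length L must be at least 2")
    T = len(clip)
    H, W = clip.shape
    if T < L:
        logger.warning(
            "clip has %d frames, shorter than trajectory length %d; "
            "no trajectories extracted",
            T,
            L,
        )
        return []
    flows = clip.flow()
    done: list[Trajectory] = []
    # active tracks: list of (start_frame, [points...]) with current point last
    active: list[list] = []
    n_cells_y = int(np.ceil(H / sampling_stride))
    n_cells_x = int(np.ceil(W / sampling_stride))
    for t in range(T):
        # occupancy of the seeding grid by current track points
        occupied = np.zeros((n_cells_y, n_cells_x), dtype=bool)
        for trk in active:
            x, y = trk[-1]
            occupied[int(y) // sampling_stride, int(x) // sampling_stride] = True
        if t <= T - L:  # only seed tracks that can reach full length
            for cy in range(n_cells_y):
                for cx in range(n_cells_x):
                    if occupied[cy, cx]:
                        continue
                    x = min(cx * sampling_stride + sampling_stride / 2, W - 1)
                    y = min(cy * sampling_stride + sampling_stride / 2, H - 1)
                    active.append([t, (x, y)])
        if t == T - 1:
            break
        flow = flows[t]
        survivors = []
        for trk in active:
            x, y = trk[-1]
            r, c = int(round(y)), int(round(x))
            r = min(max(r, 0), H - 1)
            c = min(max(c, 0), W - 1)
            nx = x + flow[1, r, c]
            ny = y + flow[0, r, c]
            if not (0 <= nx <= W - 1 and 0 <= ny <= H - 1):
                continue  # track left the image
            trk.append((nx, ny))
            if len(trk) - 1 == L:  # trk[0] is the start frame
                traj = Trajectory(np.array(trk[1:]), start_frame=trk[0])
                if traj.total_displacement() >= min_displacement:
                    done.append(traj)
            else:
                survivors.append(trk)
        active = survivors
    return done


def _orientation_histogram(dx: np.ndarray, dy: np.ndarray) -> np.ndarray:
    """Magnitude-weighted 8-bin orientation histogram of a vector field."""
    mag = np.hypot(dx, dy)
    ang = np.mod(np.arctan2(dy, dx), 2 * np.pi)
    bins = np.minimum((ang / (2 * np.pi / N_ORIENT_BINS)).astype(int), N_ORIENT_BINS - 1)
    hist = np.zeros(N_ORIENT_BINS)
    np.add.at(hist, bins.ravel(), mag.ravel())
    return hist


def _tube_cells(
    x: float, y: float, H: int, W: int, patch: int
) -> list[tuple[slice, slice]]:
    """2x2 spatial cells of a patch centered at (x, y), clamped to the image."""
    half = patch // 2
    r0 = int(round(y)) - half
    c0 = int(round(x)) - half
    cells = []
    step = patch // TUBE_SPATIAL
    for i in range(TUBE_SPATIAL):
        for j in range(TUBE_SPATIAL):
            rs = slice(max(r0 + i * step, 0), min(max(r0 + (i + 1) * step, 0), H))
            cs = slice(max(c0 + j * step, 0), min(max(c0 + (j + 1) * step, 0), W))
            cells.append((rs, cs))
    return cells


def compute_descriptors(
    trajectories: Sequence[Trajectory],
    clip: VideoClip,
    patch_size: int = 16,
) -> list[TrajectoryDescriptor]:
    """One descriptor per trajectory: shape + tube motion + tube appearance.

    The tube is a ``patch_size`` x ``patch_size`` window following the
    trajectory, divided into 2x2 spatial cells and 3 temporal cells; flow
    and gradient orientation histograms are accumulated per cell. Windows
    reaching past the image are clamped to its border.
    """
    gray = clip.gray()
    flows = clip.flow()
    H, W = clip.shape
    grads_y, grads_x = {}, {}

    def grad(t: int) -> tuple[np.ndarray, np.ndarray]:
        if t not in grads_x:
            gy, gx = np.gradient(gray[t])
            grads_y[t], grads_x[t] = gy, gx
        return grads_y[t], grads_x[t]

    descriptors = []
    for traj in trajectories:
        L = traj.length
        disp = traj.displacements()
        total = np.linalg.norm(disp, axis=1).sum()
        shape = (disp / total).ravel() if total > 0 else np.zeros(2 * (L - 1))
        n_steps = L - 1
        cells_per_t = TUBE_SPATIAL * TUBE_SPATIAL
        motion = np.zeros((TUBE_TEMPORAL, cells_per_t, N_ORIENT_BINS))
        appearance = np.zeros_like(motion)
        for i in range(n_steps):
            tcell = min(i * TUBE_TEMPORAL // n_steps, TUBE_TEMPORAL - 1)
            t = traj.start_frame + i
            x, y = traj.points[i]
            gy, gx = grad(t)
            fl = flows[t]
            for ci, (rs, cs) in enumerate(_tube_cells(x, y, H, W, patch_size)):
                motion[tcell, ci] += _orientation_histogram(fl[1, rs, cs], fl[0, rs, cs])
                appearance[tcell, ci] += _orientation_histogram(gx[rs, cs], gy[rs, cs])
        motion = motion.ravel()
        appearance = appearance.ravel()
        for block in (motion, appearance):
            norm = np.linalg.norm(block)
            if norm > 1e-12:
                block /= norm
        descriptors.append(TrajectoryDescriptor(shape, motion, appearance))
    return descriptors


@dataclass
class FisherCodebook:
    """Gaussian-mixture codebook (diagonal covariances) over projected descriptors."""

    n_components: int
    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    projection: PCA
    seed: int

    def __post_init__(self) -> None:
        if not np.isclose(self.weights.sum(), 1.0, atol=1e-9):
            raise ValueError("mixture weights must sum to 1")
        if (self.weights <= 0).any() or (self.variances <= 0).any():
            raise ValueError("weights and variances must be strictly positive")

    @property
    def dim(self) -> int:
        return self.means.shape[1]

    def project(self, X: np.ndarray) -> np.ndarray:
        return self.projection.transform(X)


def fit_codebook(
    descriptor_sample: Sequence[TrajectoryDescriptor] | np.ndarray,
    K: int = 64,
    projected_dim: Optional[int] = None,
    seed: int = 0,
    reg_covar: float = 1e-3,
) -> FisherCodebook:
    """Fit the Fisher codebook on a training descriptor sample.

    Descriptors are first reduced by PCA (default: half their dimension),
    then a K-component diagonal Gaussian mixture is fitted. ``reg_covar``
    floors the per-dimension variances: without it, near-degenerate
    descriptor clusters get vanishing variances and their components
    dominate the Fisher encoding. If the sample contains fewer distinct
    descriptors than K, K is reduced with a warning. The fit is
    reproducible from ``seed``.
    """
    if isinstance(descriptor_sample, np.ndarray):
        X = np.asarray(descriptor_sample, dtype=float)
    else:
        if len(descriptor_sample) == 0:
            raise ValueError("descriptor sample must be non-empty")
        X = np.stack([d.vector for d in descriptor_sample])
    if X.ndim != 2 or len(X) == 0:
        raise ValueError("descriptor sample must be a non-empty 2-D array")
    n_unique = len(np.unique(X, axis=0))
    if n_unique < K:
        warnings.warn(
            f"only {n_unique} distinct descriptors for K={K} components; "
            f"reducing K to {n_unique}",
            stacklevel=2,
        )
        K = n_unique
    if projected_dim is None:
        projected_dim = max(1, X.shape[1] // 2)
    projected_dim = min(projected_dim, X.shape[1], len(X))
    pca = PCA(n_components=projected_dim, svd_solver="full", random_state=seed)
    Z = pca.fit_transform(X)
    gmm = GaussianMixture(
        n_components=K,
        covariance_type="diag",
        random_state=seed,
        reg_covar=reg_covar,
        max_iter=300,
    )
    gmm.fit(Z)
    return FisherCodebook(
        n_components=K,
        weights=gmm.weights_,
        means=gmm.means_,
        variances=gmm.covariances_,
        projection=pca,
        seed=seed,
    )


@dataclass
class VideoEmbedding:
    """Fisher-vector embedding of one video from one camera view.

    ``empty`` flags videos with no usable trajectories (e.g. a fully
    occluded view); their vector is all zeros and is *not* unit-norm.
    """

    vector: np.ndarray
    view_id: int = 0
    instance_id: str = ""
    empty: bool = False


def _posteriors(Z: np.ndarray, cb: FisherCodebook) -> np.ndarray:
    # log N(z | mu_k, diag sigma2_k) + log w_k, normalized across k
    diff = Z[:, None, :] - cb.means[None, :, :]
    log_det = np.log(cb.variances).sum(axis=1)
    maha = (diff**2 / cb.variances[None, :, :]).sum(axis=2)
    log_p = (
        np.log(cb.weights)[None, :]
        - 0.5 * (log_det[None, :] + maha + cb.dim * np.log(2 * np.pi))
    )
    log_p -= log_p.max(axis=1, keepdims=True)
    q = np.exp(log_p)
    return q / q.sum(axis=1, keepdims=True)


def encode_fisher(
    descriptors: Sequence[TrajectoryDescriptor] | np.ndarray,
    codebook: FisherCodebook,
    view_id: int = 0,
    instance_id: str = "",
) -> VideoEmbedding:
    """Fisher-vector encoding of one video's descriptor set.

    Concatenates per-component first-order (mean-deviation) and
    second-order (variance-deviation) blocks, averaged over descriptors,
    then applies signed square-root and L2 normalization. An empty
    descriptor set yields a flagged all-zero embedding so that downstream
    multi-view learning can treat the view as uninformative.
    """
    K, D = codebook.n_components, codebook.dim
    if isinstance(descriptors, np.ndarray):
        X = descriptors
    elif len(descriptors) == 0:
        X = np.empty((0, 1))
    else:
        X = np.stack([d.vector for d in descriptors])
    if len(X) == 0:
        return VideoEmbedding(
            np.zeros(2 * K * D), view_id=view_id, instance_id=instance_id, empty=True
        )
    Z = codebook.project(X)
    q = _posteriors(Z, codebook)  # (N, K)
    sigma = np.sqrt(codebook.variances)  # (K, D)
    u = (Z[:, None, :] - codebook.means[None, :, :]) / sigma[None, :, :]
    N = len(Z)
    w = codebook.weights
    phi1 = np.einsum("nk,nkd->kd", q, u) / (N * np.sqrt(w)[:, None])
    phi2 = np.einsum("nk,nkd->kd", q, u**2 - 1.0) / (N * np.sqrt(2 * w)[:, None])
    fv = np.concatenate([phi1.ravel(), phi2.ravel()])
    fv = np.sign(fv) * np.sqrt(np.abs(fv))
    norm = np.linalg.norm(fv)
    if norm > 1e-12:
        fv /= norm
    return VideoEmbedding(fv, view_id=view_id, instance_id=instance_id)


def embed_clip(
    clip: VideoClip,
    codebook: FisherCodebook,
    instance_id: str = "",
    sampling_stride: int = 5,
    L: int = 15,
    min_displacement: float = 1.0,
    patch_size: int = 16,
) -> VideoEmbedding:
    """Full pipeline for one clip: trajectories, descriptors, Fisher vector."""
    trajs = extract_trajectories(clip, sampling_stride, L, min_displacement)
    descs = compute_descriptors(trajs, clip, patch_size)
    return encode_fisher(descs, codebook, view_id=clip.view_id, instance_id=instance_id)
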