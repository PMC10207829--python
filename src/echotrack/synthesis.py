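"""Synthetic ultrasound-like scenes with known ground truth.

Real B-mode recordings of the upper limb are not redistributable, so this
module generates the test substrate: speckle-textured frames in which a
small number of bright features move along smooth, known trajectories.
Four motion presets emulate the study conditions — ``walk`` (fast motion
with periodic impact transients), ``mvc`` (small fast motion), ``reach``
(slow large excursions) and ``rest`` (near-static) — at 60 frames/s.

The generator also provides "drifting trackers": synthetic trackers that
return ground truth plus a deterministic bias and/or a seeded random walk.
They isolate the drift phenomenon from image content, so the correction
algorithms can be tested against an exactly known error process.

Everything is bit-reproducible given the scene seed.  The speckle model
(smoothed uniform field with a Rayleigh multiplicative component) mimics
the granular appearance of B-mode texture; it does not model acoustics,
point-spread functions or scan conversion.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from .core import LabelSet, Trajectory, VideoSequence
from .evaluation import mirror_trajectory

__all__ = [
    "MotionProfile",
    "SceneSpec",
    "make_trajectory",
    "render_video",
    "speckle_frame",
    "make_drifting_tracker",
    "DriftingTracker",
    "drifting_tracker_factory",
    "make_labelset",
]

#: Movement presets: (amplitude_px, frequency_hz, impact_fraction).
_PRESETS = {
    "walk": (15.0, 1.5, 0.5),
    "mvc": (5.0, 2.0, 0.0),
    "reach": (30.0, 0.1, 0.0),
    "rest": (1.0, 0.2, 0.0),
}


@dataclasses.dataclass
class MotionProfile:
    """A movement regime for ground-truth trajectories.

    ``amplitude_px`` is the sinusoidal half-excursion, ``frequency_hz`` its
    rate, and ``impact_fraction`` the relative size of the sharp periodic
    transients superimposed for impact-type motion (walking).
    """

    kind: str = "rest"
    amplitude_px: float = 1.0
    frequency_hz: float = 0.2
    impact_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude_px < 0 or self.frequency_hz < 0:
            raise ValueError("amplitude and frequency must be non-negative")
        if not 0.0 <= self.impact_fraction <= 1.0:
            raise ValueError("impact_fraction must lie in [0, 1]")

    @classmethod
    def preset(cls, kind: str) -> "MotionProfile":
        if kind not in _PRESETS:
            raise ValueError(f"unknown motion kind {kind!r}; choose from {sorted(_PRESETS)}")
        a, f, imp = _PRESETS[kind]
        return cls(kind=kind, amplitude_px=a, frequency_hz=f, impact_fraction=imp)


@dataclasses.dataclass
class SceneSpec:
    """Parameters of a synthetic scene (fully determined by ``seed``)."""

    frame_shape: tuple[int, int] = (400, 400)
    n_points: int = 3
    speckle_grain_px: float = 3.0
    noise_sigma: float = 0.03
    frame_rate_hz: float = 60.0
    n_frames: int = 600
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_points < 1:
            raise ValueError("n_points must be >= 1")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.speckle_grain_px <= 0:
            raise ValueError("speckle_grain_px must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")


#: Points never approach the frame border closer than this (room for
#: tracker windows).
EDGE_MARGIN_PX = 30.0


def make_trajectory(spec: SceneSpec, profile: MotionProfile) -> Trajectory:
    """Smooth ground-truth paths for ``spec.n_points`` points.

    Each point follows a low-frequency sinusoid of the profile's amplitude
    (full amplitude along x, 60% along y, independent random phases); the
    ``walk`` regime adds periodic raised-cosine impact transients of
    relative size ``impact_fraction``.  Paths keep ``EDGE_MARGIN_PX`` away
    from the borders; an amplitude too large for the frame is rejected.
    """
    h, w = spec.frame_shape
    a = profile.amplitude_px
    margin = EDGE_MARGIN_PX + a * (1.0 + profile.impact_fraction)
    if 2 * margin >= min(h, w):
        raise ValueError(
            f"amplitude {a} px too large for frame {spec.frame_shape} "
            f"(needs {2 * margin:.0f} px of clearance)"
        )
    rng = np.random.default_rng(spec.seed)
    t = np.arange(spec.n_frames) / spec.frame_rate_hz
    base_x = rng.uniform(margin, w - 1 - margin, spec.n_points)
    base_y = rng.uniform(margin, h - 1 - margin, spec.n_points)
    phase_x = rng.uniform(0, 2 * np.pi, spec.n_points)
    phase_y = rng.uniform(0, 2 * np.pi, spec.n_points)

    omega = 2 * np.pi * profile.frequency_hz
    x = base_x[None, :] + a * np.sin(omega * t[:, None] + phase_x[None, :])
    y = base_y[None, :] + 0.6 * a * np.sin(omega * t[:, None] + phase_y[None, :])

    if profile.impact_fraction > 0 and profile.frequency_hz > 0:
        # raised-cosine pulses of ~100 ms at each impact, shared by all points
        period = 1.0 / profile.frequency_hz
        phase = np.mod(t, period)
        width = min(0.1, period / 2)
        pulse = np.where(
            phase < width, 0.5 * (1 - np.cos(2 * np.pi * phase / width)), 0.0
        )
        y = y + a * profile.impact_fraction * pulse[:, None]

    positions = np.stack([x, y], axis=-1)
    return Trajectory(positions, frame_rate_hz=spec.frame_rate_hz)


def speckle_frame(
    shape: tuple[int, int], grain_px: float, seed: int
) -> np.ndarray:
    """One static speckle texture: smoothed uniform noise in [0, 1]."""
    rng = np.random.default_rng(seed)
    field = ndimage.gaussian_filter(rng.uniform(size=shape), sigma=grain_px)
    lo, hi = field.min(), field.max()
    return (field - lo) / (hi - lo) if hi > lo else np.full(shape, 0.5)


def render_video(spec: SceneSpec, truth: Trajectory) -> VideoSequence:
    """Render a speckle video whose features follow ``truth``.

    Each frame is a fixed speckle texture advected with the scene's mean
    ground-truth motion, plus a bright Gaussian blob centred on each true
    point, degraded by Rayleigh-distributed multiplicative speckle and
    additive Gaussian noise, both of strength ``spec.noise_sigma``.
    Intensities are clipped to [0, 1]; with ``noise_sigma = 0`` and a
    static truth all frames are identical.
    """
    if truth.n_frames != spec.n_frames:
        raise ValueError("truth length must match spec.n_frames")
    h, w = spec.frame_shape
    rng = np.random.default_rng(spec.seed + 1)
    pad = 64
    texture = speckle_frame((h + 2 * pad, w + 2 * pad), spec.speckle_grain_px, spec.seed)
    texture = 0.15 + 0.55 * texture  # headroom for the bright features

    yy, xx = np.mgrid[0:h, 0:w]
    blob_sigma = 2.5
    frames = np.empty((spec.n_frames, h, w))
    disp = truth.positions.mean(axis=1) - truth.positions[0].mean(axis=0)
    for f in range(spec.n_frames):
        dx, dy = disp[f]
        bg = ndimage.map_coordinates(
            texture,
            [yy.ravel() + pad - dy, xx.ravel() + pad - dx],
            order=1,
            mode="nearest",
        ).reshape(h, w)
        frame = bg
        for px, py in truth.positions[f]:
            r2 = (xx - px) ** 2 + (yy - py) ** 2
            frame = frame + 0.35 * np.exp(-r2 / (2 * blob_sigma**2))
        if spec.noise_sigma > 0:
            ray = rng.rayleigh(scale=1.0, size=(h, w))
            mu, sd = np.sqrt(np.pi / 2), np.sqrt((4 - np.pi) / 2)
            frame = frame * (1.0 + spec.noise_sigma * (ray - mu) / sd)
            frame = frame + rng.normal(0.0, spec.noise_sigma, (h, w))
        frames[f] = np.clip(frame, 0.0, 1.0)
    return VideoSequence(frames, spec.frame_rate_hz)


class DriftingTracker:
    """Synthetic tracker: ground truth plus bias and/or random-walk drift.

    Satisfies the tracker contract.  Every step adds the constant
    ``bias_px_per_frame`` vector and, if ``random_walk_sigma > 0``, a
    seeded Gaussian increment to an accumulated offset applied on top of
    the true positions.  With zero bias and zero sigma this is the ideal
    tracker.  The frame indices passed to ``step`` select the ground-truth
    positions, so the same instance works forward and backward.

    Each ``initialize`` starts a fresh, independent random stream derived
    from ``(seed, initialization count)``: separate tracking passes (e.g.
    a forward and a backward pass over the same segment) have independent
    drift realisations, as two real tracking passes would, while a freshly
    constructed tracker reproduces the whole sequence bit-identically.
    """

    def __init__(
        self,
        truth: Trajectory,
        bias_px_per_frame=(0.0, 0.0),
        random_walk_sigma: float = 0.0,
        seed: int = 0,
    ):
        self.truth = truth
        self.bias = np.asarray(bias_px_per_frame, dtype=float)
        if self.bias.shape != (2,):
            raise ValueError("bias must be an (x, y) vector")
        self.sigma = float(random_walk_sigma)
        self.seed = int(seed)
        self._offset: np.ndarray | None = None
        self._rng = None
        self._stream = 0

    def initialize(self, frame, points, frame_index: int = 0) -> None:
        pts = np.asarray(points, dtype=float)
        truth_pts = self.truth.at(frame_index)  # raises if out of range
        if pts.shape != truth_pts.shape:
            raise ValueError(
                f"expected {truth_pts.shape[0]} points, got {pts.shape[0]}"
            )
        self._offset = pts - truth_pts
        self._rng = np.random.default_rng([self.seed, self._stream])
        self._stream += 1

    def step(self, prev_frame, next_frame, prev_index=None, next_index=None):
        if self._offset is None:
            raise RuntimeError("tracker not initialized")
        if next_index is None:
            raise ValueError("DriftingTracker requires frame indices in step()")
        self._offset = self._offset + self.bias
        if self.sigma > 0:
            self._offset = self._offset + self._rng.normal(
                0.0, self.sigma, self._offset.shape
            )
        pts = self.truth.at(next_index) + self._offset
        return pts.copy(), np.ones(pts.shape[0], dtype=bool)


def make_drifting_tracker(
    truth: Trajectory,
    bias_px_per_frame=(0.0, 0.0),
    random_walk_sigma: float = 0.0,
    seed: int = 0,
) -> DriftingTracker:
    """Construct a :class:`DriftingTracker` over ``truth``."""
    return DriftingTracker(truth, bias_px_per_frame, random_walk_sigma, seed)


def drifting_tracker_factory(
    truth: Trajectory,
    bias_px_per_frame=(0.0, 0.0),
    random_walk_sigma: float = 0.0,
    seed: int = 0,
):
    """Tracker factory for :func:`echotrack.evaluation.drift_error`.

    The drift protocol mirrors the video; the synthetic tracker's ground
    truth must be mirrored to match, which this factory does from the
    mirrored video's length.
    """

    def factory(mirrored_video: VideoSequence) -> DriftingTracker:
        n = (mirrored_video.n_frames + 1) // 2
        return DriftingTracker(
            mirror_trajectory(truth, n), bias_px_per_frame, random_walk_sigma, seed
        )

    return factory


def make_labelset(truth: Trajectory, n_labels: int) -> LabelSet:
    """Labels at ``n_labels`` equally spaced frames of ``truth``.

    The first and last frames are always included (for ``n_labels >= 2``)
    and coordinates are copied from the ground truth.
    """
    if n_labels < 1:
        raise ValueError("n_labels must be >= 1")
    if n_labels > truth.n_frames:
        raise ValueError(
            f"cannot place {n_labels} labels on {truth.n_frames} frames"
        )
    frames = np.round(
        np.linspace(truth.start_frame, truth.end_frame, n_labels)
    ).astype(int)
    return LabelSet({int(f): truth.at(int(f)).copy() for f in frames})
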