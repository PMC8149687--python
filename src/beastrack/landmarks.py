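"""Landmark-based geometrical transforms and post-hoc ROI propagation.

Tracked cell centroids serve as landmarks: for each consecutive frame pair a
global geometric transform T is fitted by least squares,

    theta* = argmin_theta sum_i || x_i(f+1) - T(x_i(f)) ||^2,

and manually drawn ROIs are moved through the recording by chaining the
fitted transforms.  Supported models: translation (2 parameters), affine
(6), and degree-2 polynomial (12).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.draw import polygon2mask

__all__ = [
    "FrameTransform",
    "TrackedROI",
    "estimate_frame_transform",
    "propagate_rois",
    "extract_roi_signals",
    "landmarks_from_tracks",
]

_MIN_POINTS = {"translation": 1, "affine": 3, "polynomial-2": 6}
_SIMPLER = {"polynomial-2": "affine", "affine": "translation"}


def _design(points: np.ndarray, model: str) -> np.ndarray:
    x, y = points[:, 0], points[:, 1]
    one = np.ones_like(x)
    if model == "affine":
        return np.column_stack([one, x, y])
    if model == "polynomial-2":
        return np.column_stack([one, x, y, x * x, x * y, y * y])
    raise ValueError(f"unknown model {model!r}")


@dataclass
class FrameTransform:
    """Fitted map from frame ``f`` to frame ``f + 1``.

    ``params`` has shape (2,) for translation and (k, 2) otherwise, with one
    column of monomial coefficients per output coordinate.
    """

    model: str
    params: np.ndarray
    frames: tuple[int, int] = (0, 1)
    residual_rms: float = 0.0

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        if self.model == "translation":
            return points + self.params
        return _design(points, self.model) @ self.params

    def inverse(self) -> "FrameTransform":
        """Analytic inverse (translation/affine only)."""
        if self.model == "translation":
            return FrameTransform("translation", -self.params, self.frames[::-1])
        if self.model == "affine":
            a = self.params[1:].T  # 2x2 linear part
            b = self.params[0]
            a_inv = np.linalg.inv(a)
            params = np.vstack([-(a_inv @ b), a_inv.T])
            return FrameTransform("affine", params, self.frames[::-1])
        raise ValueError("polynomial-2 transforms have no analytic inverse")


def estimate_frame_transform(
    landmarks_f: np.ndarray,
    landmarks_f1: np.ndarray,
    model: str = "affine",
    frames: tuple[int, int] = (0, 1),
) -> FrameTransform:
    """Least-squares fit of T mapping ``landmarks_f`` onto ``landmarks_f1``.

    Falls back to the next simpler model (with a warning) when the system is
    under-determined or rank-deficient.
    """
    p0 = np.atleast_2d(np.asarray(landmarks_f, dtype=float))
    p1 = np.atleast_2d(np.asarray(landmarks_f1, dtype=float))
    if p0.shape != p1.shape:
        raise ValueError("landmark lists must have equal length")
    if model not in _MIN_POINTS:
        raise ValueError(f"unknown model {model!r}")

    def fallback(reason):
        simpler = _SIMPLER.get(model)
        if simpler is None:
            raise ValueError(f"cannot fit translation: {reason}")
        warnings.warn(
            f"{model} fit {reason}; falling back to {simpler}", stacklevel=2
        )
        return estimate_frame_transform(p0, p1, simpler, frames)

    if p0.shape[0] < _MIN_POINTS[model]:
        return fallback("is under-determined")

    if model == "translation":
        params = (p1 - p0).mean(axis=0)
        res = p1 - (p0 + params)
    else:
        a = _design(p0, model)
        if np.linalg.matrix_rank(a) < a.shape[1]:
            return fallback("is rank-deficient")
        params, *_ = np.linalg.lstsq(a, p1, rcond=None)
        res = p1 - a @ params
    rms = float(np.sqrt(np.mean(np.sum(res**2, axis=1)))) if len(res) else 0.0
    return FrameTransform(model, params, frames, rms)


def landmarks_from_tracks(tracks, model: str = "affine") -> list[FrameTransform]:
    """Per-frame-pair transforms fitted from tracked cell centroids.

    Cells flagged lost or degenerate on either frame of a pair are excluded
    from that fit.
    """
    n_frames = len(tracks[0].centroids)
    transforms = []
    for f in range(n_frames - 1):
        ok = [
            i
            for i, tr in enumerate(tracks)
            if tr.status[f] == "tracked" and tr.status[f + 1] == "tracked"
        ]
        p0 = np.array([tracks[i].centroids[f] for i in ok])
        p1 = np.array([tracks[i].centroids[f + 1] for i in ok])
        transforms.append(estimate_frame_transform(p0, p1, model, (f, f + 1)))
    return transforms


@dataclass
class TrackedROI:
    """A manually drawn ROI with its propagated per-frame vertex positions."""

    roi_id: int
    vertices: dict = field(default_factory=dict)  # frame -> (V, 2) array
    backward_refused: bool = False

    def at(self, frame: int) -> np.ndarray:
        return self.vertices[frame]


def propagate_rois(
    rois: dict[int, np.ndarray],
    transforms: list[FrameTransform],
    drawn_at: int = 0,
) -> list[TrackedROI]:
    """Chain the frame transforms to move ROIs through the whole recording.

    ``rois`` maps roi_id to an (V, 2) vertex array drawn on frame
    ``drawn_at``.  Vertices are pushed forward with T_f and pulled backward
    with the analytic inverse; backward propagation is refused (flagged) for
    non-invertible models.
    """
    n_frames = len(transforms) + 1
    out = []
    for roi_id, verts in rois.items():
        verts = np.atleast_2d(np.asarray(verts, dtype=float))
        roi = TrackedROI(roi_id, {drawn_at: verts.copy()})
        cur = verts
        for f in range(drawn_at, n_frames - 1):
            cur = transforms[f].apply(cur)
            roi.vertices[f + 1] = cur
        cur = verts
        for f in range(drawn_at - 1, -1, -1):
            try:
                cur = transforms[f].inverse().apply(cur)
            except ValueError:
                roi.backward_refused = True
                break
            roi.vertices[f] = cur
        out.append(roi)
    return out


def extract_roi_signals(stack: np.ndarray, tracked_rois: list[TrackedROI]):
    """Per-frame mean intensity over each tracked ROI's rasterized interior.

    Frames where the ROI falls fully outside the image yield NaN with a zero
    pixel count.
    """
    from .tracking import SignalTrace

    stack = np.asarray(stack, dtype=float)
    n_frames, h, w = stack.shape
    traces = []
    for roi in tracked_rois:
        vals = np.full(n_frames, np.nan)
        npx = np.zeros(n_frames, dtype=int)
        status = []
        for t in range(n_frames):
            if t not in roi.vertices:
                status.append("missing")
                continue
            mask = polygon2mask((h, w), roi.vertices[t][:, ::-1])
            npx[t] = int(mask.sum())
            if npx[t] > 0:
                vals[t] = float(stack[t][mask].mean())
                status.append("tracked")
            else:
                status.append("outside")
        traces.append(SignalTrace(roi.roi_id, vals, npx, status))
    return traces
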