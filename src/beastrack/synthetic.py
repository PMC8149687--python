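"""Ground-truthed artificial Ca2+-imaging scenes.

The generator emulates the evaluation conditions of GCaMP recordings in
contractile tissue: a cluster of overlapping cells with equal baseline
intensity, bright cytoplasm and dark nucleus, smooth frame-to-frame motion of
a few pixels, per-cell Ca2+-transient intensity waveforms, occasional
Gaussian-blurred out-of-focus frames, and additive sensor noise.  Every frame
comes with exact per-cell masks and the true cytoplasm-mean waveform.

Cells are rendered by ownership: where cells overlap, each pixel is
attributed to the cell whose boundary it is deepest inside (smallest
normalized radial coordinate).  At rest all cells share one baseline, so the
overlap is borderless exactly as in the recordings this emulates, while the
ground-truth cytoplasm mean of every cell equals its configured waveform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "SceneConfig",
    "GroundTruth",
    "PlacementError",
    "generate_scene",
    "inject_transient",
    "normalized_rmse",
    "iou_score",
    "double_exponential",
]


class PlacementError(RuntimeError):
    """Cells could not be placed at the requested overlap."""


@dataclass
class SceneConfig:
    """Parameters of the artificial scene.

    ``overlap_factor`` is the relative center-distance deficit of neighboring
    cells: neighbors are placed at ``(r_i + r_j) * (1 - overlap_factor)``;
    zero (or negative) leaves a 2 px safety gap so masks are disjoint.
    ``transients="auto"`` plants one double-exponential peak per cell with
    seeded onsets; ``blur_frames="auto"`` blurs every ``blur_every``-th frame.
    """

    image_size: tuple = (256, 256)
    n_cells: int = 7
    cell_radius_mean: float = 14.0
    cell_radius_sd: float = 2.0
    nucleus_fraction: float = 0.45
    baseline_intensity: float = 100.0
    nucleus_intensity: float = 30.0
    background_intensity: float = 20.0
    overlap_factor: float = 0.15
    shape_irregularity: float = 0.06
    motion_amplitude: float = 3.0
    motion_smoothness: float = 0.7
    motion_coherence: float = 0.8
    motion_reversion: float = 0.04
    global_motion: dict | None = None
    transients: object = "auto"  # "auto" | None | list of per-cell parameter dicts
    transient_amplitude: float = 120.0
    tau_rise: float = 2.0
    tau_decay: float = 10.0
    blur_frames: object = "auto"  # "auto" | sequence of frame indices
    blur_every: int = 25
    blur_sigma: float = 7.0
    noise_sd: float = 16.0
    n_frames: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.cell_radius_mean <= 0 or self.n_cells < 1 or self.n_frames < 1:
            raise ValueError("radii, n_cells and n_frames must be positive")
        if min(self.baseline_intensity, self.nucleus_intensity,
               self.background_intensity) < 0:
            raise ValueError("intensities must be non-negative")

    def resolved_blur_frames(self) -> list[int]:
        if self.blur_frames == "auto":
            start = max(1, self.blur_every - 5)
            return [t for t in range(start, self.n_frames, self.blur_every)]
        return list(self.blur_frames or [])


@dataclass
class GroundTruth:
    """Exact per-frame truth of a generated scene (captured before noise)."""

    cyt_masks: np.ndarray  # (T, C, H, W) bool, cytoplasm annulus (overlap included)
    nuc_masks: np.ndarray  # (T, C, H, W) bool
    owner: np.ndarray  # (T, H, W) int16, owning cell per pixel, -1 background
    waveforms: np.ndarray  # (C, T) true cytoplasm mean intensity
    centroids: np.ndarray  # (C, T, 2) cell center (x, y)
    blur_frames: list = field(default_factory=list)

    def cell_mask(self, t: int, c: int) -> np.ndarray:
        """Whole-cell (cytoplasm + nucleus) mask."""
        return self.cyt_masks[t, c] | self.nuc_masks[t, c]


def double_exponential(t: np.ndarray, onset: float, amplitude: float,
                       tau_rise: float, tau_decay: float) -> np.ndarray:
    """Ca2+-transient kernel: rising/decaying exponentials, peak = amplitude."""
    s = np.maximum(t - onset, 0.0)
    w = (1.0 - np.exp(-s / tau_rise)) * np.exp(-s / tau_decay)
    peak = w.max()
    return amplitude * w / peak if peak > 0 else w


def _cell_shapes(cfg: SceneConfig, rng: np.random.Generator):
    """Per-cell boundary radius lookup r(theta) on a fine angle grid."""
    theta = np.linspace(0.0, 2.0 * np.pi, 721)
    shapes = []
    for _ in range(cfg.n_cells):
        r0 = max(4.0, rng.normal(cfg.cell_radius_mean, cfg.cell_radius_sd))
        r = np.full_like(theta, r0)
        for m in (2, 3, 4):
            amp = cfg.shape_irregularity * r0 * rng.uniform(0.2, 1.0) / m
            r += amp * np.cos(m * theta + rng.uniform(0, 2 * np.pi))
        shapes.append((r0, theta, r))
    return shapes


def _place_cells(cfg: SceneConfig, shapes, rng: np.random.Generator) -> np.ndarray:
    """Cluster layout: one center cell, the rest on rings at the target overlap."""
    h, w = cfg.image_size
    center = np.array([w / 2.0, h / 2.0])
    rmax = [s[2].max() for s in shapes]
    gap = 2.0 if cfg.overlap_factor <= 0 else 0.0
    shrink = max(cfg.overlap_factor, 0.0)
    centers = [center.copy()]
    k = 1
    ring = 1
    while k < cfg.n_cells:
        n_ring = min(6 * ring, cfg.n_cells - k)
        base_angle = rng.uniform(0, 2 * np.pi)
        for j in range(n_ring):
            ang = base_angle + 2 * np.pi * (j / max(6 * ring, 1))
            dist = ring * ((rmax[0] + rmax[k]) * (1.0 - shrink) + gap)
            centers.append(center + dist * np.array([np.cos(ang), np.sin(ang)]))
            k += 1
            if k >= cfg.n_cells:
                break
        ring += 1
    centers = np.asarray(centers)
    margin = np.array([r + cfg.motion_amplitude * 4 + 2 for r in rmax])
    for attempt in range(1000):
        ok = (
            (centers[:, 0] > margin)
            & (centers[:, 0] < w - margin)
            & (centers[:, 1] > margin)
            & (centers[:, 1] < h - margin)
        )
        if ok.all():
            return centers
        centers = (centers - center) * 0.97 + center  # contract the cluster
    raise PlacementError("could not place cells inside the image at this overlap")


def _motion(cfg: SceneConfig, start: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Smooth trajectories: coherent tissue drift plus small per-cell jitter.

    Contractile tissue moves cells together; ``motion_coherence`` is the
    fraction of the motion amplitude carried by the shared component, the
    rest is independent per-cell wobble.  ``motion_reversion`` pulls each
    cell back toward its rest position: contractions deform the tissue but
    the ganglion stays anchored in the field of view instead of drifting
    away.  Per-frame displacement is clipped to ``motion_amplitude``.
    """
    c = start.shape[0]
    t = cfg.n_frames
    pos = np.zeros((c, t, 2))
    pos[:, 0] = start
    if cfg.motion_amplitude > 0 and t > 1:
        alpha = cfg.motion_smoothness
        coh = float(np.clip(cfg.motion_coherence, 0.0, 1.0))
        rev = max(0.0, cfg.motion_reversion)
        sd = cfg.motion_amplitude * 0.6 * np.sqrt(max(1e-9, 1 - alpha**2))
        v_shared = np.zeros(2)
        v_cell = np.zeros((c, 2))
        for k in range(1, t):
            v_shared = alpha * v_shared + rng.normal(0.0, sd, size=2)
            v_cell = alpha * v_cell + rng.normal(0.0, sd, size=(c, 2))
            v = coh * v_shared[None, :] + (1.0 - coh) * v_cell
            v = v + rev * (start - pos[:, k - 1])
            speed = np.linalg.norm(v, axis=1, keepdims=True)
            over = speed > cfg.motion_amplitude
            v = np.where(over, v * cfg.motion_amplitude / speed, v)
            pos[:, k] = pos[:, k - 1] + v
    else:
        pos[:] = start[:, None, :]
    if cfg.global_motion:
        pos = _apply_global_motion(cfg, pos)
    h, w = cfg.image_size
    pos[..., 0] = np.clip(pos[..., 0], 4, w - 5)
    pos[..., 1] = np.clip(pos[..., 1], 4, h - 5)
    return pos


def _apply_global_motion(cfg: SceneConfig, pos: np.ndarray) -> np.ndarray:
    gm = cfg.global_motion
    h, w = cfg.image_size
    center = np.array(gm.get("center", (w / 2.0, h / 2.0)))
    dxy = np.asarray(gm.get("translation_per_frame", (0.0, 0.0)), dtype=float)
    drot = np.deg2rad(gm.get("rotation_deg_per_frame", 0.0))
    out = pos.copy()
    for k in range(pos.shape[1]):
        ang = drot * k
        rot = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        out[:, k] = (pos[:, k] - center) @ rot.T + center + dxy * k
    return out


def _waveforms(cfg: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    t = np.arange(cfg.n_frames, dtype=float)
    w = np.zeros((cfg.n_cells, cfg.n_frames))
    if cfg.transients == "auto":
        lo, hi = 5, max(6, cfg.n_frames - int(3 * cfg.tau_decay))
        for c in range(cfg.n_cells):
            onset = rng.uniform(lo, hi)
            w[c] = double_exponential(
                t, onset, cfg.transient_amplitude, cfg.tau_rise, cfg.tau_decay
            )
    elif cfg.transients:
        for c, peaks in enumerate(cfg.transients):
            for peak in np.atleast_1d(peaks):
                w[c] += double_exponential(
                    t,
                    peak["onset"],
                    peak.get("amplitude", cfg.transient_amplitude),
                    peak.get("tau_rise", cfg.tau_rise),
                    peak.get("tau_decay", cfg.tau_decay),
                )
    return w


def generate_scene(config: SceneConfig):
    """Render the scene; returns ``(stack, GroundTruth)``.

    The stack is float32 with noise and blur applied; all ground truth is
    captured from the pre-noise rendering.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.image_size
    t_n, c_n = cfg.n_frames, cfg.n_cells

    shapes = _cell_shapes(cfg, rng)
    centers0 = _place_cells(cfg, shapes, rng)
    pos = _motion(cfg, centers0, rng)
    waves = _waveforms(cfg, rng)
    blur_frames = cfg.resolved_blur_frames()

    stack = np.empty((t_n, h, w), dtype=np.float32)
    cyt_masks = np.zeros((t_n, c_n, h, w), dtype=bool)
    nuc_masks = np.zeros((t_n, c_n, h, w), dtype=bool)
    owner = np.full((t_n, h, w), -1, dtype=np.int16)

    yy, xx = np.mgrid[0:h, 0:w]
    for t in range(t_n):
        img = np.full((h, w), cfg.background_intensity, dtype=float)
        depth = np.full((h, w), np.inf)  # normalized radial coordinate of the owner
        for c in range(c_n):
            r0, theta_lut, r_lut = shapes[c]
            cx, cy = pos[c, t]
            rmax = r_lut.max()
            x0, x1 = int(max(0, cx - rmax - 2)), int(min(w, cx + rmax + 3))
            y0, y1 = int(max(0, cy - rmax - 2)), int(min(h, cy + rmax + 3))
            dx = xx[y0:y1, x0:x1] - cx
            dy = yy[y0:y1, x0:x1] - cy
            rr = np.hypot(dx, dy)
            th = np.arctan2(dy, dx) % (2 * np.pi)
            bound = np.interp(th, theta_lut, r_lut)
            inside = rr <= bound
            nuc = rr <= cfg.nucleus_fraction * r0
            cyt = inside & ~nuc
            cyt_masks[t, c, y0:y1, x0:x1] = cyt
            nuc_masks[t, c, y0:y1, x0:x1] = nuc
            norm_r = np.where(inside, rr / np.maximum(bound, 1e-9), np.inf)
            win_owner = owner[t, y0:y1, x0:x1]
            win_depth = depth[y0:y1, x0:x1]
            take = inside & (norm_r < win_depth)
            win_depth[take] = norm_r[take]
            win_owner[take] = c
            img_win = img[y0:y1, x0:x1]
            val = np.where(nuc, cfg.nucleus_intensity, cfg.baseline_intensity + waves[c, t])
            img_win[take] = val[take]
        if t in blur_frames:
            img = gaussian_filter(img, cfg.blur_sigma)
        stack[t] = img

    if cfg.noise_sd > 0:
        stack += rng.normal(0.0, cfg.noise_sd, size=stack.shape).astype(np.float32)

    truth = GroundTruth(
        cyt_masks=cyt_masks,
        nuc_masks=nuc_masks,
        owner=owner,
        waveforms=cfg.baseline_intensity + waves,
        centroids=pos.astype(float),
        blur_frames=blur_frames,
    )
    return stack, truth


def inject_transient(stack: np.ndarray, mask_track, waveform,
                     mode: str = "additive") -> np.ndarray:
    """Plant an artificial Ca2+ waveform into masked pixels of a recording.

    ``mask_track`` holds one boolean mask per frame (e.g. a tracked cell's
    cytoplasm); ``waveform`` one additive (or multiplicative) value per frame.
    """
    stack = np.array(stack, dtype=float, copy=True)
    waveform = np.asarray(waveform, dtype=float)
    if len(mask_track) != stack.shape[0] or waveform.shape[0] != stack.shape[0]:
        raise ValueError("mask_track and waveform must cover every frame")
    for t in range(stack.shape[0]):
        mask = mask_track[t]
        if not mask.any():
            warnings.warn(f"empty mask on frame {t}; skipped", stacklevel=2)
            continue
        if mode == "additive":
            stack[t][mask] += waveform[t]
        elif mode == "multiplicative":
            stack[t][mask] *= 1.0 + waveform[t]
        else:
            raise ValueError(f"unknown mode {mode!r}")
    return stack


def normalized_rmse(signal: np.ndarray, reference: np.ndarray) -> float:
    """RMSE between the traces divided by the reference's dynamic range."""
    signal = np.asarray(signal, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if signal.shape != reference.shape:
        raise ValueError("signal and reference must have equal length")
    rng_ = reference.max() - reference.min()
    if rng_ == 0:
        raise ValueError("reference is constant; normalized RMSE undefined")
    return float(np.sqrt(np.mean((signal - reference) ** 2)) / rng_)


def iou_score(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Intersection over union of two boolean masks (0 if both are empty)."""
    mask_a = np.asarray(mask_a, dtype=bool)
    mask_b = np.asarray(mask_b, dtype=bool)
    if mask_a.shape != mask_b.shape:
        raise ValueError("masks must have the same shape")
    union = np.logical_or(mask_a, mask_b).sum()
    if union == 0:
        warnings.warn("both masks empty; IoU defined as 0", stacklevel=2)
        return 0.0
    inter = np.logical_and(mask_a, mask_b).sum()
    return float(inter / union)
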