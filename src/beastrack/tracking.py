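"""Per-frame energy minimization and the frame-to-frame tracking loop.

Each frame is segmented by evolving every cell's contour with a modified
gradient descent with feedback step-adjustment: node radii move along the
total per-node radial force, an energy-increasing step is reverted and the
step size shrunk, an accepted step grows it.  Cells are updated sequentially
(competition terms see the neighbors' current contours frozen), re-centered
to their interior centroid, and the result seeds the next frame.

Intensities are normalized to [0, 1] over the whole stack before tracking so
that the default energy weights transfer across recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import shapely
from shapely.geometry import LinearRing, Polygon

from .contour import (
    DegenerateContourError,
    DoubleContour,
    PolarContour,
    contour_mask,
    contour_polygon,
    local_mean_curvature,
    make_ellipse_contour,
    recentre_and_resample,
)
from .energy import (
    EnergyConfig,
    area_range_energy,
    area_range_force,
    area_stability_force,
)

__all__ = [
    "DescentConfig",
    "CellTrack",
    "SignalTrace",
    "initialize_contours",
    "evolve_contour",
    "evolve_double",
    "segment_frame",
    "track",
    "extract_signals",
]


@dataclass
class DescentConfig:
    """Controls of the feedback-step gradient descent.

    The step size (px, equal to the largest node displacement per iteration)
    is multiplied by ``step_up`` after an accepted move and by ``step_down``
    after a rejected (energy-increasing) one; descent stops when the step
    falls below ``tolerance`` or after ``max_iterations``.
    """

    initial_step: float = 0.5
    step_up: float = 1.1
    step_down: float = 0.5
    max_iterations: int = 60
    tolerance: float = 0.05
    outer_sweeps: int = 2

    def __post_init__(self):
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")
        if not self.step_up > 1 or not 0 < self.step_down < 1:
            raise ValueError("need step_up > 1 and 0 < step_down < 1")


@dataclass
class CellTrack:
    """Per-frame contour(s), status and centroid trajectory of one cell."""

    cell_id: int
    mode: str  # "one_layer" | "double"
    contours: list = field(default_factory=list)
    status: list = field(default_factory=list)  # "tracked" | "degenerate" | "lost"
    centroids: list = field(default_factory=list)
    diagnostics: list = field(default_factory=list)

    def centroid_array(self) -> np.ndarray:
        return np.asarray(self.centroids, dtype=float)

    def outer(self, frame: int) -> PolarContour:
        c = self.contours[frame]
        return c.cytoplasm if isinstance(c, DoubleContour) else c


@dataclass
class SignalTrace:
    """Mean-intensity time series of one cell plus the averaging-region size."""

    cell_id: int
    values: np.ndarray
    n_pixels: np.ndarray
    status: list


# ----------------------------------------------------------------------
# frozen-neighbor geometry cache
# ----------------------------------------------------------------------

class _FrozenNeighbor:
    """Shapely geometry of a neighbor contour, built once per cell update."""

    def __init__(self, contour: PolarContour):
        xy = contour_polygon(contour)
        self.ring = LinearRing(xy)
        self.poly = Polygon(xy)
        shapely.prepare(self.poly)
        self.pole = contour.pole
        self.max_r = float(contour.node_radii.max())

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        pts = shapely.points(points[:, 0], points[:, 1])
        d = shapely.distance(pts, self.ring)
        return np.where(shapely.contains(self.poly, pts), -d, d)


def _near(contour: PolarContour, nb: _FrozenNeighbor, d_thresh: float) -> bool:
    gap = np.linalg.norm(contour.pole - nb.pole)
    return gap < contour.node_radii.max() + nb.max_r + d_thresh + 2.0


# ----------------------------------------------------------------------
# single-layer evolution
# ----------------------------------------------------------------------

class _ImageData:
    """A frame plus its (lightly smoothed) intensity gradient field.

    The data force needs the directional derivative of the image along each
    node normal, averaged over the band samples; computing the gradient once
    per frame on a sigma=1 smoothed copy keeps that estimate stable under
    sensor noise.
    """

    def __init__(self, image: np.ndarray, grad_sigma: float = 1.0):
        from scipy.ndimage import gaussian_filter

        self.image = np.asarray(image, dtype=float)
        smooth = gaussian_filter(self.image, grad_sigma)
        self.gy, self.gx = np.gradient(smooth)

    @classmethod
    def wrap(cls, image):
        return image if isinstance(image, cls) else cls(image)


# gain of the pole-translation component of the descent relative to the
# radial forces: large enough that a cell can follow rigid motion without the
# radial noise floor throttling it, small enough that a symmetric force
# pattern (no net translation evidence) leaves the pole in place
POLE_GAIN = 8.0


def _project_basis(f: np.ndarray, degree: int) -> np.ndarray:
    """Project per-node forces onto the B-spline coefficient space.

    The energy gradient with respect to a coefficient gathers the node forces
    weighted by the basis, a circular convolution with ``beta_d`` at integer
    lags; this is what keeps the evolution smooth along the contour.
    """
    from .contour import bspline_basis

    n = f.shape[0]
    lags = np.arange(n, dtype=float)
    lags[lags > n // 2] -= n
    kern = bspline_basis(lags, degree)
    return np.real(np.fft.ifft(np.fft.fft(f) * np.fft.fft(kern)))


class _LayerState:
    """Everything needed to score and differentiate one contour on one frame.

    The data force is the first variation of the band means under a window
    that translates with the node: ``d u / d r`` is the band-averaged
    directional image gradient along the node normal, so the force is exactly
    the descent direction of the energy this state evaluates.
    """

    def __init__(self, data: _ImageData, contour, prev_area, nbs,
                 cfg: EnergyConfig, competition: bool = True, polarity: int = 1):
        # polarity +1: bright interior (cytoplasm layer); -1: dark interior
        # (nucleus layer).  The separation criterion is signed accordingly so
        # a contour cannot lock onto an interface with the wrong orientation.
        from scipy.ndimage import map_coordinates
        from .energy import BAND_WIDTH, COMPETITION_SCALE, band_samples

        self.contour = contour
        pts, normals, in_xy, out_xy = band_samples(contour, cfg.rho, BAND_WIDTH)
        self.normals = normals
        shape = data.image.shape
        m = in_xy.shape[1]
        allxy = np.concatenate([in_xy, out_xy], axis=1)
        xs, ys = allxy[..., 0], allxy[..., 1]
        valid = (xs >= 0) & (xs <= shape[1] - 1) & (ys >= 0) & (ys <= shape[0] - 1)
        coords = [ys.ravel(), xs.ravel()]
        vals = map_coordinates(data.image, coords, order=1, mode="nearest").reshape(xs.shape)
        gxv = map_coordinates(data.gx, coords, order=1, mode="nearest").reshape(xs.shape)
        gyv = map_coordinates(data.gy, coords, order=1, mode="nearest").reshape(xs.shape)
        dirv = gxv * normals[:, None, 0] + gyv * normals[:, None, 1]

        def band_mean(a, sl):
            v = valid[:, sl]
            n = v.sum(axis=1)
            s = np.where(v, a[:, sl], 0.0).sum(axis=1)
            with np.errstate(invalid="ignore"):
                return np.where(n > 0, s / np.maximum(n, 1), np.nan), n

        self.u_in, self.n_in = band_mean(vals, slice(0, m))
        self.u_out, self.n_out = band_mean(vals, slice(m, None))
        self.dudr_in, _ = band_mean(dirv, slice(0, m))
        self.dudr_out, _ = band_mean(dirv, slice(m, None))

        self.poly_xy = contour_polygon(contour)
        x, y = self.poly_xy[:, 0], self.poly_xy[:, 1]
        self.area = float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2)
        ok = (self.n_in > 0) & (self.n_out > 0)
        self._data_ok = ok
        self._polarity = polarity
        du = self.u_in[ok] - self.u_out[ok]
        self.e_data = float(-np.sum(polarity * du * np.abs(du)))
        self.kappa = local_mean_curvature(contour)
        amin = cfg.area_min if cfg.area_min is not None else 0.0
        amax = cfg.area_max if cfg.area_max is not None else np.inf
        self._bounds = (amin, amax)
        e_reg = (
            cfg.w_kappa * float(np.sum(0.5 * self.kappa**2 * (self.kappa < 0)))
            * contour.dtheta
            + cfg.w_area * area_range_energy(self.area, amin, amax)
            + cfg.w_area_stab * (
                0.0 if prev_area is None
                else 0.5 * ((self.area - prev_area) / prev_area) ** 2
            )
        )
        self.psi = []
        self.overlap_area = 0.0
        if competition and nbs:
            poly = None
            for nb in nbs:
                if not _near(contour, nb, cfg.d_thresh):
                    self.psi.append(None)
                    continue
                psi = nb.signed_distance(contour.node_positions())
                self.psi.append(psi)
                pen = np.where(psi < cfg.d_thresh, cfg.d_thresh - psi, 0.0)
                e_reg += COMPETITION_SCALE * float(pen.sum())
                if psi.min() < 0:
                    if poly is None:
                        poly = Polygon(self.poly_xy)
                    inter = poly.intersection(nb.poly).area
                    self.overlap_area += inter
                    e_reg += COMPETITION_SCALE * cfg.w_comp * inter
        else:
            self.psi = [None] * len(nbs)
        self.energy = self.e_data + e_reg
        self._cfg = cfg
        self._prev_area = prev_area

    def data_forces(self) -> np.ndarray:
        ok = self._data_ok
        f = np.zeros(self.contour.n_nodes)
        f[ok] = (
            2.0
            * self._polarity
            * np.abs(self.u_in[ok] - self.u_out[ok])
            * (self.dudr_in[ok] - self.dudr_out[ok])
        )
        return f

    def forces(self) -> np.ndarray:
        cfg = self._cfg
        f = self.data_forces()
        f -= cfg.w_kappa * np.where(self.kappa < 0, self.kappa, 0.0)
        amin, amax = self._bounds
        f += cfg.w_area * area_range_force(self.area, amin, amax)
        f += cfg.w_area_stab * area_stability_force(self.area, self._prev_area)
        from .energy import COMPETITION_SCALE

        for psi in self.psi:
            if psi is None:
                continue
            f -= COMPETITION_SCALE * np.where(psi < cfg.d_thresh, cfg.d_thresh - psi, 0.0)
            f -= COMPETITION_SCALE * cfg.w_comp * np.where(psi < 0, -psi, 0.0)
        return _project_basis(f, self.contour.degree)

    def pole_force(self, f: np.ndarray) -> np.ndarray:
        """Energy gradient with respect to the pole: node forces projected
        onto their outward normals and averaged.  Lets a cell translate
        rigidly instead of synthesizing motion from shape changes."""
        return (f[:, None] * self.normals).mean(axis=0)


def evolve_contour(
    image: np.ndarray,
    contour: PolarContour,
    prev_area: float | None,
    neighbors: list[PolarContour] | None,
    energy_config: EnergyConfig | None = None,
    descent_config: DescentConfig | None = None,
    forbid_overlap: bool = False,
):
    """Minimize the one-layer energy of a single contour with neighbors frozen.

    Returns ``(contour, converged, energy)``.  Radii are clamped to 1 px; a
    fully collapsed contour raises :class:`DegenerateContourError` upstream.
    """
    cfg = energy_config or EnergyConfig()
    dsc = descent_config or DescentConfig()
    nbs = [_FrozenNeighbor(nb) for nb in (neighbors or [])]
    data = _ImageData.wrap(image)
    state = _LayerState(data, contour.copy(), prev_area, nbs, cfg)
    step = dsc.initial_step
    converged = False
    for _ in range(dsc.max_iterations):
        f = state.forces()
        # the pole follows the image evidence alone; competition reshapes
        # the radii but must not translate the cell
        v = state.pole_force(_project_basis(state.data_forces(),
                                            state.contour.degree))
        m = max(np.abs(f).max(), POLE_GAIN * np.linalg.norm(v))
        if m == 0:
            converged = True
            break
        cand = PolarContour(
            state.contour.pole + step * POLE_GAIN * v / m,
            state.contour.node_radii + step * f / m,
            state.contour.degree,
        )
        cand_state = _LayerState(data, cand, prev_area, nbs, cfg)
        reject = cand_state.energy > state.energy
        if forbid_overlap and cand_state.overlap_area > 0:
            reject = True
        if reject:
            step *= dsc.step_down
            if step < dsc.tolerance:
                converged = True
                break
        else:
            state = cand_state
            if step < dsc.tolerance:
                converged = True  # accepted displacement below tolerance
                break
            step *= dsc.step_up
    return state.contour, converged, state.energy


# ----------------------------------------------------------------------
# double-contour evolution
# ----------------------------------------------------------------------

def evolve_double(
    image: np.ndarray,
    dc: DoubleContour,
    prev_areas: tuple[float | None, float | None],
    neighbors: list[PolarContour] | None,
    energy_config: EnergyConfig | None = None,
    descent_config: DescentConfig | None = None,
    nucleus_config: EnergyConfig | None = None,
    forbid_overlap: bool = False,
):
    """Jointly evolve the coupled nucleus + cytoplasm pair on the summed energy.

    Both layers move in the same descent loop; after every candidate step the
    ordering constraint ``r_cyt >= r_nuc + margin`` is restored by projecting
    the cytoplasm radii upward.  Competition acts on the cytoplasm layer only.
    Returns ``(dc, converged, energy, low_contrast)``; ``low_contrast`` flags
    frames where the nucleus-cytoplasm intensity separation is too weak to
    anchor the inner layer.
    """
    cfg = energy_config or EnergyConfig()
    if nucleus_config is None:
        # the nucleus is small: a band as long as the cytoplasm's would cross
        # it entirely, so its rho is tied to the current nucleus radius
        r_nuc = float(np.mean(dc.nucleus.node_radii))
        # the inward band stays dark even past the pole, so rho can be the
        # full nucleus radius; below ~4 px the band cannot cover the
        # frame-to-frame motion and the anchor loses its lock
        ncfg = replace(cfg, rho=float(np.clip(r_nuc, 4.0, cfg.rho)),
                       area_min=None, area_max=None)
    else:
        ncfg = nucleus_config
    dsc = descent_config or DescentConfig()
    nbs = [_FrozenNeighbor(nb) for nb in (neighbors or [])]
    prev_nuc, prev_cyt = prev_areas
    data = _ImageData.wrap(image)

    cur = dc.copy()
    converged = True

    # phase 1 - the nucleus is the anchor: it alone sets the shared pole,
    # dragging the whole cell rigidly; its sharp dark-bright interface is the
    # most reliable feature of a GCaMP cell
    s_nuc = _LayerState(data, cur.nucleus, prev_nuc, [], ncfg,
                        competition=False, polarity=-1)
    step = dsc.initial_step
    for _ in range(dsc.max_iterations):
        f = s_nuc.forces()
        v = s_nuc.pole_force(f)
        m = np.abs(f).max()
        vn = np.linalg.norm(v)
        if m == 0 and vn == 0:
            break
        # the pole step is normalized on its own: radial noise jitter must
        # not throttle the anchor's translation
        new_pole = cur.nucleus.pole + (step * v / vn if vn > 0 else 0.0)
        # the anchor may not leak past the (frozen) cytoplasm boundary: the
        # background is as dark as a nucleus, so cap r_nuc <= r_cyt - margin
        dr = step * f / m if m > 0 else 0.0
        capped = np.minimum(
            cur.nucleus.node_radii + dr,
            cur.cytoplasm.node_radii - cur.margin,
        )
        cand = DoubleContour(
            PolarContour(new_pole, capped, cur.nucleus.degree),
            PolarContour(new_pole, cur.cytoplasm.node_radii,
                         cur.cytoplasm.degree),
            cur.margin,
        )
        c_nuc = _LayerState(data, cand.nucleus, prev_nuc, [], ncfg,
                            competition=False, polarity=-1)
        if c_nuc.energy > s_nuc.energy:
            step *= dsc.step_down
            if step < dsc.tolerance:
                break
        else:
            cur, s_nuc = cand, c_nuc
            if step < dsc.tolerance:
                break
            step *= dsc.step_up

    # phase 2 - the cytoplasm layer shapes around the fixed pole under the
    # full energy (data + regularization + competition); the radial-ordering
    # constraint r_cyt >= r_nuc + margin is restored after every step
    s_cyt = _LayerState(data, cur.cytoplasm, prev_cyt, nbs, cfg)
    step = dsc.initial_step
    converged = False
    for _ in range(dsc.max_iterations):
        f = s_cyt.forces()
        m = np.abs(f).max()
        if m == 0:
            converged = True
            break
        cand = DoubleContour(
            cur.nucleus,
            cur.cytoplasm.with_radii(cur.cytoplasm.node_radii + step * f / m),
            cur.margin,
        )
        c_cyt = _LayerState(data, cand.cytoplasm, prev_cyt, nbs, cfg)
        reject = c_cyt.energy > s_cyt.energy
        if forbid_overlap and c_cyt.overlap_area > 0:
            reject = True
        if reject:
            step *= dsc.step_down
            if step < dsc.tolerance:
                converged = True
                break
        else:
            cur, s_cyt = cand, c_cyt
            if step < dsc.tolerance:
                converged = True
                break
            step *= dsc.step_up
    energy = s_nuc.energy + s_cyt.energy
    ok = s_nuc._data_ok
    contrast = float(np.mean(s_nuc.u_out[ok] - s_nuc.u_in[ok])) if ok.any() else 0.0
    return cur, converged, energy, contrast < 0.02


# ----------------------------------------------------------------------
# multi-cell frame segmentation and tracking
# ----------------------------------------------------------------------

def _outer(c) -> PolarContour:
    return c.cytoplasm if isinstance(c, DoubleContour) else c


def _resample_about(contour: PolarContour, new_pole: np.ndarray) -> PolarContour:
    """Re-grid a contour's nodes onto the regular angle grid about a new pole."""
    rel = contour.node_positions() - new_pole
    th = np.arctan2(rel[:, 1], rel[:, 0]) % (2.0 * np.pi)
    rr = np.hypot(rel[:, 0], rel[:, 1])
    order = np.argsort(th)
    th, rr = th[order], rr[order]
    th_ext = np.concatenate([th[-1:] - 2 * np.pi, th, th[:1] + 2 * np.pi])
    rr_ext = np.concatenate([rr[-1:], rr, rr[:1]])
    new_r = np.interp(contour.node_angles, th_ext, rr_ext)
    if np.any(new_r <= 0):
        raise DegenerateContourError("resampling about the new pole collapsed")
    return PolarContour(new_pole, new_r, contour.degree)


def _recentre_cell(cell):
    """Re-centre a cell on its interior centroid and re-grid the nodes.

    One-layer cells re-centre on the contour centroid.  Double contours
    re-centre on the *nucleus* centroid: the nucleus is the anchor, and tying
    the shared pole to the outer layer would let a competition-distorted
    cytoplasm drag the pole off the nucleus and break the inner lock.
    """
    if isinstance(cell, DoubleContour):
        new_nuc = recentre_and_resample(cell.nucleus)
        new_cyt = _resample_about(cell.cytoplasm, new_nuc.pole)
        return DoubleContour(new_nuc, new_cyt, cell.margin)
    return recentre_and_resample(cell)


def segment_frame(
    image: np.ndarray,
    cells: list,
    prev_areas: list,
    configs: list[EnergyConfig] | EnergyConfig,
    descent_config: DescentConfig | None = None,
    forbid_overlap: bool = False,
    nucleus_configs: list | None = None,
):
    """One frame of multi-cell segmentation with contour competition.

    ``cells`` holds PolarContour or DoubleContour seeds (one per cell);
    ``prev_areas`` the previous-frame areas (scalar, or (nuc, cyt) tuple for
    double contours, or None on the first frame).  Cells are evolved
    sequentially in id order for ``outer_sweeps`` rounds, each against the
    others' current contours, then re-centered.  Returns
    ``(cells, statuses)``.
    """
    dsc = descent_config or DescentConfig()
    n = len(cells)
    if n == 0:
        raise ValueError("segment_frame needs at least one contour")
    image = _ImageData.wrap(image)
    if isinstance(configs, EnergyConfig):
        configs = [configs] * n
    cells = [c.copy() for c in cells]
    statuses = ["tracked"] * n
    for sweep in range(max(1, dsc.outer_sweeps)):
        order = range(n) if sweep % 2 == 0 else range(n - 1, -1, -1)
        for i in order:
            if statuses[i] == "lost":
                continue
            nbs = [_outer(cells[j]) for j in range(n) if j != i and statuses[j] != "lost"]
            try:
                if isinstance(cells[i], DoubleContour):
                    pa = prev_areas[i] if prev_areas[i] is not None else (None, None)
                    ncfg = nucleus_configs[i] if nucleus_configs else None
                    new, _, _, _ = evolve_double(
                        image, cells[i], pa, nbs, configs[i],
                        dsc, nucleus_config=ncfg, forbid_overlap=forbid_overlap,
                    )
                else:
                    new, _, _ = evolve_contour(
                        image, cells[i], prev_areas[i], nbs, configs[i],
                        dsc, forbid_overlap=forbid_overlap,
                    )
                cells[i] = _recentre_cell(new)
                h, w = image.image.shape
                px, py = _outer(cells[i]).pole
                if not (0 <= px < w and 0 <= py < h):
                    statuses[i] = "lost"
            except DegenerateContourError:
                statuses[i] = "degenerate"
    return cells, statuses


def initialize_contours(
    first_frame: np.ndarray,
    ellipses,
    mode: str = "one_layer",
    energy_config: EnergyConfig | None = None,
    descent_config: DescentConfig | None = None,
    n_nodes: int = 32,
    nucleus_fraction: float = 0.5,
):
    """Turn user ellipses into converged frame-0 contours, forbidding overlap.

    ``ellipses`` is a sequence of ``(cx, cy, a, b, angle_rad)``.  Each ellipse
    is evolved to convergence on the first frame with any overlapping move
    rejected; in double mode the nucleus layer starts at ``nucleus_fraction``
    of the ellipse and is pulled to the dark-bright interface in the same
    joint descent.
    """
    cfg = energy_config or EnergyConfig()
    dsc = descent_config or DescentConfig()
    if isinstance(first_frame, _ImageData):
        image = first_frame
    else:
        image = _ImageData.wrap(_normalize(np.asarray(first_frame, dtype=float)))
    h, w = image.image.shape
    # "overlap not allowed" during initialization: the overlap penalty weight
    # is made effectively infinite so any overlap is pushed out; it scales
    # from the configured weight so that disabling competition (w_comp = 0)
    # disables it here too, which is what a competition-ablation run means
    init_cfg = replace(cfg, w_comp=40.0 * cfg.w_comp)
    init_dsc = replace(dsc, max_iterations=max(dsc.max_iterations, 100))
    done: list = []
    for (cx, cy, a, b, ang) in ellipses:
        if a <= 0 or b <= 0:
            raise ValueError("ellipse semi-axes must be positive")
        if not (0 <= cx < w and 0 <= cy < h):
            raise ValueError("ellipse center outside the image")
        outer = make_ellipse_contour((cx, cy), (a, b), ang, n_nodes)
        # first lock each contour onto its own cell without competition: the
        # user ellipse is the per-cell prior and must not be displaced by
        # neighbors initialized earlier; its area also bounds the contour so
        # a cell without visible borders cannot engulf its neighborhood
        a_ell = np.pi * a * b
        solo_cfg = replace(cfg, area_min=0.5 * a_ell, area_max=1.15 * a_ell)
        if mode == "double":
            nuc = make_ellipse_contour(
                (cx, cy), (a * nucleus_fraction, b * nucleus_fraction), ang, n_nodes
            )
            dc = DoubleContour(nuc, outer, cfg.margin_dc)
            dc, _, _, _ = evolve_double(image, dc, (None, None), [], solo_cfg, init_dsc)
            done.append(_recentre_cell(dc))
        else:
            c, _, _ = evolve_contour(image, outer, None, [], solo_cfg, init_dsc)
            done.append(_recentre_cell(c))
    if len(done) > 1:
        # then resolve the overlaps jointly under an effectively infinite
        # overlap penalty; each cell keeps area bounds around its solo fit so
        # the negotiation shares the overlap instead of crushing anyone
        prev = [(None, None) if mode == "double" else None] * len(done)
        cfgs = []
        for cell in done:
            a0 = _cell_area(cell)
            if isinstance(a0, tuple):
                a0 = a0[1]
            # the area penalty must be stiff enough that a cell surrounded
            # by overlapping neighbors stands its ground instead of
            # collapsing to resolve the overlap single-handedly
            cfgs.append(replace(init_cfg, w_area=10 * init_cfg.w_area,
                                area_min=0.55 * a0, area_max=1.1 * a0))
        nb_sweeps = replace(dsc, outer_sweeps=max(4, dsc.outer_sweeps))
        done, _ = segment_frame(image, done, prev, cfgs, nb_sweeps)
    return done


def _normalize(stack: np.ndarray) -> np.ndarray:
    stack = np.asarray(stack, dtype=float)
    lo, hi = float(stack.min()), float(stack.max())
    if hi <= lo:
        return np.zeros_like(stack)
    return (stack - lo) / (hi - lo)


def _cell_area(cell):
    from .contour import contour_area

    if isinstance(cell, DoubleContour):
        return (contour_area(cell.nucleus), contour_area(cell.cytoplasm))
    return contour_area(cell)


def track(
    stack: np.ndarray,
    ellipses,
    mode: str = "one_layer",
    energy_config: EnergyConfig | None = None,
    descent_config: DescentConfig | None = None,
    n_nodes: int = 32,
    nucleus_fraction: float = 0.5,
    auto_area_bounds: tuple[float, float] | None = (0.7, 1.6),
) -> list[CellTrack]:
    """Track all cells through the stack, seeding each frame with the previous one.

    When ``energy_config.area_min``/``area_max`` are unset and
    ``auto_area_bounds`` is given, per-cell area bounds are derived from the
    frame-0 segmentation as ``(lo * A0, hi * A0)``.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3 or stack.shape[0] < 1:
        raise ValueError("stack must be a (frames, H, W) array with >= 1 frame")
    cfg = energy_config or EnergyConfig()
    dsc = descent_config or DescentConfig()
    norm = _normalize(stack)

    cells = initialize_contours(
        norm[0], ellipses, mode, cfg, dsc, n_nodes, nucleus_fraction
    )
    n = len(cells)
    configs = [cfg] * n
    if cfg.area_min is None and cfg.area_max is None and auto_area_bounds:
        lo, hi = auto_area_bounds
        configs = []
        for c in cells:
            a = _cell_area(c)
            a0 = a[1] if isinstance(a, tuple) else a
            configs.append(replace(cfg, area_min=lo * a0, area_max=hi * a0))

    nucleus_configs = None
    if mode == "double":
        nucleus_configs = []
        for c in cells:
            r_nuc = float(np.mean(c.nucleus.node_radii))
            a_nuc = _cell_area(c)[0]
            nucleus_configs.append(
                replace(cfg, rho=float(np.clip(r_nuc, 4.0, cfg.rho)),
                        area_min=0.6 * a_nuc, area_max=1.5 * a_nuc)
            )

    tracks = [CellTrack(cell_id=i, mode=mode) for i in range(n)]
    statuses = ["tracked"] * n
    prev_areas: list = [None] * n

    def record(frame_cells, frame_statuses):
        for i, tr in enumerate(tracks):
            tr.contours.append(frame_cells[i])
            tr.status.append(frame_statuses[i])
            tr.centroids.append(_outer(frame_cells[i]).pole.copy())

    record(cells, statuses)
    prev_areas = [_cell_area(c) for c in cells]

    for t in range(1, stack.shape[0]):
        new_cells, new_statuses = segment_frame(
            norm[t], cells, prev_areas, configs, dsc,
            nucleus_configs=nucleus_configs,
        )
        for i in range(n):
            if new_statuses[i] != "tracked":
                new_cells[i] = cells[i]  # freeze last valid contour
            else:
                prev_areas[i] = _cell_area(new_cells[i])
        cells = new_cells
        record(cells, new_statuses)
    return tracks


def extract_signals(stack: np.ndarray, tracks: list[CellTrack], mode: str | None = None):
    """Mean-intensity traces over each cell's tracked averaging region.

    One-layer cells average over the whole contour interior; double contours
    average over cytoplasm-minus-nucleus pixels only, which excludes the dark
    nucleus from the Ca2+ signal.  Frozen (lost/degenerate) frames carry the
    value from the frozen contour and keep their status flag.
    """
    stack = np.asarray(stack, dtype=float)
    traces = []
    shape = stack.shape[1:]
    for tr in tracks:
        vals = np.full(stack.shape[0], np.nan)
        npx = np.zeros(stack.shape[0], dtype=int)
        for t, cell in enumerate(tr.contours):
            if isinstance(cell, DoubleContour):
                mask = contour_mask(cell.cytoplasm, shape) & ~contour_mask(
                    cell.nucleus, shape
                )
            else:
                mask = contour_mask(cell, shape)
            npx[t] = int(mask.sum())
            if npx[t] > 0:
                vals[t] = float(stack[t][mask].mean())
        traces.append(
            SignalTrace(cell_id=tr.cell_id, values=vals, n_pixels=npx, status=list(tr.status))
        )
    return traces
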