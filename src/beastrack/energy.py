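"""Data-attachment and regularization energies with per-node radial forces.

The contour is driven by a localized region-based criterion (Yezzi): at each
node, mean intensities are estimated inside and outside the boundary within a
short column of pixels along the node normal, and the contour moves to
maximize the separation of those means, ``F = -(u_in - u_out)^2``.
Regularization adds curvature, area-range and area-stability penalties, plus
two competition terms between neighboring cells: a proximity penalty that
discourages contours from approaching closer than ``d_thresh``, and an
overlap-area penalty ``w_comp * A_overlap`` that makes actual overlap costly
on both contours.

All forces follow the convention: positive = outward (radius grows).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from scipy.ndimage import map_coordinates
from shapely.geometry import LinearRing, Polygon

from .contour import PolarContour, contour_polygon, local_mean_curvature

__all__ = [
    "EnergyConfig",
    "NodeForces",
    "local_band",
    "localized_means",
    "yezzi_force",
    "curvature_gradient",
    "area_gradient",
    "area_stability",
    "proximity_penalty",
    "overlap_penalty",
    "total_regularization",
]


@dataclass
class EnergyConfig:
    """Weights and scales of all energy terms.

    rho
        Neighborhood radius (px): number of unit-spaced samples taken on each
        side of a node along its normal.  Sets the largest per-frame motion
        the data term can see; choose slightly below the cell radius.
    w_kappa, w_area, w_area_stab, w_comp
        Weights of the curvature, area-range, area-stability and overlap
        penalties.  Tuned for images normalized to [0, 1].
    d_thresh
        Minimal allowed distance (px) between a node and a neighboring
        contour before the proximity penalty activates.
    area_min, area_max
        Admissible contour area range (px^2).  ``None`` means "derive per
        cell from the initial segmentation" (handled by the tracker).
    margin_dc
        Radial margin (px) of the double-contour ordering constraint.
    """

    rho: float = 8.0
    w_kappa: float = 0.05
    w_area: float = 0.005
    w_area_stab: float = 2.0
    w_comp: float = 0.5
    d_thresh: float = 2.0
    area_min: float | None = None
    area_max: float | None = None
    margin_dc: float = 1.0

    def __post_init__(self):
        if self.rho < 1:
            raise ValueError("rho must be >= 1")
        for name in ("w_kappa", "w_area", "w_area_stab", "w_comp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.area_min is not None and self.area_max is not None:
            if not self.area_min < self.area_max:
                raise ValueError("area_min must be < area_max")


@dataclass
class NodeForces:
    """Per-node radial forces, one array per energy term, plus total energy."""

    data: np.ndarray
    curvature: np.ndarray
    area: np.ndarray
    area_stab: np.ndarray
    proximity: np.ndarray
    overlap: np.ndarray
    energy: float = 0.0

    def total(self) -> np.ndarray:
        return (
            self.data
            + self.curvature
            + self.area
            + self.area_stab
            + self.proximity
            + self.overlap
        )


# ----------------------------------------------------------------------
# data attachment
# ----------------------------------------------------------------------

# lateral half-width (px) of the averaging band used by the evolution engine;
# the extra parallel sample columns tame sensor noise in the local means
BAND_WIDTH = 1

# the competition penalties are measured in pixels (proximity) and px^2
# (overlap) while the data term lives on squared normalized intensities; this
# factor brings them onto a common scale inside the evolution engine so that
# d_thresh and w_comp keep interpretable units
COMPETITION_SCALE = 0.05


def band_samples(contour: PolarContour, rho: float, width: int = 0):
    """Continuous band sample positions for all nodes.

    Returns (pts, normals, inside_xy, outside_xy) where inside/outside are
    (N, rho * (2*width+1), 2) positions at unit spacing along the
    inward/outward normal, replicated at ``2*width+1`` lateral offsets along
    the tangent (width=0: a single column).
    """
    pts, normals = contour.outward_normals()
    steps = np.arange(1, int(round(rho)) + 1, dtype=float)
    tangents = np.column_stack([-normals[:, 1], normals[:, 0]])
    offsets = np.arange(-width, width + 1, dtype=float)
    base_out = pts[:, None, :] + steps[None, :, None] * normals[:, None, :]
    base_in = pts[:, None, :] - steps[None, :, None] * normals[:, None, :]
    def widen(base):
        cols = [base + o * tangents[:, None, :] for o in offsets]
        return np.concatenate(cols, axis=1)
    return pts, normals, widen(base_in), widen(base_out)


def _clip_round(xy: np.ndarray, shape) -> tuple[np.ndarray, np.ndarray]:
    """Round positions to pixels; return (int_xy, valid) with out-of-image dropped."""
    ij = np.rint(xy).astype(int)
    valid = (
        (ij[..., 0] >= 0)
        & (ij[..., 0] <= shape[1] - 1)
        & (ij[..., 1] >= 0)
        & (ij[..., 1] <= shape[0] - 1)
    )
    return ij, valid


def local_band(image_shape, contour: PolarContour, node_index: int, rho: float):
    """Pixel sets sampled along the inward and outward normal of one node."""
    _, _, in_xy, out_xy = band_samples(contour, rho)
    out = []
    for xy in (in_xy[node_index], out_xy[node_index]):
        ij, valid = _clip_round(xy, image_shape)
        out.append(ij[valid])
    return tuple(out)


def band_statistics(image: np.ndarray, contour: PolarContour, rho: float,
                    bilinear: bool = True):
    """Vectorized per-node band means for all nodes.

    Returns (u_in, u_out, n_in, n_out, i_node); means are NaN where a band is
    empty, i_node is the bilinear image intensity at the node position.
    With ``bilinear=True`` (the evolution engine's mode) band values are
    interpolated at the continuous sample positions, which keeps the energy
    continuous in the radii, and the band is widened laterally by
    ``BAND_WIDTH`` tangent columns to tame noise; ``bilinear=False``
    reproduces the rounded single-column pixel-set statistics of
    :func:`local_band`/:func:`localized_means`.
    """
    width = BAND_WIDTH if bilinear else 0
    pts, _, in_xy, out_xy = band_samples(contour, rho, width)
    shape = image.shape
    imgf = np.asarray(image, dtype=float)
    res = []
    for xy in (in_xy, out_xy):
        _, valid = _clip_round(xy, shape)
        if bilinear:
            vals = map_coordinates(
                imgf, [xy[..., 1].ravel(), xy[..., 0].ravel()], order=1, mode="nearest"
            ).reshape(xy.shape[:2])
        else:
            ij = np.rint(xy).astype(int)
            vals = imgf[
                ij[..., 1].clip(0, shape[0] - 1), ij[..., 0].clip(0, shape[1] - 1)
            ]
        n = valid.sum(axis=1)
        s = np.where(valid, vals, 0.0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            u = np.where(n > 0, s / np.maximum(n, 1), np.nan)
        res.append((u, n))
    i_node = map_coordinates(imgf, [pts[:, 1], pts[:, 0]], order=1, mode="nearest")
    (u_in, n_in), (u_out, n_out) = res
    return u_in, u_out, n_in, n_out, i_node


def localized_means(image: np.ndarray, contour: PolarContour, node_index: int, rho: float):
    """(u_in, u_out) mean intensities of one node's band pixels (NaN where empty)."""
    u_in, u_out, _, _, _ = band_statistics(image, contour, rho, bilinear=False)
    return float(u_in[node_index]), float(u_out[node_index])


def yezzi_forces(image: np.ndarray, contour: PolarContour, rho: float) -> np.ndarray:
    """Per-node radial forces of the localized mean-separation criterion.

    Descent direction on ``E_d = sum_k -(u_in - u_out)^2``: moving a node
    outward transfers the pixel under it from the outside to the inside band,
    so ``f = (u_in - u_out) * ((I - u_in)/n_in + (I - u_out)/n_out)``.
    Nodes with an empty band exert no force.
    """
    u_in, u_out, n_in, n_out, i_node = band_statistics(image, contour, rho)
    ok = (n_in > 0) & (n_out > 0)
    f = np.zeros(contour.n_nodes)
    f[ok] = (u_in[ok] - u_out[ok]) * (
        (i_node[ok] - u_in[ok]) / n_in[ok] + (i_node[ok] - u_out[ok]) / n_out[ok]
    )
    return f


def yezzi_force(image: np.ndarray, contour: PolarContour, node_index: int, rho: float) -> float:
    return float(yezzi_forces(image, contour, rho)[node_index])


def data_energy(image: np.ndarray, contour: PolarContour, rho: float) -> float:
    """``sum_k -(u_in - u_out)^2`` over nodes with defined means."""
    u_in, u_out, n_in, n_out, _ = band_statistics(image, contour, rho)
    ok = (n_in > 0) & (n_out > 0)
    return float(-np.sum((u_in[ok] - u_out[ok]) ** 2))


# ----------------------------------------------------------------------
# regularization
# ----------------------------------------------------------------------

def curvature_gradient(contour: PolarContour) -> np.ndarray:
    """Per-node gradient ``kappa * H(-kappa)`` of the concavity penalty.

    Zero at convex nodes; the descent force (its negation) pushes concave
    dents outward.
    """
    k = local_mean_curvature(contour)
    return np.where(k < 0, k, 0.0)


def curvature_energy(contour: PolarContour) -> float:
    k = local_mean_curvature(contour)
    return float(np.sum(0.5 * k**2 * (k < 0)) * contour.dtheta)


def area_gradient(area: float, area_min: float, area_max: float) -> float:
    """``(A - A_min) H(A_min - A) + (A_max - A) H(A - A_max)`` (zero in range)."""
    g = 0.0
    if area < area_min:
        g += area - area_min
    if area > area_max:
        g += area_max - area
    return g


def area_range_force(area: float, area_min: float, area_max: float) -> float:
    """Uniform radial force: expand below ``area_min``, shrink above ``area_max``."""
    if area < area_min:
        return area_min - area
    if area > area_max:
        return area_max - area
    return 0.0


def area_range_energy(area: float, area_min: float, area_max: float) -> float:
    if area < area_min:
        return 0.5 * (area - area_min) ** 2
    if area > area_max:
        return 0.5 * (area - area_max) ** 2
    return 0.0


def area_stability(area_t: float, area_prev: float | None) -> float:
    """Relative area change ``|A_t - A_{t-1}| / A_{t-1}`` (0 on the first frame)."""
    if area_prev is None:
        return 0.0
    return abs(area_t - area_prev) / area_prev


def area_stability_force(area_t: float, area_prev: float | None) -> float:
    """Uniform radial restoring force toward the previous frame's area.

    Proportional to the relative area change (the descent direction of the
    differentiable surrogate ``((A_t - A_prev)/A_prev)^2 / 2``), so a cell
    squeezed by its neighbors is pushed back toward its size instead of
    receiving a fixed-magnitude nudge.
    """
    if area_prev is None or area_prev <= 0:
        return 0.0
    return (area_prev - area_t) / area_prev


# -- competition -------------------------------------------------------

def signed_distance_to(contour_j: PolarContour, points: np.ndarray) -> np.ndarray:
    """Euclidean distance from points to contour j's dense boundary, negative inside."""
    poly_xy = contour_polygon(contour_j)
    ring = LinearRing(poly_xy)
    poly = Polygon(poly_xy)
    pts = shapely.points(points[:, 0], points[:, 1])
    d = shapely.distance(pts, ring)
    inside = shapely.contains(poly, pts)
    return np.where(inside, -d, d)


def proximity_penalty(
    contour_i: PolarContour, contour_j: PolarContour, d_thresh: float
) -> np.ndarray:
    """Per-node penalties ``(d_T - psi) H(d_T - psi)`` of contour i against j."""
    psi = signed_distance_to(contour_j, contour_i.node_positions())
    return np.where(psi < d_thresh, d_thresh - psi, 0.0)


def overlap_penalty(contour_i: PolarContour, contour_j: PolarContour, w_comp: float):
    """Overlap-area penalty ``w_comp * A_overlap`` with inward forces on both contours.

    Only nodes lying inside the other contour are pushed, with magnitude
    proportional to their penetration depth.
    """
    poly_i = Polygon(contour_polygon(contour_i))
    poly_j = Polygon(contour_polygon(contour_j))
    if not poly_i.intersects(poly_j):
        z = np.zeros
        return 0.0, z(contour_i.n_nodes), z(contour_j.n_nodes)
    a_c = poly_i.intersection(poly_j).area
    energy = w_comp * a_c
    forces = []
    for this, other in ((contour_i, contour_j), (contour_j, contour_i)):
        psi = signed_distance_to(other, this.node_positions())
        depth = np.where(psi < 0, -psi, 0.0)
        forces.append(-w_comp * depth)
    return energy, forces[0], forces[1]


def total_regularization(
    contour_i: PolarContour,
    neighbors: list[PolarContour],
    prev_area: float | None,
    config: EnergyConfig,
    area: float | None = None,
) -> NodeForces:
    """Weighted sum of all regularization forces on contour i (neighbors frozen)."""
    from .contour import contour_area

    n = contour_i.n_nodes
    a = contour_area(contour_i) if area is None else area
    amin = config.area_min if config.area_min is not None else 0.0
    amax = config.area_max if config.area_max is not None else np.inf

    f_kappa = -config.w_kappa * curvature_gradient(contour_i)
    f_area = np.full(n, config.w_area * area_range_force(a, amin, amax))
    f_as = np.full(n, config.w_area_stab * area_stability_force(a, prev_area))

    f_prox = np.zeros(n)
    f_ov = np.zeros(n)
    e_comp = 0.0
    for nb in neighbors:
        pen = proximity_penalty(contour_i, nb, config.d_thresh)
        f_prox -= pen
        e_comp += float(pen.sum())
        e_ov, f_i, _ = overlap_penalty(contour_i, nb, config.w_comp)
        f_ov += f_i
        e_comp += e_ov

    energy = (
        config.w_kappa * curvature_energy(contour_i)
        + config.w_area * area_range_energy(a, amin, amax)
        + config.w_area_stab * area_stability(a, prev_area)
        + e_comp
    )
    return NodeForces(
        data=np.zeros(n),
        curvature=f_kappa,
        area=f_area,
        area_stab=f_as,
        proximity=f_prox,
        overlap=f_ov,
        energy=energy,
    )
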