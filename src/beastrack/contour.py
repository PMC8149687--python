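"""Explicit closed contours in polar coordinates.

A cell boundary is represented explicitly as ``r = psi(theta)`` around a
movable pole, where ``psi`` is a periodic uniform B-spline

    psi(theta) = sum_k c[k] * beta_d(theta/h - k)

with ``beta_d`` the uniform symmetric B-spline of degree ``d``, knot spacing
``h`` equal to the node interval ``dtheta = 2*pi/N``, and coefficient indices
wrapped modulo N.  This keeps evaluation, smoothing and analytic derivatives
(for curvature) cheap while restricting the boundary to star-shaped,
cell-like topologies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import solve_circulant
from shapely.geometry import Polygon
from skimage.draw import polygon2mask

__all__ = [
    "PolarContour",
    "DoubleContour",
    "bspline_basis",
    "bspline_basis_d1",
    "bspline_basis_d2",
    "make_ellipse_contour",
    "evaluate_radius",
    "fit_coefficients",
    "contour_polygon",
    "contour_mask",
    "contour_area",
    "recentre_and_resample",
    "local_mean_curvature",
    "DegenerateContourError",
]

MIN_RADIUS = 1.0  # px; radii are clamped here so the pole can never cross the boundary


class DegenerateContourError(RuntimeError):
    """The contour can no longer be represented as a star-shaped polar curve."""


def bspline_basis(x: np.ndarray | float, degree: int) -> np.ndarray:
    """Uniform symmetric B-spline ``beta_d`` centered at 0, support [-(d+1)/2, (d+1)/2].

    Evaluated with the classical alternating-sum of shifted truncated powers.
    """
    x = np.asarray(x, dtype=float)
    d = int(degree)
    if d < 0:
        raise ValueError("degree must be >= 0")
    if d == 0:
        # indicator of [-1/2, 1/2) with the symmetric convention at the edges
        return ((x >= -0.5) & (x < 0.5)).astype(float)
    out = np.zeros_like(x)
    for j in range(d + 2):
        t = x + (d + 1) / 2.0 - j
        out += (-1.0) ** j * math.comb(d + 1, j) * np.where(t > 0, t, 0.0) ** d
    # outside the support the alternating sum cancels only to rounding noise
    return np.where(np.abs(x) < (d + 1) / 2.0, out / math.factorial(d), 0.0)


def bspline_basis_d1(x: np.ndarray | float, degree: int) -> np.ndarray:
    """First derivative of ``beta_d`` (degree >= 1)."""
    x = np.asarray(x, dtype=float)
    return bspline_basis(x + 0.5, degree - 1) - bspline_basis(x - 0.5, degree - 1)


def bspline_basis_d2(x: np.ndarray | float, degree: int) -> np.ndarray:
    """Second derivative of ``beta_d`` (degree >= 2)."""
    x = np.asarray(x, dtype=float)
    b = bspline_basis
    return b(x + 1.0, degree - 2) - 2.0 * b(x, degree - 2) + b(x - 1.0, degree - 2)


@dataclass
class PolarContour:
    """Closed boundary ``r = psi(theta)`` about a movable pole.

    Parameters
    ----------
    pole : (2,) array, (x, y) pixel coordinates (continuous, 0-based).
    node_radii : (N,) positive radii at the regular node angles ``k * 2pi/N``.
    degree : B-spline degree (default 2, quadratic).

    ``coefficients`` are fitted so that evaluation interpolates ``node_radii``
    at the node angles.  Angle 0 lies along +x (image columns), increasing
    counter-clockwise in the mathematical sense.
    """

    pole: np.ndarray
    node_radii: np.ndarray
    degree: int = 2
    coefficients: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self):
        self.pole = np.asarray(self.pole, dtype=float).reshape(2)
        self.node_radii = np.maximum(
            np.asarray(self.node_radii, dtype=float).reshape(-1), MIN_RADIUS
        )
        if self.n_nodes < 8:
            raise ValueError("a contour needs at least 8 nodes")
        if self.coefficients is None:
            self.coefficients = fit_coefficients(self.node_radii, self.degree)
        else:
            self.coefficients = np.asarray(self.coefficients, dtype=float).reshape(-1)

    # -- basic geometry -------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.node_radii.shape[0]

    @property
    def dtheta(self) -> float:
        return 2.0 * np.pi / self.n_nodes

    @property
    def node_angles(self) -> np.ndarray:
        return np.arange(self.n_nodes) * self.dtheta

    def node_positions(self) -> np.ndarray:
        """(N, 2) array of node (x, y) coordinates."""
        th = self.node_angles
        return self.pole + self.node_radii[:, None] * np.column_stack(
            [np.cos(th), np.sin(th)]
        )

    def with_radii(self, radii: np.ndarray) -> "PolarContour":
        return PolarContour(self.pole.copy(), radii, self.degree)

    def copy(self) -> "PolarContour":
        return replace(
            self,
            pole=self.pole.copy(),
            node_radii=self.node_radii.copy(),
            coefficients=self.coefficients.copy(),
        )

    # -- spline evaluation ----------------------------------------------
    def _eval_basis(self, angles, basis_fn):
        t = (np.asarray(angles, dtype=float) / self.dtheta) % self.n_nodes
        d = self.degree
        k0 = np.floor(t - (d + 1) / 2.0).astype(int)
        out = np.zeros_like(t)
        for j in range(d + 2):
            k = k0 + 1 + j
            out += self.coefficients[k % self.n_nodes] * basis_fn(t - k, d)
        return out

    def radius(self, angles) -> np.ndarray:
        """psi(theta); periodic, angles wrapped mod 2*pi."""
        return self._eval_basis(angles, bspline_basis)

    def radius_d1(self, angles) -> np.ndarray:
        """d psi / d theta."""
        return self._eval_basis(angles, bspline_basis_d1) / self.dtheta

    def radius_d2(self, angles) -> np.ndarray:
        """d^2 psi / d theta^2."""
        return self._eval_basis(angles, bspline_basis_d2) / self.dtheta**2

    def outward_normals(self, angles=None):
        """Unit outward normals of the curve at the given angles (default: nodes).

        Returns (points, normals), each (M, 2).
        """
        th = self.node_angles if angles is None else np.asarray(angles, dtype=float)
        r = self.radius(th)
        dr = self.radius_d1(th)
        c, s = np.cos(th), np.sin(th)
        # tangent of (r cos, r sin); outward normal is its -90 deg rotation
        tx = dr * c - r * s
        ty = dr * s + r * c
        norm = np.hypot(tx, ty)
        n = np.column_stack([ty, -tx]) / norm[:, None]
        pts = self.pole + r[:, None] * np.column_stack([c, s])
        return pts, n


@dataclass
class DoubleContour:
    """Coupled nucleus + cytoplasm contour pair sharing one pole.

    GCaMP is excluded from the nucleus, so a cell shows a dark nucleus inside
    a bright cytoplasm; the inner contour tracks the nucleus-cytoplasm
    interface and anchors the outer one.  The coupling contract is
    ``r_cyt(theta_k) >= r_nuc(theta_k) + margin`` at every node.
    """

    nucleus: PolarContour
    cytoplasm: PolarContour
    margin: float = 1.0

    def __post_init__(self):
        if self.nucleus.n_nodes != self.cytoplasm.n_nodes:
            raise ValueError("both layers must share the node grid")
        self.nucleus.pole = self.cytoplasm.pole
        self.enforce_ordering()

    def enforce_ordering(self) -> None:
        """Project the cytoplasm radii up so the layer ordering holds."""
        lo = self.nucleus.node_radii + self.margin
        if np.any(self.cytoplasm.node_radii < lo):
            self.cytoplasm.node_radii = np.maximum(self.cytoplasm.node_radii, lo)
            self.cytoplasm.coefficients = fit_coefficients(
                self.cytoplasm.node_radii, self.cytoplasm.degree
            )

    def copy(self) -> "DoubleContour":
        dc = DoubleContour(self.nucleus.copy(), self.cytoplasm.copy(), self.margin)
        return dc


# ----------------------------------------------------------------------
# free functions (operations)
# ----------------------------------------------------------------------

def fit_coefficients(node_radii: np.ndarray, degree: int = 2) -> np.ndarray:
    """Interpolating periodic B-spline coefficients for radii on the node grid.

    With knots on the node grid the collocation matrix is circulant with
    entries ``beta_d(i - k mod N)``; the system is solved spectrally.
    """
    r = np.asarray(node_radii, dtype=float).reshape(-1)
    n = r.shape[0]
    if degree <= 1:
        return r.copy()  # beta_0/beta_1 interpolate at the knots
    lags = np.arange(n)
    lags = np.where(lags > n // 2, lags - n, lags)
    col = bspline_basis(lags.astype(float), degree)
    eig = np.fft.fft(col)
    if np.min(np.abs(eig)) < 1e-12:
        raise np.linalg.LinAlgError("singular periodic interpolation system")
    return np.real(solve_circulant(col, r))


def make_ellipse_contour(
    center, semi_axes, orientation: float = 0.0, n_nodes: int = 32, degree: int = 2
) -> PolarContour:
    """Contour whose nodes lie exactly on the given ellipse.

    ``orientation`` is the angle (radians) of the first semi-axis relative to
    the +x axis.  This is the shape users draw to initialize a cell.
    """
    a, b = float(semi_axes[0]), float(semi_axes[1])
    if a <= 0 or b <= 0:
        raise ValueError("ellipse semi-axes must be positive")
    if n_nodes < 8:
        raise ValueError("n_nodes must be >= 8")
    th = np.arange(n_nodes) * 2.0 * np.pi / n_nodes - float(orientation)
    radii = a * b / np.sqrt((b * np.cos(th)) ** 2 + (a * np.sin(th)) ** 2)
    return PolarContour(np.asarray(center, dtype=float), radii, degree)


def evaluate_radius(contour: PolarContour, angles) -> np.ndarray:
    """``psi(theta)`` for arbitrary angles (wrapped mod 2*pi)."""
    return contour.radius(angles)


def contour_polygon(contour: PolarContour, samples_per_segment: int = 8) -> np.ndarray:
    """Densely sampled closed polygon, (N*s, 2) (x, y), counter-clockwise."""
    n = contour.n_nodes * int(samples_per_segment)
    th = np.arange(n) * 2.0 * np.pi / n
    r = np.maximum(contour.radius(th), MIN_RADIUS * 1e-3)
    return contour.pole + r[:, None] * np.column_stack([np.cos(th), np.sin(th)])


def contour_mask(contour: PolarContour, image_shape, samples_per_segment: int = 8) -> np.ndarray:
    """Boolean interior mask of the contour on an image grid."""
    poly = contour_polygon(contour, samples_per_segment)
    return polygon2mask(image_shape, poly[:, ::-1])  # polygon2mask wants (row, col)


def contour_area(contour: PolarContour, samples_per_segment: int = 8) -> float:
    """Shoelace area (px^2) of the dense boundary polygon."""
    p = contour_polygon(contour, samples_per_segment)
    x, y = p[:, 0], p[:, 1]
    return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)


def contour_centroid(contour: PolarContour, samples_per_segment: int = 8) -> np.ndarray:
    """Area centroid of the contour interior."""
    c = Polygon(contour_polygon(contour, samples_per_segment)).centroid
    return np.array([c.x, c.y])


def recentre_and_resample(contour: PolarContour) -> PolarContour:
    """Translate the pole to the interior centroid and re-grid the nodes.

    After a segmentation step the pole is moved to the geometric centroid of
    the produced shape (so it stays inside the cell even under movement) and
    the nodes are resampled back onto the regular angle grid by linear
    interpolation of the old nodes' polar coordinates about the new pole.
    """
    poly = Polygon(contour_polygon(contour))
    cen = poly.centroid
    if not poly.contains(cen):
        raise DegenerateContourError("centroid fell outside the contour")
    new_pole = np.array([cen.x, cen.y])

    rel = contour.node_positions() - new_pole
    th = np.arctan2(rel[:, 1], rel[:, 0]) % (2.0 * np.pi)
    rr = np.hypot(rel[:, 0], rel[:, 1])
    order = np.argsort(th)
    th, rr = th[order], rr[order]
    # periodic padding for wrap-around interpolation
    th_ext = np.concatenate([th[-1:] - 2.0 * np.pi, th, th[:1] + 2.0 * np.pi])
    rr_ext = np.concatenate([rr[-1:], rr, rr[:1]])
    grid = np.arange(contour.n_nodes) * contour.dtheta
    new_r = np.interp(grid, th_ext, rr_ext)
    if np.any(new_r <= 0):
        raise DegenerateContourError("resampled radius collapsed to zero")
    return PolarContour(new_pole, new_r, contour.degree)


def local_mean_curvature(contour: PolarContour, angles=None) -> np.ndarray:
    """Curvature of the planar curve r(theta) at the node angles.

    kappa = (r^2 + 2 r'^2 - r r'') / (r^2 + r'^2)^(3/2); positive for a
    convex boundary (circle: 1/r).
    """
    th = contour.node_angles if angles is None else np.asarray(angles, dtype=float)
    r = contour.radius(th)
    d1 = contour.radius_d1(th)
    d2 = contour.radius_d2(th)
    return (r**2 + 2.0 * d1**2 - r * d2) / (r**2 + d1**2) ** 1.5
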