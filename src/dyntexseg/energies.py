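"""The four energy terms of the segmentation model.

The partition of the image into thrombus, vessel and background is scored
by a weighted sum of two likelihood energies and two priors:

* motion segmentation: Gaussian likelihood of each pixel's DT model under
  its region's manifold statistics;
* event detection: Gaussian likelihood of the per-pixel Martin distance
  between the initial and the current temporal window (the thrombus is the
  region whose motion pattern *changed*);
* tubular shape prior: pixels of the aortic region pay
  ``exp(d_R^2 / 2 sigma^2) - 1`` with ``d_R`` the distance to an "infinite
  rectangle" (a band of half-width r about the vessel centerline) refit at
  every outer iteration;
* topological prior: the level-set sign class that is neither thrombus,
  vessel nor background is penalized by its (smoothed) area, which keeps
  the thrombus inside the aorta.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize

from .dt_model import DEFAULT_DISTANCE_CAP, DTField
from .errors import DegenerateMask, GridMismatch, MissingStats

# Exponents inside the shape prior are clipped here to keep exp() finite.
_EXP_CLIP = 600.0


# ---------------------------------------------------------------------------
# Motion-segmentation energy
# ---------------------------------------------------------------------------

def motion_segmentation_energy(
    partition: np.ndarray,
    region_terms: dict[int, tuple[np.ndarray, float]],
) -> float:
    """Total motion-segmentation energy of a labelled partition.

    ``region_terms`` maps each label to ``(sq_distance_map, variance)``
    where the (H, W) map holds the squared Martin distance of every pixel's
    model to that region's mean (or Doss expectation).  Empty regions
    contribute zero; a nonempty label without statistics raises
    :class:`MissingStats`.
    """
    partition = np.asarray(partition)
    total = 0.0
    for label in np.unique(partition):
        mask = partition == label
        if int(label) not in region_terms:
            raise MissingStats(f"no statistics for nonempty region {label}")
        sq_map, variance = region_terms[int(label)]
        variance = max(float(variance), 1e-300)
        total += float(np.sum(sq_map[mask] / (2.0 * variance)))
        total += mask.sum() * 0.5 * np.log(variance)
    return total


# ---------------------------------------------------------------------------
# Event detection
# ---------------------------------------------------------------------------

@dataclass
class EventMap:
    """Per-pixel squared Martin distance between two temporal windows."""

    delta: np.ndarray  # (H, W), nonnegative, clamped


def event_detection_map(
    field_t0: DTField,
    field_t: DTField,
    cap: float = DEFAULT_DISTANCE_CAP,
) -> EventMap:
    """Martin distance between the models of two windows at each position.

    Pixels without a model of their own inherit the nearest modeled grid
    node, matching how the energies sample the field.
    """
    if not field_t0.same_grid(field_t):
        raise GridMismatch("event map requires fields with identical grid geometry")
    Q0 = field_t0.orth_observability()
    Q1 = field_t.orth_observability()
    M = np.swapaxes(Q0, 1, 2) @ Q1  # (N, n, n)
    sign, logabs = np.linalg.slogdet(M)
    d2 = -2.0 * logabs
    d2[sign == 0] = np.inf
    d2 = np.clip(d2, 0.0, cap)
    return EventMap(delta=d2[field_t.pixel_model_index()])


def event_detection_energy(
    event_map: EventMap,
    partition: np.ndarray,
    event_stats: dict[int, tuple[float, float]],
) -> float:
    """Gaussian event energy ``sum_k sum_x (delta - mu_k)^2/(2 s_k^2) + log s_k``.

    ``event_stats`` maps labels to ``(mean, std)``.
    """
    partition = np.asarray(partition)
    delta = event_map.delta
    total = 0.0
    for label in np.unique(partition):
        if int(label) not in event_stats:
            raise MissingStats(f"no event statistics for nonempty region {label}")
        mu, sd = event_stats[int(label)]
        sd = max(float(sd), 1e-300)
        mask = partition == label
        total += float(np.sum((delta[mask] - mu) ** 2 / (2.0 * sd ** 2)))
        total += mask.sum() * np.log(sd)
    return total


# ---------------------------------------------------------------------------
# Tubular shape prior
# ---------------------------------------------------------------------------

@dataclass
class Rectangle:
    """An "infinite rectangle": a band of half-width ``radius`` about a
    straight centerline through ``center`` (x, y pixel coordinates)."""

    slope: float            # dy/dx of the centerline (may be +-inf near vertical)
    center: tuple[float, float]   # (x_c, y_c) = (col, row) of the centroid
    radius: float
    angle: float = 0.0      # centerline inclination in radians, in (-pi/2, pi/2]

    def centerline_distance(self, shape: tuple[int, int]) -> np.ndarray:
        """Unsigned distance of every pixel to the centerline."""
        H, W = shape
        yy, xx = np.mgrid[0:H, 0:W].astype(float)
        nx, ny = -np.sin(self.angle), np.cos(self.angle)  # unit normal
        return np.abs(nx * (xx - self.center[0]) + ny * (yy - self.center[1]))

    def band_mask(self, shape: tuple[int, int]) -> np.ndarray:
        return self.centerline_distance(shape) <= self.radius

    def distance_map(self, shape: tuple[int, int]) -> np.ndarray:
        """Distance transform of the band: 0 inside, Euclidean distance to
        the band outside (clipped to the image)."""
        band = self.band_mask(shape)
        if band.all():
            return np.zeros(shape)
        if not band.any():
            return self.centerline_distance(shape)
        return ndimage.distance_transform_edt(~band)


def _pca_centerline(coords_xy: np.ndarray) -> tuple[float, np.ndarray]:
    """First principal axis of (x, y) pixel coordinates: (angle, centroid)."""
    centroid = coords_xy.mean(axis=0)
    centred = coords_xy - centroid
    cov = centred.T @ centred / len(coords_xy)
    evals, evecs = np.linalg.eigh(cov)
    if evals[0] <= 1e-9 * max(evals[1], 1.0):
        raise DegenerateMask("mask is collinear or too small for rectangle fitting")
    direction = evecs[:, np.argmax(evals)]
    angle = np.arctan2(direction[1], direction[0])
    if angle <= -np.pi / 2:
        angle += np.pi
    elif angle > np.pi / 2:
        angle -= np.pi
    return float(angle), centroid


def _boundary_pixels(mask: np.ndarray) -> np.ndarray:
    eroded = ndimage.binary_erosion(mask)
    boundary = mask & ~eroded
    return np.argwhere(boundary)  # (m, 2) as (row, col)


def fit_rectangle(
    vessel_mask: np.ndarray,
    angle_threshold: float = np.deg2rad(30.0),
    refine: bool = True,
) -> Rectangle:
    """Fit an infinite rectangle to the current aortic region.

    The centerline is the first principal axis of the mask's pixel
    coordinates through the centroid; the radius is the median distance of
    the boundary pixels to that line.  When the centerline inclination
    exceeds ``angle_threshold`` the (angle, normal offset, radius) triple is
    refined by Nelder-Mead minimization of the summed squared distances of
    the boundary pixels to the rectangle boundary, which compensates the
    quantization of the PCA slope at steep angles.
    """
    mask = np.asarray(vessel_mask, dtype=bool)
    coords_rc = np.argwhere(mask)
    if len(coords_rc) < 2:
        raise DegenerateMask("rectangle fitting needs at least two pixels")
    coords_xy = coords_rc[:, ::-1].astype(float)  # (x, y) = (col, row)
    angle, centroid = _pca_centerline(coords_xy)

    boundary_rc = _boundary_pixels(mask)
    bx = boundary_rc[:, 1].astype(float)
    by = boundary_rc[:, 0].astype(float)

    def line_dist(a: float, offset: float) -> np.ndarray:
        nx, ny = -np.sin(a), np.cos(a)
        return np.abs(nx * (bx - centroid[0]) + ny * (by - centroid[1]) - offset)

    radius = float(np.median(line_dist(angle, 0.0)))
    offset = 0.0
    if refine and abs(angle) > angle_threshold:
        def objective(params: np.ndarray) -> float:
            a, off, r = params
            return float(np.sum((line_dist(a, off) - abs(r)) ** 2))

        res = optimize.minimize(
            objective, x0=np.array([angle, 0.0, radius]), method="Nelder-Mead",
            options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 400},
        )
        angle, offset, radius = float(res.x[0]), float(res.x[1]), abs(float(res.x[2]))
    center = (
        centroid[0] - np.sin(angle) * offset,
        centroid[1] + np.cos(angle) * offset,
    )
    slope = np.tan(angle) if abs(np.cos(angle)) > 1e-12 else np.inf
    return Rectangle(slope=float(slope), center=(float(center[0]), float(center[1])),
                     radius=max(float(radius), 0.5), angle=float(angle))


def shape_prior_map(rect: Rectangle, shape: tuple[int, int], sigma_sp: float) -> np.ndarray:
    """Per-pixel shape penalty ``exp(d_R^2 / 2 sigma^2) - 1`` (0 inside the band)."""
    d = rect.distance_map(shape)
    expo = np.clip(d ** 2 / (2.0 * sigma_sp ** 2), 0.0, _EXP_CLIP)
    return np.exp(expo) - 1.0


def shape_prior_energy(
    partition: np.ndarray,
    rect: Rectangle,
    sigma_sp: float,
    aortic_labels: tuple[int, ...] = (1, 2),
) -> float:
    """Shape-prior energy over the aortic region (vessel plus thrombus)."""
    if sigma_sp <= 0:
        raise ValueError("sigma_sp must be positive")
    partition = np.asarray(partition)
    mask = np.isin(partition, aortic_labels)
    if not mask.any():
        return 0.0
    penalty = shape_prior_map(rect, partition.shape, sigma_sp)
    return float(penalty[mask].sum())


# ---------------------------------------------------------------------------
# Topological prior and total energy
# ---------------------------------------------------------------------------

def topological_energy(phi1: np.ndarray, phi2: np.ndarray, eps_h: float = 1.5) -> float:
    """Smoothed area of the forbidden sign class (phi1 < 0 and phi2 > 0)."""
    from .levelset_solver import smooth_heaviside

    if phi1.shape != phi2.shape:
        raise ValueError("phi1 and phi2 must share a shape")
    h1 = smooth_heaviside(phi1, eps_h)
    h2 = smooth_heaviside(phi2, eps_h)
    return float(np.sum((1.0 - h1) * h2))


def total_energy(
    e_ms: float,
    e_ed: float,
    e_sp: float,
    e_top: float,
    alpha: float = 1.0,
    beta: float = 0.5,
    gamma: float = 0.1,
    zeta: float = 1.25,
) -> float:
    """Weighted combination ``alpha E_ms + beta E_ed - gamma E_sp + zeta E_top``.

    Note the sign convention: the gradient flow treats the shape prior as a
    penalty (its printed gradient shrinks the aorta away from far pixels),
    so the descent functional uses ``+ gamma E_sp``; this reported
    combination keeps the stated sign.
    """
    return alpha * e_ms + beta * e_ed - gamma * e_sp + zeta * e_top


def descent_energy(
    e_ms: float,
    e_ed: float,
    e_sp: float,
    e_top: float,
    alpha: float = 1.0,
    beta: float = 0.5,
    gamma: float = 0.1,
    zeta: float = 1.25,
) -> float:
    """The functional the gradient flow actually descends
    (``+ gamma E_sp``: the shape prior acts as a penalty)."""
    return alpha * e_ms + beta * e_ed + gamma * e_sp + zeta * e_top
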