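"""Approximate normal statistics on the manifold of DT models.

The manifold of dynamic-texture models has no tractable log/exp maps, so
region statistics are approximated through the Martin distance: the region
mean is either the *Fréchet* mean restricted to the finite set of models
observed in the scene (exhaustive search over candidates) or the *Doss*
surrogate, which replaces the squared distance to the mean by the weighted
expectation of squared distances to a random sample of region models.  The
region variance is the weighted mean of those squared distances over the
region, and the Gaussian negative log-likelihood of a model under a region
is ``d^2 / (2 sigma^2) + log sigma``.

Patches that straddle a region boundary mix two generating processes, so
their models fit neither region.  Confidence weights down-weight them:
``w(y) = min(d(y, boundary)^2, s^2)`` with ``s`` the patch side, normalized
to sum one over the sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .dt_model import DEFAULT_DISTANCE_CAP, DTField, DTModel, _observability_batch
from .errors import EmptyRegion, EmptySamples

#: Floor applied to region variances (squared-distance units).
VARIANCE_FLOOR = 1e-6
#: Floor applied to event-map standard deviations.
EVENT_STD_FLOOR = 1e-3


@dataclass
class RegionStatistics:
    """Manifold and event statistics of one region at one outer iteration."""

    region_id: int
    mean_mode: str                      # 'frechet' or 'doss'
    frechet_mean: DTModel | None        # set only in frechet mode
    sample_positions: np.ndarray        # (m, 2) pixel positions inside the region
    sample_weights: np.ndarray          # (m,) nonnegative, sums to 1
    variance: float                     # sigma^2_k >= VARIANCE_FLOOR
    event_mean: float = 0.0
    event_std: float = 1.0
    empty: bool = False


def _boundary_distance(region_mask: np.ndarray) -> np.ndarray:
    """Distance of in-region pixels to the region boundary (boundary pixels
    score 0); zero outside the region."""
    d = ndimage.distance_transform_edt(region_mask)
    return np.maximum(d - 1.0, 0.0)


def confidence_weights(
    region_mask: np.ndarray,
    sample_positions: np.ndarray,
    patch_side: int = 5,
) -> np.ndarray:
    """Boundary-confidence weights ``min(d^2, s^2)`` normalized to sum 1.

    ``sample_positions`` is an (m, 2) array of (row, col) pixel positions
    inside the region; ``s`` is the patch side.  When every raw weight is
    zero (all samples on the boundary) the weights fall back to uniform.
    """
    region_mask = np.asarray(region_mask, dtype=bool)
    pos = np.atleast_2d(np.asarray(sample_positions, dtype=int))
    if pos.size == 0 or not region_mask.any():
        raise EmptyRegion("confidence weights need a nonempty region and samples")
    if not region_mask[pos[:, 0], pos[:, 1]].all():
        raise ValueError("sample positions must lie inside the region")
    d = _boundary_distance(region_mask)[pos[:, 0], pos[:, 1]]
    raw = np.minimum(d ** 2, float(patch_side) ** 2)
    total = raw.sum()
    if total <= 0:
        return np.full(len(raw), 1.0 / len(raw))
    return raw / total


def _model_orth_obs(model: DTModel) -> np.ndarray:
    obs = _observability_batch(model.A[None], model.C[None])
    q, _ = np.linalg.qr(obs)
    return q


def _positions_to_flat(field: DTField, positions: np.ndarray) -> np.ndarray:
    pos = np.atleast_2d(np.asarray(positions, dtype=int))
    index_map = field.pixel_model_index()
    return index_map[pos[:, 0], pos[:, 1]]


def sample_sq_distances(
    field: DTField,
    sample_positions: np.ndarray,
    cap: float = DEFAULT_DISTANCE_CAP,
) -> np.ndarray:
    """Squared Martin distances from every field model to each sample model,
    shape ``(n_models, m)``; the workhorse behind Doss maps and variances."""
    from .dt_model import pairwise_sq_distances

    flat = _positions_to_flat(field, sample_positions)
    Q = field.orth_observability()
    return pairwise_sq_distances(Q, Q[flat], cap=cap)


def doss_sq_distance(
    x_model: DTModel,
    field: DTField,
    sample_positions: np.ndarray,
    weights: np.ndarray,
    cap: float = DEFAULT_DISTANCE_CAP,
) -> float:
    """Doss surrogate for the squared distance of ``x_model`` to the region
    mean: ``sum_y w(y) d_M(x, D_y)^2`` over the sampled region models."""
    from .dt_model import pairwise_sq_distances

    pos = np.atleast_2d(np.asarray(sample_positions, dtype=int))
    if pos.size == 0:
        raise EmptySamples("doss_sq_distance needs at least one sample")
    flat = _positions_to_flat(field, pos)
    qx = _model_orth_obs(x_model)
    d2 = pairwise_sq_distances(qx[None] if qx.ndim == 2 else qx, field.orth_observability()[flat], cap=cap)
    return float(d2[0] @ np.asarray(weights, dtype=float))


def frechet_mean(
    field: DTField,
    sample_positions: np.ndarray,
    weights: np.ndarray,
    candidate_positions: np.ndarray | None = None,
    cap: float = DEFAULT_DISTANCE_CAP,
) -> tuple[DTModel, int]:
    """Exhaustive Fréchet mean over a finite candidate set.

    Returns the candidate model minimizing ``sum_y w(y) d_M(c, D_y)^2`` and
    the flat model index it came from.  Candidates default to the whole
    modeled grid; ties break to the lowest flat (linear) index, which the
    candidate ordering guarantees for ``np.argmin``.
    """
    from .dt_model import pairwise_sq_distances

    pos = np.atleast_2d(np.asarray(sample_positions, dtype=int))
    if pos.size == 0:
        raise EmptySamples("frechet_mean needs at least one sample")
    w = np.asarray(weights, dtype=float)
    flat_samples = _positions_to_flat(field, pos)
    Q = field.orth_observability()
    if candidate_positions is None:
        cand_flat = np.arange(field.n_models)
    else:
        cand_flat = np.unique(_positions_to_flat(field, candidate_positions))
    d2 = pairwise_sq_distances(Q[cand_flat], Q[flat_samples], cap=cap)
    objective = d2 @ w
    best = int(cand_flat[int(np.argmin(objective))])
    return field.flat_model(best), best


def region_variance(
    field: DTField,
    region_mask: np.ndarray,
    region_weights: np.ndarray | None,
    sq_distance_map: np.ndarray,
) -> float:
    """Region variance ``sigma^2 = sum_x p(x) d^2(D_x, mean)`` (floored).

    ``sq_distance_map`` is an (H, W) map of squared distances to the region
    mean (Fréchet) or the Doss expectation; ``region_weights`` an (H, W)
    nonnegative weight field (normalized internally over the region), or
    None for uniform weights.
    """
    region_mask = np.asarray(region_mask, dtype=bool)
    if not region_mask.any():
        raise EmptyRegion("region_variance needs a nonempty region")
    d2 = sq_distance_map[region_mask]
    if region_weights is None:
        var = float(d2.mean())
    else:
        w = np.asarray(region_weights, dtype=float)[region_mask]
        total = w.sum()
        if total <= 0:
            var = float(d2.mean())
        else:
            var = float((w / total) @ d2)
    return max(var, VARIANCE_FLOOR)


def region_log_likelihood(sq_distance: np.ndarray | float, variance: float) -> np.ndarray | float:
    """Gaussian negative log-likelihood ``d^2/(2 sigma^2) + log sigma``."""
    variance = max(float(variance), VARIANCE_FLOOR)
    return np.asarray(sq_distance) / (2.0 * variance) + 0.5 * np.log(variance)


def model_region_log_likelihood(
    x_model: DTModel,
    stats: RegionStatistics,
    field: DTField,
    cap: float = DEFAULT_DISTANCE_CAP,
) -> float:
    """Negative log-likelihood of one model under a region's statistics,
    using the region's configured mean notion (Doss or Fréchet)."""
    from .dt_model import martin_distance

    if stats.mean_mode == "frechet" and stats.frechet_mean is not None:
        d2 = martin_distance(x_model, stats.frechet_mean, cap=cap)
    else:
        d2 = doss_sq_distance(x_model, field, stats.sample_positions,
                              stats.sample_weights, cap=cap)
    return float(region_log_likelihood(d2, stats.variance))


def compute_region_statistics(
    field: DTField,
    region_mask: np.ndarray,
    region_id: int,
    rng: np.random.Generator,
    n_samples: int = 60,
    mean_mode: str = "doss",
    event_delta: np.ndarray | None = None,
    cap: float = DEFAULT_DISTANCE_CAP,
) -> tuple[RegionStatistics, np.ndarray]:
    """Sample a region, estimate its manifold mean/variance and event stats.

    Returns ``(stats, sq_distance_map)`` where the (H, W) map holds the
    squared distance of every pixel's model to the region (mean or Doss
    expectation); for an empty region the stats are flagged and the map is
    filled with the cap so no pixel is attracted to the region.
    """
    region_mask = np.asarray(region_mask, dtype=bool)
    H, W = field.image_shape
    if not region_mask.any():
        stats = RegionStatistics(
            region_id=region_id, mean_mode=mean_mode, frechet_mean=None,
            sample_positions=np.empty((0, 2), dtype=int),
            sample_weights=np.empty(0), variance=VARIANCE_FLOOR, empty=True,
        )
        return stats, np.full((H, W), cap)

    coords = np.argwhere(region_mask)
    k = min(n_samples, len(coords))
    sel = rng.choice(len(coords), size=k, replace=False)
    positions = coords[np.sort(sel)]
    weights = confidence_weights(region_mask, positions, patch_side=field.patch_side)

    d2_samples = sample_sq_distances(field, positions, cap=cap)  # (N_models, m)
    index_map = field.pixel_model_index()
    mean_model = None
    if mean_mode == "frechet":
        mean_model, best = frechet_mean(field, positions, weights,
                                        candidate_positions=coords, cap=cap)
        from .dt_model import pairwise_sq_distances

        Q = field.orth_observability()
        d2_flat = pairwise_sq_distances(Q, Q[best][None], cap=cap)[:, 0]
    elif mean_mode == "doss":
        d2_flat = d2_samples @ weights
    else:
        raise ValueError(f"unknown mean_mode {mean_mode!r}")
    sq_map = d2_flat[index_map]

    conf = np.zeros((H, W))
    bd = _boundary_distance(region_mask)
    conf[region_mask] = np.minimum(bd[region_mask] ** 2, float(field.patch_side) ** 2)
    var = region_variance(field, region_mask, conf, sq_map)

    stats = RegionStatistics(
        region_id=region_id, mean_mode=mean_mode, frechet_mean=mean_model,
        sample_positions=positions, sample_weights=weights, variance=var,
    )
    if event_delta is not None:
        vals = event_delta[region_mask]
        stats.event_mean = float(vals.mean())
        stats.event_std = max(float(vals.std()), EVENT_STD_FLOOR)
    return stats, sq_map
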