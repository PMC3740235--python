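"""Backward tracking of the thrombus and vessel through a sequence.

The thrombus only exists late in a recording, so segmentation starts at the
last temporal window (where a polygon initialization is possible) and is
propagated backward: the result at frame ``t+k`` initializes frame ``t``,
and a small temporal term keeps the vessel contour close to its previous
position.  Active segmentation runs every ``decimation``-th frame (emulating
a 25 -> 2.5 fps reduction); skipped frames are filled by shape-based
interpolation of the signed distance fields.  When the backward-propagated
thrombus contour vanishes (pre-attachment regime) earlier frames run in
two-region mode with an empty thrombus.

From the per-frame partitions the tracker extracts the thrombus surface
area (TSA) series and the time to attachment (TTA), the first time the
thrombus area reaches a configurable threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from scipy import ndimage

from .dt_model import compute_dt_field
from .energies import event_detection_map
from .errors import SequenceTooShort, ZeroReference
from .levelset_solver import (
    THROMBUS,
    VESSEL,
    SegmentationResult,
    SolverConfig,
    segment,
    signed_distance,
)

#: Physical pixel size (width, height) in micrometres: a 110 um x 70 um
#: field of view imaged at 200 x 125 pixels.
DEFAULT_PIXEL_SIZE_UM = (0.55, 0.56)


@dataclass
class TrackerConfig:
    solver: SolverConfig = field(default_factory=SolverConfig)
    decimation: int = 10          # active segmentation every k-th frame
    epsilon_temporal: float = 1e-2  # vessel temporal-regularization weight
    min_area: int = 5             # px threshold operationalizing "attachment"
    frame_rate: float = 25.0      # frames per second
    pixel_size_um: tuple[float, float] = DEFAULT_PIXEL_SIZE_UM
    warm_max_outer: int = 5       # outer iterations for warm-started frames
    event_z_threshold: float = 1.0
    """A thrombus only exists where the motion pattern *changed* relative to
    the initial window: at every propagated frame the thrombus embedding is
    re-seeded from the connected component of the (smoothed) event map that
    exceeds the aortic median by this many standard deviations and overlaps
    the thrombus of the previously segmented (later) frame.  When no such
    component remains, the contour has vanished (pre-attachment regime).
    Only applied when the event energy is active (beta > 0)."""
    event_smooth_sigma: float = 3.0
    tau_event: int | None = 30
    """Transitions of the (shorter) window used for the event map.  The
    motion statistics benefit from a long window, but a long window smears
    the attachment time by up to half its length; the event map therefore
    uses its own, shorter window.  None reuses the main window."""


@dataclass
class TrackResult:
    frame_labels: np.ndarray        # (H, W, T) uint8
    active_frames: list[int]        # ascending frame indices actively segmented
    tsa_px: np.ndarray              # (T,) thrombus area in pixels
    tsa_um2: np.ndarray             # (T,) thrombus area in um^2
    vessel_px: np.ndarray           # (T,) uncoagulated-vessel area in pixels
    tta_s: float | None             # seconds, None when never attached
    meta: dict


def plug_tracking_config(seed: int = 0, **solver_overrides) -> TrackerConfig:
    """Tracker configuration for synthetic growing-plug sequences: order-4
    models over a 51-frame window on a stride-2 grid, motion + event
    likelihoods with the topological prior, 10-frame decimation."""
    base = dict(
        alpha=1.0, beta=0.5, gamma=0.0, zeta=1.25, n=4, tau=50,
        stride=2, n_samples=40, max_outer=15, max_inner=25,
        lambda_d=0.1, eta_infinite=True, seed=seed,
    )
    base.update(solver_overrides)
    from .levelset_solver import SolverConfig

    return TrackerConfig(
        solver=SolverConfig(**base),
        decimation=10,
        warm_max_outer=8,
    )


def shape_interpolate(mask_a: np.ndarray, mask_b: np.ndarray, u: float) -> np.ndarray:
    """Shape-based interpolation: threshold of the blended signed distances.

    ``u = 0`` returns ``mask_a`` exactly, ``u = 1`` returns ``mask_b``.
    """
    if mask_a.shape != mask_b.shape:
        raise ValueError("masks must share a shape")
    sdf = (1.0 - u) * signed_distance(mask_a) + u * signed_distance(mask_b)
    return sdf < 0


def compute_tta(
    frame_labels: np.ndarray, frame_rate: float, min_area: int = 5
) -> float | None:
    """Time (s) of the first frame whose thrombus area reaches ``min_area``.

    Returns None when the thrombus never reaches the threshold.
    """
    if frame_rate <= 0:
        raise ValueError("frame_rate must be positive")
    areas = np.sum(np.asarray(frame_labels) == THROMBUS, axis=(0, 1))
    hits = np.nonzero(areas >= min_area)[0]
    if len(hits) == 0:
        return None
    return float(hits[0]) / frame_rate


def compute_tsa(
    frame_labels: np.ndarray,
    pixel_size_um: tuple[float, float] = DEFAULT_PIXEL_SIZE_UM,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame thrombus area in pixels and in um^2 (per-axis pixel scale)."""
    areas = np.sum(np.asarray(frame_labels) == THROMBUS, axis=(0, 1)).astype(float)
    return areas, areas * pixel_size_um[0] * pixel_size_um[1]


def normalized_sad(tsa_est: np.ndarray, tsa_gt: np.ndarray) -> float:
    """Normalized sum of absolute differences between two area series.

    ``sum |est - gt| / sum gt``; tends to 0 for a faithful estimate and
    exceeds 1 when the error is larger than the quantity itself.
    """
    est = np.asarray(tsa_est, dtype=float)
    gt = np.asarray(tsa_gt, dtype=float)
    if est.shape != gt.shape:
        raise ValueError("series must have equal length")
    total = gt.sum()
    if total <= 0:
        raise ZeroReference("ground-truth series sums to zero")
    return float(np.abs(est - gt).sum() / total)


def track(
    sequence: np.ndarray,
    init_polygons: tuple[np.ndarray | None, np.ndarray],
    config: TrackerConfig | None = None,
) -> TrackResult:
    """Segment the last window from polygons, propagate backward, measure.

    ``init_polygons`` is ``(thrombus_polygon_or_None, vessel_polygon)`` in
    (row, col) vertices, placed at the *last* temporal window where the
    thrombus has developed.
    """
    config = config or TrackerConfig()
    solver = config.solver
    sequence = np.asarray(sequence, dtype=float)
    H, W, T = sequence.shape
    tau = solver.tau
    half = tau // 2
    if T <= tau:
        raise SequenceTooShort(f"sequence of {T} frames needs more than tau={tau}")

    t_last = T - 1 - half
    t_min = half
    active = list(range(t_last, t_min - 1, -config.decimation))

    tau_e = config.tau_event if config.tau_event is not None else tau
    half_e = tau_e // 2
    field_t0_short = None
    if solver.beta != 0.0:
        # The event map uses the short window: a long window smears the
        # attachment time backward by up to half its length.  The motion
        # statistics keep the main (longer) window.
        field_t0_short = compute_dt_field(
            sequence, (0, tau_e + 1), patch_side=solver.patch_side,
            n=solver.n, stride=solver.stride,
        )

    def _event_candidate(delta: np.ndarray, aorta: np.ndarray,
                         prev_thr: np.ndarray | None) -> np.ndarray | None:
        """Connected component of elevated event response that continues the
        previously tracked thrombus; None when no credible component exists."""
        sm = ndimage.gaussian_filter(delta, config.event_smooth_sigma)
        vals = sm[aorta]
        if vals.size == 0:
            return None
        mu = float(np.median(vals))
        sd = max(float(vals.std()), 1e-12)
        cand = ((sm - mu) / sd > config.event_z_threshold) & aorta
        lab_cc, ncc = ndimage.label(cand)
        if ncc == 0:
            return None
        sel = None
        if prev_thr is None or not prev_thr.any():
            sizes = ndimage.sum(cand, lab_cc, range(1, ncc + 1))
            sel = lab_cc == int(np.argmax(sizes)) + 1
        else:
            ref = ndimage.binary_dilation(prev_thr, iterations=3)
            best = 0
            for c in range(1, ncc + 1):
                m = lab_cc == c
                ov = int((m & ref).sum())
                if ov > best:
                    best, sel = ov, m
        if sel is None or sel.sum() < config.min_area:
            return None
        return sel

    results: dict[int, SegmentationResult] = {}
    prev: SegmentationResult | None = None
    two_region = False
    for t in active:
        window = (t - half, t - half + tau + 1)
        frame_seed = int((solver.seed * 9973 + t) % (2 ** 31))
        field_t = compute_dt_field(
            sequence, window, patch_side=solver.patch_side,
            n=solver.n, stride=solver.stride,
        )
        ev = None
        if field_t0_short is not None:
            field_te = compute_dt_field(
                sequence, (t - half_e, t - half_e + tau_e + 1),
                patch_side=solver.patch_side, n=solver.n, stride=solver.stride,
            )
            ev = event_detection_map(field_t0_short, field_te)
        if prev is None:
            res = segment(
                sequence, window,
                init_polygons=init_polygons, config=replace(solver, seed=frame_seed),
                field_t=field_t, event_map=ev,
            )
        else:
            cfg = replace(solver, seed=frame_seed, max_outer=config.warm_max_outer)
            aorta_prev = prev.state.phi2 < 0
            phi1 = None
            if not two_region:
                if ev is not None:
                    # Re-seed the thrombus from the event map: the thrombus
                    # is the region whose motion changed, and re-deriving it
                    # each frame prevents drift of the backward-propagated
                    # contour.
                    cand = _event_candidate(ev.delta, aorta_prev,
                                            prev.thrombus_mask)
                    if cand is None:
                        two_region = True
                    else:
                        phi1 = signed_distance(cand)
                elif prev.thrombus_mask.any():
                    phi1 = signed_distance(prev.thrombus_mask)
                else:
                    two_region = True
            res = segment(
                sequence, window,
                init_phis=(phi1, prev.state.phi2), config=cfg,
                two_region=phi1 is None, field_t=field_t, event_map=ev,
                phi2_prev=prev.state.phi2,
                epsilon_temporal=config.epsilon_temporal,
            )
            if not two_region and not res.thrombus_mask.any():
                two_region = True  # pre-attachment regime for earlier frames
        results[t] = res
        prev = res

    active_sorted = sorted(results)
    thr_masks = {t: results[t].thrombus_mask for t in results}
    aorta_masks = {t: results[t].aorta_mask for t in results}

    labels_out = np.zeros((H, W, T), dtype=np.uint8)

    def compose(thr: np.ndarray, aorta: np.ndarray) -> np.ndarray:
        out = np.zeros((H, W), dtype=np.uint8)
        out[aorta] = VESSEL
        out[thr & aorta] = THROMBUS
        return out

    for t in range(T):
        if t <= active_sorted[0]:
            ta = tb = active_sorted[0]
        elif t >= active_sorted[-1]:
            ta = tb = active_sorted[-1]
        else:
            idx = np.searchsorted(active_sorted, t)
            ta, tb = active_sorted[idx - 1], active_sorted[idx]
        if ta == tb or t == ta:
            labels_out[:, :, t] = compose(thr_masks[ta], aorta_masks[ta])
        elif t == tb:
            labels_out[:, :, t] = compose(thr_masks[tb], aorta_masks[tb])
        else:
            u = (t - ta) / (tb - ta)
            thr = shape_interpolate(thr_masks[ta], thr_masks[tb], u)
            aorta = shape_interpolate(aorta_masks[ta], aorta_masks[tb], u)
            labels_out[:, :, t] = compose(thr, aorta)

    tsa_px, tsa_um2 = compute_tsa(labels_out, config.pixel_size_um)
    vessel_px = np.sum(labels_out == VESSEL, axis=(0, 1)).astype(float)
    tta = compute_tta(labels_out, config.frame_rate, config.min_area)
    return TrackResult(
        frame_labels=labels_out,
        active_frames=active_sorted,
        tsa_px=tsa_px,
        tsa_um2=tsa_um2,
        vessel_px=vessel_px,
        tta_s=tta,
        meta={
            "frame_rate": config.frame_rate,
            "pixel_size_um": config.pixel_size_um,
            "decimation": config.decimation,
            "min_area": config.min_area,
            "tau": tau,
        },
    )
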