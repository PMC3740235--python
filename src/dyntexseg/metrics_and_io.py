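"""Evaluation metrics, sequence/label I/O and configuration loading.

The label legend is fixed package-wide: 0 background, 1 vessel, 2 thrombus,
3 forbidden (the transient level-set sign class penalized by the
topological prior).  For evaluation, forbidden pixels count as background.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from sklearn.metrics import rand_score

from .errors import EmptyDirectory, MixedBitDepth, ShapeMismatch, UnreadableFile
from .levelset_solver import BACKGROUND, FORBIDDEN, SolverConfig
from .tracker import TrackerConfig, TrackResult

LABEL_LEGEND = {0: "background", 1: "vessel", 2: "thrombus", 3: "forbidden"}


@dataclass
class LabelMap:
    """An (H, W) small-integer label field with the fixed legend."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        bad = set(np.unique(self.labels).tolist()) - set(LABEL_LEGEND)
        if bad:
            raise ValueError(f"labels outside the legend: {sorted(bad)}")

    @property
    def forbidden_count(self) -> int:
        return int(np.sum(self.labels == FORBIDDEN))


def _merge_forbidden(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    if (labels == FORBIDDEN).any():
        labels = np.where(labels == FORBIDDEN, BACKGROUND, labels)
    return labels


def rand_index(labels_a: np.ndarray, labels_b: np.ndarray) -> float:
    """Fraction of pixel pairs on which two partitions agree.

    Forbidden pixels are scored as background.  Computed through the
    contingency-table identity (pair counting), which equals exhaustive
    pair enumeration.
    """
    a = _merge_forbidden(labels_a)
    b = _merge_forbidden(labels_b)
    if a.shape != b.shape:
        raise ShapeMismatch(f"label shapes differ: {a.shape} vs {b.shape}")
    return float(rand_score(a.ravel(), b.ravel()))


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice coefficient ``2|A & B| / (|A| + |B|)``; 1 when both masks are empty."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ShapeMismatch(f"mask shapes differ: {a.shape} vs {b.shape}")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)


def cross_stability(masks: list[np.ndarray]) -> float:
    """Mean pairwise Dice over repeated runs, diagonal included:
    ``(1/n^2) sum_p sum_q DC(mask_p, mask_q)``.  Tends to 1 when the runs
    agree, to 0 when they do not."""
    if len(masks) < 1:
        raise ValueError("cross_stability needs at least one mask")
    n = len(masks)
    total = 0.0
    for p in range(n):
        for q in range(n):
            total += dice(masks[p], masks[q])
    return total / (n * n)


# ---------------------------------------------------------------------------
# Sequence and label I/O
# ---------------------------------------------------------------------------

_FRAME_SUFFIXES = {".png", ".tif", ".tiff"}


def _normalize(stack: np.ndarray) -> np.ndarray:
    if stack.dtype == np.uint8:
        return stack.astype(float) / 255.0
    if stack.dtype == np.uint16:
        return stack.astype(float) / 65535.0
    return np.clip(stack.astype(float), 0.0, 1.0)


def read_sequence(path: str | Path) -> np.ndarray:
    """Read a grayscale sequence into an (H, W, T) float stack in [0, 1].

    Accepts a multi-page TIFF or a directory of lexicographically sorted
    PNG/TIFF frames (8- or 16-bit); mixing bit depths across frames raises
    :class:`MixedBitDepth`.
    """
    import imageio.v3 as iio

    path = Path(path)
    if path.is_dir():
        frames_files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in _FRAME_SUFFIXES
        )
        if not frames_files:
            raise EmptyDirectory(f"no PNG/TIFF frames in {path}")
        frames = []
        dtype = None
        for fp in frames_files:
            try:
                frame = iio.imread(fp)
            except Exception as exc:
                raise UnreadableFile(f"cannot read frame {fp.name}: {exc}") from exc
            if frame.ndim == 3:
                frame = frame[..., 0]
            if dtype is None:
                dtype = frame.dtype
            elif frame.dtype != dtype:
                raise MixedBitDepth(
                    f"frame {fp.name} has dtype {frame.dtype}, expected {dtype}"
                )
            frames.append(frame)
        stack = np.stack(frames, axis=-1)
        return _normalize(stack)
    try:
        pages = tifffile.imread(path)
    except Exception as exc:
        raise UnreadableFile(f"cannot read {path}: {exc}") from exc
    if pages.ndim == 2:
        pages = pages[None]
    return _normalize(np.moveaxis(pages, 0, -1))


def write_sequence(path: str | Path, stack: np.ndarray, bits: int = 16) -> None:
    """Write an (H, W, T) float stack in [0, 1] as a multi-page TIFF."""
    stack = np.clip(np.asarray(stack, dtype=float), 0.0, 1.0)
    if bits == 16:
        data = np.round(stack * 65535.0).astype(np.uint16)
    elif bits == 8:
        data = np.round(stack * 255.0).astype(np.uint8)
    else:
        raise ValueError("bits must be 8 or 16")
    tifffile.imwrite(path, np.moveaxis(data, -1, 0))


def write_labels(path: str | Path, labels: np.ndarray) -> None:
    """Write (H, W) or (H, W, T) label maps as 8-bit single-channel TIFF pages."""
    labels = np.asarray(labels)
    if labels.ndim == 2:
        labels = labels[:, :, None]
    tifffile.imwrite(path, np.moveaxis(labels.astype(np.uint8), -1, 0))


def read_labels(path: str | Path) -> np.ndarray:
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    return np.moveaxis(pages.astype(np.uint8), 0, -1)


def write_measures(prefix: str | Path, result: TrackResult) -> tuple[Path, Path]:
    """Write a TrackResult as CSV (per-frame measures) plus a JSON sidecar.

    Returns the two paths written: ``<prefix>.csv`` and ``<prefix>.json``.
    """
    prefix = Path(prefix)
    T = len(result.tsa_px)
    active = np.zeros(T, dtype=bool)
    active[result.active_frames] = True
    df = pd.DataFrame({
        "frame": np.arange(T),
        "time_s": np.arange(T) / result.meta["frame_rate"],
        "tsa_px": result.tsa_px,
        "tsa_um2": result.tsa_um2,
        "vessel_px": result.vessel_px,
        "active_flag": active.astype(int),
    })
    csv_path = prefix.with_suffix(".csv")
    json_path = prefix.with_suffix(".json")
    df.to_csv(csv_path, index=False)
    sidecar = {"tta_s": result.tta_s, "meta": result.meta}
    json_path.write_text(json.dumps(sidecar, indent=2))
    return csv_path, json_path


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

def solver_config_from_dict(data: dict) -> SolverConfig:
    known = {f for f in SolverConfig.__dataclass_fields__}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown solver config keys: {sorted(unknown)}")
    return SolverConfig(**data)


def tracker_config_from_dict(data: dict) -> TrackerConfig:
    data = dict(data)
    solver = solver_config_from_dict(data.pop("solver", {}))
    known = {f for f in TrackerConfig.__dataclass_fields__} - {"solver"}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown tracker config keys: {sorted(unknown)}")
    return TrackerConfig(solver=solver, **data)


def load_config(path: str | Path) -> dict:
    """Load a YAML/key-value configuration file into a plain dict."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return data or {}


def dump_config(config: SolverConfig | TrackerConfig) -> dict:
    return asdict(config)
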