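"""Synthetic scenes with known dynamic-texture ground truth.

This module generates every fixture the rest of the package is tested
against: single-patch LDS draws, multi-region dynamic-texture scenes,
temporally shifted event pairs, a bright tubular vessel phantom with
collateral branches, and a growing-plug sequence with known per-frame
thrombus area.

Region textures are built from quadrature sinusoid pairs: the spatial modes
of region ``k`` are ``cos(k_j . x)`` / ``sin(k_j . x)`` pairs driven by a
shared hidden state that rotates and decays (a stable LDS).  A translated
patch sees a phase-shifted restriction of the same pair, which spans the
same two-dimensional function space, so every interior patch of a region is
an *exact* LDS with the same transition dynamics and a translation-invariant
observability subspace.  Distinct regions use distinct frequencies and
rotation rates, which separates them in Martin distance.  Three presets
mirror the motion regimes of an injured-vessel microscopy scene: a slow,
coherent thrombus-like texture, a fast chaotic blood-flow texture, and a
near-static low-amplitude background.

All generators are pure functions of their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


# ---------------------------------------------------------------------------
# Patch-level LDS fixtures
# ---------------------------------------------------------------------------

@dataclass
class LDSSpec:
    """A fully specified stable LDS for one spatio-temporal patch."""

    A: np.ndarray       # (n, n), spectral radius < 1
    C: np.ndarray       # (p, n), orthonormal columns
    y_bar: np.ndarray   # (p,)
    Q: np.ndarray       # (n, n) state-noise covariance
    R: np.ndarray       # (p, p) observation-noise covariance (diagonal)
    seed: int

    @property
    def n(self) -> int:
        return self.A.shape[0]

    @property
    def p(self) -> int:
        return self.C.shape[0]


def random_stable_lds(
    n: int,
    p: int,
    seed: int,
    smoothness: float = 1.0,
    q_std: float = 0.1,
    r_std: float = 0.01,
    spectral_radius: float = 0.95,
) -> LDSSpec:
    """Draw a reproducible random stable LDS.

    ``A`` is a Gaussian matrix rescaled to the requested spectral radius;
    ``C`` holds orthonormalized spatially smoothed Gaussian modes
    (``smoothness`` is the Gaussian blur width along the pixel axis, in
    pixels; 0 disables smoothing).
    """
    if n > p:
        raise ValueError("order n must not exceed patch pixel count p")
    rng = np.random.default_rng(seed)
    A = rng.standard_normal((n, n))
    radius = np.max(np.abs(np.linalg.eigvals(A)))
    A *= spectral_radius / max(radius, 1e-12)
    raw = rng.standard_normal((p, n))
    if smoothness > 0:
        raw = ndimage.gaussian_filter1d(raw, smoothness, axis=0, mode="nearest")
    C, _ = np.linalg.qr(raw)
    y_bar = np.full(p, 0.5)
    return LDSSpec(
        A=A, C=C, y_bar=y_bar,
        Q=(q_std ** 2) * np.eye(n),
        R=(r_std ** 2) * np.eye(p),
        seed=seed,
    )


def simulate_lds(spec: LDSSpec, T: int, z0: np.ndarray | None = None) -> np.ndarray:
    """Run the LDS forward for ``T`` frames; returns a (p, T) intensity matrix.

    Iterates ``z(t+1) = A z(t) + v(t)``, ``y(t) = y_bar + C z(t) + w(t)``
    with seeded Gaussian noise; intensities are clipped to [0, 1].
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n, spec.p
    z = np.zeros(n) if z0 is None else np.asarray(z0, dtype=float).copy()
    q_sqrt = np.linalg.cholesky(spec.Q + 1e-300 * np.eye(n))
    r_std = np.sqrt(np.diag(spec.R))
    out = np.empty((p, T))
    for t in range(T):
        w = r_std * rng.standard_normal(p)
        out[:, t] = spec.y_bar + spec.C @ z + w
        v = q_sqrt @ rng.standard_normal(n)
        z = spec.A @ z + v
    return np.clip(out, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Region texture presets and scene rendering
# ---------------------------------------------------------------------------

@dataclass
class TexturePreset:
    """Parameters of one region's quadrature-mode texture.

    ``freqs`` lists one spatial frequency vector (ky, kx) in rad/px per
    quadrature pair; the model order is ``2 * len(freqs)``.  ``rho`` and
    ``omegas`` define the per-pair damped rotation of the hidden state
    (spectral radius and rotation rate in rad/frame).  ``amp`` scales the
    spatial modes (intensity units), ``noise`` is the per-pixel observation
    noise std, and ``y_level`` the mean intensity.
    """

    name: str
    freqs: tuple[tuple[float, float], ...]
    rho: float
    omegas: tuple[float, ...]
    amp: float = 0.1
    noise: float = 0.01
    y_level: float = 0.5

    @property
    def order(self) -> int:
        return 2 * len(self.freqs)


def thrombus_preset() -> TexturePreset:
    """Slow, coherent texture (aggregating blood cells moving with the
    heart beat: ~1 Hz phase advance at 25 fps)."""
    return TexturePreset(
        name="thrombus_slow",
        freqs=((0.62, -0.30), (-0.28, 0.66)),
        rho=0.96,
        omegas=(0.30, 0.45),
        amp=0.08,
        noise=0.093,
    )


def vessel_preset() -> TexturePreset:
    """Fast, chaotic texture (circulating blood cells)."""
    return TexturePreset(
        name="vessel_fast",
        freqs=((0.70, 0.45), (0.35, 0.80)),
        rho=0.80,
        omegas=(0.90, 1.40),
        amp=0.08,
        noise=0.133,
    )


def background_preset() -> TexturePreset:
    """Slow near-static texture (epithelium / background drift).

    Spatial frequencies and noise of the three presets are chosen so that
    every region's estimated models form clusters of comparable dispersion
    (no region acts as a likelihood catch-all); regions are told apart by
    mode orientation and state dynamics, as in real scenes.
    """
    return TexturePreset(
        name="background_static",
        freqs=((0.75, 0.10), (0.05, 0.72)),
        rho=0.95,
        omegas=(0.15, 0.22),
        amp=0.08,
        noise=0.12,
    )


def event_foreground_preset() -> TexturePreset:
    """Alternative fast texture used as the post-event foreground."""
    return TexturePreset(
        name="event_foreground",
        freqs=((0.50, 0.85), (0.95, 0.25)),
        rho=0.92,
        omegas=(0.45, 0.70),
        amp=0.08,
        noise=0.12,
    )


@dataclass
class SceneSpec:
    """A labelled multi-region scene: geometry plus per-region textures."""

    shape: tuple[int, int]
    labels: np.ndarray                      # (H, W) small ints
    presets: dict[int, TexturePreset]       # label -> texture
    T: int
    seed: int

    def __post_init__(self) -> None:
        present = set(np.unique(self.labels).tolist())
        missing = present - set(self.presets)
        if missing:
            raise ValueError(f"labels without a texture preset: {sorted(missing)}")


def _simulate_state(preset: TexturePreset, T: int, rng: np.random.Generator) -> np.ndarray:
    """Hidden state (n, T) of a preset: independent damped-rotation pairs
    excited to unit stationary variance, started from stationarity."""
    n_pairs = len(preset.freqs)
    z = np.empty((2 * n_pairs, T))
    for j, omega in enumerate(preset.omegas):
        rho = preset.rho
        c, s = np.cos(omega), np.sin(omega)
        A = rho * np.array([[c, -s], [s, c]])
        q = np.sqrt(max(1.0 - rho ** 2, 1e-12))  # unit stationary variance
        zj = rng.standard_normal(2)
        for t in range(T):
            z[2 * j: 2 * j + 2, t] = zj
            zj = A @ zj + q * rng.standard_normal(2)
    return z


def _render_texture(
    preset: TexturePreset,
    shape: tuple[int, int],
    T: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Render one full-frame texture (H, W, T) from a preset."""
    H, W = shape
    z = _simulate_state(preset, T, rng)
    yy, xx = np.mgrid[0:H, 0:W].astype(float)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=len(preset.freqs))
    tex = np.full((H, W, T), preset.y_level)
    for j, (ky, kx) in enumerate(preset.freqs):
        arg = ky * yy + kx * xx + phases[j]
        modes = np.stack([np.cos(arg), np.sin(arg)], axis=-1)  # (H, W, 2)
        tex += preset.amp * (modes @ z[2 * j: 2 * j + 2, :])
    tex += preset.noise * rng.standard_normal((H, W, T))
    return tex


def make_scene(spec: SceneSpec) -> tuple[np.ndarray, np.ndarray]:
    """Render a scene: each region's pixels follow its own texture.

    Returns ``(sequence (H, W, T) in [0, 1], ground-truth labels (H, W))``.
    """
    rng = np.random.default_rng(spec.seed)
    H, W = spec.shape
    seq = np.zeros((H, W, spec.T))
    for label in sorted(spec.presets):
        mask = spec.labels == label
        if not mask.any():
            continue
        tex = _render_texture(spec.presets[label], spec.shape, spec.T, rng)
        seq[mask] = tex[mask]
    return np.clip(seq, 0.0, 1.0), spec.labels.copy()


# ---------------------------------------------------------------------------
# Canonical scenes
# ---------------------------------------------------------------------------

# Label legend shared with metrics_and_io: 0 background, 1 vessel, 2 thrombus.
BACKGROUND, VESSEL, THROMBUS = 0, 1, 2


def three_region_labels(shape: tuple[int, int] = (64, 64)) -> np.ndarray:
    """Disk-in-square layout: a thrombus-like disk inside a square vessel."""
    H, W = shape
    labels = np.zeros((H, W), dtype=np.uint8)
    r0, r1 = round(0.16 * H), round(0.84 * H)
    c0, c1 = round(0.16 * W), round(0.84 * W)
    labels[r0:r1, c0:c1] = VESSEL
    yy, xx = np.mgrid[0:H, 0:W]
    disk = (yy - H / 2) ** 2 + (xx - W / 2) ** 2 <= (0.07 * (H + W)) ** 2
    labels[disk & (labels == VESSEL)] = THROMBUS
    return labels


def default_three_region_scene(
    seed: int, shape: tuple[int, int] = (64, 64), T: int = 75
) -> tuple[np.ndarray, np.ndarray]:
    """Documented default three-region scene (disk-in-square, presets above)."""
    spec = SceneSpec(
        shape=shape,
        labels=three_region_labels(shape),
        presets={
            BACKGROUND: background_preset(),
            VESSEL: vessel_preset(),
            THROMBUS: thrombus_preset(),
        },
        T=T,
        seed=seed,
    )
    return make_scene(spec)


def default_scene_polygons(
    shape: tuple[int, int] = (64, 64),
    jitter: float = 0.0,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Polygonal initial contours for the default three-region scene.

    Returns ``(thrombus_polygon, vessel_polygon)`` as (row, col) vertex
    arrays.  The vessel polygon is deliberately inflated and rotated and the
    thrombus polygon offset, so that the initial partition only partially
    overlaps the truth (Rand around 0.7 against the default scene);
    ``jitter`` adds a seeded uniform perturbation (in pixels) to every
    vertex for initialization-robustness experiments.
    """
    H, W = shape
    sy, sx = H / 64.0, W / 64.0
    vessel = np.array([[12, 1], [2, 52], [54, 62], [61, 12]], dtype=float)
    thrombus = np.array([[27, 24], [24, 35], [36, 38], [38, 26]], dtype=float)
    vessel = vessel * [sy, sx]
    thrombus = thrombus * [sy, sx]
    if jitter > 0:
        rng = np.random.default_rng(seed)
        vessel = vessel + rng.uniform(-jitter, jitter, vessel.shape)
        thrombus = thrombus + rng.uniform(-jitter, jitter, thrombus.shape)
        vessel = np.clip(vessel, 0, [H - 1, W - 1])
        thrombus = np.clip(thrombus, 0, [H - 1, W - 1])
    return thrombus, vessel


def make_event_pair(
    shape: tuple[int, int] = (64, 64),
    T: int = 61,
    seed: int = 0,
    foreground: np.ndarray | None = None,
    noise: float = 0.06,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Two temporally shifted windows in which only the foreground motion changes.

    The background texture is statistically identical across the two windows
    (same preset, independent noise draws); the foreground region swaps to a
    different texture in the second window while keeping its shape.  Rendered
    at moderate observation noise (``noise``), emulating the high-SNR
    dynamic-texture sequences this protocol comes from.  Returns
    ``(sequence_t0, sequence_t, foreground_mask)``.
    """
    from dataclasses import replace as _replace

    H, W = shape
    if foreground is None:
        yy, xx = np.mgrid[0:H, 0:W]
        foreground = ((yy - H / 2) ** 2 / (0.3 * H) ** 2
                      + (xx - W / 2) ** 2 / (0.33 * W) ** 2) <= 1.0
    labels = foreground.astype(np.uint8)
    bg = _replace(background_preset(), noise=noise)
    fg_a = _replace(vessel_preset(), noise=noise)
    fg_b = _replace(event_foreground_preset(), noise=noise)
    spec0 = SceneSpec(shape, labels, {0: bg, 1: fg_a}, T=T, seed=seed * 2 + 1)
    spec1 = SceneSpec(shape, labels, {0: bg, 1: fg_b}, T=T, seed=seed * 2 + 2)
    seq0, _ = make_scene(spec0)
    seq1, _ = make_scene(spec1)
    return seq0, seq1, foreground.astype(bool)


def default_plug_polygons(shape: tuple[int, int] = (96, 128)) -> tuple[np.ndarray, np.ndarray]:
    """Initial contours for the default growing-plug scene, placed at the
    last temporal window: ``(thrombus_polygon, vessel_polygon)``."""
    H, W = shape
    sy, sx = H / 96.0, W / 128.0
    vessel = np.array([[28, 2], [26, 125], [69, 123], [67, 4]], dtype=float) * [sy, sx]
    thrombus = np.array([[52, 52], [50, 74], [74, 76], [76, 54]], dtype=float) * [sy, sx]
    return thrombus, vessel


def make_vessel_phantom(
    H: int = 96,
    W: int = 128,
    tube_halfwidth: float = 11.0,
    tube_row: float | None = None,
    n_collaterals: int = 4,
    collateral_len: int = 24,
    collateral_halfwidth: int = 1,
    T: int = 5,
    noise: float = 0.02,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Intensity phantom of a bright aorta with thin collateral branches.

    Vessels carry high intensity, the background low intensity.  Returns
    ``(sequence (H, W, T), tube_mask, tube_plus_collateral_mask)``.
    """
    rng = np.random.default_rng(seed)
    if tube_row is None:
        tube_row = H / 2
    yy, xx = np.mgrid[0:H, 0:W]
    tube = np.abs(yy - tube_row) <= tube_halfwidth
    collaterals = np.zeros((H, W), dtype=bool)
    cols = np.linspace(0.12 * W, 0.88 * W, n_collaterals).astype(int)
    for i, c in enumerate(cols):
        direction = -1 if i % 2 == 0 else 1  # alternate above / below the tube
        start = int(tube_row + direction * tube_halfwidth)
        stop = start + direction * collateral_len
        r_lo, r_hi = sorted((start, stop))
        drift = rng.integers(-2, 3)
        for r in range(max(r_lo, 0), min(r_hi, H)):
            cc = c + drift * (r - start) // max(collateral_len, 1)
            lo = max(cc - collateral_halfwidth, 0)
            collaterals[r, lo: cc + collateral_halfwidth + 1] = True
    collaterals &= ~tube
    image = np.full((H, W), 0.2)
    image[tube] = 0.8
    image[collaterals] = 0.75
    image = ndimage.gaussian_filter(image, 0.8)
    seq = image[:, :, None] + noise * rng.standard_normal((H, W, T))
    return np.clip(seq, 0.0, 1.0), tube, tube | collaterals


def make_growing_plug_sequence(
    shape: tuple[int, int] = (96, 128),
    T: int = 300,
    onset: int = 120,
    growth_rate: float = 4.0,
    max_area: float = 420.0,
    vessel_rows: tuple[int, int] | None = None,
    plug_center_col: float | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Thrombus-formation analogue: a slow-texture plug grows inside the vessel.

    Before ``onset`` the scene holds two textures (fast vessel band, static
    background).  From ``onset`` a disk-shaped plug with the slow
    thrombus-like texture grows inside the vessel, its area ramping linearly
    at ``growth_rate`` px/frame up to ``max_area``.  Returns ``(sequence,
    per-frame truth labels (H, W, T) uint8, truth dict)`` where the truth
    dict carries the TSA series (px) and the onset frame.
    """
    if not 0 <= onset < T:
        raise ValueError("onset must lie inside the sequence")
    H, W = shape
    if vessel_rows is None:
        vessel_rows = (H // 3, 2 * H // 3)
    r0, r1 = vessel_rows
    if plug_center_col is None:
        plug_center_col = W / 2
    plug_center = ((r0 + r1) / 2, plug_center_col)
    rng = np.random.default_rng(seed)
    tex_bg = _render_texture(background_preset(), shape, T, rng)
    tex_vessel = _render_texture(vessel_preset(), shape, T, rng)
    tex_plug = _render_texture(thrombus_preset(), shape, T, rng)

    yy, xx = np.mgrid[0:H, 0:W]
    vessel_mask = (yy >= r0) & (yy < r1)
    dist2 = (yy - plug_center[0]) ** 2 + (xx - plug_center[1]) ** 2

    labels = np.zeros((H, W, T), dtype=np.uint8)
    labels[vessel_mask] = VESSEL
    seq = np.where(vessel_mask[:, :, None], tex_vessel, tex_bg)
    tsa = np.zeros(T)
    for t in range(onset, T):
        area = min(growth_rate * (t - onset), max_area)
        radius2 = area / np.pi
        plug = (dist2 <= radius2) & vessel_mask
        labels[:, :, t][plug] = THROMBUS
        seq[:, :, t][plug] = tex_plug[:, :, t][plug]
        tsa[t] = plug.sum()
    truth = {"tsa_px": tsa, "onset_frame": onset, "vessel_rows": vessel_rows}
    return np.clip(seq, 0.0, 1.0), labels, truth
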