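"""Dynamic-texture models and the Martin distance.

A dynamic texture (DT) describes the intensities of a small spatio-temporal
patch with a linear dynamical system (LDS): a hidden state ``z`` of order
``n`` evolves as ``z(t+1) = A z(t) + v(t)``, and the ``p`` patch intensities
are observed through orthonormal spatial modes, ``y(t) - y_bar = C z(t) +
w(t)``.  Estimation uses the classic closed-form sub-optimal solution: an SVD
of the mean-subtracted data matrix gives ``C`` (left singular vectors) and
the state trajectory, and ``A`` is the least-squares one-step predictor of
that trajectory.

Two models are compared by the Martin distance, a subspace distance between
their extended observability matrices ``O = [C; CA; ...; CA^(n-1)]``:

    d_M^2(D1, D2) = -log prod_i cos^2 theta_i,

where ``theta_i`` are the principal angles between the column spaces of the
two observability matrices.  The noise covariances play no role in this
distance, so estimated models carry only ``(A, C, y_bar)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.util import view_as_windows

from .errors import GridMismatch, InsufficientFrames, OrderMismatch, WindowOutOfRange

#: Default cap applied to (squared) Martin distances before they enter
#: region statistics.  Degenerate model pairs (orthogonal subspaces) have
#: infinite distance; the cap keeps sums and averages finite.
DEFAULT_DISTANCE_CAP = 1e6

# Relative singular-value threshold below which a direction is treated as
# numerically absent (rank-deficient patch data).
_RANK_RTOL = 1e-10
_RANK_ATOL = 1e-12


@dataclass
class DTModel:
    """One estimated dynamic-texture model.

    Attributes
    ----------
    A : (n, n) ndarray
        State-transition matrix.
    C : (p, n) ndarray
        Observation matrix with orthonormal columns (``C.T @ C == I``).
    y_bar : (p,) ndarray
        Temporal mean intensity of the patch over the estimation window.
    n : int
        Model order.
    degenerate : bool
        True when the mean-subtracted data had rank below ``n`` and the
        missing directions were padded; such models describe near-static
        patches and remain eligible for distance computations.
    """

    A: np.ndarray
    C: np.ndarray
    y_bar: np.ndarray
    n: int
    degenerate: bool = False

    @property
    def p(self) -> int:
        return self.C.shape[0]


def estimate_dt(patch_stack: np.ndarray, n: int) -> DTModel:
    """Estimate an order-``n`` DT model from a ``p x (tau+1)`` patch matrix.

    Each column of ``patch_stack`` holds the patch intensities of one frame.
    Raises :class:`InsufficientFrames` when the window provides fewer than
    ``n`` transitions.  Rank-deficient data does not raise: the model is
    padded with the orthonormal completion returned by the SVD, the dead
    state directions of ``A`` are zeroed, and ``degenerate`` is set.
    """
    stack = np.asarray(patch_stack, dtype=float)
    if stack.ndim != 2:
        raise ValueError("patch_stack must be a p x (tau+1) matrix")
    p, n_frames = stack.shape
    tau = n_frames - 1
    if tau < n:
        raise InsufficientFrames(f"window has {tau} transitions, order {n} needs >= {n}")
    if p < n:
        raise ValueError(f"patch has {p} pixels, cannot support order {n}")
    if not np.all(np.isfinite(stack)):
        raise ValueError("patch_stack contains non-finite values")
    A, C, y_bar, degen = _estimate_batch(stack[None], n)
    return DTModel(A=A[0], C=C[0], y_bar=y_bar[0], n=n, degenerate=bool(degen[0]))


def _estimate_batch(stacks: np.ndarray, n: int):
    """Vectorized closed-form estimation for ``(N, p, tau+1)`` patch stacks.

    Returns ``(A, C, y_bar, degenerate)`` with leading batch axis.
    """
    stacks = np.asarray(stacks, dtype=float)
    N, p, n_frames = stacks.shape
    y_bar = stacks.mean(axis=2)
    Y = stacks - y_bar[:, :, None]
    U, s, Vh = np.linalg.svd(Y, full_matrices=False)
    C = U[:, :, :n]
    # State trajectory Z = Sigma V^T restricted to the leading n directions.
    Z = s[:, :n, None] * Vh[:, :n, :]
    Z1 = Z[:, :, :-1]
    Z2 = Z[:, :, 1:]
    A = Z2 @ np.linalg.pinv(Z1)
    s_lead = s[:, 0]
    thresh = np.maximum(_RANK_RTOL * s_lead, _RANK_ATOL)
    dead = s[:, :n] <= thresh[:, None]  # (N, n) directions with no signal
    degenerate = dead.any(axis=1)
    if degenerate.any():
        A = A.copy()
        A[dead[:, :, None] | dead[:, None, :]] = 0.0
    return A, C, y_bar, degenerate


def observability_matrix(model: DTModel) -> np.ndarray:
    """Extended observability matrix ``[C; CA; ...; CA^(n-1)]`` of shape (p*n, n)."""
    blocks = [model.C]
    for _ in range(model.n - 1):
        blocks.append(blocks[-1] @ model.A)
    return np.vstack(blocks)


def _observability_batch(A: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Batched observability matrices for stacked models (N, p*n, n)."""
    n = A.shape[-1]
    blocks = [C]
    for _ in range(n - 1):
        blocks.append(blocks[-1] @ A)
    return np.concatenate(blocks, axis=1)


def martin_distance(d1: DTModel, d2: DTModel, cap: float = np.inf) -> float:
    """Squared Martin distance ``-log prod cos^2 theta_i`` between two models.

    Principal angles are obtained by orthonormalizing each observability
    matrix (QR) and taking the singular values of the cross-product, clamped
    to [0, 1] against floating-point overshoot.  Returns ``+inf`` when any
    principal angle reaches 90 degrees (cosine numerically zero); pass a
    finite ``cap`` to clamp instead.
    """
    if d1.n != d2.n or d1.p != d2.p:
        raise OrderMismatch(
            f"models differ in order or patch size: ({d1.n},{d1.p}) vs ({d2.n},{d2.p})"
        )
    q1, _ = np.linalg.qr(observability_matrix(d1))
    q2, _ = np.linalg.qr(observability_matrix(d2))
    sv = np.linalg.svd(q1.T @ q2, compute_uv=False)
    cos2 = np.clip(sv, 0.0, 1.0) ** 2
    if np.any(cos2 < 1e-300):
        return min(float("inf"), cap)
    d2m = float(-np.sum(np.log(cos2)))
    return min(max(d2m, 0.0), cap)


def pairwise_sq_distances(Qa: np.ndarray, Qb: np.ndarray, cap: float = DEFAULT_DISTANCE_CAP) -> np.ndarray:
    """Squared Martin distances between two stacks of orthonormalized
    observability matrices, shapes ``(Na, pn, n)`` and ``(Nb, pn, n)``.

    Because the inputs are orthonormal, ``prod_i cos^2 theta_i`` equals
    ``det(Qa^T Qb)^2``, evaluated stably through ``slogdet``; this is
    algebraically identical to the principal-angle form used by
    :func:`martin_distance`.  Singular cross-products map to the cap.
    """
    if Qa.shape[1:] != Qb.shape[1:]:
        raise GridMismatch("observability stacks differ in (p*n, n) geometry")
    Na = Qa.shape[0]
    Nb = Qb.shape[0]
    QaT = np.ascontiguousarray(np.swapaxes(Qa, 1, 2))  # (Na, n, pn)
    out = np.empty((Na, Nb), dtype=float)
    for j in range(Nb):
        M = QaT @ Qb[j]  # (Na, n, n)
        sign, logabs = np.linalg.slogdet(M)
        d2 = -2.0 * logabs
        d2[sign == 0] = np.inf
        out[:, j] = d2
    np.clip(out, 0.0, cap, out=out)
    return out


@dataclass
class DTField:
    """A strided grid of DT models covering one temporal window.

    Grid node ``(i, j)`` sits at pixel ``(rows[i], cols[j])`` and carries the
    model of the ``patch_side`` x ``patch_side`` patch centred there; only
    positions whose full patch fits in the image are modeled, so border
    pixels carry no model and, for energy evaluation, inherit the nearest
    modeled node (see :meth:`pixel_model_index`).
    """

    A: np.ndarray          # (Gh, Gw, n, n)
    C: np.ndarray          # (Gh, Gw, p, n)
    y_bar: np.ndarray      # (Gh, Gw, p)
    degenerate: np.ndarray  # (Gh, Gw) bool
    window: tuple[int, int]
    image_shape: tuple[int, int]
    patch_side: int
    stride: int
    n: int
    _orth_obs: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.A.shape[0], self.A.shape[1]

    @property
    def n_models(self) -> int:
        gh, gw = self.grid_shape
        return gh * gw

    @property
    def rows(self) -> np.ndarray:
        """Pixel row of each grid row."""
        half = self.patch_side // 2
        return half + self.stride * np.arange(self.grid_shape[0])

    @property
    def cols(self) -> np.ndarray:
        half = self.patch_side // 2
        return half + self.stride * np.arange(self.grid_shape[1])

    def model_at(self, row: int, col: int) -> DTModel | None:
        """Model stored at pixel position (row, col); None when unmodeled."""
        half = self.patch_side // 2
        r = row - half
        c = col - half
        if r < 0 or c < 0 or r % self.stride or c % self.stride:
            return None
        i, j = r // self.stride, c // self.stride
        gh, gw = self.grid_shape
        if i >= gh or j >= gw:
            return None
        return self.flat_model(i * gw + j)

    def flat_model(self, k: int) -> DTModel:
        gh, gw = self.grid_shape
        i, j = divmod(k, gw)
        return DTModel(
            A=self.A[i, j],
            C=self.C[i, j],
            y_bar=self.y_bar[i, j],
            n=self.n,
            degenerate=bool(self.degenerate[i, j]),
        )

    def orth_observability(self) -> np.ndarray:
        """Orthonormalized observability matrices, flat stack (N, p*n, n).

        Computed once and cached; every distance computation on the field
        goes through this stack.
        """
        if self._orth_obs is None:
            gh, gw = self.grid_shape
            n = self.n
            p = self.C.shape[2]
            A_flat = self.A.reshape(-1, n, n)
            C_flat = self.C.reshape(-1, p, n)
            obs = _observability_batch(A_flat, C_flat)
            q, _ = np.linalg.qr(obs)
            self._orth_obs = q
        return self._orth_obs

    def pixel_model_index(self) -> np.ndarray:
        """(H, W) int map from each pixel to the flat index of its nearest
        modeled grid node (border pixels clip to the nearest interior node)."""
        H, W = self.image_shape
        half = self.patch_side // 2
        gh, gw = self.grid_shape
        ri = np.clip(np.round((np.arange(H) - half) / self.stride).astype(int), 0, gh - 1)
        ci = np.clip(np.round((np.arange(W) - half) / self.stride).astype(int), 0, gw - 1)
        return ri[:, None] * gw + ci[None, :]

    def same_grid(self, other: "DTField") -> bool:
        return (
            self.grid_shape == other.grid_shape
            and self.image_shape == other.image_shape
            and self.patch_side == other.patch_side
            and self.stride == other.stride
            and self.n == other.n
        )

    def save(self, path) -> None:
        """Serialize the field to an .npz archive for caching."""
        np.savez_compressed(
            path,
            A=self.A, C=self.C, y_bar=self.y_bar, degenerate=self.degenerate,
            window=np.array(self.window), image_shape=np.array(self.image_shape),
            meta=np.array([self.patch_side, self.stride, self.n]),
        )

    @classmethod
    def load(cls, path) -> "DTField":
        z = np.load(path)
        ps, stride, n = (int(v) for v in z["meta"])
        return cls(
            A=z["A"], C=z["C"], y_bar=z["y_bar"], degenerate=z["degenerate"],
            window=tuple(int(v) for v in z["window"]),
            image_shape=tuple(int(v) for v in z["image_shape"]),
            patch_side=ps, stride=stride, n=n,
        )


def compute_dt_field(
    sequence: np.ndarray,
    window: tuple[int, int],
    patch_side: int = 5,
    n: int = 4,
    stride: int = 1,
) -> DTField:
    """Estimate a DT model on a strided grid of patches over one window.

    ``sequence`` is an (H, W, T) intensity stack; ``window`` is half-open
    ``[t_start, t_end)``.  Every grid position whose full
    ``patch_side x patch_side`` patch fits in the image receives a model.
    """
    sequence = np.asarray(sequence, dtype=float)
    if sequence.ndim != 3:
        raise ValueError("sequence must be an (H, W, T) stack")
    H, W, T = sequence.shape
    t0, t1 = window
    if not (0 <= t0 < t1 <= T):
        raise WindowOutOfRange(f"window {window} does not fit a {T}-frame sequence")
    if patch_side % 2 == 0 or patch_side < 1:
        raise ValueError("patch_side must be a positive odd integer")
    tau = t1 - t0 - 1
    if tau < n:
        raise InsufficientFrames(f"window has {tau} transitions, order {n} needs >= {n}")
    sub = np.ascontiguousarray(sequence[:, :, t0:t1])
    Tw = t1 - t0
    wins = view_as_windows(sub, (patch_side, patch_side, Tw), step=(stride, stride, Tw))
    gh, gw = wins.shape[0], wins.shape[1]
    stacks = wins.reshape(gh * gw, patch_side * patch_side, Tw)
    A, C, y_bar, degen = _estimate_batch(stacks, n)
    p = patch_side * patch_side
    return DTField(
        A=A.reshape(gh, gw, n, n),
        C=C.reshape(gh, gw, p, n),
        y_bar=y_bar.reshape(gh, gw, p),
        degenerate=degen.reshape(gh, gw),
        window=(t0, t1),
        image_shape=(H, W),
        patch_side=patch_side,
        stride=stride,
        n=n,
    )
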