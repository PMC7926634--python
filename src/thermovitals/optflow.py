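"""Dense two-frame optical flow via local polynomial expansion.

Each pixel neighborhood of an image is approximated by a quadratic
polynomial ``f(u) ~= u' A u + b' u + c`` fitted by Gaussian-weighted
least squares; between two frames the displacement ``d`` satisfies
``A d = -(b2 - b1) / 2`` for a pure translation.  The dense estimator
solves this pointwise system with spatial averaging of the normal
equations and iterative warping over a coarse-to-fine image pyramid,
which extends the valid range to multi-pixel motion.

The expansion itself is computed with separable correlations: for a
Gaussian applicability the Gram matrix of the monomial basis
``{1, x, y, x^2, y^2, xy}`` is spatially invariant, so the per-pixel
coefficients are a fixed 6x6 solve applied to six moment images.

Coordinates: ``x`` = columns, ``y`` = rows; positive ``dx``/``dy`` mean
the pattern moved right/down from ``prev`` to ``next``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = ["FlowParams", "FlowField", "PolyExpansion", "polynomial_expansion", "dense_flow"]

_EPS = 1e-9


@dataclass(frozen=True)
class FlowParams:
    """Hyperparameters for polynomial expansion and the pyramid solver.

    The source method's description fixes only the algorithm, not its
    parameters; these defaults follow the reference description of the
    method and are overridable everywhere they are consumed.
    """

    window_size: int = 7
    gaussian_sigma: float | None = None  # default 1.5 * window_size / 5
    pyramid_levels: int = 3
    pyramid_scale: float = 0.5
    iterations: int = 3
    smoothing_size: int = 15

    def __post_init__(self) -> None:
        if self.window_size < 3 or self.window_size % 2 == 0:
            raise ValueError(f"window_size must be odd and >= 3, got {self.window_size}")
        if not (0.0 < self.pyramid_scale < 1.0):
            raise ValueError(f"pyramid_scale must lie in (0, 1), got {self.pyramid_scale}")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.pyramid_levels < 1:
            raise ValueError("pyramid_levels must be >= 1")
        if self.smoothing_size < 1:
            raise ValueError("smoothing_size must be >= 1")

    @property
    def sigma(self) -> float:
        return self.gaussian_sigma if self.gaussian_sigma is not None else 1.5 * self.window_size / 5


@dataclass
class FlowField:
    """Per-pixel displacement between two frames (px per frame pair)."""

    dx: np.ndarray
    dy: np.ndarray

    def __post_init__(self) -> None:
        if self.dx.shape != self.dy.shape:
            raise ValueError("dx/dy shape mismatch")
        if not (np.all(np.isfinite(self.dx)) and np.all(np.isfinite(self.dy))):
            raise ValueError("flow field contains non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.dx.shape  # type: ignore[return-value]

    def mean(self, margin: int = 0) -> tuple[float, float]:
        """Spatial mean of (dx, dy), optionally ignoring a border margin."""
        sl = (slice(margin, self.dx.shape[0] - margin), slice(margin, self.dx.shape[1] - margin))
        if margin and (self.dx[sl].size == 0):
            sl = (slice(None), slice(None))
        return float(self.dx[sl].mean()), float(self.dy[sl].mean())


@dataclass
class PolyExpansion:
    """Per-pixel quadratic coefficients: A (symmetric 2x2), b (2-vector), c."""

    a_xx: np.ndarray
    a_yy: np.ndarray
    a_xy: np.ndarray  # off-diagonal entry of A (i.e. half the xy coefficient sum)
    b_x: np.ndarray
    b_y: np.ndarray
    c: np.ndarray


def _basis_kernels(params: FlowParams) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    m = params.window_size // 2
    u = np.arange(-m, m + 1, dtype=np.float64)
    g = np.exp(-(u**2) / (2.0 * params.sigma**2))
    g /= g.sum()
    return u, g, g * u  # coordinate axis, weight, weight*coordinate


def _gram_inverse(params: FlowParams) -> np.ndarray:
    """Inverse Gram matrix of {1, x, y, x^2, y^2, xy} under the window weight."""
    m = params.window_size // 2
    u = np.arange(-m, m + 1, dtype=np.float64)
    g1 = np.exp(-(u**2) / (2.0 * params.sigma**2))
    g1 /= g1.sum()
    wy, wx = np.meshgrid(g1, g1, indexing="ij")
    w = wy * wx
    yy, xx = np.meshgrid(u, u, indexing="ij")
    basis = np.stack([np.ones_like(xx), xx, yy, xx**2, yy**2, xx * yy])
    gram = np.einsum("iuv,juv,uv->ij", basis, basis, w)
    return np.linalg.inv(gram)


def polynomial_expansion(image: np.ndarray, params: FlowParams) -> PolyExpansion:
    """Fit ``f(u) ~= u'Au + b'u + c`` around every pixel.

    Borders are handled by edge replication; coefficients there are
    biased and excluded from the accuracy guarantees.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError(f"expected 2-D image, got shape {image.shape}")
    _, g, gu = _basis_kernels(params)
    gu2 = gu * np.arange(-(params.window_size // 2), params.window_size // 2 + 1)

    def corr(img: np.ndarray, ky: np.ndarray, kx: np.ndarray) -> np.ndarray:
        tmp = ndimage.correlate1d(img, ky, axis=0, mode="nearest")
        return ndimage.correlate1d(tmp, kx, axis=1, mode="nearest")

    # moment images v_i = sum_u w(u) * monomial_i(u) * f(x + u)
    v = np.stack(
        [
            corr(image, g, g),  # 1
            corr(image, g, gu),  # x
            corr(image, gu, g),  # y
            corr(image, g, gu2),  # x^2
            corr(image, gu2, g),  # y^2
            corr(image, gu, gu),  # xy
        ],
        axis=-1,
    )
    r = v @ _gram_inverse(params).T
    return PolyExpansion(
        c=r[..., 0],
        b_x=r[..., 1],
        b_y=r[..., 2],
        a_xx=r[..., 3],
        a_yy=r[..., 4],
        a_xy=r[..., 5] / 2.0,
    )


def _warp(arr: np.ndarray, cy: np.ndarray, cx: np.ndarray) -> np.ndarray:
    return ndimage.map_coordinates(arr, [cy, cx], order=1, mode="nearest")


def _flow_step(
    e1: PolyExpansion,
    e2: PolyExpansion,
    dx: np.ndarray,
    dy: np.ndarray,
    params: FlowParams,
) -> tuple[np.ndarray, np.ndarray]:
    """One fixed-point refinement of the displacement field."""
    h, w = dx.shape
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    cy = np.clip(yy + dy, 0, h - 1)
    cx = np.clip(xx + dx, 0, w - 1)

    a_xx = 0.5 * (e1.a_xx + _warp(e2.a_xx, cy, cx))
    a_yy = 0.5 * (e1.a_yy + _warp(e2.a_yy, cy, cx))
    a_xy = 0.5 * (e1.a_xy + _warp(e2.a_xy, cy, cx))
    db_x = -0.5 * (_warp(e2.b_x, cy, cx) - e1.b_x) + a_xx * dx + a_xy * dy
    db_y = -0.5 * (_warp(e2.b_y, cy, cx) - e1.b_y) + a_xy * dx + a_yy * dy

    # normal equations G d = h with G = A'A, averaged over a neighborhood
    g11 = a_xx**2 + a_xy**2
    g12 = a_xy * (a_xx + a_yy)
    g22 = a_yy**2 + a_xy**2
    h1 = a_xx * db_x + a_xy * db_y
    h2 = a_xy * db_x + a_yy * db_y
    size = params.smoothing_size
    if size > 1:
        g11, g12, g22, h1, h2 = (
            ndimage.uniform_filter(m, size=size, mode="nearest") for m in (g11, g12, g22, h1, h2)
        )
    det = g11 * g22 - g12**2
    reg = _EPS * (1.0 + g11 + g22)
    det = np.where(np.abs(det) < reg, det + reg, det)
    new_dx = (g22 * h1 - g12 * h2) / det
    new_dy = (g11 * h2 - g12 * h1) / det
    return new_dx, new_dy


def _downsample(image: np.ndarray, scale: float) -> np.ndarray:
    # anti-alias before subsampling; sigma for a scale-s reduction
    sigma = np.sqrt(max((1.0 / scale) ** 2 - 1.0, 0.0)) / 2.0
    smoothed = ndimage.gaussian_filter(image, sigma, mode="nearest")
    return ndimage.zoom(smoothed, scale, order=1, mode="nearest", grid_mode=False)


def _n_levels(shape: tuple[int, int], params: FlowParams) -> int:
    levels = 1
    size = min(shape)
    while (
        levels < params.pyramid_levels
        and size * params.pyramid_scale >= params.window_size
    ):
        size *= params.pyramid_scale
        levels += 1
    return levels


def build_pyramid(image: np.ndarray, params: FlowParams) -> list[np.ndarray]:
    """Image pyramid, level 0 = full resolution, coarser levels appended."""
    image = np.asarray(image, dtype=np.float64)
    levels = [image]
    for _ in range(_n_levels(image.shape, params) - 1):
        levels.append(_downsample(levels[-1], params.pyramid_scale))
    return levels


def expand_pyramid(pyramid: list[np.ndarray], params: FlowParams) -> list[PolyExpansion]:
    return [polynomial_expansion(img, params) for img in pyramid]


def flow_from_expansions(
    exps1: list[PolyExpansion],
    exps2: list[PolyExpansion],
    shapes: list[tuple[int, int]],
    params: FlowParams,
) -> FlowField:
    """Coarse-to-fine solve given precomputed expansion pyramids."""
    dx = np.zeros(shapes[-1], dtype=np.float64)
    dy = np.zeros_like(dx)
    for level in range(len(shapes) - 1, -1, -1):
        if dx.shape != shapes[level]:
            fy = shapes[level][0] / dx.shape[0]
            fx = shapes[level][1] / dx.shape[1]
            dx = ndimage.zoom(dx, (fy, fx), order=1, mode="nearest") * fx
            dy = ndimage.zoom(dy, (fy, fx), order=1, mode="nearest") * fy
        for _ in range(params.iterations):
            dx, dy = _flow_step(exps1[level], exps2[level], dx, dy, params)
    return FlowField(dx=dx, dy=dy)


def dense_flow(prev: np.ndarray, next: np.ndarray, params: FlowParams | None = None) -> FlowField:
    """Dense displacement field mapping ``prev`` toward ``next``.

    Inputs are expected on a common intensity scale (normalize first);
    shapes must match.
    """
    params = params or FlowParams()
    prev = np.asarray(prev, dtype=np.float64)
    next = np.asarray(next, dtype=np.float64)
    if prev.shape != next.shape:
        raise ValueError(f"shape mismatch: {prev.shape} vs {next.shape}")
    pyr1 = build_pyramid(prev, params)
    pyr2 = build_pyramid(next, params)
    shapes = [p.shape for p in pyr1]
    return flow_from_expansions(
        expand_pyramid(pyr1, params), expand_pyramid(pyr2, params), shapes, params
    )
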