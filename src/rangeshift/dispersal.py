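"""Fat-tailed 2Dt dispersal kernels and their discretization on the grid.

Seeds and pollen disperse according to a two-dimensional t-distribution
(2Dt) with density

    f(r) = p / (pi * u) * (1 + r^2 / u) ** -(p + 1),

which integrates to 1 over the plane and has mean dispersal distance

    E[r] = sqrt(pi * u) / 2 * Gamma(p - 1/2) / Gamma(p).

The kernel is fat-tailed: most propagules stay in their patch of origin
while a few travel much farther than the mean.  Life histories are
parameterized by their mean distances; the scale u is recovered from the
mean by inverting the closed form above (shape p defaults to 1).

Discretization integrates the density over destination patch footprints
with the source at its patch center.  Two discrete forms are provided:

* :func:`build_operator` — a truncated square stencil of offset
  probabilities for per-source multinomial dispersal of integer counts;
* :func:`grid_kernel` — a full-grid offset array covering every offset
  reachable inside an (n_rows, n_cols) grid, for convolution-based
  dispersal with an exactly absorbing boundary (off-grid mass is lost).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import signal
from scipy.special import gammaln

__all__ = [
    "Kernel2Dt",
    "DispersalOperator",
    "scale_from_mean",
    "kernel_from_mean",
    "build_operator",
    "grid_kernel",
    "disperse",
]


def _mean_factor(p: float) -> float:
    """E[r] / sqrt(u) for the 2Dt kernel with shape p."""
    return 0.5 * np.sqrt(np.pi) * np.exp(gammaln(p - 0.5) - gammaln(p))


@dataclass(frozen=True)
class Kernel2Dt:
    """2Dt dispersal kernel with shape ``p`` (> 1/2) and scale ``u`` (m^2)."""

    p: float
    u: float

    def __post_init__(self) -> None:
        if self.p <= 0.5:
            raise ValueError("shape p must exceed 0.5 for a finite mean")
        if self.u <= 0:
            raise ValueError("scale u must be positive")

    @property
    def mean_distance(self) -> float:
        return float(np.sqrt(self.u) * _mean_factor(self.p))

    def density(self, r):
        """Planar density f(r) at radial distance(s) r (per m^2)."""
        r = np.asarray(r, dtype=float)
        return self.p / (np.pi * self.u) * (1.0 + r**2 / self.u) ** -(self.p + 1.0)

    def radial_tail(self, r: float) -> float:
        """P(distance > r), closed form: (1 + r^2/u)^(-p)."""
        return float((1.0 + r**2 / self.u) ** -self.p)


def scale_from_mean(mean_distance: float, p: float = 1.0) -> float:
    """Invert the closed-form mean: u such that E[r] = mean_distance."""
    if mean_distance <= 0:
        raise ValueError("mean_distance must be positive")
    if p <= 0.5:
        raise ValueError("shape p must exceed 0.5")
    return float((mean_distance / _mean_factor(p)) ** 2)


def kernel_from_mean(mean_distance: float, p: float = 1.0) -> Kernel2Dt:
    return Kernel2Dt(p=p, u=scale_from_mean(mean_distance, p))


def _offset_probabilities(
    kernel: Kernel2Dt, patch_size: float, k_rows: int, k_cols: int
) -> np.ndarray:
    """Integral of the density over each destination patch footprint.

    Returns a (2*k_rows+1, 2*k_cols+1) array of probabilities for offsets
    (-k_rows..k_rows, -k_cols..k_cols), source at the center patch's
    center.  Cells are integrated by subsampled midpoint quadrature, finer
    near the origin where the density is steep.
    """

    def cell_mass(di: np.ndarray, dj: np.ndarray, ss: int) -> np.ndarray:
        # di, dj: 1-D integer offset arrays; ss: subsamples per axis
        frac = (np.arange(ss) + 0.5) / ss - 0.5
        off = frac * patch_size
        x = di[:, None, None] * patch_size + off[None, :, None]
        y = dj[:, None, None] * patch_size + off[None, None, :]
        r = np.sqrt(x**2 + y**2)
        dens = kernel.density(r)
        return dens.mean(axis=(-2, -1)) * patch_size**2

    di, dj = np.meshgrid(
        np.arange(-k_rows, k_rows + 1), np.arange(-k_cols, k_cols + 1), indexing="ij"
    )
    near = (np.abs(di) <= 2) & (np.abs(dj) <= 2)
    probs = np.empty(di.shape, dtype=float)
    probs[~near] = cell_mass(di[~near], dj[~near], ss=5)
    probs[near] = cell_mass(di[near], dj[near], ss=41)
    # the density can be extremely peaked inside the source patch (short
    # kernels), so integrate the origin cell exactly in polar coordinates
    # using the closed-form radial CDF F(r) = 1 - (1 + r^2/u)^-p
    theta = np.linspace(0.0, np.pi / 4, 513)
    radius = (patch_size / 2.0) / np.cos(theta)
    cdf = 1.0 - (1.0 + radius**2 / kernel.u) ** -kernel.p
    probs[k_rows, k_cols] = (4.0 / np.pi) * np.trapezoid(cdf, theta)
    return probs


@dataclass(frozen=True)
class DispersalOperator:
    """Truncated patch-to-patch dispersal stencil.

    ``stencil[k + di, k + dj]`` is the probability a propagule lands in
    the patch offset (di, dj) from its source; mass beyond the stencil
    (and beyond the grid, under the absorbing boundary) is lost.
    """

    stencil: np.ndarray
    patch_size: float

    @property
    def half_width(self) -> int:
        return self.stencil.shape[0] // 2

    @property
    def retention(self) -> float:
        """Probability of staying in the source patch."""
        k = self.half_width
        kc = self.stencil.shape[1] // 2
        return float(self.stencil[k, kc])

    @property
    def total_mass(self) -> float:
        return float(self.stencil.sum())


def build_operator(
    kernel: Kernel2Dt, patch_size: float, mass_tol: float = 1e-3, max_radius: float | None = None
) -> DispersalOperator:
    """Discretize a kernel into a square stencil of offset probabilities.

    The stencil half-width is chosen from the closed-form radial tail so
    the omitted mass is below ``mass_tol`` (optionally capped by
    ``max_radius`` in meters, e.g. the grid extent, since farther offsets
    can never land on the grid).
    """
    if patch_size <= 0:
        raise ValueError("patch_size must be positive")
    # radius R with P(distance > R) = mass_tol
    r_tol = float(np.sqrt(kernel.u * (mass_tol ** (-1.0 / kernel.p) - 1.0)))
    radius = r_tol if max_radius is None else min(r_tol, max_radius)
    if radius < patch_size:
        raise ValueError(
            f"truncation radius {radius:.3g} m is smaller than one patch ({patch_size} m)"
        )
    k = int(np.ceil(radius / patch_size))
    stencil = _offset_probabilities(kernel, patch_size, k, k)
    return DispersalOperator(stencil=stencil, patch_size=patch_size)


@lru_cache(maxsize=32)
def _grid_kernel_cached(
    p: float, u: float, patch_size: float, n_rows: int, n_cols: int
) -> np.ndarray:
    probs = _offset_probabilities(Kernel2Dt(p, u), patch_size, n_rows - 1, n_cols - 1)
    probs.setflags(write=False)
    return probs


def grid_kernel(
    kernel: Kernel2Dt, patch_size: float, n_rows: int, n_cols: int
) -> np.ndarray:
    """(2*n_rows-1, 2*n_cols-1) offset-probability array for convolution.

    Covers every source-to-destination offset realizable inside the grid,
    so convolving with zero padding implements the absorbing boundary
    exactly (mass landing off-grid is discarded).
    """
    return _grid_kernel_cached(kernel.p, kernel.u, patch_size, n_rows, n_cols)


def convolve_expected(fields: np.ndarray, kern: np.ndarray) -> np.ndarray:
    """Expected post-dispersal field(s): zero-padded 'same' convolution.

    ``fields`` is (..., n_rows, n_cols); ``kern`` comes from
    :func:`grid_kernel` for the same grid shape.
    """
    fields = np.asarray(fields, dtype=float)
    if fields.ndim == 2:
        out = signal.fftconvolve(fields, kern, mode="same")
    else:
        out = signal.fftconvolve(fields, kern[None, ...], mode="same", axes=(-2, -1))
    return np.clip(out, 0.0, None)


def disperse(
    counts: np.ndarray,
    op: DispersalOperator,
    rng: np.random.Generator | None = None,
    mode: str = "multinomial",
) -> np.ndarray:
    """Disperse an integer count field patch-to-patch.

    Each source patch's count is multinomially allocated across the
    stencil offsets plus a residual "lost" category for the truncated
    tail; destinations off the grid are discarded (absorbing boundary).
    ``mode="expected"`` instead returns the deterministic expected field
    (real-valued), for tests and diagnostics.
    """
    counts = np.asarray(counts)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    n_rows, n_cols = counts.shape
    kh = op.stencil.shape[0] // 2
    kw = op.stencil.shape[1] // 2

    if mode == "expected":
        out = signal.fftconvolve(np.asarray(counts, dtype=float), op.stencil, mode="full")
        # 'full' output is (n_rows + 2*kh, n_cols + 2*kw); crop back to the grid
        return np.clip(out[kh : kh + n_rows, kw : kw + n_cols], 0.0, None)
    if mode != "multinomial":
        raise ValueError(f"unknown mode {mode!r}")
    if rng is None:
        raise ValueError("multinomial mode requires an rng")

    flat_probs = op.stencil.ravel()
    lost = max(0.0, 1.0 - flat_probs.sum())
    pvec = np.concatenate([flat_probs, [lost]])
    pvec /= pvec.sum()

    out = np.zeros((n_rows + 2 * kh, n_cols + 2 * kw), dtype=np.int64)
    rows, cols = np.nonzero(counts)
    for i, j in zip(rows, cols):
        draw = rng.multinomial(int(counts[i, j]), pvec)[:-1]
        out[i : i + 2 * kh + 1, j : j + 2 * kw + 1] += draw.reshape(op.stencil.shape)
    return out[kh : kh + n_rows, kw : kw + n_cols]
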