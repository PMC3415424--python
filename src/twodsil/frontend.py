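"""V1 front end: oriented difference-of-Gaussians simple cells and
complex-cell pooling.

Simple cells
------------
A model simple cell is an oriented difference of two concentric 2-D Gaussians.
In coordinates rotated so that ``u`` runs along the preferred orientation and
``v`` across it, the kernel is::

    K(u, v) = A * [exp(-v^2 / 2 sigma^2) - (1/WR) * exp(-v^2 / 2 (WR sigma)^2)]
                * exp(-u^2 / 2 (AR sigma)^2)

with ``sigma = size / 4``: the nominal cell ``size`` names the 4-sigma
excitatory core of the cross-section.  ``WR`` is the width ratio of the
inhibitory to the excitatory Gaussian and ``AR`` the aspect ratio setting the
elongation along the preferred orientation.  The sampled support extends to
the natural decay of the wider of the surround and the length envelope
(half-width ``ceil(2 * max(WR, AR) * sigma)``) rather than being cut at the
nominal size; truncating the elongated envelope of the large cells changes
their curvature preference qualitatively.  The surround amplitude ``1/WR``
makes the 1-D cross-section integrate to zero; the sampled kernel is
additionally forced to zero mean (no DC response) and unit L2 norm so
responses are comparable across scales.  Kernels are even-symmetric, so
orientation is defined modulo pi.

Complex cells
-------------
A model complex cell is the rectified, normalized Gaussian-weighted sum of 5
simple cells of the same orientation, laterally displaced perpendicular to the
preferred orientation.  Subunit spacing and weight spread are proportional to
the cell size (``size / 8`` each by default), giving the complex map a wider,
more position-tolerant receptive field than its simple input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.fft

__all__ = [
    "OrientedDoGParams",
    "FilterBankConfig",
    "ResponseStack",
    "make_dog_kernel",
    "build_filter_bank",
    "simple_responses",
    "complex_responses",
    "shift_bilinear",
]

_DEF_ORIENTATIONS = tuple(math.radians(15 * k) for k in range(12))


@dataclass(frozen=True)
class OrientedDoGParams:
    """Parameters of one oriented DoG simple-cell kernel."""

    size: int
    orientation: float
    aspect_ratio: float
    width_ratio: float = 2.5
    height: float = 1.0

    def __post_init__(self):
        if self.size < 3:
            raise ValueError("kernel size must be >= 3 px")
        if self.aspect_ratio <= 0:
            raise ValueError("aspect ratio must be positive")
        if self.width_ratio <= 1:
            raise ValueError("width ratio must exceed 1")


@dataclass(frozen=True)
class FilterBankConfig:
    """Simple/complex filter-bank configuration.

    Defaults: 12 orientations in 15-degree steps and four heterogeneous
    simple-cell groups (size, AR) = (40, 0.7), (60, 1.4), (88, 2.15),
    (120, 3), WR = 2.5 — 48 filter types in total.
    """

    orientations: tuple[float, ...] = _DEF_ORIENTATIONS
    sizes: tuple[int, ...] = (40, 60, 88, 120)
    aspect_ratios: tuple[float, ...] = (0.7, 1.4, 2.15, 3.0)
    width_ratio: float = 2.5
    #: complex-cell subunit spacing and Gaussian weight sigma, as a fraction
    #: of the simple-cell size
    subunit_spacing_fraction: float = 1.0 / 8.0
    subunit_count: int = 5

    def __post_init__(self):
        object.__setattr__(self, "orientations", tuple(float(o) for o in self.orientations))
        object.__setattr__(self, "sizes", tuple(int(s) for s in self.sizes))
        object.__setattr__(self, "aspect_ratios", tuple(float(a) for a in self.aspect_ratios))
        if not self.orientations or not self.sizes:
            raise ValueError("need at least one orientation and one size")
        if len(self.aspect_ratios) != len(self.sizes):
            raise ValueError(
                f"aspect_ratios has {len(self.aspect_ratios)} entries for "
                f"{len(self.sizes)} sizes; one AR per size is required"
            )
        if self.subunit_count % 2 != 1:
            raise ValueError("subunit_count must be odd")

    @property
    def n_scales(self) -> int:
        return len(self.sizes)

    @property
    def n_orientations(self) -> int:
        return len(self.orientations)


@dataclass
class ResponseStack:
    """Rectified activation maps indexed (scale, orientation, y, x)."""

    values: np.ndarray
    config: FilterBankConfig

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 4:
            raise ValueError("ResponseStack values must be 4-D")
        if v.shape[0] != self.config.n_scales or v.shape[1] != self.config.n_orientations:
            raise ValueError("ResponseStack shape does not match its config")
        self.values = v

    @property
    def spatial_shape(self) -> tuple[int, int]:
        return self.values.shape[2:]


def kernel_support(params: OrientedDoGParams) -> int:
    """Side length (odd) of the sampled square support of one kernel."""
    sigma = params.size / 4.0
    half = int(math.ceil(2.0 * max(params.width_ratio, params.aspect_ratio) * sigma))
    return 2 * half + 1


def make_dog_kernel(params: OrientedDoGParams) -> np.ndarray:
    """Sample the oriented DoG kernel on its full (odd, square) support.

    The returned kernel has zero mean and unit L2 norm (scaled by ``height``).
    """
    s = kernel_support(params)
    sigma = params.size / 4.0
    sigma_len = params.aspect_ratio * sigma
    sigma_wide = params.width_ratio * sigma
    c = (s - 1) / 2.0
    y, x = np.mgrid[0:s, 0:s].astype(float)
    xr, yr = x - c, y - c
    ct, st = math.cos(params.orientation), math.sin(params.orientation)
    u = xr * ct + yr * st
    v = -xr * st + yr * ct
    cross = np.exp(-(v**2) / (2 * sigma**2)) - (1.0 / params.width_ratio) * np.exp(
        -(v**2) / (2 * sigma_wide**2)
    )
    k = cross * np.exp(-(u**2) / (2 * sigma_len**2))
    k -= k.mean()
    norm = np.linalg.norm(k)
    if norm == 0:
        raise ValueError("degenerate kernel")
    return params.height * k / norm


def build_filter_bank(config: FilterBankConfig) -> list[OrientedDoGParams]:
    """One kernel parameterization per (size, orientation) pair."""
    return [
        OrientedDoGParams(
            size=size,
            orientation=theta,
            aspect_ratio=ar,
            width_ratio=config.width_ratio,
        )
        for size, ar in zip(config.sizes, config.aspect_ratios)
        for theta in config.orientations
    ]


# ---------------------------------------------------------------------------
# convolution machinery (kernel FFTs cached per config and image shape)

_fft_cache: dict = {}


def _bank_ffts(config: FilterBankConfig, shape: tuple[int, int]):
    key = (config, shape)
    hit = _fft_cache.get(key)
    if hit is not None:
        return hit
    H, W = shape
    supports = [
        kernel_support(OrientedDoGParams(size, 0.0, ar, config.width_ratio))
        for size, ar in zip(config.sizes, config.aspect_ratios)
    ]
    kmax = max(supports)
    fh = scipy.fft.next_fast_len(H + kmax - 1)
    fw = scipy.fft.next_fast_len(W + kmax - 1)
    ffts = np.empty(
        (config.n_scales, config.n_orientations, fh, fw // 2 + 1), dtype=complex
    )
    for si, (size, ar) in enumerate(zip(config.sizes, config.aspect_ratios)):
        for oi, theta in enumerate(config.orientations):
            k = make_dog_kernel(
                OrientedDoGParams(size, theta, ar, config.width_ratio)
            )
            ffts[si, oi] = scipy.fft.rfft2(k, s=(fh, fw))
    entry = (fh, fw, supports, ffts)
    _fft_cache[key] = entry
    return entry


def simple_responses(image, config: FilterBankConfig) -> ResponseStack:
    """Rectified oriented-DoG responses, same spatial size as the input.

    ``image`` is a :class:`~twodsil.stimuli.StimulusImage` or 2-D array.
    Zero padding is used at the borders ("same" convolution).
    """
    px = np.asarray(getattr(image, "pixels", image), dtype=float)
    if px.ndim != 2 or px.size == 0:
        raise ValueError("input image must be a non-empty 2-D grid")
    H, W = px.shape
    fh, fw, supports, kffts = _bank_ffts(config, (H, W))
    img_fft = scipy.fft.rfft2(px, s=(fh, fw))
    out = np.empty((config.n_scales, config.n_orientations, H, W))
    for si, support in enumerate(supports):
        off = (support - 1) // 2  # "same" crop of the full convolution
        for oi in range(config.n_orientations):
            full = scipy.fft.irfft2(img_fft * kffts[si, oi], s=(fh, fw))
            out[si, oi] = full[off : off + H, off : off + W]
    np.maximum(out, 0.0, out=out)
    return ResponseStack(out, config)


def shift_bilinear(a: np.ndarray, dy: float, dx: float) -> np.ndarray:
    """Sample ``a`` at (y + dy, x + dx) with bilinear interpolation.

    Locations falling outside the grid read as 0 (black padding), matching the
    convolution border policy.
    """
    out = np.zeros_like(a)
    iy, ix = math.floor(dy), math.floor(dx)
    fy, fx = dy - iy, dx - ix
    for oy, wy in ((iy, 1 - fy), (iy + 1, fy)):
        for ox, wx in ((ix, 1 - fx), (ix + 1, fx)):
            w = wy * wx
            if w == 0:
                continue
            src_y0, src_y1 = max(0, oy), min(a.shape[0], a.shape[0] + oy)
            dst_y0, dst_y1 = max(0, -oy), min(a.shape[0], a.shape[0] - oy)
            src_x0, src_x1 = max(0, ox), min(a.shape[1], a.shape[1] + ox)
            dst_x0, dst_x1 = max(0, -ox), min(a.shape[1], a.shape[1] - ox)
            if src_y0 >= src_y1 or src_x0 >= src_x1:
                continue
            out[dst_y0:dst_y1, dst_x0:dst_x1] += w * a[src_y0:src_y1, src_x0:src_x1]
    return out


def _subunit_weights(n: int) -> np.ndarray:
    k = np.arange(n) - n // 2
    w = np.exp(-(k**2) / 2.0)  # distance in units of the subunit spacing
    return w / w.sum()


def complex_responses(stack: ResponseStack) -> ResponseStack:
    """Pool 5 laterally displaced simple cells into complex-cell maps.

    Subunits are sampled perpendicular to the preferred orientation with
    bilinear interpolation; weights fall off as a Gaussian of distance from
    the centre and are normalized to sum to 1, so five equal inputs map to the
    same output value.
    """
    cfg = stack.config
    n = cfg.subunit_count
    weights = _subunit_weights(n)
    ks = np.arange(n) - n // 2
    out = np.zeros_like(stack.values)
    for si, size in enumerate(cfg.sizes):
        spacing = size * cfg.subunit_spacing_fraction
        for oi, theta in enumerate(cfg.orientations):
            # displacement perpendicular to the preferred orientation
            pdx, pdy = -math.sin(theta), math.cos(theta)
            plane = stack.values[si, oi]
            acc = out[si, oi]
            for k, w in zip(ks, weights):
                if k == 0:
                    acc += w * plane
                else:
                    acc += w * shift_bilinear(plane, k * spacing * pdy, k * spacing * pdx)
    np.maximum(out, 0.0, out=out)
    return ResponseStack(out, cfg)
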