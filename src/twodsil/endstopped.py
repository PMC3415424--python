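"""Endstopped (hypercomplex) operators: degree and sign of curvature.

A degree-of-curvature endstopped cell is the rectified difference between one
excitatory simple cell at the centre and two inhibitory complex cells of the
same orientation, displaced half a receptive-field size along the preferred
orientation on either side::

    E = g( R( c_c * S  -  c_d * C(+d)  -  c_d * C(-d) ) ),   d = size / 2

A short contour matched to the centre cell drives S without touching the
flanks; a long bar or a broad curve also drives the flanks and is suppressed.
Because the geometry scales with the cell size, each of the four scales is
band-pass for a different range of curvature radii (sharp for the smallest
cell, broad for the largest).

A sign-of-curvature endstopped cell instead uses flanking complex cells at
orientations theta+45 and theta+135 degrees, displaced along those
orientations so both flanks lie on one side of the preferred axis; the
opposite-sign variant displaces them to the other side.  A curve bending into
the flanked side is inhibited while its mirror image is not, so the pair
discriminates convex from concave bends.

``g`` is a baseline-subtracted logistic saturation ``g(x) =
s(alpha*(x - beta)) - s(-alpha*beta)`` with ``s`` the standard logistic;
``beta`` is the maximum response of the scale's cell population divided by
8.5, recomputed per stimulus batch, and ``g(0) = 0`` so blank inputs stay
silent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .frontend import FilterBankConfig, ResponseStack, complex_responses, shift_bilinear, simple_responses
from .stimuli import ArcSpec, render_arc

__all__ = [
    "EndstoppedConfig",
    "saturate",
    "degree_response",
    "degree_responses_raw",
    "sign_response",
    "sign_responses_raw",
    "curvature_tuning_curve",
    "band_90pct",
    "fit_arc_spec",
]


@dataclass(frozen=True)
class EndstoppedConfig:
    """Gains, displacements and saturation of the endstopped operators.

    Defaults follow the four-scale model: flank gains (1.5, 1.25, 1, 3) from
    the smallest to the largest cell, centre gain 1, degree-cell displacement
    1/2 of the simple-cell size, sign-cell displacements (1/5, 1/4, 1/4, 2/5)
    of the size (sign cells need a larger receptive-field overlap), logistic
    slope alpha = 0.01 and half-saturation beta = batch maximum / 8.5.
    """

    center_gain: float = 1.0
    flank_gains: tuple[float, ...] = (1.5, 1.25, 1.0, 3.0)
    #: conversion between the units the published flank gains assume and the
    #: unit-L2-normalized responses this implementation produces; the flank
    #: inhibition coefficient is flank_gains[scale] * flank_drive.  Calibrated
    #: once against the published 90%-of-maximum curvature-radius bands of the
    #: smallest and largest scales.
    flank_drive: float = 0.165
    #: flank drive of the sign-of-curvature cells; the full published gains
    #: (drive 1) give the crisp convex/concave discrimination the sign pair
    #: needs (sign cells are tuned separately from the degree cells)
    sign_flank_drive: float = 1.0
    degree_displacement_fraction: float = 0.5
    sign_displacement_fractions: tuple[float, ...] = (0.2, 0.25, 0.25, 0.4)
    sigmoid_alpha: float = 0.01
    sigmoid_beta_divisor: float = 8.5

    def __post_init__(self):
        object.__setattr__(self, "flank_gains", tuple(float(g) for g in self.flank_gains))
        object.__setattr__(
            self,
            "sign_displacement_fractions",
            tuple(float(f) for f in self.sign_displacement_fractions),
        )
        if self.center_gain <= 0 or any(g <= 0 for g in self.flank_gains):
            raise ValueError("gains must be positive")
        if self.flank_drive <= 0 or self.sign_flank_drive <= 0:
            raise ValueError("flank drives must be positive")
        if not 0 < self.degree_displacement_fraction < 1:
            raise ValueError("degree displacement fraction must lie in (0, 1)")
        if any(not 0 < f < 1 for f in self.sign_displacement_fractions):
            raise ValueError("sign displacement fractions must lie in (0, 1)")


def saturate(x: np.ndarray, alpha: float, beta: float) -> np.ndarray:
    """Monotone logistic saturation with g(0) = 0."""
    base = 1.0 / (1.0 + math.exp(alpha * beta))
    return 1.0 / (1.0 + np.exp(-alpha * (np.asarray(x) - beta))) - base


def _check_scale(config: EndstoppedConfig, bank: FilterBankConfig, scale: int) -> None:
    if not 0 <= scale < bank.n_scales:
        raise IndexError(f"scale index {scale} out of range for {bank.n_scales} scales")
    if len(config.flank_gains) < bank.n_scales:
        raise ValueError("flank_gains must provide one gain per scale")


def degree_responses_raw(
    simple: ResponseStack,
    complex_: ResponseStack,
    config: EndstoppedConfig,
    scale: int,
) -> np.ndarray:
    """Rectified (pre-saturation) degree-of-curvature maps for one scale,
    all orientations; shape (n_orientations, H, W)."""
    bank = simple.config
    _check_scale(config, bank, scale)
    size = bank.sizes[scale]
    d = config.degree_displacement_fraction * size
    cc = config.center_gain
    cf = config.flank_gains[scale] * config.flank_drive
    out = np.empty_like(simple.values[scale])
    for oi, theta in enumerate(bank.orientations):
        dx, dy = d * math.cos(theta), d * math.sin(theta)
        cplane = complex_.values[scale, oi]
        flank1 = shift_bilinear(cplane, dy, dx)
        flank2 = shift_bilinear(cplane, -dy, -dx)
        out[oi] = cc * simple.values[scale, oi] - cf * flank1 - cf * flank2
    np.maximum(out, 0.0, out=out)
    return out


def degree_response(
    simple: ResponseStack,
    complex_: ResponseStack,
    config: EndstoppedConfig,
    scale: int,
    orientation: int,
    beta: float | None = None,
) -> np.ndarray:
    """Saturated degree-of-curvature map for one (scale, orientation).

    ``beta`` defaults to this scale's population maximum over orientations
    and positions divided by the configured divisor.
    """
    raw = degree_responses_raw(simple, complex_, config, scale)
    if beta is None:
        beta = raw.max() / config.sigmoid_beta_divisor
    return saturate(raw[orientation], config.sigmoid_alpha, beta)


_SIGNS = ("positive", "negative")


def sign_responses_raw(
    simple: ResponseStack,
    complex_: ResponseStack,
    config: EndstoppedConfig,
    scale: int,
    sign: str,
) -> np.ndarray:
    """Rectified sign-of-curvature maps for one scale and sign variant,
    all orientations; shape (n_orientations, H, W).

    Requires the orientation sampling to contain theta+45 and theta+135
    degrees for every channel theta (i.e. a multiple of 4 orientations evenly
    spaced over 180 degrees).
    """
    if sign not in _SIGNS:
        raise ValueError(f"sign must be one of {_SIGNS}, got {sign!r}")
    bank = simple.config
    _check_scale(config, bank, scale)
    n_or = bank.n_orientations
    if n_or % 4 != 0:
        raise ValueError(
            "sign-of-curvature cells need 45-degree flank channels: use a "
            "multiple of 4 evenly spaced orientations"
        )
    q = n_or // 4  # index offset corresponding to +45 degrees
    size = bank.sizes[scale]
    d = config.sign_displacement_fractions[scale] * size
    cc = config.center_gain
    cf = config.flank_gains[scale] * config.sign_flank_drive
    side = 1.0 if sign == "positive" else -1.0
    out = np.empty_like(simple.values[scale])
    for oi, theta in enumerate(bank.orientations):
        o45 = (oi + q) % n_or
        o135 = (oi + 3 * q) % n_or
        a45 = theta + math.pi / 4
        a135 = theta + 3 * math.pi / 4
        f1 = shift_bilinear(
            complex_.values[scale, o45], side * d * math.sin(a45), side * d * math.cos(a45)
        )
        f2 = shift_bilinear(
            complex_.values[scale, o135], side * d * math.sin(a135), side * d * math.cos(a135)
        )
        out[oi] = cc * simple.values[scale, oi] - cf * f1 - cf * f2
    np.maximum(out, 0.0, out=out)
    return out


def sign_response(
    simple: ResponseStack,
    complex_: ResponseStack,
    config: EndstoppedConfig,
    scale: int,
    orientation: int,
    sign: str,
    beta: float | None = None,
) -> np.ndarray:
    """Saturated sign-of-curvature map for one (scale, orientation, sign)."""
    raw = sign_responses_raw(simple, complex_, config, scale, sign)
    if beta is None:
        beta = raw.max() / config.sigmoid_beta_divisor
    return saturate(raw[orientation], config.sigmoid_alpha, beta)


# ---------------------------------------------------------------------------
# curvature-radius tuning


#: default angular extent cap for tuning arcs: 3/4 of the full circle, so the
#: stimulus stays an open arc (a closed circle adds a second, opposite-
#: curvature apex inside small cells' receptive fields)
ARC_EXTENT_CAP = 1.5 * math.pi


def fit_arc_spec(
    radius: float,
    canvas: int = 400,
    margin: float = 4.0,
    extent_cap: float = ARC_EXTENT_CAP,
) -> ArcSpec:
    """Largest arc of the given radius whose apex sits at the canvas centre.

    The circle centre is placed below the apex (at ``(c, c + radius)``); the
    angular extent is the largest symmetric window around the apex that keeps
    the arc inside the canvas, capped at ``extent_cap`` (270 degrees by
    default, keeping the stimulus an open arc).
    """
    c = (canvas - 1) / 2.0
    cx, cy = c, c + radius
    lo, hi = margin, canvas - 1 - margin
    phis = -math.pi / 2 + np.linspace(0, math.pi, 2001)
    xs = cx + radius * np.cos(phis)
    ys = cy + radius * np.sin(phis)
    inside = (xs >= lo) & (xs <= hi) & (ys >= lo) & (ys <= hi)
    bad = np.nonzero(~inside)[0]
    half = math.pi if len(bad) == 0 else max(phis[bad[0] - 1] + math.pi / 2, 1e-3)
    extent = min(2 * half, extent_cap, 2 * math.pi)
    return ArcSpec(radius=radius, arc_center=(cx, cy), angular_extent=extent, orientation=-math.pi / 2)


def _single_scale_bank(bank: FilterBankConfig, scale: int) -> FilterBankConfig:
    return FilterBankConfig(
        orientations=bank.orientations,
        sizes=(bank.sizes[scale],),
        aspect_ratios=(bank.aspect_ratios[scale],),
        width_ratio=bank.width_ratio,
        subunit_spacing_fraction=bank.subunit_spacing_fraction,
        subunit_count=bank.subunit_count,
    )


def _single_scale_es(config: EndstoppedConfig, scale: int) -> EndstoppedConfig:
    return EndstoppedConfig(
        center_gain=config.center_gain,
        flank_gains=(config.flank_gains[scale],),
        flank_drive=config.flank_drive,
        sign_flank_drive=config.sign_flank_drive,
        degree_displacement_fraction=config.degree_displacement_fraction,
        sign_displacement_fractions=(config.sign_displacement_fractions[scale],),
        sigmoid_alpha=config.sigmoid_alpha,
        sigmoid_beta_divisor=config.sigmoid_beta_divisor,
    )


def curvature_tuning_curve(
    scale: int,
    radii,
    bank: FilterBankConfig | None = None,
    config: EndstoppedConfig | None = None,
    canvas: int = 400,
) -> pd.DataFrame:
    """Degree-of-curvature tuning: response versus arc radius.

    For each radius the largest apex-centred arc fitting the canvas is
    rendered (anti-aliased, so stair-step rasterization noise does not alias
    into the curvature channels) and the scale's degree endstopped response is
    read out at the model cell centred on the arc apex: the maximum over
    orientations within a small (+-6 px) positional neighbourhood of the
    apex, emulating a single-unit recording with the stimulus centred on the
    receptive field.  (Arcs of radius beyond ~half the canvas must be clipped,
    and their line terminators -- loci of locally infinite curvature -- would
    otherwise dominate a whole-map maximum at every radius.)

    The saturation beta is computed once from the whole sweep (the stimulus
    batch) and the curve is normalized to [0, 1] by its maximum.  Returns a
    DataFrame with columns ``radius`` and ``response``.
    """
    radii = [float(r) for r in radii]
    if not radii:
        raise ValueError("need at least one radius")
    bank = bank if bank is not None else FilterBankConfig()
    config = config if config is not None else EndstoppedConfig()
    sub_bank = _single_scale_bank(bank, scale)
    sub_es = _single_scale_es(config, scale)
    win = 6
    c0 = (canvas - 1) // 2
    lo, hi = c0 - win, c0 + win + 2
    raw_peaks = np.empty(len(radii))
    for i, r in enumerate(radii):
        img = render_arc(fit_arc_spec(r, canvas=canvas), canvas=canvas, antialias=True)
        s = simple_responses(img, sub_bank)
        c = complex_responses(s)
        raw_peaks[i] = degree_responses_raw(s, c, sub_es, 0)[:, lo:hi, lo:hi].max()
    beta = raw_peaks.max() / config.sigmoid_beta_divisor
    resp = saturate(raw_peaks, config.sigmoid_alpha, beta)
    top = resp.max()
    if top > 0:
        resp = resp / top
    return pd.DataFrame({"radius": radii, "response": resp})


def band_90pct(curve: pd.DataFrame, fraction: float = 0.9) -> tuple[float, float]:
    """Radius interval over which the tuning curve is >= ``fraction`` of its
    maximum, with linear interpolation between sampled radii."""
    if len(curve) == 0:
        raise ValueError("empty tuning curve")
    r = np.asarray(curve["radius"], dtype=float)
    v = np.asarray(curve["response"], dtype=float)
    order = np.argsort(r)
    r, v = r[order], v[order]
    vmax = v.max()
    if vmax <= 0:
        raise ValueError("tuning curve is identically zero")
    thr = fraction * vmax
    above = v >= thr
    idx = np.nonzero(above)[0]
    lo_i, hi_i = idx[0], idx[-1]
    lo = r[lo_i]
    if lo_i > 0:
        r0, r1, v0, v1 = r[lo_i - 1], r[lo_i], v[lo_i - 1], v[lo_i]
        lo = r0 + (thr - v0) * (r1 - r0) / (v1 - v0)
    hi = r[hi_i]
    if hi_i < len(r) - 1:
        r0, r1, v0, v1 = r[hi_i], r[hi_i + 1], v[hi_i], v[hi_i + 1]
        hi = r0 + (thr - v0) * (r1 - r0) / (v1 - v0)
    return float(lo), float(hi)
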