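"""Local-curvature cells: signed curvature classes from endstopped responses.

A local curvature cell fuses a degree-of-curvature endstopped cell with the
pair of sign-of-curvature cells at the same scale and orientation: the degree
response is routed to the positive class where the positive-sign cell beats
the negative-sign cell, to the negative class where it loses, and to neither
on an exact tie.  With four degree scales this doubles the four magnitude
classes into eight signed classes (sharp...broad x convex/concave).

Where the endstopped population is nearly silent but an orientation-tuned
simple cell is strongly active, the contour is a straight line: those
locations are flagged zero-curvature and all signed planes are cleared there.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from scipy.ndimage import maximum_filter

from .frontend import ResponseStack

__all__ = ["CurvatureConfig", "CurvatureMap", "local_curvature_map"]


@dataclass(frozen=True)
class CurvatureConfig:
    """Thresholds of the straight-contour rule and scale-pooling policy.

    A location is flagged straight when its best (full-inhibition) endstopped
    response is below ``straight_endstopped_threshold`` times its own best
    simple response -- a local contrast between the curvature evidence and
    the orientation evidence -- while that simple response also exceeds
    ``straight_simple_threshold`` times the simple scene maximum.  The
    ratio form is scale-free, so it survives the downstream [0, 1]
    normalization.
    """

    straight_endstopped_threshold: float = 0.55
    straight_simple_threshold: float = 0.5
    #: half-width (px) of the neighbourhood over which endstopped evidence is
    #: pooled before the weakness test: curvature responses peak a few pixels
    #: off the contour, so a purely pixelwise test misfires on curved apices
    straight_pool_radius: int = 5
    #: if True, keep only the strongest scale's class at each location
    winner_take_all: bool = False

    def __post_init__(self):
        if self.straight_endstopped_threshold < 0:
            raise ValueError("straight_endstopped_threshold must be non-negative")
        if not 0 <= self.straight_simple_threshold <= 1:
            raise ValueError("straight_simple_threshold must lie in [0, 1]")


@dataclass
class CurvatureMap:
    """Per-location responses of the 2*n signed curvature classes.

    ``class_values`` is indexed (scale, sign, y, x) with sign 0 = positive
    (convex) and 1 = negative (concave); ``classes()`` flattens to the
    canonical 2*n-class axis ordered sharp-positive, sharp-negative, ...,
    broad-positive, broad-negative.  ``straight`` flags zero-curvature
    (straight contour) locations.
    """

    class_values: np.ndarray
    straight: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.class_values, dtype=float)
        if v.ndim != 4 or v.shape[1] != 2:
            raise ValueError("class_values must have shape (n_scales, 2, H, W)")
        if self.straight.shape != v.shape[2:]:
            raise ValueError("straight plane must match the spatial dims")
        self.class_values = v
        self.straight = np.asarray(self.straight, dtype=bool)

    @property
    def n_scales(self) -> int:
        return self.class_values.shape[0]

    @property
    def n_classes(self) -> int:
        return 2 * self.n_scales

    def classes(self) -> np.ndarray:
        """(n_classes, H, W) view, class index = 2*scale + sign."""
        s, _, h, w = self.class_values.shape
        return self.class_values.reshape(s * 2, h, w)

    def is_empty(self) -> bool:
        return not np.any(self.class_values) and not np.any(self.straight)


def local_curvature_map(
    degree: np.ndarray,
    sign_pos: np.ndarray,
    sign_neg: np.ndarray,
    simple: ResponseStack | np.ndarray,
    config: CurvatureConfig | None = None,
    straight_reference: np.ndarray | None = None,
) -> CurvatureMap:
    """Fuse degree and sign endstopped responses into signed curvature maps.

    Parameters
    ----------
    degree, sign_pos, sign_neg
        Arrays of shape (n_scales, n_orientations, H, W): saturated degree
        and sign-of-curvature endstopped responses.
    simple
        The simple-cell :class:`ResponseStack` (or its values), used by the
        straight-line rule.
    config
        Thresholds; defaults to :class:`CurvatureConfig`.
    straight_reference
        Endstopped responses the straight-line rule tests for weakness,
        same shape as ``degree`` (default: ``degree`` itself).  The pipeline
        passes degree responses computed at full flank inhibition, which are
        silent on straight contours.

    The routing is per (scale, orientation, location); orientation is then
    pooled with a max, since the shape layer cares about curvature classes,
    not the orientation they were detected at.
    """
    config = config if config is not None else CurvatureConfig()
    degree = np.asarray(degree, dtype=float)
    sign_pos = np.asarray(sign_pos, dtype=float)
    sign_neg = np.asarray(sign_neg, dtype=float)
    sv = simple.values if isinstance(simple, ResponseStack) else np.asarray(simple, float)
    if not (degree.shape == sign_pos.shape == sign_neg.shape == sv.shape):
        raise ValueError(
            f"shape mismatch: degree {degree.shape}, sign_pos {sign_pos.shape}, "
            f"sign_neg {sign_neg.shape}, simple {sv.shape}"
        )
    pos = np.where(sign_pos > sign_neg, degree, 0.0).max(axis=1)
    neg = np.where(sign_neg > sign_pos, degree, 0.0).max(axis=1)
    # different orientations can vote for opposite signs at one location;
    # keep only the stronger signed response so the signs stay mutually
    # exclusive per scale (an exact tie silences both, as for the raw rule)
    pos_x = np.where(pos > neg, pos, 0.0)
    neg_x = np.where(neg > pos, neg, 0.0)
    planes = np.stack([pos_x, neg_x], axis=1)  # (n_scales, 2, H, W)

    ref = degree if straight_reference is None else np.asarray(straight_reference, float)
    if ref.shape != degree.shape:
        raise ValueError("straight_reference must match the degree array shape")
    straight = np.zeros(sv.shape[2:], dtype=bool)
    s_max = sv.max()
    if s_max > 0:
        s_local = sv.max(axis=(0, 1))
        es_local = maximum_filter(
            ref.max(axis=(0, 1)), size=2 * config.straight_pool_radius + 1
        )
        weak_es = es_local < config.straight_endstopped_threshold * s_local
        strong_s = s_local > config.straight_simple_threshold * s_max
        straight = weak_es & strong_s
        planes[:, :, straight] = 0.0

    if config.winner_take_all and planes.any():
        strongest = planes.max(axis=1).argmax(axis=0)  # (H, W) best scale
        keep = strongest[None, :, :] == np.arange(planes.shape[0])[:, None, None]
        planes *= keep[:, None, :, :]

    return CurvatureMap(planes, straight)
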