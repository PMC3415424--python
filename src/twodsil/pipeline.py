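"""End-to-end pipeline: image -> simple -> complex -> endstopped -> curvature.

All stages are deterministic; two runs on the same image produce bit-identical
outputs.  The saturation half-point beta is computed per scale from the
current image (its endstopped population maximum divided by the configured
divisor), so a single-image run is self-contained; batch workflows that need
a shared beta (e.g. tuning sweeps) use the endstopped module directly.
"""

from __future__ import annotations

import logging
import time
from dataclasses import replace

import numpy as np

from .config import ModelConfig
from .curvature import CurvatureMap, local_curvature_map
from .endstopped import degree_responses_raw, saturate, sign_responses_raw
from .frontend import ResponseStack, complex_responses, simple_responses

log = logging.getLogger("twodsil")

__all__ = ["run_pipeline", "compute_curvature_map"]


def run_pipeline(image, config: ModelConfig | None = None) -> dict:
    """Run all model layers on one stimulus image.

    Returns a dict with the simple and complex :class:`ResponseStack`s, the
    saturated degree and sign endstopped arrays (scale, orientation, y, x)
    and the fused :class:`CurvatureMap`.
    """
    config = config if config is not None else ModelConfig()
    bank = config.bank
    es = config.endstopped

    t0 = time.perf_counter()
    simple = simple_responses(image, bank)
    t1 = time.perf_counter()
    cx = complex_responses(simple)
    t2 = time.perf_counter()

    n_s, n_o = bank.n_scales, bank.n_orientations
    H, W = simple.spatial_shape
    degree = np.empty((n_s, n_o, H, W))
    sign_pos = np.empty_like(degree)
    sign_neg = np.empty_like(degree)
    # full-inhibition degree responses: silent on straight contours, used by
    # the curvature layer's zero-curvature rule
    es_full = replace(es, flank_drive=1.0)
    degree_full = np.empty_like(degree)
    for s in range(n_s):
        raw_deg = degree_responses_raw(simple, cx, es, s)
        degree_full[s] = degree_responses_raw(simple, cx, es_full, s)
        raw_pos = sign_responses_raw(simple, cx, es, s, "positive")
        raw_neg = sign_responses_raw(simple, cx, es, s, "negative")
        beta_deg = raw_deg.max() / es.sigmoid_beta_divisor
        beta_sgn = max(raw_pos.max(), raw_neg.max()) / es.sigmoid_beta_divisor
        degree[s] = saturate(raw_deg, es.sigmoid_alpha, beta_deg) if raw_deg.max() > 0 else 0.0
        if max(raw_pos.max(), raw_neg.max()) > 0:
            sign_pos[s] = saturate(raw_pos, es.sigmoid_alpha, beta_sgn)
            sign_neg[s] = saturate(raw_neg, es.sigmoid_alpha, beta_sgn)
        else:
            sign_pos[s] = 0.0
            sign_neg[s] = 0.0
    t3 = time.perf_counter()
    cmap = local_curvature_map(
        degree, sign_pos, sign_neg, simple, config.curvature,
        straight_reference=degree_full,
    )
    t4 = time.perf_counter()
    log.debug(
        "pipeline timings: simple %.2fs complex %.2fs endstopped %.2fs curvature %.2fs; "
        "max activations: simple %.3g complex %.3g degree %.3g",
        t1 - t0, t2 - t1, t3 - t2, t4 - t3,
        simple.values.max(), cx.values.max(), degree.max(),
    )
    return {
        "simple": simple,
        "complex": cx,
        "degree": degree,
        "sign_positive": sign_pos,
        "sign_negative": sign_neg,
        "curvature": cmap,
    }


def compute_curvature_map(image, config: ModelConfig | None = None) -> CurvatureMap:
    """Convenience wrapper: the fused curvature map of one stimulus."""
    return run_pipeline(image, config)["curvature"]
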