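"""Response comparison and neuron-isolation aids.

Model shape-cell profiles are compared to reference profiles (e.g. recorded
V4 responses supplied as CSV) by the mean absolute difference between
normalized response vectors over a common stimulus battery.  The isolation
aid reconstructs a template stimulus for a reference neuron by superimposing
the stimuli that drove it to at least a given fraction of its maximum
response.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stimuli import StimulusImage

__all__ = [
    "ComparisonReport",
    "normalize_responses",
    "mean_abs_difference",
    "build_isolation_template",
    "compare_profiles",
]


@dataclass
class ComparisonReport:
    """Per-neuron mean absolute difference between model and reference."""

    per_neuron: pd.DataFrame  # columns: neuron_id, mean_abs_diff, stdev
    battery_size: int

    def to_csv(self, path) -> None:
        self.per_neuron.to_csv(path, index=False)


def normalize_responses(raw, template_index: int | None = None) -> np.ndarray:
    """Scale a response vector to [0, 1].

    Divides by the response to the designated template stimulus when given
    (the stimulus the neuron was isolated with), otherwise by the maximum of
    the vector.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.size == 0 or raw.max() <= 0:
        raise ValueError("cannot normalize an all-zero response vector")
    denom = raw[template_index] if template_index is not None else raw.max()
    if denom <= 0:
        raise ValueError("template response is zero; cannot normalize")
    return raw / denom


def mean_abs_difference(model, reference) -> tuple[float, float]:
    """Mean and standard deviation of |model_j - reference_j| over stimuli."""
    model = np.asarray(model, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if model.shape != reference.shape:
        raise ValueError(
            f"length mismatch: model has {model.shape}, reference {reference.shape}"
        )
    d = np.abs(model - reference)
    return float(d.mean()), float(d.std())


def build_isolation_template(
    battery,
    responses,
    percentile: float = 70.0,
    order_statistic: bool = False,
) -> StimulusImage:
    """Superimpose the stimuli that drove a neuron strongest.

    By default a stimulus is selected when its response reaches
    ``percentile`` percent of the maximum response; with ``order_statistic``
    the cut is the ``percentile``-th order-statistic percentile of the
    response distribution instead.  The template is the pixelwise maximum of
    the selected stimuli.
    """
    battery = list(battery)
    responses = np.asarray(responses, dtype=float)
    if len(battery) != len(responses):
        raise ValueError("battery and responses must have equal length")
    if len(battery) == 0 or responses.max() <= 0:
        raise ValueError("need at least one stimulus with a positive response")
    if order_statistic:
        cut = np.percentile(responses, percentile)
    else:
        cut = (percentile / 100.0) * responses.max()
    selected = [img for img, r in zip(battery, responses) if r >= cut]
    if not selected:
        raise ValueError("no stimulus passed the selection cut")
    out = selected[0].pixels.copy()
    for img in selected[1:]:
        np.maximum(out, img.pixels, out=out)
    return StimulusImage(out)


def compare_profiles(
    model: pd.DataFrame, reference: pd.DataFrame, neuron_id="neuron"
) -> ComparisonReport:
    """Compare per-stimulus model and reference profiles (CSV-shaped frames).

    Both frames need columns ``stimulus_id`` and ``response``; they are
    joined on ``stimulus_id``.
    """
    merged = model.merge(
        reference, on="stimulus_id", suffixes=("_model", "_reference")
    )
    if merged.empty:
        raise ValueError("model and reference share no stimulus ids")
    mean, std = mean_abs_difference(
        merged["response_model"].to_numpy(), merged["response_reference"].to_numpy()
    )
    report = pd.DataFrame(
        [{"neuron_id": neuron_id, "mean_abs_diff": mean, "stdev": std}]
    )
    return ComparisonReport(report, battery_size=len(merged))
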