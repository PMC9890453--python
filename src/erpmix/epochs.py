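"""Epoch-level preprocessing arithmetic and single-trial amplitude extraction.

Operations here are deliberately minimal: trigger-delay arithmetic, linear
detrend on a fixed span, prestimulus baseline subtraction, and the mean
amplitude of a component window per trial and hemisphere.  Window bounds in
ms snap to the nearest sample on the grid and the interval is closed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import EpochSet


@dataclass(frozen=True)
class DelaySpec:
    """Amplifier + display delays (ms) used to shift event timestamps."""

    amplifier_delay: float
    display_delay: float

    def __post_init__(self) -> None:
        if self.amplifier_delay < 0 or self.display_delay < 0:
            raise ValueError("delays must be non-negative")


def total_delay(spec: DelaySpec) -> float:
    """Total trigger delay in ms; timestamps are shifted later by this."""
    return spec.amplifier_delay + spec.display_delay


def _span_slice(epochs: EpochSet, start: float, end: float) -> slice:
    step = float(np.median(np.diff(epochs.times)))
    lo, hi = epochs.times[0] - step / 2, epochs.times[-1] + step / 2
    if not (lo <= start <= hi and lo <= end <= hi):
        raise ValueError(
            f"span [{start}, {end}] ms outside the epoch "
            f"[{epochs.times[0]}, {epochs.times[-1]}] ms"
        )
    i0 = epochs.sample_index(start)
    i1 = epochs.sample_index(end)
    if i1 < i0:
        i0, i1 = i1, i0
    return slice(i0, i1 + 1)


def baseline_correct(
    epochs: EpochSet, baseline: tuple[float, float] = (-200.0, 0.0)
) -> EpochSet:
    """Subtract the mean over the baseline span from every sample."""
    sl = _span_slice(epochs, *baseline)
    if sl.stop - sl.start < 1:
        raise ValueError("baseline window contains no samples")
    out = epochs.copy()
    out.data -= out.data[:, :, sl].mean(axis=2, keepdims=True)
    return out


def detrend_linear(
    epochs: EpochSet, span: tuple[float, float] = (-200.0, 996.0)
) -> EpochSet:
    """Fit a least-squares line on the span (per trial x channel) and
    subtract it across the span."""
    sl = _span_slice(epochs, *span)
    if sl.stop - sl.start < 2:
        raise ValueError("detrend span must contain at least 2 samples")
    out = epochs.copy()
    t = out.times[sl]
    X = np.column_stack([np.ones_like(t), t])
    seg = out.data[:, :, sl]
    flat = seg.reshape(-1, seg.shape[2]).T  # samples x (trial*channel)
    coef, *_ = np.linalg.lstsq(X, flat, rcond=None)
    fitted = (X @ coef).T.reshape(seg.shape)
    out.data[:, :, sl] = seg - fitted
    return out


def mean_amplitude(
    epochs: EpochSet,
    start: float,
    end: float,
    component: str,
) -> pd.DataFrame:
    """Single-trial mean amplitude per trial x hemisphere.

    Channels of each hemisphere's cluster are averaged first, then the mean
    is taken over the samples in the closed window [start, end] (bounds
    snapped to the nearest sample).  Returns the trial metadata with
    ``component``, ``hemisphere`` and ``mean_amplitude`` columns appended,
    one row per trial and hemisphere.
    """
    sl = _span_slice(epochs, start, end)
    pieces = []
    for hemi in ("left", "right"):
        labels = [c for c in epochs.channels if epochs.hemisphere[c] == hemi]
        if not labels:
            continue
        idx = epochs.channel_indices(labels)
        cluster_mean = epochs.data[:, idx, :].mean(axis=1)  # trials x samples
        amps = cluster_mean[:, sl].mean(axis=1)
        block = epochs.metadata.copy()
        block["component"] = component
        block["hemisphere"] = hemi
        block["mean_amplitude"] = amps
        pieces.append(block)
    table = pd.concat(pieces, ignore_index=True)
    if not np.isfinite(table["mean_amplitude"]).all():
        raise ValueError("non-finite mean amplitudes")
    return table
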