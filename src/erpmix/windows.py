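"""Data-driven component-window identification.

The integration window for a component is found from a condition-blind
grand-average waveform: locate the extremum of the component's polarity in a
search range, then take the contiguous span around the peak where the
waveform magnitude exceeds a fraction ``f`` of the peak magnitude (f = 0.5 is
the full-width half-maximum).  If the resulting width falls outside the
permitted range (36-40 ms by default) the fraction is adjusted by bisection —
width is monotone non-increasing in ``f`` for a unimodal waveform — until the
width lands inside the range.  Crossing times are linearly interpolated
between samples, since a 4 ms grid is too coarse for a 36-40 ms target
otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json

import numpy as np

from .simulate import EpochSet


@dataclass
class ComponentWindow:
    """A named integration window with its audit trail."""

    name: str
    polarity: str              # "positive" | "negative"
    search_range: tuple
    start: float               # ms
    end: float                 # ms
    width: float               # ms
    peak_time: float
    peak_amp: float            # uV, signed
    cluster: dict              # hemisphere -> channel labels
    fraction: float = 0.5      # final threshold fraction f
    f_trace: list = field(default_factory=list)
    n_iterations: int = 0

    def to_json(self) -> str:
        d = asdict(self)
        d["search_range"] = list(self.search_range)
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, s: str) -> "ComponentWindow":
        d = json.loads(s)
        d["search_range"] = tuple(d["search_range"])
        return cls(**d)


def grand_average(epochs: EpochSet, cluster: list) -> tuple[np.ndarray, np.ndarray]:
    """Unweighted mean over trials and cluster channels at each sample."""
    if len(cluster) == 0:
        raise ValueError("empty channel cluster")
    idx = epochs.channel_indices(cluster)
    wave = epochs.data[:, idx, :].mean(axis=(0, 1))
    return epochs.times.copy(), wave


def find_peak(
    times: np.ndarray,
    waveform: np.ndarray,
    search_range: tuple[float, float],
    polarity: str,
) -> tuple[float, float]:
    """Extremum of the stated polarity inside the closed search range.

    Ties resolve to the earliest sample.  A flat waveform in the range is
    ambiguous and raises ``ValueError``.
    """
    lo, hi = search_range
    mask = (times >= lo) & (times <= hi)
    if not mask.any():
        raise ValueError("search range contains no samples")
    t = times[mask]
    w = waveform[mask]
    if np.ptp(w) == 0:
        raise ValueError("flat waveform: ambiguous peak")
    s = w if polarity == "positive" else -w
    k = int(np.argmax(s))  # argmax returns the first (earliest) maximum
    return float(t[k]), float(w[k])


def _width_at_fraction(
    times: np.ndarray,
    signed: np.ndarray,
    peak_idx: int,
    threshold: float,
) -> tuple[float, float]:
    """Interpolated (start, end) where ``signed`` crosses ``threshold``
    on either side of the peak sample."""
    n = len(signed)
    i = peak_idx
    while i > 0 and signed[i - 1] >= threshold:
        i -= 1
    if i == 0 and signed[0] >= threshold:
        raise ValueError("waveform does not cross the threshold left of the peak")
    # crossing between i-1 and i
    t0, t1 = times[i - 1], times[i]
    y0, y1 = signed[i - 1], signed[i]
    start = t0 + (threshold - y0) / (y1 - y0) * (t1 - t0)

    j = peak_idx
    while j < n - 1 and signed[j + 1] >= threshold:
        j += 1
    if j == n - 1 and signed[n - 1] >= threshold:
        raise ValueError("waveform does not cross the threshold right of the peak")
    t0, t1 = times[j], times[j + 1]
    y0, y1 = signed[j], signed[j + 1]
    end = t0 + (threshold - y0) / (y1 - y0) * (t1 - t0)
    return float(start), float(end)


def fwhm_window(
    times: np.ndarray,
    waveform: np.ndarray,
    search_range: tuple[float, float],
    polarity: str,
    name: str = "component",
    cluster: dict | None = None,
    width_range: tuple[float, float] = (36.0, 40.0),
    f_tol: float = 1e-4,
    max_iter: int = 200,
) -> ComponentWindow:
    """Iterative FWHM integration window with width constrained to a range.

    Starts at f = 0.5; if the width falls outside ``width_range`` the
    fraction is bisected on (0, 1) until the width is inside the range
    (inclusive).  The final fraction and its trace are returned for audit.
    """
    peak_time, peak_amp = find_peak(times, waveform, search_range, polarity)
    signed = waveform if polarity == "positive" else -waveform
    peak_idx = int(np.argmin(np.abs(times - peak_time)))
    mag = abs(peak_amp)
    w_lo, w_hi = width_range

    def width_of(f: float) -> tuple[float, float, float]:
        start, end = _width_at_fraction(times, signed, peak_idx, f * mag)
        return end - start, start, end

    f = 0.5
    f_low, f_high = 0.0, 1.0  # width(f) decreasing: too wide -> raise f
    trace = []
    for it in range(max_iter):
        try:
            width, start, end = width_of(f)
        except ValueError as exc:
            raise ValueError(
                f"fwhm_window failed at f={f:.6g}: {exc}; trace={trace}"
            ) from exc
        trace.append((f, width))
        if w_lo <= width <= w_hi:
            return ComponentWindow(
                name=name,
                polarity=polarity,
                search_range=tuple(search_range),
                start=start,
                end=end,
                width=width,
                peak_time=peak_time,
                peak_amp=peak_amp,
                cluster=cluster or {},
                fraction=f,
                f_trace=[list(x) for x in trace],
                n_iterations=it + 1,
            )
        if width > w_hi:
            f_low = f
        else:
            f_high = f
        if f_high - f_low < f_tol:
            raise ValueError(
                f"no threshold fraction yields width in {width_range}; "
                f"trace={trace}"
            )
        f = 0.5 * (f_low + f_high)
    raise ValueError(f"fwhm_window did not converge in {max_iter} iterations")


def select_peak_cluster(
    epochs: EpochSet,
    candidate_clusters: dict[str, list],
    search_range: tuple[float, float],
    polarity: str,
) -> str:
    """Deterministic surrogate for visual peak-channel confirmation: among
    candidate clusters, pick the one with the largest |peak amplitude| of
    its grand average."""
    best, best_mag = None, -np.inf
    for label in sorted(candidate_clusters):
        t, w = grand_average(epochs, candidate_clusters[label])
        _, amp = find_peak(t, w, search_range, polarity)
        if abs(amp) > best_mag:
            best, best_mag = label, abs(amp)
    return best
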