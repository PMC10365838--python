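"""Spike detection and firing-pattern statistics for ramp responses.

Conventions:

* a spike is an upward crossing of -40 mV; its time is the first sample at
  or above threshold,
* the adaptation index is (#spikes on the up-ramp - #spikes on the
  down-ramp) / (total spikes), computed about the ramp peak time; positive
  values mean firing concentrated early (spike-rate adaptation), negative
  values firing concentrated late (acceleration); a spike exactly at the
  peak counts as up-ramp,
* instantaneous frequency is 1000/ISI placed at the ISI midpoint (f/t), or
  against the injected current at that midpoint, relative to the tonic
  baseline (f/I),
* f/I hysteresis is classified by the signed (shoelace) area of the closed
  loop traced by the f/I points in temporal order: clockwise loops indicate
  adaptation, counter-clockwise loops acceleration,
* inter-spike current traces are isolated by removing samples whose first
  temporal derivative or value falls outside preset bounds (presets ``net``,
  ``trpm4``, ``nav``, ``o_state`` apply the thresholds used for the model's
  current traces, in uA/cm2 and uA/(ms cm2); ``o_state`` is unitless
  occupancy).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SpikeTrain",
    "AnalysisSummary",
    "detect_spikes",
    "adaptation_index",
    "synaptic_adaptation_index",
    "instantaneous_frequency",
    "peak_instantaneous_frequency",
    "classify_hysteresis",
    "clean_interspike_trace",
    "CLEANING_PRESETS",
    "analyze_ramp_response",
]


@dataclass
class SpikeTrain:
    """Detected spike times (ms), strictly increasing."""

    spike_times: np.ndarray
    detection_threshold: float = -40.0
    source: str = ""

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.spike_times.size > 1 and np.any(np.diff(self.spike_times) <= 0):
            raise ValueError("spike times must be strictly increasing")

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)


def detect_spikes(time, v, threshold: float = -40.0, source: str = "") -> SpikeTrain:
    """Detect spikes as upward threshold crossings of a uniformly sampled trace.

    One spike per crossing: a sample counts when it is at or above threshold
    and the previous sample was below (remaining above threshold does not
    re-count).  The spike time is that first supra-threshold sample.
    """
    time = np.asarray(time, dtype=float)
    v = np.asarray(v, dtype=float)
    if time.shape != v.shape:
        raise ValueError("time and voltage must have the same shape")
    above = v >= threshold
    crossings = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    if above.size and above[0]:
        crossings = np.concatenate([[0], crossings])
    return SpikeTrain(time[crossings], detection_threshold=threshold, source=source)


def adaptation_index(train: SpikeTrain, peak_time: float) -> float:
    """(#up - #down) / (#up + #down) about ``peak_time``.

    A spike exactly at ``peak_time`` counts as up-ramp (half-open interval
    convention).  Raises on an empty train, for which the index is undefined.
    """
    n = train.n_spikes
    if n == 0:
        raise ValueError("adaptation index undefined for an empty spike train")
    n_up = int(np.sum(train.spike_times <= peak_time))
    return (n_up - (n - n_up)) / n


def synaptic_adaptation_index(
    train: SpikeTrain, stim_times: np.ndarray, n_up_stimuli: int = 15
) -> float:
    """Adaptation index for synaptically driven ramps.

    The up-ramp is defined by the first ``n_up_stimuli`` stimuli (15 of 30 by
    default): spikes occurring before the (n_up+1)-th stimulus count as
    up-ramp spikes.
    """
    stim_times = np.asarray(stim_times, dtype=float)
    if stim_times.size <= n_up_stimuli:
        raise ValueError("stimulus train shorter than the up-ramp definition")
    return adaptation_index(train, float(stim_times[n_up_stimuli]) - 1e-9)


def instantaneous_frequency(
    train: SpikeTrain,
    peak_time: float | None = None,
    time: np.ndarray | None = None,
    current: np.ndarray | None = None,
    tonic_baseline: float = 0.0,
) -> pd.DataFrame:
    """Per-ISI instantaneous frequency points.

    Returns a DataFrame with one row per ISI: frequency ``f_hz = 1000/ISI``
    placed at the ISI midpoint ``t_mid_ms``; when an injected-current trace
    is supplied, the current at the midpoint (relative to ``tonic_baseline``)
    is added as ``I_nA``; when ``peak_time`` is given each point is labelled
    ``up`` or ``down`` by its midpoint.  Fewer than two spikes give an empty
    frame.
    """
    cols: dict = {"t_mid_ms": [], "f_hz": []}
    if current is not None:
        cols["I_nA"] = []
    if peak_time is not None:
        cols["phase"] = []
    st = train.spike_times
    if st.size >= 2:
        isis = np.diff(st)
        mids = 0.5 * (st[:-1] + st[1:])
        cols["t_mid_ms"] = mids
        cols["f_hz"] = 1000.0 / isis
        if current is not None:
            if time is None:
                raise ValueError("need the time grid to sample the current trace")
            cols["I_nA"] = np.interp(mids, np.asarray(time), np.asarray(current)) - tonic_baseline
        if peak_time is not None:
            cols["phase"] = np.where(mids <= peak_time, "up", "down")
    return pd.DataFrame(cols)


def peak_instantaneous_frequency(train: SpikeTrain) -> float:
    """Largest 1000/ISI over the train, Hz; 0 for fewer than two spikes."""
    if train.n_spikes < 2:
        return 0.0
    return float(1000.0 / np.diff(train.spike_times).min())


def classify_hysteresis(
    current: np.ndarray, freq: np.ndarray, eps_frac: float = 0.02
) -> str:
    """Classify an f/I loop as clockwise, linear, or counterclockwise.

    Points must be in temporal order (up-ramp then down-ramp).  The signed
    shoelace area of the closed polygon is compared against ``eps_frac``
    times the bounding-box area of the loop: negative beyond tolerance is
    clockwise (adaptation), positive is counterclockwise (acceleration),
    within tolerance is linear.  The classification is invariant to uniform
    rescaling of either axis.
    """
    x = np.asarray(current, dtype=float)
    y = np.asarray(freq, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 f/I points spanning up and down ramps")
    area = 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
    extent = (x.max() - x.min()) * (y.max() - y.min())
    eps = eps_frac * extent
    if area < -eps:
        return "clockwise"
    if area > eps:
        return "counterclockwise"
    return "linear"


#: preset -> (max |dI/dt|, (min value, max value)); units uA/cm2 and
#: uA/(ms cm2) for the current traces, occupancy and 1/ms for ``o_state``.
CLEANING_PRESETS: dict[str, tuple[float, tuple[float, float]]] = {
    "net": (0.005, (-0.3, 0.09)),
    "trpm4": (0.15, (-np.inf, 0.0)),
    "nav": (0.2, (-10.0, np.inf)),
    "o_state": (0.00002, (-np.inf, 0.0002)),
}


def clean_interspike_trace(
    time,
    trace,
    preset: str | None = None,
    derivative_threshold: float | None = None,
    value_range: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Remove spike-contaminated samples from a current/occupancy trace.

    A sample is removed when the absolute central-difference temporal
    derivative exceeds the threshold or its value falls outside the allowed
    range.  ``preset`` selects the thresholds used for the model's net,
    TRPM4, and NaV current traces and the NaV open-state occupancy; explicit
    thresholds override.  Returns the retained (time, value) samples.
    """
    time = np.asarray(time, dtype=float)
    trace = np.asarray(trace, dtype=float)
    if preset is not None:
        if preset not in CLEANING_PRESETS:
            raise KeyError(f"unknown cleaning preset {preset!r}")
        dthr, vrange = CLEANING_PRESETS[preset]
    else:
        dthr, vrange = np.inf, (-np.inf, np.inf)
    if derivative_threshold is not None:
        dthr = derivative_threshold
    if value_range is not None:
        vrange = value_range

    keep = np.ones(trace.size, dtype=bool)
    if trace.size >= 3 and np.isfinite(dthr):
        deriv = np.gradient(trace, time)
        keep &= np.abs(deriv) <= dthr
    keep &= (trace >= vrange[0]) & (trace <= vrange[1])
    return time[keep], trace[keep]


@dataclass
class AnalysisSummary:
    """Summary statistics of one ramp response."""

    adaptation_index: float
    peak_instantaneous_frequency: float
    n_spikes: int
    f_points: pd.DataFrame = field(repr=False)
    hysteresis_class: str | None = None

    def to_dict(self) -> dict:
        return {
            "adaptation_index": self.adaptation_index,
            "peak_instantaneous_frequency_hz": self.peak_instantaneous_frequency,
            "n_spikes": self.n_spikes,
            "hysteresis_class": self.hysteresis_class,
        }


def analyze_ramp_response(
    time,
    v,
    peak_time: float,
    current: np.ndarray | None = None,
    threshold: float = -40.0,
    tonic_baseline: float = 0.0,
) -> AnalysisSummary:
    """Full pipeline: detect spikes, adaptation index, f points, hysteresis."""
    train = detect_spikes(time, v, threshold=threshold)
    if train.n_spikes == 0:
        raise ValueError("no spikes detected; analysis summary undefined")
    ai = adaptation_index(train, peak_time)
    pts = instantaneous_frequency(
        train, peak_time=peak_time, time=np.asarray(time), current=current,
        tonic_baseline=tonic_baseline,
    )
    hyst = None
    if current is not None and len(pts) >= 3:
        hyst = classify_hysteresis(pts["I_nA"].to_numpy(), pts["f_hz"].to_numpy())
    return AnalysisSummary(
        adaptation_index=ai,
        peak_instantaneous_frequency=peak_instantaneous_frequency(train),
        n_spikes=train.n_spikes,
        f_points=pts,
        hysteresis_class=hyst,
    )
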