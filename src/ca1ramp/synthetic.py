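"""Stimulus waveforms and surrogate recordings for testing the analysis stage.

Three generators:

* triangular current ramps (the place-field-like depolarizing input: 2-s
  ramps are 1 s up / 1 s down, 10-s ramps 5 s up / 5 s down),
* the ramped synaptic stimulus train (30 pulses whose instantaneous
  frequency rises linearly over stimulus index from 6.7 Hz to 25 Hz at
  mid-train and back, total duration about 2 s),
* surrogate voltage recordings: stylized spike trains with a controllable
  adaptation index, peak firing rate, and Gaussian noise, standing in for
  patch-clamp recordings so the spike-detection/adaptation pipeline can be
  tested against a known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RampSpec",
    "StimTrain",
    "SurrogateRecording",
    "gen_ramp_current",
    "gen_synaptic_stim_times",
    "gen_surrogate_recording",
]


@dataclass(frozen=True)
class RampSpec:
    """Triangular current ramp: rise over ``t_up`` ms, fall over ``t_down``."""

    t_up: float = 1000.0
    t_down: float = 1000.0
    amplitude: float = 1.0      # nA at the peak, above the tonic offset
    tonic_offset: float = 0.0   # nA
    injection_site: str = "soma"

    def __post_init__(self) -> None:
        if self.t_up <= 0 or self.t_down <= 0:
            raise ValueError("ramp durations must be positive")

    @property
    def duration(self) -> float:
        return self.t_up + self.t_down


def gen_ramp_current(
    t_up: float = 1000.0,
    t_down: float = 1000.0,
    amplitude: float = 1.0,
    tonic_offset: float = 0.0,
    dt: float = 0.025,
) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise-linear triangular waveform (time_ms, current_nA).

    Rises from ``tonic_offset`` to ``tonic_offset + amplitude`` at ``t_up``,
    then returns linearly to ``tonic_offset`` at ``t_up + t_down``.
    """
    if t_up <= 0 or t_down <= 0:
        raise ValueError("ramp durations must be positive")
    t = np.arange(0.0, t_up + t_down + dt / 2, dt)
    up = t <= t_up
    i = np.empty_like(t)
    i[up] = amplitude * t[up] / t_up
    i[~up] = amplitude * np.maximum(1.0 - (t[~up] - t_up) / t_down, 0.0)
    return t, i + tonic_offset


@dataclass(frozen=True)
class StimTrain:
    """Synaptic stimulation pulse times with a symmetric frequency ramp."""

    pulse_times: np.ndarray
    f_start: float
    f_peak: float

    @property
    def n_pulses(self) -> int:
        return int(self.pulse_times.size)

    @property
    def isis(self) -> np.ndarray:
        return np.diff(self.pulse_times)


def gen_synaptic_stim_times(
    n: int = 30, f_start: float = 6.7, f_peak: float = 25.0
) -> StimTrain:
    """Pulse times whose instantaneous frequency ramps linearly over index.

    The inter-pulse frequency rises from ``f_start`` for the first interval
    to ``f_peak`` at the middle interval and falls back symmetrically, giving
    a palindromic ISI sequence (first ISI = 1000/f_start, minimum ISI =
    1000/f_peak).
    """
    if n < 3:
        raise ValueError("need at least 3 pulses")
    if not (f_peak > f_start > 0):
        raise ValueError("require f_peak > f_start > 0")
    j = np.arange(n - 1, dtype=float)
    mid = (n - 2) / 2.0
    freq = f_start + (f_peak - f_start) * (1.0 - np.abs(j - mid) / mid)
    isis = 1000.0 / freq
    times = np.concatenate([[0.0], np.cumsum(isis)])
    return StimTrain(pulse_times=times, f_start=f_start, f_peak=f_peak)


@dataclass
class SurrogateRecording:
    """Stylized voltage recording with known spike times and adaptation index."""

    time: np.ndarray            # ms
    trace: np.ndarray           # mV
    true_spike_times: np.ndarray
    target_adaptation_index: float
    achieved_adaptation_index: float
    peak_freq: float
    ramp: RampSpec
    noise_sd: float
    seed: int
    unrealizable: bool = False  # closest achievable index differs from target

    spike_peak_mv: float = field(default=20.0, repr=False)
    baseline_mv: float = field(default=-65.0, repr=False)


def gen_surrogate_recording(
    target_index: float,
    peak_freq: float = 20.0,
    ramp: RampSpec | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    dt: float = 0.1,
) -> SurrogateRecording:
    """Render a surrogate recording realizing ``target_index`` as closely as
    the integer up/down spike counts allow.

    The total spike count is implied by the peak firing rate (mean rate about
    half the peak over the ramp); spikes are placed evenly within each ramp
    limb, rendered as 2-ms triangular spikelets to +20 mV on a -65 mV
    baseline, with additive Gaussian noise (sd in mV).  A spike exactly at
    the ramp peak belongs to the up-ramp.  Deterministic for a given seed.
    """
    if abs(target_index) > 1:
        raise ValueError("|target_index| must be <= 1")
    if not (0 < peak_freq <= 100):
        raise ValueError("peak_freq must lie in (0, 100] Hz")
    ramp = ramp or RampSpec()
    n_tot = max(2, round(peak_freq * ramp.duration / 1000.0 / 2.0))
    n_up = round(n_tot * (1.0 + target_index) / 2.0)
    n_up = min(max(n_up, 0), n_tot)
    n_down = n_tot - n_up
    achieved = (n_up - n_down) / n_tot

    margin = 2.0 * 1000.0 / peak_freq  # keep spikes off the trace edges
    up_times = (
        np.linspace(margin, ramp.t_up, n_up) if n_up else np.empty(0)
    )
    down_times = (
        ramp.t_up + np.linspace(ramp.t_down / (n_down + 1), ramp.t_down - margin, n_down)
        if n_down
        else np.empty(0)
    )
    spikes = np.concatenate([up_times, down_times])
    spikes.sort()

    time = np.arange(0.0, ramp.duration + dt / 2, dt)
    rng = np.random.default_rng(seed)
    baseline, peak = -65.0, 20.0
    trace = np.full(time.size, baseline)
    half = 1.0  # ms half-width of the triangular spikelet
    for ts in spikes:
        w = np.abs(time - ts) <= half
        trace[w] = np.maximum(trace[w], peak - (peak - baseline) * np.abs(time[w] - ts) / half)
    if noise_sd > 0:
        trace = trace + rng.normal(0.0, noise_sd, size=time.size)

    return SurrogateRecording(
        time=time,
        trace=trace,
        true_spike_times=spikes,
        target_adaptation_index=target_index,
        achieved_adaptation_index=achieved,
        peak_freq=peak_freq,
        ramp=ramp,
        noise_sd=noise_sd,
        seed=seed,
        unrealizable=abs(achieved - target_index) > 1e-9,
    )
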