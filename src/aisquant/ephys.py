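"""Current-clamp feature extraction.

Active and passive intrinsic-excitability features from families of square
current-step sweeps recorded in whole-cell current clamp:

* spike detection (local maxima above a voltage floor with a refractory gap);
* action-potential voltage threshold — the membrane voltage at which the
  rising-phase dV/dt first exceeds 10 mV/ms, found by scanning backward from
  the spike peak so that transient noise in the derivative cannot trigger the
  criterion early;
* current threshold (rheobase) — the smallest step amplitude evoking at
  least one spike;
* per-amplitude firing curve, maximum spike count and maximum firing
  frequency (count / step duration);
* input resistance — ordinary-least-squares slope of the steady-state
  voltage-current relationship over subthreshold sweeps of the passive
  protocol (steady state = mean over the last 25% of the step);
* membrane time constant — single-exponential fit to the onset transient of
  the smallest-magnitude hyperpolarizing step; capacitance = tau / Rin;
* spike waveform features — maximum upstroke and minimum downstroke dV/dt
  and latency from step onset to the first spike peak.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

from .errors import EphysError

DEFAULT_PEAK_FLOOR_MV = 0.0
DEFAULT_REFRACTORY_MS = 2.0
DEFAULT_DVDT_CRIT = 10.0          # mV/ms, rising-phase threshold criterion
STEADY_STATE_FRACTION = 0.25      # last fraction of the step used as steady state


@dataclass(frozen=True)
class StepProtocol:
    """Square current-step protocol (amplitudes in pA, times in ms)."""

    step_start_pa: float
    step_increment_pa: float
    step_duration_ms: float
    n_steps: int
    onset_ms: float = 100.0
    tail_ms: float = 100.0

    def amplitudes_pa(self) -> np.ndarray:
        return self.step_start_pa + self.step_increment_pa * np.arange(self.n_steps)


@dataclass(frozen=True)
class CurrentClampSweep:
    """One sweep: voltage trace, uniform sampling, one injected step."""

    time_ms: np.ndarray
    voltage_mv: np.ndarray
    current_amplitude_pa: float
    step_onset_ms: float
    step_offset_ms: float

    def __post_init__(self) -> None:
        t = np.asarray(self.time_ms, dtype=float)
        v = np.asarray(self.voltage_mv, dtype=float)
        object.__setattr__(self, "time_ms", t)
        object.__setattr__(self, "voltage_mv", v)
        if t.size != v.size or t.size < 3:
            raise EphysError("time and voltage must have equal length >= 3")
        dt = np.diff(t)
        if not np.all(dt > 0) or np.ptp(dt) > 1e-9:
            raise EphysError("time must be uniformly increasing")
        if not np.all(np.isfinite(v)):
            raise EphysError("voltage contains non-finite samples")
        if not (t[0] <= self.step_onset_ms < self.step_offset_ms <= t[-1]):
            raise EphysError("step window must lie within the trace")

    @property
    def dt_ms(self) -> float:
        return float(self.time_ms[1] - self.time_ms[0])

    @property
    def step_duration_ms(self) -> float:
        return self.step_offset_ms - self.step_onset_ms


@dataclass
class CellGroundTruth:
    """Generator ground truth carried by synthetic recordings."""

    rin_mohm: float
    tau_ms: float
    rest_mv: float
    spike_threshold_mv: float
    rheobase_pa: Optional[float]
    spike_times_ms: List[np.ndarray]
    upstroke_mv_per_ms: float
    downstroke_mv_per_ms: float


@dataclass
class CurrentClampRecording:
    """Ordered family of sweeps from one cell."""

    cell_id: str
    sweeps: List[CurrentClampSweep]
    protocol: StepProtocol
    ground_truth: Optional[CellGroundTruth] = None

    def __post_init__(self) -> None:
        amps = [s.current_amplitude_pa for s in self.sweeps]
        if any(b <= a for a, b in zip(amps, amps[1:])):
            raise EphysError("sweeps must be ordered by strictly increasing amplitude")
        dts = {round(s.dt_ms, 12) for s in self.sweeps}
        if len(dts) > 1:
            raise EphysError("sweeps must share one sampling interval")


@dataclass
class SpikeFeatures:
    """Active-property summary of one recording (see module docstring)."""

    spike_times_ms: List[np.ndarray]
    spike_counts: Dict[float, int]
    max_spike_count: int
    max_firing_frequency_hz: float
    current_threshold_pa: Optional[float]
    voltage_threshold_mv: Optional[float]
    latency_to_first_peak_ms: Optional[float]
    upstroke_mv_per_ms: Optional[float]
    downstroke_mv_per_ms: Optional[float]


@dataclass
class PassiveProperties:
    """Input resistance (MOhm), membrane time constant (ms), capacitance (pF)."""

    rin_mohm: float
    tau_ms: float
    capacitance_pf: float


def detect_spikes(
    sweep: CurrentClampSweep,
    peak_floor_mv: float = DEFAULT_PEAK_FLOOR_MV,
    refractory_ms: float = DEFAULT_REFRACTORY_MS,
) -> np.ndarray:
    """Spike peak times (ms) within the step window.

    Peaks are local maxima above ``peak_floor_mv`` separated by at least
    ``refractory_ms``. An empty array is a valid result.
    """
    dt = sweep.dt_ms
    distance = max(1, int(round(refractory_ms / dt)))
    idx, _ = find_peaks(sweep.voltage_mv, height=peak_floor_mv, distance=distance)
    times = sweep.time_ms[idx]
    in_step = (times >= sweep.step_onset_ms) & (times <= sweep.step_offset_ms + refractory_ms)
    return times[in_step]


def _dvdt(sweep: CurrentClampSweep) -> np.ndarray:
    return np.gradient(sweep.voltage_mv, sweep.dt_ms)


def voltage_threshold(
    sweep: CurrentClampSweep,
    first_spike_time_ms: float,
    dvdt_crit: float = DEFAULT_DVDT_CRIT,
    search_window_ms: float = 10.0,
) -> float:
    """Voltage at which the rising-phase dV/dt first exceeds ``dvdt_crit``.

    Scans backward from the spike peak to the last sample whose
    central-difference derivative is below the criterion and returns the
    voltage at the next sample (the first sustained crossing). Raises
    :class:`EphysError` when the derivative never drops below the criterion
    inside the search window, or never reaches it at all.
    """
    dvdt = _dvdt(sweep)
    peak_idx = int(np.argmin(np.abs(sweep.time_ms - first_spike_time_ms)))
    lo = max(0, peak_idx - int(round(search_window_ms / sweep.dt_ms)))
    if peak_idx <= lo:
        raise EphysError("spike peak too close to trace start for threshold search")
    if float(np.max(dvdt[lo:peak_idx])) < dvdt_crit:
        raise EphysError(
            f"voltage threshold undefined: dV/dt never exceeds {dvdt_crit} mV/ms before the peak")
    k = peak_idx - 1
    while k >= lo and dvdt[k] >= dvdt_crit:
        k -= 1
    if k < lo:
        raise EphysError("voltage threshold undefined: dV/dt never below criterion in window")
    return float(sweep.voltage_mv[k + 1])


def current_threshold(
    recording: CurrentClampRecording,
    peak_floor_mv: float = DEFAULT_PEAK_FLOOR_MV,
    refractory_ms: float = DEFAULT_REFRACTORY_MS,
) -> float:
    """Rheobase: smallest step amplitude whose sweep has >= 1 detected spike."""
    for sweep in recording.sweeps:
        if detect_spikes(sweep, peak_floor_mv, refractory_ms).size > 0:
            return sweep.current_amplitude_pa
    raise EphysError(f"{recording.cell_id}: no spiking sweep, current threshold undefined")


def firing_curve(
    recording: CurrentClampRecording,
    peak_floor_mv: float = DEFAULT_PEAK_FLOOR_MV,
    refractory_ms: float = DEFAULT_REFRACTORY_MS,
) -> Tuple[Dict[float, int], int, float]:
    """Per-amplitude spike counts, maximum count, maximum frequency (Hz)."""
    counts = {
        s.current_amplitude_pa: int(detect_spikes(s, peak_floor_mv, refractory_ms).size)
        for s in recording.sweeps
    }
    max_count = max(counts.values()) if counts else 0
    duration_s = recording.sweeps[0].step_duration_ms / 1000.0
    return counts, max_count, max_count / duration_s


def firing_frequency_at(
    recording: CurrentClampRecording,
    amplitude_pa: float,
    peak_floor_mv: float = DEFAULT_PEAK_FLOOR_MV,
    refractory_ms: float = DEFAULT_REFRACTORY_MS,
) -> float:
    """Firing frequency (Hz) of the sweep at a queried protocol amplitude."""
    for sweep in recording.sweeps:
        if math.isclose(sweep.current_amplitude_pa, amplitude_pa):
            n = detect_spikes(sweep, peak_floor_mv, refractory_ms).size
            return n / (sweep.step_duration_ms / 1000.0)
    raise EphysError(f"amplitude {amplitude_pa} pA not in protocol")


def _steady_state_mv(sweep: CurrentClampSweep, fraction: float = STEADY_STATE_FRACTION) -> float:
    t = sweep.time_ms
    start = sweep.step_offset_ms - fraction * sweep.step_duration_ms
    window = (t >= start) & (t <= sweep.step_offset_ms)
    return float(sweep.voltage_mv[window].mean())


def input_resistance(
    recording: CurrentClampRecording,
    steady_fraction: float = STEADY_STATE_FRACTION,
) -> float:
    """Input resistance (MOhm) from the steady-state V-I slope.

    Sweeps containing spikes are excluded; the slope of steady-state voltage
    (mV) against injected current (pA) is estimated by ordinary least squares
    and converted mV/pA -> MOhm (x1000). With a finite membrane time constant
    the last-25%-of-step window slightly underestimates Rin (about 3% at
    tau = 50 ms with 200 ms steps).
    """
    usable = [s for s in recording.sweeps if detect_spikes(s).size == 0]
    if len(usable) < 3:
        raise EphysError(f"{recording.cell_id}: need >= 3 spike-free sweeps for the V-I fit")
    currents = np.array([s.current_amplitude_pa for s in usable])
    voltages = np.array([_steady_state_mv(s, steady_fraction) for s in usable])
    slope = np.polyfit(currents, voltages, 1)[0]
    rin = float(slope * 1000.0)
    if rin <= 0:
        raise EphysError(f"{recording.cell_id}: non-physical V-I slope ({rin:.3g} MOhm)")
    return rin


def membrane_tau(recording: CurrentClampRecording) -> float:
    """Membrane time constant (ms) from the onset transient.

    Fits ``V(t) = V0 + dV * (1 - exp(-(t - onset)/tau))`` over the step
    window of the smallest-magnitude hyperpolarizing sweep.
    """
    hyper = [s for s in recording.sweeps if s.current_amplitude_pa < 0]
    if not hyper:
        raise EphysError(f"{recording.cell_id}: no hyperpolarizing sweep for the tau fit")
    sweep = min(hyper, key=lambda s: abs(s.current_amplitude_pa))
    t = sweep.time_ms
    window = (t >= sweep.step_onset_ms) & (t <= sweep.step_offset_ms)
    tw = t[window] - sweep.step_onset_ms
    vw = sweep.voltage_mv[window]

    def model(x, v0, dv, tau):
        return v0 + dv * (1.0 - np.exp(-x / tau))

    try:
        popt, _ = curve_fit(model, tw, vw,
                            p0=[vw[0], vw[-1] - vw[0], sweep.step_duration_ms / 5.0],
                            maxfev=10000)
    except RuntimeError as exc:  # pragma: no cover - pathological traces
        raise EphysError(f"{recording.cell_id}: tau fit failed: {exc}") from exc
    tau = float(popt[2])
    if not tau > 0:
        raise EphysError(f"{recording.cell_id}: non-physical tau {tau:.3g} ms")
    return tau


def passive_properties(recording: CurrentClampRecording) -> PassiveProperties:
    """Rin, tau and the derived capacitance C = 1000 * tau / Rin (pF)."""
    rin = input_resistance(recording)
    tau = membrane_tau(recording)
    return PassiveProperties(rin_mohm=rin, tau_ms=tau,
                             capacitance_pf=1000.0 * tau / rin)


def ap_waveform_features(
    sweep: CurrentClampSweep,
    first_spike_time_ms: float,
    dvdt_crit: float = DEFAULT_DVDT_CRIT,
    ahp_window_ms: float = 5.0,
) -> Tuple[float, float, float]:
    """(upstroke, downstroke, latency) of the first spike of a sweep.

    Upstroke is the maximum central-difference dV/dt between the voltage
    threshold and the peak; downstroke the minimum dV/dt between the peak and
    the after-spike minimum (searched within ``ahp_window_ms``); latency the
    time from step onset to the first spike peak.
    """
    dvdt = _dvdt(sweep)
    dt = sweep.dt_ms
    peak_idx = int(np.argmin(np.abs(sweep.time_ms - first_spike_time_ms)))
    thr_v = voltage_threshold(sweep, first_spike_time_ms, dvdt_crit)
    k = peak_idx
    while k > 0 and sweep.voltage_mv[k - 1] > thr_v:
        k -= 1
    upstroke = float(np.max(dvdt[k:peak_idx + 1]))
    stop = min(sweep.voltage_mv.size, peak_idx + int(round(ahp_window_ms / dt)))
    after = sweep.voltage_mv[peak_idx:stop]
    min_idx = peak_idx + int(np.argmin(after))
    downstroke = float(np.min(dvdt[peak_idx:min_idx + 1])) if min_idx > peak_idx else float("nan")
    latency = float(first_spike_time_ms - sweep.step_onset_ms)
    return upstroke, downstroke, latency


def extract_spike_features(recording: CurrentClampRecording) -> SpikeFeatures:
    """All active-property features of one firing-protocol recording.

    Voltage threshold, waveform velocities and latency are measured on the
    first evoked spike of the rheobase sweep. Cells that never spike return
    None for the spike-dependent fields.
    """
    counts, max_count, max_freq = firing_curve(recording)
    all_times = [detect_spikes(s) for s in recording.sweeps]
    try:
        rheo = current_threshold(recording)
    except EphysError:
        return SpikeFeatures(all_times, counts, max_count, max_freq,
                             None, None, None, None, None)
    sweep = next(s for s in recording.sweeps if s.current_amplitude_pa == rheo)
    first_spike = float(detect_spikes(sweep)[0])
    try:
        vthr = voltage_threshold(sweep, first_spike)
        upstroke, downstroke, latency = ap_waveform_features(sweep, first_spike)
    except EphysError:
        vthr = upstroke = downstroke = None
        latency = first_spike - sweep.step_onset_ms
    return SpikeFeatures(all_times, counts, max_count, max_freq, rheo, vthr,
                         latency, upstroke, downstroke)
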