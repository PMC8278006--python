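"""Synthetic cohorts with known ground truth.

This module generates the two kinds of data the analysis consumes:

* fluorescence line profiles (and optionally small rendered images) of
  AIS-enriched proteins, for two-condition control/treated cohorts in which a
  kinase-inhibitor-like treatment shortens the AIS, rescales the AIS
  intensity and/or rescales the dendritic intensity;
* current-clamp sweep families from square current-step protocols driven by a
  leaky-integrator membrane with a stereotyped pasted spike waveform.

Every record carries its realized ground truth (true AIS extent, compartment
integrated sums, axo:dendritic ratio; input resistance, time constant,
rheobase, spike times), so downstream estimators can be validated by
parameter recovery.

The AIS profile shape is a difference of two logistic sigmoids with a
multiplicative linear taper — a smooth unimodal bump with a dominant proximal
peak and a decaying plateau, qualitatively matching measured AIS profiles.
The continuous 15%-of-peak crossings are snapped to pixel-center boundaries
(half-grid positions) so the realized true length is exactly recoverable by
the boundary detector on noiseless data.

Seeding uses :class:`numpy.random.SeedSequence` with per-record spawn keys,
so changing the cohort size never changes the noise of other records.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.optimize import brentq, minimize_scalar
from scipy.special import expit

from .errors import ProfileError
from .ephys import CellGroundTruth, CurrentClampRecording, CurrentClampSweep, StepProtocol
from .profiles import AIS, DENDRITE, IntensityProfile, NeuronRecord, ProfileGroundTruth, Rect

CONTROL = "control"
TREATED = "treated"

# canonical bump shape parameters (unit length scale between the sigmoids)
_RISE_RATE = 0.05
_FALL_RATE = 0.15
_TAPER_SLOPE = 0.45
_TAPER_FLOOR = 0.05


def _bump(u):
    """Canonical unimodal AIS shape on a unit length scale (peak height != 1)."""
    u = np.asarray(u, dtype=float)
    gate = expit(u / _RISE_RATE) - expit((u - 1.0) / _FALL_RATE)
    taper = np.maximum(1.0 - _TAPER_SLOPE * u, _TAPER_FLOOR)
    return gate * taper


@lru_cache(maxsize=8)
def _bump_geometry(threshold_fraction: float = 0.15) -> Tuple[float, float, float, float]:
    """(u_peak, g_peak, u_left, u_right) of the canonical bump.

    u_left/u_right are the continuous positions where the bump crosses
    ``threshold_fraction * g_peak`` on either side of the peak.
    """
    grid = np.linspace(-1.0, 3.0, 4001)
    vals = _bump(grid)
    i = int(np.argmax(vals))
    res = minimize_scalar(lambda u: -_bump(u), bounds=(grid[i - 1], grid[i + 1]),
                          method="bounded", options={"xatol": 1e-12})
    u_peak = float(res.x)
    g_peak = float(_bump(u_peak))
    thr = threshold_fraction * g_peak
    u_left = brentq(lambda u: _bump(u) - thr, -1.0, u_peak, xtol=1e-12)
    u_right = brentq(lambda u: _bump(u) - thr, u_peak, 3.0, xtol=1e-12)
    return u_peak, g_peak, float(u_left), float(u_right)


@dataclass(frozen=True)
class EffectConfig:
    """Treatment effect applied to the 'treated' condition.

    length_delta_um shifts the true AIS extent (negative = shortening),
    ais_scale multiplies the AIS bump amplitude and dendrite_scale the
    dendritic expression level.
    """

    length_delta_um: float = 0.0
    ais_scale: float = 1.0
    dendrite_scale: float = 1.0

    def __post_init__(self) -> None:
        if not self.ais_scale > 0:
            raise ProfileError(f"ais_scale must be > 0, got {self.ais_scale}")
        if not self.dendrite_scale > 0:
            raise ProfileError(f"dendrite_scale must be > 0, got {self.dendrite_scale}")


#: Calibrated effect triples mirroring the qualitative inhibitor phenotypes:
#: "strong" shortens the AIS and raises both compartments (dendrites more,
#: lowering the axo:dendritic ratio), "medium" raises dendrites with a milder
#: shortening, "weak" only shortens the AIS.
EFFECT_PRESETS: Dict[str, EffectConfig] = {
    "null": EffectConfig(0.0, 1.0, 1.0),
    "weak": EffectConfig(-3.0, 1.0, 1.0),
    "medium": EffectConfig(-4.0, 1.0, 1.3),
    "strong": EffectConfig(-8.0, 1.35, 1.45),
}


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Ground-truth parameters of a two-condition imaging cohort.

    Amplitude units are arbitrary fluorescence units (a.u.); lengths are in
    micrometers. ``amp_cv`` is the coefficient of variation of per-cell
    lognormal factors applied independently to the AIS peak amplitude and the
    dendritic level; ``length_sd_um`` is the per-cell Gaussian spread of the
    true AIS extent. ``noise_sd`` is additive per-pixel Gaussian noise.
    """

    n_per_condition: int = 40
    ais_length_um: float = 30.0
    ais_peak_amp: float = 1000.0
    dendrite_level: float = 150.0
    background_level: float = 100.0
    noise_sd: float = 30.0
    pixel_size_um: float = 0.28
    profile_span_um: float = 40.0
    dendrite_span_um: float = 15.0
    amp_cv: float = 0.2
    length_sd_um: float = 2.5
    ais_start_um: float = 2.0
    effect: EffectConfig = field(default_factory=EffectConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_condition < 2:
            raise ProfileError(f"n_per_condition must be >= 2, got {self.n_per_condition}")
        if not self.pixel_size_um > 0:
            raise ProfileError("pixel_size_um must be > 0")
        if self.noise_sd < 0:
            raise ProfileError("noise_sd must be >= 0")
        if self.profile_span_um < 25:
            raise ProfileError(f"profile_span_um must be >= 25 um, got {self.profile_span_um}")
        if self.profile_span_um < self.ais_length_um:
            raise ProfileError("profile_span_um must cover ais_length_um")
        if self.amp_cv < 0 or self.length_sd_um < 0:
            raise ProfileError("variability parameters must be >= 0")


def _record_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(index,)))


def generate_profile(
    cfg: SyntheticCohortConfig,
    condition: str,
    rng: np.random.Generator,
    neuron_id: str = "cell_000",
) -> NeuronRecord:
    """One synthetic neuron: AIS bump profile plus flat dendrite profile.

    The AIS profile is ``background + A * bump`` sampled on the pixel grid,
    with the bump rescaled so its continuous 15%-crossing extent equals the
    (per-cell jittered, treatment-shifted) target length and its crossings
    sit exactly on pixel-center boundaries. The dendrite is a constant level
    over the traced span. Gaussian noise of sd ``cfg.noise_sd`` is added
    pointwise to both. The realized ground truth is stored on the record.
    """
    if condition not in (CONTROL, TREATED):
        raise ProfileError(f"condition must be '{CONTROL}' or '{TREATED}', got {condition!r}")
    treated = condition == TREATED
    p = cfg.pixel_size_um
    eff = cfg.effect

    amp_factor = float(np.exp(rng.normal(0.0, cfg.amp_cv))) if cfg.amp_cv > 0 else 1.0
    dend_factor = float(np.exp(rng.normal(0.0, cfg.amp_cv))) if cfg.amp_cv > 0 else 1.0
    length_jitter = float(rng.normal(0.0, cfg.length_sd_um)) if cfg.length_sd_um > 0 else 0.0

    target_len = cfg.ais_length_um + (eff.length_delta_um if treated else 0.0) + length_jitter
    target_len = float(np.clip(target_len, 5 * p, cfg.profile_span_um - cfg.ais_start_um - 2 * p))

    n_samples = int(math.floor(cfg.profile_span_um / p)) + 1
    n_cov = max(3, int(round(target_len / p)))       # pixels covered by the true extent
    k0 = max(1, int(round(cfg.ais_start_um / p)))    # first sample inside the AIS
    k1 = min(k0 + n_cov - 1, n_samples - 2)
    n_cov = k1 - k0 + 1
    true_length = n_cov * p
    x_left = (k0 - 0.5) * p                          # continuous 15% crossings at half-grid
    u_peak, g_peak, u_left, u_right = _bump_geometry()
    scale = true_length / (u_right - u_left)

    amp = cfg.ais_peak_amp * (eff.ais_scale if treated else 1.0) * amp_factor
    positions = np.arange(n_samples) * p
    u = u_left + (positions - x_left) / scale
    raw_bump = _bump(u)
    # normalize by the sampled maximum so the noiseless profile peak equals
    # background + amp exactly on the pixel grid
    bump = (amp / raw_bump.max()) * raw_bump
    ais_clean = cfg.background_level + bump

    dend_level = cfg.dendrite_level * (eff.dendrite_scale if treated else 1.0) * dend_factor
    n_dend = int(math.floor(cfg.dendrite_span_um / p)) + 1
    dend_clean = np.full(n_dend, cfg.background_level + dend_level)

    ais_values = ais_clean + (rng.normal(0.0, cfg.noise_sd, n_samples) if cfg.noise_sd > 0 else 0.0)
    dend_values = dend_clean + (rng.normal(0.0, cfg.noise_sd, n_dend) if cfg.noise_sd > 0 else 0.0)

    # ground truth follows the downstream conventions exactly: sums of the
    # noiseless background-free values over the true extent, per micrometer
    ais_int = float(bump[k0:k1 + 1].sum()) / ((k1 - k0) * p)
    dend_int = float(dend_level * n_dend) / ((n_dend - 1) * p)
    truth = ProfileGroundTruth(
        ais_length_um=true_length,
        peak_position_um=x_left + (u_peak - u_left) * scale,
        peak_amplitude=amp,
        ais_integrated_sum=ais_int,
        dendrite_integrated_sum=dend_int,
        adr=ais_int / dend_int,
        background_level=cfg.background_level,
    )
    return NeuronRecord(
        neuron_id=neuron_id,
        treatment=condition,
        analyte="synthetic",
        ais_profile=IntensityProfile.from_intensities(ais_values, p, AIS, "synthetic"),
        dendrite_profile=IntensityProfile.from_intensities(dend_values, p, DENDRITE, "synthetic"),
        ground_truth=truth,
    )


def generate_cohort(cfg: SyntheticCohortConfig) -> List[NeuronRecord]:
    """2 * n_per_condition records, control first, with per-record child seeds."""
    records = []
    n = cfg.n_per_condition
    for i in range(2 * n):
        condition = CONTROL if i < n else TREATED
        short = "ctl" if condition == CONTROL else "trt"
        rec = generate_profile(cfg, condition, _record_rng(cfg.seed, i),
                               neuron_id=f"{short}_{i % n:03d}")
        records.append(rec)
    return records


def render_image(
    record: NeuronRecord,
    width_px: int = 3,
    psf_sd_px: float = 0.0,
    rng: Optional[np.random.Generator] = None,
    noise_sd: float = 0.0,
    image_height: int = 24,
) -> Tuple[np.ndarray, Dict[str, Rect]]:
    """Paint the AIS profile along a straight horizontal neurite.

    Returns the image together with two ROI rectangles: ``"ais"`` covering
    the neurite, and ``"background"`` in a region away from it. The painted
    values are the record's stored profile; optional Gaussian blur
    (``psf_sd_px``) and additive noise are applied on top.
    """
    if width_px < 3:
        raise ProfileError(f"width_px must be >= 3, got {width_px}")
    bg = record.ground_truth.background_level if record.ground_truth else 0.0
    values = record.ais_profile.intensities
    n_cols = values.size
    height = max(image_height, width_px + 10)
    img = np.full((height, n_cols), float(bg))
    r0 = height // 2
    img[r0:r0 + width_px, :] = values[np.newaxis, :]
    if psf_sd_px > 0:
        img = gaussian_filter(img, psf_sd_px)
    if rng is not None and noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, img.shape)
    rois = {
        "ais": Rect(r0, r0 + width_px, 0, n_cols),
        "background": Rect(0, min(4, r0 - 2), 0, n_cols),
    }
    return img, rois


# --------------------------------------------------------------------------
# current-clamp sweep families
# --------------------------------------------------------------------------

FIRING_PROTOCOL = StepProtocol(step_start_pa=10.0, step_increment_pa=10.0,
                               step_duration_ms=500.0, n_steps=10,
                               onset_ms=100.0, tail_ms=100.0)
PASSIVE_PROTOCOL = StepProtocol(step_start_pa=-120.0, step_increment_pa=20.0,
                                step_duration_ms=200.0, n_steps=8,
                                onset_ms=100.0, tail_ms=100.0)


@dataclass(frozen=True)
class SyntheticCellConfig:
    """Leaky-integrator cell plus square-step protocol and spike template.

    The membrane follows ``tau dV/dt = -(V - rest) + I * R`` (pA * MOhm
    scaled to mV). When V reaches ``spike_threshold_mv`` a fixed template
    (half-cosine rise to ``spike_amp_mv`` above threshold over
    ``spike_rise_ms``, half-cosine decay back to rest over ``spike_fall_ms``)
    is pasted and integration resumes from rest. Gaussian measurement noise
    of sd ``noise_sd_mv`` is added after simulation.
    """

    rin_mohm: float = 600.0
    tau_ms: float = 50.0
    rest_mv: float = -60.0
    spike_threshold_mv: float = -40.0
    protocol: StepProtocol = field(default_factory=lambda: FIRING_PROTOCOL)
    sample_interval_ms: float = 0.05
    noise_sd_mv: float = 0.2
    spike_amp_mv: float = 100.0
    spike_rise_ms: float = 1.0
    spike_fall_ms: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("rin_mohm", "tau_ms", "sample_interval_ms",
                     "spike_rise_ms", "spike_fall_ms"):
            if not getattr(self, name) > 0:
                raise ProfileError(f"{name} must be > 0")
        if not self.protocol.step_duration_ms > 0:
            raise ProfileError("step_duration_ms must be > 0")
        if self.noise_sd_mv < 0:
            raise ProfileError("noise_sd_mv must be >= 0")


def _spike_template(cfg: SyntheticCellConfig) -> np.ndarray:
    """Voltage template relative to threshold, from threshold back to rest."""
    dt = cfg.sample_interval_ms
    n_rise = max(2, int(round(cfg.spike_rise_ms / dt)))
    n_fall = max(2, int(round(cfg.spike_fall_ms / dt)))
    amp = cfg.spike_amp_mv
    end = cfg.rest_mv - cfg.spike_threshold_mv
    t_rise = np.arange(0, n_rise + 1) / n_rise     # starts at the threshold voltage
    rise = amp * 0.5 * (1.0 - np.cos(np.pi * t_rise))
    t_fall = np.arange(1, n_fall + 1) / n_fall
    fall = amp + (end - amp) * 0.5 * (1.0 - np.cos(np.pi * t_fall))
    return np.concatenate([rise, fall])


def template_upstroke_mv_per_ms(cfg: SyntheticCellConfig) -> float:
    """Analytic maximum rise slope of the spike template."""
    return cfg.spike_amp_mv * math.pi / (2.0 * cfg.spike_rise_ms)


def template_downstroke_mv_per_ms(cfg: SyntheticCellConfig) -> float:
    """Analytic minimum (most negative) decay slope of the spike template."""
    drop = cfg.spike_amp_mv - (cfg.rest_mv - cfg.spike_threshold_mv)
    return -drop * math.pi / (2.0 * cfg.spike_fall_ms)


def rheobase_closed_form(cfg: SyntheticCellConfig) -> Optional[float]:
    """Smallest protocol amplitude whose step deflection crosses threshold.

    Derived from the integrator solution
    ``V(t) = rest + I R (1 - exp(-t/tau))``: the sweep spikes iff
    ``I R (1 - exp(-T/tau)) >= threshold - rest`` with T the step duration.
    Returns None when no protocol step crosses.
    """
    need = cfg.spike_threshold_mv - cfg.rest_mv
    settle = 1.0 - math.exp(-cfg.protocol.step_duration_ms / cfg.tau_ms)
    for amp in cfg.protocol.amplitudes_pa():
        if amp * cfg.rin_mohm / 1000.0 * settle >= need:
            return amp
    return None


def generate_sweep_family(
    cfg: SyntheticCellConfig,
    cell_id: str = "cell_000",
    protocol: Optional[StepProtocol] = None,
) -> CurrentClampRecording:
    """Simulate one cell's ordered sweep family with stored ground truth."""
    proto = protocol if protocol is not None else cfg.protocol
    dt = cfg.sample_interval_ms
    n_total = int(round((proto.onset_ms + proto.step_duration_ms + proto.tail_ms) / dt)) + 1
    time = np.arange(n_total) * dt
    onset_idx = int(round(proto.onset_ms / dt))
    offset_idx = int(round((proto.onset_ms + proto.step_duration_ms) / dt))
    template = _spike_template(cfg)
    decay = math.exp(-dt / cfg.tau_ms)
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(0,)))

    sweeps = []
    spike_times: List[np.ndarray] = []
    n_rise = max(2, int(round(cfg.spike_rise_ms / dt)))
    for amp_pa in proto.amplitudes_pa():
        v = np.full(n_total, cfg.rest_mv)
        drive_step = cfg.rest_mv + amp_pa * cfg.rin_mohm / 1000.0
        peaks = []
        k = onset_idx
        while k < n_total - 1:
            drive = drive_step if onset_idx <= k < offset_idx else cfg.rest_mv
            v_next = drive + (v[k] - drive) * decay
            if v_next >= cfg.spike_threshold_mv and onset_idx <= k < offset_idx:
                # paste the stereotyped spike starting at the crossing sample
                start = k + 1
                stop = min(start + template.size, n_total)
                v[start:stop] = cfg.spike_threshold_mv + template[:stop - start]
                peaks.append(time[start] + n_rise * dt)
                v[stop - 1] = cfg.rest_mv if stop == start + template.size else v[stop - 1]
                k = stop - 1
                if stop == n_total:
                    break
                continue
            v[k + 1] = v_next
            k += 1
        if cfg.noise_sd_mv > 0:
            v = v + rng.normal(0.0, cfg.noise_sd_mv, n_total)
        sweeps.append(CurrentClampSweep(
            time_ms=time, voltage_mv=v, current_amplitude_pa=float(amp_pa),
            step_onset_ms=proto.onset_ms,
            step_offset_ms=proto.onset_ms + proto.step_duration_ms))
        spike_times.append(np.asarray(peaks))

    spiking = [s.current_amplitude_pa for s, t in zip(sweeps, spike_times) if t.size > 0]
    truth = CellGroundTruth(
        rin_mohm=cfg.rin_mohm,
        tau_ms=cfg.tau_ms,
        rest_mv=cfg.rest_mv,
        spike_threshold_mv=cfg.spike_threshold_mv,
        rheobase_pa=min(spiking) if spiking else None,
        spike_times_ms=spike_times,
        upstroke_mv_per_ms=template_upstroke_mv_per_ms(cfg),
        downstroke_mv_per_ms=template_downstroke_mv_per_ms(cfg),
    )
    return CurrentClampRecording(cell_id=cell_id, sweeps=sweeps, protocol=proto,
                                 ground_truth=truth)
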