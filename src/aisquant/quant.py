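"""AIS fluorescence quantification.

Implements the line-profile pipeline used to quantify axon-initial-segment
(AIS) proteins from confocal images: sum projection of a Z-stack, extraction
of a mean intensity profile from a thin rectangular ROI, subtraction of an
off-neurite background mean, a three-point moving average, detection of the
analyte-specific AIS extent as the region where the smoothed signal stays at
or above 15% of its peak, integrated sums (summed background-subtracted
intensity per unit length), the axo:dendritic ratio, and normalization of a
cohort to its vehicle-control mean.

Conventions
-----------
* The smoothed profile is used only to locate the peak and the 15% boundaries;
  integrated sums are computed on the unsmoothed background-subtracted values.
* Peak ties break to the first (most proximal) index.
* A boundary is the last sample still at/above threshold walking outward from
  the peak; the AIS length is the pixel extent covered by the boundary
  samples, ``(end - start + 1) * pixel_size_um``.
* Negative post-subtraction values are retained in sums.
"""
from __future__ import annotations

import math
import warnings
from typing import Iterable, List, Sequence

import numpy as np

from .errors import NoAISDetectedError, ProfileError
from .profiles import AIS, DENDRITE, AISBoundaries, IntensityProfile, NeuronRecord, QuantResult, Rect

DEFAULT_THRESHOLD_FRACTION = 0.15
DEFAULT_SMOOTH_WINDOW = 3


def sum_project(stack: np.ndarray) -> np.ndarray:
    """Pixelwise sum of a Z-stack (planes, rows, cols) into one 2-D image.

    The dtype is widened to float64 so integer stacks cannot overflow.
    """
    arr = np.asarray(stack)
    if arr.ndim != 3:
        raise ProfileError(f"expected a 3-D stack (planes, rows, cols), got ndim={arr.ndim}")
    if arr.shape[0] < 1:
        raise ProfileError("empty stack")
    return arr.astype(np.float64, copy=False).sum(axis=0)


def extract_profile(
    image: np.ndarray,
    roi: Rect,
    pixel_size_um: float,
    compartment: str = AIS,
    analyte: str = "",
) -> IntensityProfile:
    """Mean-across-width intensity profile from a rectangular ROI.

    The ROI long axis is horizontal (columns); each profile point is the mean
    of the ``roi.height`` pixels in that column. Widths other than the 3 or 4
    pixels used at acquisition are allowed but warned about.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ProfileError(f"expected a 2-D image, got ndim={img.ndim}")
    if roi.height < 1:
        raise ProfileError("ROI width must be >= 1 pixel")
    if (roi.row_start < 0 or roi.col_start < 0
            or roi.row_stop > img.shape[0] or roi.col_stop > img.shape[1]):
        raise ProfileError(f"ROI {roi} outside image of shape {img.shape}")
    if roi.height not in (3, 4):
        warnings.warn(
            f"ROI width {roi.height} px differs from the 3-4 px acquisition convention",
            stacklevel=2)
    block = img[roi.row_start:roi.row_stop, roi.col_start:roi.col_stop]
    values = block.mean(axis=0)
    return IntensityProfile.from_intensities(values, pixel_size_um, compartment, analyte)


def subtract_background(profile: IntensityProfile, background_mean: float) -> IntensityProfile:
    """Remove the mean of an off-neurite background region from every sample.

    Negative results are retained; subtracting twice is rejected.
    """
    if profile.background_subtracted:
        raise ProfileError("profile is already background-subtracted")
    return profile.replace(intensities=profile.intensities - float(background_mean),
                           background_subtracted=True)


def _moving_average(values: np.ndarray, window: int) -> np.ndarray:
    # centered window; at the edges the window shrinks to the available samples
    half = window // 2
    cumsum = np.concatenate(([0.0], np.cumsum(values)))
    n = values.size
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, n)
    return (cumsum[hi] - cumsum[lo]) / (hi - lo)


def smooth_profile(profile: IntensityProfile, window: int = DEFAULT_SMOOTH_WINDOW) -> IntensityProfile:
    """Centered moving average; edge windows shrink, length is preserved."""
    if window < 1 or window % 2 == 0:
        raise ProfileError(f"window must be an odd positive integer, got {window}")
    if window > profile.n:
        raise ProfileError(f"window {window} exceeds profile length {profile.n}")
    if window == 1:
        return profile
    return profile.replace(intensities=_moving_average(profile.intensities, window))


def detect_ais_boundaries(
    profile: IntensityProfile,
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
) -> AISBoundaries:
    """Locate the AIS peak and the 15%-of-peak start/end on a profile.

    The background-subtracted profile is smoothed internally (three-point
    average by default); the peak is the first index attaining the smoothed
    maximum, and each boundary is the last index walking outward whose
    smoothed value is still >= ``threshold_fraction * peak``. When the signal
    never falls below threshold before the ROI edge the boundary is clamped to
    the edge and flagged.
    """
    if not profile.background_subtracted:
        raise ProfileError("boundary detection requires a background-subtracted profile")
    if not 0 < threshold_fraction < 1:
        raise ProfileError(f"threshold_fraction must be in (0, 1), got {threshold_fraction}")
    smoothed = smooth_profile(profile, smooth_window).intensities
    peak_index = int(np.argmax(smoothed))  # argmax returns the first maximum
    peak_value = float(smoothed[peak_index])
    if peak_value <= 0:
        raise NoAISDetectedError("no AIS detected: smoothed profile has no positive peak")
    threshold = threshold_fraction * peak_value
    start = peak_index
    while start - 1 >= 0 and smoothed[start - 1] >= threshold:
        start -= 1
    end = peak_index
    n = smoothed.size
    while end + 1 < n and smoothed[end + 1] >= threshold:
        end += 1
    clamped_start = start == 0
    clamped_end = end == n - 1
    length_um = (end - start + 1) * profile.pixel_size_um
    return AISBoundaries(peak_index, peak_value, start, end, length_um,
                         clamped_start, clamped_end)


def integrated_sum(profile: IntensityProfile, start_index: int, end_index: int) -> float:
    """Summed background-subtracted intensity over a segment per unit length.

    The sum runs over the raw (unsmoothed) values on ``[start, end]``
    inclusive and is divided by the segment length
    ``(end - start) * pixel_size_um`` in micrometers.
    """
    if not profile.background_subtracted:
        raise ProfileError("integrated sum requires a background-subtracted profile")
    if not (0 <= start_index <= end_index < profile.n):
        raise ProfileError(
            f"segment [{start_index}, {end_index}] out of range for length {profile.n}")
    if start_index == end_index:
        raise ProfileError("zero-length segment: integrated sum undefined")
    total = float(profile.intensities[start_index:end_index + 1].sum())
    length_um = (end_index - start_index) * profile.pixel_size_um
    return total / length_um


def quantify_neuron(
    record: NeuronRecord,
    background_mean_ais: float,
    background_mean_dend: float,
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
) -> QuantResult:
    """Full single-neuron quantification.

    Background-subtracts both compartment profiles, detects the AIS extent on
    the axonal profile, computes the AIS integrated sum over the detected
    boundaries and the dendritic integrated sum over the full traced segment
    (no 15% rule for dendrites), and forms the axo:dendritic ratio.
    """
    ais = record.ais_profile
    dend = record.dendrite_profile
    if not ais.background_subtracted:
        ais = subtract_background(ais, background_mean_ais)
    if not dend.background_subtracted:
        dend = subtract_background(dend, background_mean_dend)
    bounds = detect_ais_boundaries(ais, threshold_fraction, smooth_window)
    ais_sum = integrated_sum(ais, bounds.start_index, bounds.end_index)
    dend_sum = integrated_sum(dend, 0, dend.n - 1)
    adr_defined = dend_sum > 0
    adr = ais_sum / dend_sum if adr_defined else math.nan
    return QuantResult(
        neuron_id=record.neuron_id,
        treatment=record.treatment,
        analyte=record.analyte,
        ais_length_um=bounds.length_um,
        ais_integrated_sum=ais_sum,
        dendrite_integrated_sum=dend_sum,
        adr=adr,
        adr_defined=adr_defined,
        clamped_start=bounds.clamped_start,
        clamped_end=bounds.clamped_end,
    )


def normalize_to_control(results: Sequence[QuantResult], control_label: str) -> List[QuantResult]:
    """Divide each value by its analyte's control-group mean.

    After normalization the control group of every analyte averages 1 for each
    of the three quantities (AIS integrated sum, dendritic integrated sum,
    axo:dendritic ratio).
    """
    results = list(results)
    analytes = {r.analyte for r in results}
    means = {}
    for analyte in analytes:
        controls = [r for r in results if r.analyte == analyte and r.treatment == control_label]
        if not controls:
            raise ProfileError(f"no control records labeled {control_label!r} for analyte {analyte!r}")
        mean_ais = float(np.mean([r.ais_integrated_sum for r in controls]))
        mean_dend = float(np.mean([r.dendrite_integrated_sum for r in controls]))
        defined = [r.adr for r in controls if r.adr_defined]
        mean_adr = float(np.mean(defined)) if defined else math.nan
        for name, value in (("AIS", mean_ais), ("dendrite", mean_dend), ("adr", mean_adr)):
            if not value > 0:
                raise ProfileError(
                    f"control mean for {name} of analyte {analyte!r} is not positive ({value})")
        means[analyte] = (mean_ais, mean_dend, mean_adr)
    out = []
    for r in results:
        mean_ais, mean_dend, mean_adr = means[r.analyte]
        out.append(QuantResult(
            **{**r.__dict__,
               "normalized_ais": r.ais_integrated_sum / mean_ais,
               "normalized_dendrite": r.dendrite_integrated_sum / mean_dend,
               "normalized_adr": r.adr / mean_adr if r.adr_defined else None}))
    return out


def log_transform(values: Iterable[float], names: Sequence[str] | None = None) -> np.ndarray:
    """Natural logarithm elementwise; non-positive values raise with the record named."""
    arr = np.asarray(list(values) if not isinstance(values, np.ndarray) else values, dtype=float)
    bad = np.flatnonzero(~(arr > 0))
    if bad.size:
        i = int(bad[0])
        label = names[i] if names is not None else f"index {i}"
        raise ProfileError(f"log transform undefined for non-positive value {arr[i]} ({label})")
    return np.log(arr)
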