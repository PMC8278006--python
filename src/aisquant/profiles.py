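"""Core in-memory containers for fluorescence line-profile analysis.

An :class:`IntensityProfile` is a 1-D fluorescence trace sampled at a uniform
physical pixel spacing along a neurite, tagged with the compartment it was
traced in (axon initial segment or dendrite) and the analyte (protein) it
reports. :class:`AISBoundaries` holds the peak / 15%-of-peak start / end
positions that define the analyte-specific AIS extent, and
:class:`NeuronRecord` bundles the two compartment profiles of one neuron
together with optional simulation ground truth.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import ProfileError

AIS = "ais"
DENDRITE = "dendrite"

_SPACING_TOL = 1e-9


@dataclass(frozen=True)
class IntensityProfile:
    """A 1-D fluorescence trace with uniform physical pixel spacing.

    Parameters
    ----------
    positions_um
        Distance of each sample from the ROI origin, in micrometers.
        Must be uniformly spaced (spacing == ``pixel_size_um``) starting at 0.
    intensities
        Fluorescence values in arbitrary units, same length as positions.
    pixel_size_um
        Physical size of one pixel along the trace, micrometers.
    compartment
        ``"ais"`` or ``"dendrite"``.
    analyte
        Label of the imaged protein (free-form).
    background_subtracted
        Whether the image background mean has already been removed.
    """

    positions_um: np.ndarray
    intensities: np.ndarray
    pixel_size_um: float
    compartment: str = AIS
    analyte: str = ""
    background_subtracted: bool = False

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions_um, dtype=float)
        val = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "positions_um", pos)
        object.__setattr__(self, "intensities", val)
        if pos.ndim != 1 or val.ndim != 1 or pos.size != val.size:
            raise ProfileError("positions and intensities must be 1-D and of equal length")
        if pos.size < 3:
            raise ProfileError(f"profile needs >= 3 samples, got {pos.size}")
        if not self.pixel_size_um > 0:
            raise ProfileError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        spacing = np.diff(pos)
        if np.any(np.abs(spacing - self.pixel_size_um) > _SPACING_TOL):
            raise ProfileError("positions must be uniformly spaced at pixel_size_um")
        if self.compartment not in (AIS, DENDRITE):
            raise ProfileError(f"compartment must be 'ais' or 'dendrite', got {self.compartment!r}")

    @classmethod
    def from_intensities(
        cls,
        intensities,
        pixel_size_um: float,
        compartment: str = AIS,
        analyte: str = "",
        background_subtracted: bool = False,
    ) -> "IntensityProfile":
        """Build a profile with positions ``0, p, 2p, ...`` from raw values."""
        values = np.asarray(intensities, dtype=float)
        positions = np.arange(values.size) * float(pixel_size_um)
        return cls(positions, values, float(pixel_size_um), compartment, analyte,
                   background_subtracted)

    @property
    def n(self) -> int:
        return int(self.intensities.size)

    @property
    def span_um(self) -> float:
        """Distance from the first to the last sample position."""
        return float(self.positions_um[-1] - self.positions_um[0])

    def replace(self, **kwargs) -> "IntensityProfile":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class AISBoundaries:
    """Peak and 15%-of-peak boundaries of an analyte-specific AIS.

    ``start_index``/``end_index`` are the outermost samples whose smoothed,
    background-subtracted value is still at or above the threshold fraction of
    the smoothed peak. ``length_um`` is the pixel extent covered by those
    samples, ``(end - start + 1) * pixel_size_um`` — each boundary sample
    contributes its full pixel, which makes the estimate an unbiased
    discretization of the continuous crossing-to-crossing distance.
    ``clamped_*`` flags mark boundaries that hit the ROI edge before the
    profile ever fell below threshold.
    """

    peak_index: int
    peak_value: float
    start_index: int
    end_index: int
    length_um: float
    clamped_start: bool = False
    clamped_end: bool = False

    def __post_init__(self) -> None:
        if not (self.start_index <= self.peak_index <= self.end_index):
            raise ProfileError("boundary indices must satisfy start <= peak <= end")
        if not self.peak_value > 0:
            raise ProfileError("peak value must be positive")
        if self.length_um < 0:
            raise ProfileError("length must be non-negative")

    @property
    def n_pixels(self) -> int:
        """Number of samples between the boundaries, inclusive."""
        return self.end_index - self.start_index + 1


@dataclass(frozen=True)
class ProfileGroundTruth:
    """Simulation ground truth attached to a synthetic NeuronRecord."""

    ais_length_um: float
    peak_position_um: float
    peak_amplitude: float
    ais_integrated_sum: float
    dendrite_integrated_sum: float
    adr: float
    background_level: float


@dataclass
class NeuronRecord:
    """One neuron's paired AIS and dendrite profiles."""

    neuron_id: str
    treatment: str
    analyte: str
    ais_profile: IntensityProfile
    dendrite_profile: IntensityProfile
    ground_truth: Optional[ProfileGroundTruth] = None

    def __post_init__(self) -> None:
        if self.ais_profile.compartment != AIS:
            raise ProfileError(f"{self.neuron_id}: ais_profile tagged {self.ais_profile.compartment!r}")
        if self.dendrite_profile.compartment != DENDRITE:
            raise ProfileError(
                f"{self.neuron_id}: dendrite_profile tagged {self.dendrite_profile.compartment!r}")


@dataclass
class QuantResult:
    """Per-neuron quantification output.

    ``adr`` (axo:dendritic ratio) is the AIS integrated sum divided by the
    dendritic integrated sum; when the dendritic sum is not positive the ratio
    is undefined and ``adr_defined`` is False (``adr`` holds NaN rather than a
    silent infinity). ``normalized_*`` fields stay None until
    :func:`aisquant.quant.normalize_to_control` fills them.
    """

    neuron_id: str
    treatment: str
    analyte: str
    ais_length_um: float
    ais_integrated_sum: float
    dendrite_integrated_sum: float
    adr: float
    adr_defined: bool
    clamped_start: bool
    clamped_end: bool
    normalized_ais: Optional[float] = None
    normalized_dendrite: Optional[float] = None
    normalized_adr: Optional[float] = None


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle in pixel coordinates, 0-based, half-open."""

    row_start: int
    row_stop: int
    col_start: int
    col_stop: int

    def __post_init__(self) -> None:
        if self.row_stop <= self.row_start or self.col_stop <= self.col_start:
            raise ProfileError(f"degenerate rectangle {self}")

    @property
    def height(self) -> int:
        return self.row_stop - self.row_start

    @property
    def width(self) -> int:
        return self.col_stop - self.col_start

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "Rect":
        return cls(int(d["row_start"]), int(d["row_stop"]),
                   int(d["col_start"]), int(d["col_stop"]))
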