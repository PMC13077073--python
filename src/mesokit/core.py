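"""Shared data containers for mesoscale two-photon analysis.

Axis order is (z, y, x) everywhere; voxel indices are 0-based and physical
positions in micrometres refer to voxel centres.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "VolumeStack",
    "CenterlineSegment",
    "CenterlineGraph",
    "SegmentMetrics",
    "DensityResult",
    "FluorescenceTraces",
    "DffTraces",
    "LocomotionTrace",
    "ZernikeCoefficients",
]


@dataclass
class VolumeStack:
    """A 3D (z, y, x) or 4D (t, y, x) / (t, z, y, x) intensity array with
    physical voxel spacing in micrometres.

    For time series ``data`` is (frames, y, x) and ``spacing_um`` refers to
    the spatial axes of a single frame.
    """

    data: np.ndarray
    spacing_um: tuple[float, ...]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.spacing_um = tuple(float(s) for s in self.spacing_um)
        if any(s <= 0 for s in self.spacing_um):
            raise ValueError(f"voxel spacing must be positive, got {self.spacing_um}")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def voxel_volume_um3(self) -> float:
        """Physical volume of one voxel (requires 3 spacing components)."""
        if len(self.spacing_um) != 3:
            raise ValueError("voxel volume requires 3D spacing")
        return float(np.prod(self.spacing_um))


@dataclass
class CenterlineSegment:
    """One branch of a vessel skeleton: ordered centreline points with radii.

    ``points_um`` is (N, 3) in (z, y, x) micrometres; ``radii_um`` is (N,).
    ``degenerate`` marks single-point segments that carry no length.
    """

    segment_id: int
    points_um: np.ndarray
    radii_um: np.ndarray
    region_label: Optional[str] = None
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.points_um = np.atleast_2d(np.asarray(self.points_um, dtype=float))
        self.radii_um = np.atleast_1d(np.asarray(self.radii_um, dtype=float))

    @property
    def n_points(self) -> int:
        return len(self.points_um)


@dataclass
class CenterlineGraph:
    """Branch-decomposed vessel skeleton."""

    segments: list[CenterlineSegment] = field(default_factory=list)
    branch_points_um: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))
    spacing_um: tuple[float, float, float] = (1.0, 1.0, 1.0)
    warnings: list[str] = field(default_factory=list)

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def segment(self, segment_id: int) -> CenterlineSegment:
        for seg in self.segments:
            if seg.segment_id == segment_id:
                return seg
        raise KeyError(f"no segment with id {segment_id}")


@dataclass
class SegmentMetrics:
    segment_id: int
    diameter_um: float
    length_um: float
    ivd_um: float
    region_label: Optional[str] = None


@dataclass
class DensityResult:
    vessel_volume_um3: float
    roi_volume_um3: float

    @property
    def density(self) -> float:
        return self.vessel_volume_um3 / self.roi_volume_um3


@dataclass
class FluorescenceTraces:
    """Raw ROI fluorescence: neurons x frames, with optional neuropil traces."""

    f: np.ndarray
    frame_rate_hz: float
    f_neuropil: Optional[np.ndarray] = None
    positions_um: Optional[np.ndarray] = None
    region_labels: Optional[Sequence[str]] = None
    neuropil_offset: float = 0.0

    def __post_init__(self) -> None:
        self.f = np.atleast_2d(np.asarray(self.f, dtype=float))
        if self.f_neuropil is not None:
            self.f_neuropil = np.atleast_2d(np.asarray(self.f_neuropil, dtype=float))
            if self.f_neuropil.shape != self.f.shape:
                raise ValueError("neuropil traces must match the shape of f")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")
        if self.positions_um is not None:
            self.positions_um = np.asarray(self.positions_um, dtype=float)
            if not np.all(np.isfinite(self.positions_um)):
                raise ValueError("ROI positions must be finite")

    @property
    def n_neurons(self) -> int:
        return self.f.shape[0]

    @property
    def n_frames(self) -> int:
        return self.f.shape[1]


@dataclass
class DffTraces:
    """Normalised activity dff = (f - f0) / f0 with per-neuron baseline f0."""

    dff: np.ndarray
    f0: np.ndarray
    frame_rate_hz: float
    positions_um: Optional[np.ndarray] = None
    region_labels: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        self.dff = np.atleast_2d(np.asarray(self.dff, dtype=float))
        self.f0 = np.atleast_1d(np.asarray(self.f0, dtype=float))
        if np.any(self.f0 <= 0):
            raise ValueError("every baseline f0 must be positive")
        if not np.all(np.isfinite(self.dff)):
            raise ValueError("dff must be finite")

    @property
    def n_neurons(self) -> int:
        return self.dff.shape[0]

    @property
    def n_frames(self) -> int:
        return self.dff.shape[1]


@dataclass
class LocomotionTrace:
    """Per-frame treadmill/platform speed, aligned to the imaging frames."""

    speed_mm_s: np.ndarray
    frame_rate_hz: float

    def __post_init__(self) -> None:
        self.speed_mm_s = np.asarray(self.speed_mm_s, dtype=float)
        if np.any(self.speed_mm_s < 0):
            raise ValueError("speeds must be non-negative")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")

    @property
    def n_frames(self) -> int:
        return len(self.speed_mm_s)


@dataclass
class ZernikeCoefficients:
    """Modal aberration amplitudes, Noll-indexed from j=2 (piston excluded).

    ``coeffs[k]`` is the amplitude of Noll mode ``k + 2`` in radians RMS of
    pupil phase (unit coefficient -> unit RMS over the pupil).
    """

    coeffs: np.ndarray

    def __post_init__(self) -> None:
        self.coeffs = np.atleast_1d(np.asarray(self.coeffs, dtype=float))
        if not np.all(np.isfinite(self.coeffs)):
            raise ValueError("Zernike coefficients must be finite")

    @property
    def n_modes(self) -> int:
        return len(self.coeffs)

    def rms(self) -> float:
        """Total RMS wavefront error (modes are orthonormal over the pupil)."""
        return float(np.sqrt(np.sum(self.coeffs**2)))
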