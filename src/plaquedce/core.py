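"""Core domain types shared across the simulation and analysis stages.

The acquisition model targets axial multi-slice 2D spoiled gradient recalled
echo (SPGR) dynamic imaging of the carotid bifurcation: 18 time frames 18 s
apart, with a 0.05 mmol/kg gadolinium bolus injected coincident with the
third frame. Two vendor platforms are supported with slightly different
slice prescriptions (GE: 8 x 2 mm slices, TR 117 ms; Philips: 4 x 3 mm
slices, TR 126 ms); in-plane geometry, echo time and flip angle are shared.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "AcquisitionProtocol",
    "AIFCurve",
    "ScanRecord",
    "GE_PROTOCOL",
    "PHILIPS_PROTOCOL",
    "protocol_for_vendor",
]

VENDORS = ("GE", "Philips")


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Acquisition parameters of one dynamic contrast-enhanced carotid scan.

    Attributes
    ----------
    vendor : str
        Scanner platform, ``"GE"`` or ``"Philips"``.
    n_slices : int
        Number of contiguous axial slices centered on the carotid bifurcation.
    slice_thickness : float
        Slice thickness in mm.
    tr, te : float
        Repetition and echo time in ms.
    flip_angle : float
        Excitation flip angle in degrees.
    fov : float
        In-plane field of view in mm (square).
    matrix : int
        Acquisition matrix (square), so pixel_size = fov / matrix.
    n_frames : int
        Number of dynamic frames.
    frame_interval : float
        Time between consecutive frames in seconds.
    injection_frame : int
        1-based index of the frame coincident with contrast injection.
    dose : float
        Contrast dose in mmol/kg.
    injection_rate : float
        Power-injector rate in ml/s.
    """

    vendor: str = "GE"
    n_slices: int = 8
    slice_thickness: float = 2.0
    tr: float = 117.0
    te: float = 5.0
    flip_angle: float = 50.0
    fov: float = 160.0
    matrix: int = 256
    n_frames: int = 18
    frame_interval: float = 18.0
    injection_frame: int = 3
    dose: float = 0.05
    injection_rate: float = 0.7

    def __post_init__(self) -> None:
        if self.vendor not in VENDORS:
            raise ValueError(f"unknown vendor {self.vendor!r}; expected one of {VENDORS}")
        for name in ("n_slices", "slice_thickness", "tr", "te", "flip_angle", "fov",
                     "matrix", "n_frames", "frame_interval", "dose", "injection_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_frames < self.injection_frame + 2:
            raise ValueError("need at least two frames after the injection frame")

    @property
    def pixel_size(self) -> float:
        """In-plane pixel size in mm (fov / matrix)."""
        return self.fov / self.matrix

    @property
    def frame_times(self) -> np.ndarray:
        """Frame acquisition times in seconds, starting at 0."""
        return np.arange(self.n_frames, dtype=float) * self.frame_interval

    @property
    def baseline_frames(self) -> np.ndarray:
        """0-based indices of pre-contrast frames (before the injection frame)."""
        return np.arange(self.injection_frame - 1)

    def with_(self, **kwargs) -> "AcquisitionProtocol":
        return replace(self, **kwargs)


GE_PROTOCOL = AcquisitionProtocol(vendor="GE", n_slices=8, slice_thickness=2.0, tr=117.0)
PHILIPS_PROTOCOL = AcquisitionProtocol(vendor="Philips", n_slices=4, slice_thickness=3.0, tr=126.0)


def protocol_for_vendor(vendor: str) -> AcquisitionProtocol:
    if vendor == "GE":
        return GE_PROTOCOL
    if vendor == "Philips":
        return PHILIPS_PROTOCOL
    raise ValueError(f"unknown vendor {vendor!r}")


@dataclass(frozen=True)
class AIFCurve:
    """Arterial input function: plasma contrast concentration over frame times.

    ``times`` are in seconds, ``cp`` in mmol/L. The curve is zero on all
    pre-injection frames and non-negative everywhere.
    """

    times: np.ndarray
    cp: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "cp", np.asarray(self.cp, dtype=float))
        if self.times.shape != self.cp.shape or self.times.ndim != 1:
            raise ValueError("times and cp must be 1D arrays of equal length")
        if np.any(self.cp < -1e-12):
            raise ValueError("cp must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.times.size

    def integral_minutes(self) -> np.ndarray:
        """Running trapezoidal integral of cp over time expressed in minutes.

        This is the abscissa of the Patlak plot; using minutes keeps the
        transfer constant in its conventional min^-1 units.
        """
        from scipy.integrate import cumulative_trapezoid

        return cumulative_trapezoid(self.cp, self.times / 60.0, initial=0.0)


@dataclass
class ScanRecord:
    """Metadata of one acquired scan, carrying protocol-compliance and quality flags.

    ``quality_score`` is an ordinal 1-4 reading of image quality where 1 means
    uninterpretable (severe motion and/or low SNR).
    """

    subject_id: str
    scan_index: int
    vendor: str
    site_id: str = "site01"
    frame_interval_actual: float = 18.0
    n_frames_actual: int = 18
    contrast_injected: bool = True
    slab_centered_on_bifurcation: bool = True
    quality_score: int = 3

    def __post_init__(self) -> None:
        if self.scan_index not in (1, 2):
            raise ValueError("scan_index must be 1 or 2")
        if self.quality_score not in (1, 2, 3, 4):
            raise ValueError("quality_score must be in {1, 2, 3, 4}")
        if self.vendor not in VENDORS:
            raise ValueError(f"unknown vendor {self.vendor!r}")
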