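"""Shared domain types: acquisition geometry, PRFS physical constants, phase scans.

The proton-resonance-frequency-shift (PRFS) method maps temperature *change*
onto inter-scan phase differences of a gradient-echo acquisition:

    dT(n) = wrap(phi_n - phi_00) / (gamma * alpha * B0 * TE)

where ``gamma`` is the gyromagnetic ratio, ``alpha`` the PRF change
coefficient (ppm per deg C), ``B0`` the static field strength and ``TE`` the
echo time.  Everything downstream of the simulator works in units of deg C
relative to the first baseline scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from pydantic import BaseModel, field_validator, model_validator

#: Intraluminal probe locations benchmarked against MR thermometry.
PROBE_LOCATIONS = ("bladder", "rectum", "vagina")

#: Circular probe-ROI diameter in cm (in-plane area 1.47 cm^2).
ROI_DIAMETER_CM = 1.37

#: Maximum probe mapping length along a catheter, cm.
MAX_PROBE_RANGE_CM = 14.0

#: Duration of one thermometry scan, seconds.
SCAN_DURATION_S = 83.0


class ScanGeometry(BaseModel):
    """Acquisition grid of one thermometry scan series.

    Defaults mirror the clinical protocol (25 axial slices, 256x256
    reconstruction over a 50x50 cm field of view, 1 cm slices); the matrix
    is configurable down to 64 for fast synthetic studies.
    """

    model_config = {"frozen": True}

    n_slices: int = 25
    matrix: int = 256
    fov_cm: float = 50.0
    slice_thickness_cm: float = 1.0

    @field_validator("n_slices", "matrix")
    @classmethod
    def _positive_int(cls, v: int) -> int:
        if v <= 0:
            raise ValueError("grid dimensions must be strictly positive")
        return v

    @field_validator("fov_cm", "slice_thickness_cm")
    @classmethod
    def _positive(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("physical dimensions must be strictly positive")
        return v

    @property
    def voxel_inplane_cm(self) -> float:
        return self.fov_cm / self.matrix

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in mL (cm^3)."""
        return self.voxel_inplane_cm**2 * self.slice_thickness_cm

    @property
    def shape(self) -> tuple[int, int, int]:
        """Volume shape as ``(x, y, slice)``."""
        return (self.matrix, self.matrix, self.n_slices)

    def slice_offset_cm(self, k: int) -> float:
        """Physical offset label of slice ``k`` (slice 0 at -2 cm, descending)."""
        return -(2.0 + k * self.slice_thickness_cm)


class PRFSConstants(BaseModel):
    """Physical constants of the PRFS temperature reconstruction."""

    model_config = {"frozen": True}

    gamma_rad_per_t_s: float = 267.5e6
    alpha_ppm_per_c: float = -0.001
    b0_t: float = 1.5
    te_s: float = 0.0191

    @model_validator(mode="after")
    def _check(self) -> "PRFSConstants":
        if self.gamma_rad_per_t_s <= 0 or self.b0_t <= 0 or self.te_s <= 0:
            raise ValueError("gamma, B0 and TE must be strictly positive")
        if self.alpha_ppm_per_c == 0:
            raise ValueError("alpha must be nonzero")
        return self

    @property
    def phase_rad_per_c(self) -> float:
        """Phase increment per deg C: gamma * alpha * B0 * TE (rad/degC)."""
        return (
            self.gamma_rad_per_t_s * self.alpha_ppm_per_c * 1e-6 * self.b0_t * self.te_s
        )


#: Conventional literature PRF coefficient, selectable instead of the default.
ALPHA_LITERATURE_PPM_PER_C = -0.01


def wrap_phase(phi: np.ndarray) -> np.ndarray:
    """Wrap phase values into (-pi, pi]."""
    return np.pi - np.mod(np.pi - np.asarray(phi), 2.0 * np.pi)


def wrapped_difference(phi: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Wrap-safe phase difference angle(exp(i*(phi - ref)))."""
    return np.angle(np.exp(1j * (np.asarray(phi) - np.asarray(ref))))


@dataclass
class PhaseScan:
    """One gradient-echo acquisition: phase + magnitude volumes with timestamp."""

    phase: np.ndarray  # wrapped to (-pi, pi], shape (x, y, slice)
    magnitude: np.ndarray
    time_s: float
    is_baseline: bool = False

    def __post_init__(self) -> None:
        if self.phase.shape != self.magnitude.shape:
            raise ValueError("phase and magnitude volumes must be congruent")


@dataclass
class ProbeTrace:
    """Intraluminal temperature mapping for one location over a session.

    ``readings`` has shape ``(n_cycles, n_positions)``; positions step 1 cm
    along the catheter (the slice axis), at most 14 positions.
    """

    location: str
    cycle_times_s: np.ndarray
    positions: np.ndarray  # (n_positions, 3) voxel indices along the track
    slice_offsets_cm: np.ndarray
    readings: np.ndarray

    def cycle_mean(self, i: int) -> float:
        return float(np.mean(self.readings[i]))

    def aligned_mean(
        self, scan_time_s: float, scan_duration_s: float = SCAN_DURATION_S,
        max_offset_s: float = 150.0,
    ) -> float | None:
        """Probe-ROI mean aligned with a scan.

        The mapping cycle whose start time is nearest to the scan midpoint is
        used, requiring the offset to be at most ``max_offset_s``; ``None``
        when no cycle qualifies.
        """
        midpoint = scan_time_s + 0.5 * scan_duration_s
        offsets = np.abs(self.cycle_times_s - midpoint)
        i = int(np.argmin(offsets))
        if offsets[i] > max_offset_s:
            return None
        return self.cycle_mean(i)
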