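"""Physics conversions: Bragg spacing and rotational diffusion coefficient.

The ensemble median decay constant Gamma (1/s) converts to a rotational
diffusion coefficient via

    D_R = Gamma * Phi_theta**2 / 4    [pm^2/s],

where Phi_theta (pm) is the rotational displacement: the picometer-scale
arc corresponding to one resolvable angular step of the crystallite.
Phi_theta is a required configuration input — its derivation involves
experiment-specific calibration that cannot be recovered from detector
geometry alone — but a clearly non-normative diagnostic estimate from the
pixel angular subtense is available for sanity logging.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stack_io import DetectorGeometry

__all__ = [
    "DynamicsResult",
    "bragg_d",
    "rotational_displacement",
    "pixel_subtense_estimate",
    "rotational_diffusion_coefficient",
]


@dataclass(frozen=True)
class DynamicsResult:
    """Condition-level physical summary of a DXB analysis."""

    two_theta: float  # degrees
    d_space: float  # Angstrom
    phi_theta: float  # pm
    gamma_summary: float  # median decay constant, 1/s
    d_r: float  # pm^2/s
    motion_class: str = "rotational-diffusion"  # | "d-space-fluctuation" | "both"

    def __post_init__(self) -> None:
        for name in ("two_theta", "d_space", "phi_theta", "gamma_summary", "d_r"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def bragg_d(two_theta: float, wavelength: float) -> float:
    """Lattice spacing d = lambda / (2 sin(theta)) from 2-theta in degrees."""
    if not 0.0 < two_theta < 180.0:
        raise ValueError("two_theta must be in (0, 180) degrees")
    if wavelength <= 0:
        raise ValueError("wavelength must be positive")
    return wavelength / (2.0 * np.sin(np.radians(two_theta) / 2.0))


def rotational_displacement(config: dict) -> float:
    """Return the configured rotational displacement Phi_theta (pm).

    Raises a configuration error naming the missing key when absent.
    """
    if "phi_theta" not in config or config["phi_theta"] is None:
        raise KeyError("configuration missing required key 'phi_theta' (pm)")
    phi = float(config["phi_theta"])
    if phi <= 0:
        raise ValueError("phi_theta must be positive")
    return phi


def pixel_subtense_estimate(
    d_space: float, geometry: DetectorGeometry, bin_size: int = 1
) -> float:
    """Diagnostic (non-normative) displacement scale from the pixel subtense.

    d * (pixel_pitch * bin / distance), converted from Angstrom to pm.  For
    logging/sanity comparison with the configured Phi_theta only; it is not
    the calibrated rotational displacement and is never used in D_R.
    """
    subtense = geometry.pixel_pitch * 1e-3 * bin_size / geometry.distance  # rad
    return d_space * 100.0 * subtense  # Angstrom -> pm


def rotational_diffusion_coefficient(gamma: float, phi_theta: float) -> float:
    """D_R = Gamma * Phi_theta^2 / 4 in pm^2/s (Gamma in 1/s, Phi_theta in pm)."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    if phi_theta <= 0:
        raise ValueError("phi_theta must be positive")
    return gamma * phi_theta**2 / 4.0
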