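"""Contrast transfer function model.

Standard weak-phase-object CTF for a 300 kV microscope:

    CTF(s) = -[ sqrt(1 - A^2) sin(gamma) + A cos(gamma) ],
    gamma(s) = pi * lambda * dz * s^2 - (pi/2) * Cs * lambda^3 * s^4,

with s the spatial frequency in 1/A, dz the defocus (underfocus stored
positive; micrographs quoted as "-0.5 to -3.5 um" map to 0.5-3.5 um
underfocus), Cs the spherical aberration and A the amplitude-contrast
fraction.  lambda is the relativistic electron wavelength.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "AcquisitionParams",
    "CtfParams",
    "electron_wavelength_A",
    "ctf_function",
    "ctf_2d",
    "apply_ctf",
    "ctf_first_zero",
]


@dataclass(frozen=True)
class AcquisitionParams:
    """Microscope/detector settings shared by a dataset."""

    voltage_kV: float = 300.0
    spherical_aberration_mm: float = 2.0
    amplitude_contrast: float = 0.1
    pixel_size_A: float = 1.1
    dose_e_per_A2: float = 20.0

    def __post_init__(self) -> None:
        for name in ("voltage_kV", "spherical_aberration_mm", "pixel_size_A", "dose_e_per_A2"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.amplitude_contrast < 1:
            raise ValueError("amplitude_contrast must be in [0, 1)")


@dataclass(frozen=True)
class CtfParams:
    """Per-image CTF parameters (underfocus positive, in Angstrom)."""

    defocus_A: float

    def __post_init__(self) -> None:
        if self.defocus_A <= 0:
            raise ValueError("defocus_A must be positive (underfocus convention)")


def electron_wavelength_A(voltage_kV: float) -> float:
    """Relativistic electron wavelength; 0.0197 A at 300 kV."""
    V = voltage_kV * 1e3
    return 12.2639 / np.sqrt(V * (1.0 + 0.97845e-6 * V))


def _gamma(s: np.ndarray, defocus_A: float, acq: AcquisitionParams) -> np.ndarray:
    lam = electron_wavelength_A(acq.voltage_kV)
    cs = acq.spherical_aberration_mm * 1e7  # mm -> A
    s2 = np.square(s)
    return np.pi * lam * defocus_A * s2 - 0.5 * np.pi * cs * lam**3 * s2 * s2


def ctf_function(ctf: CtfParams, acq: AcquisitionParams, s) -> np.ndarray:
    """CTF value at spatial frequency ``s`` (1/A); bounded in [-1, 1]."""
    s = np.asarray(s, dtype=float)
    if np.any(s < 0):
        raise ValueError("spatial frequency must be >= 0")
    A = acq.amplitude_contrast
    g = _gamma(s, ctf.defocus_A, acq)
    return -(np.sqrt(1.0 - A * A) * np.sin(g) + A * np.cos(g))


def ctf_2d(ctf: CtfParams, acq: AcquisitionParams, shape: tuple[int, int], pixel_size_A: float) -> np.ndarray:
    """CTF evaluated on the 2D FFT frequency grid of an image."""
    fy = np.fft.fftfreq(shape[0], d=pixel_size_A)
    fx = np.fft.rfftfreq(shape[1], d=pixel_size_A)
    s = np.sqrt(fy[:, None] ** 2 + fx[None, :] ** 2)
    return ctf_function(ctf, acq, s)


def apply_ctf(image: np.ndarray, ctf: CtfParams, acq: AcquisitionParams, pixel_size_A: float) -> np.ndarray:
    """Multiply the image transform by the CTF (convolution by its PSF)."""
    H = ctf_2d(ctf, acq, image.shape, pixel_size_A)
    return np.fft.irfft2(np.fft.rfft2(image) * H, s=image.shape)


def ctf_first_zero(ctf: CtfParams, acq: AcquisitionParams, s_max: float = 1.0) -> float:
    """Frequency (1/A) of the first sign change of the CTF.

    With CTF(s) = -sin(gamma(s) + delta), delta = atan2(A, sqrt(1-A^2)),
    the first zero solves gamma(s) = pi - delta (gamma rises from zero
    under the positive-underfocus convention); bracketing + brentq.
    """
    A = acq.amplitude_contrast
    target = np.pi - np.arctan2(A, np.sqrt(1.0 - A * A))

    def f(s):
        return _gamma(np.asarray(s), ctf.defocus_A, acq) - target

    grid = np.linspace(1e-6, s_max, 4000)
    vals = f(grid)
    sign_change = np.nonzero(np.diff(np.sign(vals)))[0]
    if len(sign_change) == 0:
        raise ValueError("no CTF zero below s_max")
    i = sign_change[0]
    return float(brentq(f, grid[i], grid[i + 1]))
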