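"""Low-level interpolation ops on [z, y, x] volumes.

Linear interpolation throughout (accuracy/speed balance at desk scale;
the splatted Gaussian densities used here are smooth on the voxel grid).
All rotations are right-handed about the named physical axis; volume
centre is at index (N-1)/2 on each axis.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = [
    "rotate_volume_z",
    "rotate_volume_x",
    "screw_transform_volume",
    "shift_image",
    "rotate_image",
    "cylinder_mask",
    "radial_spectrum_3d",
]

_ORDER = 1


def _affine(vol: np.ndarray, M: np.ndarray, offset: np.ndarray, order: int = _ORDER) -> np.ndarray:
    return ndimage.affine_transform(
        vol, M, offset=offset, order=order, mode="constant", cval=0.0, prefilter=order > 1
    )


def _zrot_matrix(angle_deg: float) -> np.ndarray:
    """Index-space (z, y, x) matrix sampling the input at Rz(-angle)."""
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    # physical (x, y) live in index slots 2, 1
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def rotate_volume_z(vol: np.ndarray, angle_deg: float, order: int = _ORDER) -> np.ndarray:
    """Rotate the volume by ``angle_deg`` about the +z (helix) axis."""
    if angle_deg % 360 == 0:
        return vol.copy()
    M = _zrot_matrix(angle_deg)
    c0 = (np.array(vol.shape) - 1) / 2.0
    return _affine(vol, M, c0 - M @ c0, order)


def rotate_volume_x(vol: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotate the volume by ``angle_deg`` about the +x axis (tilts z toward y)."""
    if angle_deg % 360 == 0:
        return vol.copy()
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    # physical (y, z) live in index slots 1, 0
    M = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    c0 = (np.array(vol.shape) - 1) / 2.0
    return _affine(vol, M, c0 - M @ c0)


def screw_transform_volume(vol: np.ndarray, twist_deg: float, rise_px: float, order: int = _ORDER) -> np.ndarray:
    """Apply the screw (rotate ``twist_deg`` about z, translate ``rise_px`` along z).

    The output samples the input at the inverse screw; voxels screwed in
    from outside the box are zero.
    """
    M = _zrot_matrix(twist_deg)
    c0 = (np.array(vol.shape) - 1) / 2.0
    rise_vec = np.array([rise_px, 0.0, 0.0])
    return _affine(vol, M, c0 - M @ c0 - rise_vec, order)


def shift_image(img: np.ndarray, dz_px: float, dx_px: float) -> np.ndarray:
    """Shift an image by (dz, dx) pixels (rows are z)."""
    if dz_px == 0 and dx_px == 0:
        return img.copy()
    return ndimage.shift(img, (dz_px, dx_px), order=_ORDER, mode="constant", cval=0.0, prefilter=False)


def rotate_image(img: np.ndarray, angle_deg: float) -> np.ndarray:
    """In-plane rotation about the image centre."""
    if angle_deg % 360 == 0:
        return img.copy()
    return ndimage.rotate(img, angle_deg, reshape=False, order=_ORDER, mode="constant", cval=0.0, prefilter=False)


def cylinder_mask(
    shape: tuple[int, int, int],
    voxel_size_A: float,
    r_min_A: float = 0.0,
    r_max_A: float = np.inf,
    z_margin_A: float = 0.0,
) -> np.ndarray:
    """Boolean mask of a coaxial cylindrical annulus, optionally z-trimmed."""
    nz, ny, nx = shape
    cz, cy, cx = (nz - 1) / 2.0, (ny - 1) / 2.0, (nx - 1) / 2.0
    z = (np.arange(nz) - cz) * voxel_size_A
    y = (np.arange(ny) - cy) * voxel_size_A
    x = (np.arange(nx) - cx) * voxel_size_A
    r = np.sqrt(y[None, :, None] ** 2 + x[None, None, :] ** 2)
    radial = (r >= r_min_A) & (r <= r_max_A)
    axial = np.abs(z) <= (nz - 1) / 2.0 * voxel_size_A - z_margin_A
    return radial & axial[:, None, None]


def radial_spectrum_3d(vol: np.ndarray, voxel_size_A: float) -> tuple[np.ndarray, np.ndarray]:
    """Rotationally averaged Fourier amplitude vs frequency (1/A)."""
    F = np.fft.fftn(vol)
    n = vol.shape[0]
    f = np.fft.fftfreq(n, d=voxel_size_A)
    s = np.sqrt(
        f[:, None, None] ** 2 + f[None, :, None] ** 2 + f[None, None, :] ** 2
    )
    bins = (s * n * voxel_size_A).astype(int)  # integer voxel shells
    bins = np.minimum(bins, n // 2)
    amps = np.bincount(bins.ravel(), weights=np.abs(F).ravel(), minlength=n // 2 + 1)
    counts = np.bincount(bins.ravel(), minlength=n // 2 + 1)
    freqs = np.arange(n // 2 + 1) / (n * voxel_size_A)
    return freqs, amps / np.maximum(counts, 1)
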