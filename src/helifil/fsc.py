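"""Fourier shell correlation and resolution assessment.

Two conventions are supported as named thresholds: 0.143 for the FSC
between two independent half-maps and 0.4 for the FSC between a map
and a density rendered from the refined atomic model.  Shells are one
Fourier voxel wide by default; no masking or phase-randomization
correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume import DensityVolume

__all__ = [
    "FscCurve",
    "FSC_THRESHOLDS",
    "fsc",
    "smooth_fsc_curve",
    "resolution_at_threshold",
    "model_to_density",
]

FSC_THRESHOLDS = {"half_map": 0.143, "model_map": 0.4}


@dataclass(frozen=True)
class FscCurve:
    """Per-shell correlation: centre frequencies (1/A), FSC, voxel counts."""

    frequencies: np.ndarray
    correlations: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        if np.any(np.abs(self.correlations) > 1.0 + 1e-9):
            raise ValueError("correlations must lie in [-1, 1]")


def fsc(map_a: DensityVolume, map_b: DensityVolume, shell_width_vox: int = 1) -> FscCurve:
    """Fourier shell correlation between two maps on the same grid."""
    if map_a.shape != map_b.shape or not np.isclose(map_a.voxel_size_A, map_b.voxel_size_A):
        raise ValueError("maps must share grid dimensions and voxel size")
    n = map_a.shape[0]
    A = np.fft.fftn(map_a.data)
    B = np.fft.fftn(map_b.data)
    f = np.fft.fftfreq(n)  # cycles per voxel
    s_vox = np.sqrt(
        f[:, None, None] ** 2 + f[None, :, None] ** 2 + f[None, None, :] ** 2
    ) * n
    shells = (s_vox / shell_width_vox).astype(int)
    n_shells = n // 2 // shell_width_vox
    keep = shells < n_shells
    sh = shells[keep]
    cross = np.bincount(sh.ravel(), weights=(A[keep] * np.conj(B[keep])).real.ravel(), minlength=n_shells)
    pa = np.bincount(sh.ravel(), weights=np.abs(A[keep]).ravel() ** 2, minlength=n_shells)
    pb = np.bincount(sh.ravel(), weights=np.abs(B[keep]).ravel() ** 2, minlength=n_shells)
    counts = np.bincount(sh.ravel(), minlength=n_shells)
    denom = np.sqrt(pa * pb)
    corr = np.divide(cross, denom, out=np.zeros_like(cross), where=denom > 0)
    corr = np.clip(corr, -1.0, 1.0)
    freqs = (np.arange(n_shells) + 0.5) * shell_width_vox / (n * map_a.voxel_size_A)
    # drop the DC-containing shell from the curve? keep it; it is informative
    return FscCurve(freqs, corr, counts)


def smooth_fsc_curve(curve: FscCurve, window: int = 3) -> FscCurve:
    """Moving-average smoothing of the per-shell correlations.

    Per-shell FSC values fluctuate by ~1/sqrt(shell voxel count); a
    short moving average stabilizes threshold-crossing detection in the
    noisy tail without shifting the crossing systematically.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    k = np.ones(window) / window
    padded = np.pad(curve.correlations, window // 2, mode="edge")
    sm = np.convolve(padded, k, mode="valid")
    return FscCurve(curve.frequencies, np.clip(sm, -1.0, 1.0), curve.counts)


def resolution_at_threshold(curve: FscCurve, threshold: float | str) -> tuple[float, bool]:
    """Resolution (A) at the first downward crossing of ``threshold``.

    ``threshold`` may be a number in (-1, 1) or one of the presets
    'half_map' (0.143) and 'model_map' (0.4).  Linear interpolation
    between the bracketing shells; if the curve never crosses, the
    Nyquist resolution is returned with ``never_crossed=True``.
    Returns (resolution_A, never_crossed).
    """
    if isinstance(threshold, str):
        threshold = FSC_THRESHOLDS[threshold]
    if not -1.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (-1, 1), got {threshold}")
    if len(curve.frequencies) == 0:
        raise ValueError("empty FSC curve")
    c = curve.correlations
    f = curve.frequencies
    below = np.nonzero((c[1:] < threshold) & (c[:-1] >= threshold))[0]
    if len(below) == 0:
        return float(1.0 / f[-1]), True
    i = below[0]
    # linear interpolation of the crossing frequency
    f_cross = f[i] + (f[i + 1] - f[i]) * (c[i] - threshold) / (c[i] - c[i + 1])
    return float(1.0 / f_cross), False


# Approximate atomic numbers for the elements handled by the renderer.
_ATOMIC_NUMBER = {"H": 1, "C": 6, "N": 7, "O": 8, "P": 15, "S": 16}


def model_to_density(model, voxel_A: float, box_px: int, bfactor_A2: float = 100.0) -> DensityVolume:
    """Render an atomic model as a map for model:map FSC.

    One isotropic Gaussian per atom, amplitude proportional to atomic
    number and variance B/(8 pi^2) (a single-Gaussian stand-in for
    tabulated scattering factors, adequate for FSC consistency at ~4 A
    and coarser).  The model is expected in the map frame (axis on z
    through the box centre); atoms outside the box are an error.
    """
    import gemmi

    data = np.zeros((box_px, box_px, box_px), dtype=np.float32)
    c0 = (box_px - 1) / 2.0
    sigma = np.sqrt(bfactor_A2 / (8.0 * np.pi**2))
    half_A = c0 * voxel_A

    positions, weights = [], []
    if isinstance(model, gemmi.Structure):
        for mdl in model:
            for chain in mdl:
                for res in chain:
                    for atom in res:
                        positions.append([atom.pos.x, atom.pos.y, atom.pos.z])
                        weights.append(_ATOMIC_NUMBER.get(atom.element.name, 6))
    else:  # (n, 3) coordinates, carbon weights
        positions = list(np.asarray(model, dtype=float))
        weights = [6] * len(positions)
    if len(positions) == 0:
        return DensityVolume(data, voxel_A)
    pos = np.asarray(positions, dtype=float)
    if np.any(np.abs(pos) > half_A):
        worst = float(np.max(np.abs(pos)))
        raise ValueError(f"atoms outside box: extent {worst:.1f} A > half-box {half_A:.1f} A")

    from .simulate import _splat

    _splat(data, pos, np.asarray(weights, dtype=float), np.full(len(pos), sigma), voxel_A)
    return DensityVolume(data, voxel_A)
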