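"""Iterative helical real-space reconstruction (IHRSR-style engine).

The cycle alternates projection matching of boxed segments against
references from the current volume, filtered back-projection, a
continuous search for the helical screw parameters that best map the
volume onto itself, and imposition of the found symmetry.  Because the
out-of-plane tilt is fixed near 90 degrees, every z-slice of the volume
is an independent 2D parallel-beam problem, so back-projection uses a
per-slice ramp-filtered scheme; images that were phase-flipped (i.e.
multiplied by their CTF a second time) are amplitude-corrected by
dividing the volume transform by the summed squared CTF plus a Wiener
constant.

Also here: two-class sorting of segment mixtures that differ in axial
rise (the F-pilus case) and transfer of alignment parameters from a
high-dose to a paired low-dose stack.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .ctf import AcquisitionParams, CtfParams, ctf_2d, ctf_function
from .symmetry import HelicalSymmetry
from .volume import META_COLUMNS, DensityVolume, SegmentStack
from .voxel_ops import (
    cylinder_mask,
    rotate_volume_z,
    screw_transform_volume,
    shift_image,
)

__all__ = [
    "BoxingParams",
    "AlignmentParams",
    "ReconstructionState",
    "SymmetrySearchResult",
    "extract_overlapping_boxes",
    "phase_flip",
    "make_references",
    "align_segments",
    "backproject",
    "symmetry_search",
    "cyclic_symmetry_residual",
    "symmetrize",
    "make_cylinder_volume",
    "ihrsr",
    "sort_segments",
    "transfer_alignment",
]


@dataclass(frozen=True)
class BoxingParams:
    """Segment boxing geometry: box edge and inter-box step, in pixels."""

    box_px: int = 384
    step_px: int = 18

    def __post_init__(self) -> None:
        if not 0 < self.step_px <= self.box_px:
            raise ValueError("require 0 < step_px <= box_px")


@dataclass
class AlignmentParams:
    """Per-segment projection-matching result."""

    azimuth_deg: np.ndarray
    inplane_deg: np.ndarray
    shift_x_px: np.ndarray
    shift_z_px: np.ndarray
    score: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.azimuth_deg)
        for name in ("inplane_deg", "shift_x_px", "shift_z_px", "score"):
            if len(getattr(self, name)) != n:
                raise ValueError("alignment fields must have equal length")
        if not np.all(np.isfinite(self.score)):
            raise ValueError("non-finite alignment scores")

    def __len__(self) -> int:
        return len(self.azimuth_deg)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "azimuth_deg": self.azimuth_deg,
                "inplane_deg": self.inplane_deg,
                "shift_x_px": self.shift_x_px,
                "shift_z_px": self.shift_z_px,
                "score": self.score,
            }
        )


@dataclass
class ReconstructionState:
    """Volume + symmetry + per-iteration (twist, rise) history."""

    volume: DensityVolume
    symmetry: HelicalSymmetry
    iteration: int
    history: list[tuple[float, float]] = field(default_factory=list)
    converged: bool = False
    alignment: AlignmentParams | None = None

    def __post_init__(self) -> None:
        if len(self.history) != self.iteration + 1:
            raise ValueError("history length must equal iteration index + 1")


@dataclass(frozen=True)
class SymmetrySearchResult:
    symmetry: HelicalSymmetry
    residual: float
    degenerate: bool = False


def extract_overlapping_boxes(
    long_box_image: np.ndarray,
    params: BoxingParams,
    pixel_size_A: float = 1.1,
    filament_id: int = 0,
) -> SegmentStack:
    """Cut overlapping square boxes from a long filament image.

    The long box is (L, box_px) with the filament axis along rows; boxes
    are stepped ``step_px`` rows apart, yielding
    floor((L - box)/step) + 1 segments ordered along the filament, with
    the originating filament id and row offset recorded.
    """
    L = long_box_image.shape[0]
    b, s = params.box_px, params.step_px
    if L < b:
        raise ValueError(f"long box length {L} < box size {b}")
    if long_box_image.shape[1] != b:
        raise ValueError("long box width must equal box_px")
    n = (L - b) // s + 1
    images = np.stack([long_box_image[i * s : i * s + b] for i in range(n)])
    meta = pd.DataFrame(
        {
            "filament_id": filament_id,
            "azimuth_deg": np.nan,
            "tilt_deg": 90.0,
            "inplane_deg": 0.0,
            "shift_x_px": 0.0,
            "shift_z_px": 0.0,
            "defocus_A": np.nan,
            "class_label": -1,
        },
        columns=META_COLUMNS,
        index=range(n),
    )
    meta["box_offset_px"] = np.arange(n) * s
    return SegmentStack(images, meta, pixel_size_A)


def phase_flip(stack: SegmentStack, acq: AcquisitionParams) -> SegmentStack:
    """Multiply each image's transform by its CTF (phase correction).

    This is the Wiener filter in the very-poor-SNR limit; the returned
    stack is flagged ``ctf_flipped`` so back-projection knows the signal
    now carries a CTF^2 weighting to be divided out.
    """
    if stack.meta["defocus_A"].isna().any():
        raise ValueError("phase_flip requires a defocus for every segment")
    out = np.empty_like(stack.images)
    shape = stack.images.shape[1:]
    for i, img in enumerate(stack.images):
        H = ctf_2d(CtfParams(float(stack.meta["defocus_A"].iloc[i])), acq, shape, stack.pixel_size_A)
        out[i] = np.fft.irfft2(np.fft.rfft2(img) * H, s=shape)
    return SegmentStack(out, stack.meta.copy(), stack.pixel_size_A, ctf_flipped=True)


def make_references(
    volume: DensityVolume,
    sym: HelicalSymmetry,
    angular_step_deg: float = 4.0,
) -> list[tuple[float, np.ndarray]]:
    """Projection references over the symmetry-reduced azimuthal range.

    For a Cn volume only azimuths 0 .. 360/n - step are distinct.
    """
    from .simulate import project_volume

    if angular_step_deg <= 0:
        raise ValueError("angular step must be positive")
    span = 360.0 / sym.cyclic_order
    azimuths = np.arange(0.0, span - 1e-9, angular_step_deg)
    return [(float(a), project_volume(volume, a)) for a in azimuths]


def _standardize(img: np.ndarray) -> np.ndarray:
    v = img - img.mean()
    n = np.linalg.norm(v)
    return v / n if n > 0 else v


def align_segments(
    stack: SegmentStack,
    references: list[tuple[float, np.ndarray]],
    shift_range_px: tuple[float, float] = (4.0, 4.0),
) -> AlignmentParams:
    """Exhaustive projection matching by normalized cross-correlation.

    For each segment, the (reference azimuth, x/z shift) maximising the
    normalized cross-correlation over the shift window is returned
    (axial window should be about one rise).  Correlations are computed
    by FFT over all shifts and masked to the window.
    """
    if len(stack) == 0:
        raise ValueError("empty stack")
    n, H, W = stack.images.shape
    dz_max, dx_max = shift_range_px

    imgs = np.array([_standardize(im) for im in stack.images])
    F_imgs = np.fft.rfft2(imgs)

    zsh = np.fft.fftfreq(H) * H  # signed shift values per FFT index
    xsh = np.fft.fftfreq(W) * W
    window = (np.abs(zsh)[:, None] <= dz_max) & (np.abs(xsh)[None, :] <= dx_max)

    best_score = np.full(n, -np.inf)
    best_az = np.zeros(n)
    best_dz = np.zeros(n)
    best_dx = np.zeros(n)
    for az, ref in references:
        F_ref = np.fft.rfft2(_standardize(ref))
        cc = np.fft.irfft2(F_imgs * F_ref.conj(), s=(H, W))
        cc = np.where(window[None, :, :], cc, -np.inf)
        flat = cc.reshape(n, -1)
        idx = np.argmax(flat, axis=1)
        score = flat[np.arange(n), idx]
        better = score > best_score
        zi, xi = np.unravel_index(idx[better], (H, W))
        best_score[better] = score[better]
        best_az[better] = az
        best_dz[better] = zsh[zi]
        best_dx[better] = xsh[xi]
    return AlignmentParams(
        azimuth_deg=best_az,
        inplane_deg=np.zeros(n),
        shift_x_px=best_dx,
        shift_z_px=best_dz,
        score=best_score,
    )


def _ramp_filter(width: int) -> np.ndarray:
    return np.abs(np.fft.rfftfreq(width) * width) / width  # cycles/px scale


def backproject(
    stack: SegmentStack,
    params: AlignmentParams,
    acq: AcquisitionParams | None = None,
    wiener_fraction: float = 0.1,
) -> DensityVolume:
    """Slice-wise filtered back-projection of aligned segments.

    Segments are un-shifted, averaged per matched azimuth, ramp-filtered
    along the in-plane axis and smeared back along their view
    directions.  If the stack was phase-flipped, the volume transform is
    divided per frequency shell by (sum of squared CTFs + Wiener
    constant), the amplitude correction for images that have been
    multiplied by the CTF twice (microscope + phase flip).  The Wiener
    constant defaults to ``wiener_fraction`` x mean of the summed CTF^2.
    """
    if len(stack) == 0:
        raise ValueError("empty stack")
    if len(params) != len(stack):
        raise ValueError("alignment/stack length mismatch")
    n, H, W = stack.images.shape

    sums: dict[float, np.ndarray] = {}
    counts: dict[float, int] = {}
    for i in range(n):
        img = shift_image(stack.images[i], -params.shift_z_px[i], -params.shift_x_px[i])
        az = float(params.azimuth_deg[i])
        if az in sums:
            sums[az] += img
            counts[az] += 1
        else:
            sums[az] = img.astype(np.float64)
            counts[az] = 1

    azimuths = sorted(sums)
    if len(azimuths) > 1:
        step = np.median(np.diff(azimuths))
    else:
        step = 4.0
    ramp = _ramp_filter(W)
    vol = np.zeros((H, H, W), dtype=np.float64)
    for az in azimuths:
        mean_img = sums[az] / counts[az]
        filt = np.fft.irfft2(np.fft.rfft2(mean_img) * ramp[None, :], s=(H, W))
        smear = np.broadcast_to(filt[:, None, :], (H, H, W)).astype(np.float32)
        vol += rotate_volume_z(np.ascontiguousarray(smear), -az)
    vol *= np.deg2rad(step) / 2.0

    if stack.ctf_flipped:
        if acq is None:
            raise ValueError("acq required to amplitude-correct a phase-flipped stack")
        freqs = np.fft.fftfreq(H, d=stack.pixel_size_A)
        s_bins = np.arange(H // 2 + 1) / (H * stack.pixel_size_A)
        sum_ctf2 = np.zeros_like(s_bins)
        for d in stack.meta["defocus_A"]:
            sum_ctf2 += ctf_function(CtfParams(float(d)), acq, s_bins) ** 2
        sum_ctf2 /= n
        wiener = wiener_fraction * float(sum_ctf2.mean())
        F = np.fft.fftn(vol)
        s3 = np.sqrt(
            freqs[:, None, None] ** 2 + freqs[None, :, None] ** 2 + freqs[None, None, :] ** 2
        )
        denom = np.interp(s3, s_bins, sum_ctf2) + wiener
        vol = np.fft.ifftn(F / denom).real

    return DensityVolume(vol.astype(np.float32), stack.pixel_size_A)


def cyclic_symmetry_residual(volume: DensityVolume, n: int, r_mask_A=(5.0, 45.0)) -> float:
    """Normalized MSE between the volume and its 360/n rotation (Cn check)."""
    mask = cylinder_mask(volume.data.shape, volume.voxel_size_A, *r_mask_A)
    rot = rotate_volume_z(volume.data, 360.0 / n)
    var = volume.data[mask].var()
    if var <= 0:
        return np.inf
    return float(((volume.data - rot) ** 2)[mask].mean() / var)


def symmetry_search(
    volume: DensityVolume,
    init_sym: HelicalSymmetry,
    twist_range_deg: float = 2.0,
    rise_range_A: float = 1.0,
    grid: tuple[int, int] = (7, 7),
    r_mask_A: tuple[float, float] = (5.0, 45.0),
) -> SymmetrySearchResult:
    """Find the (twist, rise) that best maps the volume onto itself.

    Minimizes the variance-normalized mean-squared difference between
    the volume screwed forward by half the candidate operation and
    screwed backward by the other half, inside an interior cylindrical
    mask (radii ``r_mask_A``, trimmed axially by one rise).  Comparing
    two equally-interpolated copies cancels the sub-voxel bias a
    one-sided comparison would have.  Coarse grid bracketing
    ``init_sym`` followed by Nelder-Mead refinement.  A featureless
    volume returns the input symmetry with a degeneracy flag.
    """
    vox = volume.voxel_size_A
    data = volume.data
    z_margin = abs(init_sym.rise_A) + rise_range_A + vox
    mask = cylinder_mask(data.shape, vox, *r_mask_A, z_margin_A=z_margin)
    var = float(data[mask].var())
    if var < 1e-12 * max(1.0, float(np.abs(data).max()) ** 2) or var == 0.0:
        return SymmetrySearchResult(init_sym, np.inf, degenerate=True)

    def residual(p) -> float:
        twist, rise = p
        a = screw_transform_volume(data, twist / 2.0, rise / 2.0 / vox)
        b = screw_transform_volume(data, -twist / 2.0, -rise / 2.0 / vox)
        return float(((a - b) ** 2)[mask].mean() / var)

    twists = init_sym.twist_deg + np.linspace(-twist_range_deg, twist_range_deg, grid[0])
    rises = init_sym.rise_A + np.linspace(-rise_range_A, rise_range_A, grid[1])
    best, best_r = None, np.inf
    for tw in twists:
        for ri in rises:
            if ri <= 0:
                continue
            r = residual((tw, ri))
            if r < best_r:
                best, best_r = (tw, ri), r
    # local refinement stays inside the bracketing window: the residual of
    # a noisy volume is trivially zero at the null screw, so the search
    # must not be allowed to drift there
    bounds = [
        (init_sym.twist_deg - twist_range_deg, init_sym.twist_deg + twist_range_deg),
        (max(init_sym.rise_A - rise_range_A, 0.1), init_sym.rise_A + rise_range_A),
    ]
    res = minimize(
        residual,
        np.array(best),
        method="Nelder-Mead",
        bounds=bounds,
        options={"xatol": 1e-3, "fatol": 1e-8, "maxiter": 200},
    )
    twist, rise = res.x
    return SymmetrySearchResult(
        HelicalSymmetry(float(twist), float(rise), init_sym.cyclic_order), float(res.fun)
    )


def _cn_average(data: np.ndarray, n: int) -> np.ndarray:
    acc = data.astype(np.float64).copy()
    for k in range(1, n):
        acc += rotate_volume_z(data, k * 360.0 / n)
    return (acc / n).astype(np.float32)


def symmetry_search_split(
    vol_a: DensityVolume,
    vol_b: DensityVolume,
    init_sym: HelicalSymmetry,
    twist_range_deg: float = 2.0,
    rise_range_A: float = 1.0,
    grid: tuple[int, int] = (7, 7),
    n_lags: int = 4,
    r_mask_A: tuple[float, float] = (5.0, 45.0),
    lowpass_px: float = 1.0,
) -> SymmetrySearchResult:
    """Noise-robust screw search from two independent half-reconstructions.

    A candidate (twist, rise) is scored by the covariance, inside a
    cylindrical mask, between the two half-maps after each has been
    averaged over screw powers -n_lags..+n_lags of the candidate.  At
    the true parameters the signal averages coherently in both halves
    and the cross term is maximal; at wrong parameters the incoherent
    averaging destroys it.  Because the noise of the two halves is
    independent it cancels from the covariance, which makes the score
    usable on reconstructions far too noisy for a self-consistency
    residual.  z-shifts are applied exactly in Fourier space (linear
    interpolation of sub-voxel shifts would attenuate fractional-voxel
    rises and bias the estimate toward integer-pixel values); rotations
    (rise-independent) use linear interpolation.

    Scoring is restricted to the radial window ``r_mask_A``; since
    z-rotation preserves radius the volumes are cropped laterally to
    that window first, which makes each evaluation cheap.
    """
    if vol_a.shape != vol_b.shape:
        raise ValueError("half-maps must share a grid")
    vox = vol_a.voxel_size_A
    N = vol_a.shape[0]
    n = init_sym.cyclic_order

    from scipy.ndimage import gaussian_filter

    def prep(v: DensityVolume) -> np.ndarray:
        d = _cn_average(v.data, n)
        if lowpass_px:
            d = gaussian_filter(d, lowpass_px)
        return d

    A, B = prep(vol_a), prep(vol_b)
    if A.std() == 0 or B.std() == 0:
        return SymmetrySearchResult(init_sym, np.inf, degenerate=True)

    # lateral crop to the scoring annulus (z-rotation preserves radius)
    r_hi_px = int(np.ceil(r_mask_A[1] / vox)) + 2
    c = (N - 1) / 2.0
    lo = max(0, int(np.floor(c - r_hi_px)))
    hi = min(N, int(np.ceil(c + r_hi_px)) + 1)
    A = np.ascontiguousarray(A[:, lo:hi, lo:hi])
    B = np.ascontiguousarray(B[:, lo:hi, lo:hi])
    w = hi - lo
    cw = (w - 1) / 2.0
    yy = (np.arange(w) - cw) * vox
    rr = np.sqrt(yy[:, None] ** 2 + yy[None, :] ** 2)
    mask2 = (rr >= r_mask_A[0]) & (rr <= r_mask_A[1])

    n_pad = int(2 ** np.ceil(np.log2(N + n_lags * (init_sym.rise_A + rise_range_A) / vox + 2)))
    kz = np.fft.rfftfreq(n_pad)
    lags = [i for i in range(-n_lags, n_lags + 1)]
    z_idx = np.arange(N)

    def rot_ffts(data: np.ndarray, twist: float) -> list[np.ndarray]:
        out = []
        for i in lags:
            R = data if i == 0 else rotate_volume_z(data, i * twist)
            P = np.zeros((n_pad, w, w), np.float32)
            P[:N] = R
            out.append(np.fft.rfft(P, axis=0))
        return out

    cache: dict[float, tuple[list[np.ndarray], list[np.ndarray]]] = {}

    def get(twist: float):
        key = round(twist, 4)
        if key not in cache:
            if len(cache) > 30:
                cache.pop(next(iter(cache)))
            cache[key] = (rot_ffts(A, twist), rot_ffts(B, twist))
        return cache[key]

    def score(twist: float, rise: float) -> float:
        fa, fb = get(twist)
        rise_px = rise / vox
        phases = [np.exp(-2j * np.pi * kz * (i * rise_px))[:, None, None] for i in lags]
        wt = np.zeros(N)
        for i in lags:
            src = z_idx - i * rise_px
            wt += (src >= 0) & (src <= N - 1)
        accs = []
        for fs in (fa, fb):
            acc = np.zeros_like(fa[0])
            for F, ph in zip(fs, phases):
                acc += F * ph
            accs.append(np.fft.irfft(acc, n=n_pad, axis=0)[:N] / np.maximum(wt, 1)[:, None, None])
        sel = mask2[None, :, :] & (wt >= 0.7 * len(lags))[:, None, None]
        a = accs[0][sel]
        b = accs[1][sel]
        return float(((a - a.mean()) * (b - b.mean())).mean())

    t_lo = init_sym.twist_deg - twist_range_deg
    t_hi = init_sym.twist_deg + twist_range_deg
    r_lo = max(init_sym.rise_A - rise_range_A, 0.1)
    r_hi = init_sym.rise_A + rise_range_A
    best, best_s = (init_sym.twist_deg, init_sym.rise_A), -np.inf
    for tw in np.linspace(t_lo, t_hi, grid[0]):
        for ri in np.linspace(r_lo, r_hi, grid[1]):
            s = score(tw, ri)
            if s > best_s:
                best, best_s = (tw, ri), s

    from scipy.optimize import minimize_scalar

    tw, ri = best
    for _ in range(3):
        res = minimize_scalar(
            lambda x: -score(tw, x), bounds=(r_lo, r_hi), method="bounded",
            options={"xatol": 5e-4},
        )
        ri = float(res.x)
        res = minimize_scalar(
            lambda x: -score(x, ri), bounds=(t_lo, t_hi), method="bounded",
            options={"xatol": 2e-3},
        )
        tw = float(res.x)
    return SymmetrySearchResult(
        HelicalSymmetry(tw, ri, n), -score(tw, ri)
    )


def symmetrize(volume: DensityVolume, sym: HelicalSymmetry) -> DensityVolume:
    """Average the volume over its helical lattice operations.

    First averages over the Cn rotations, then over all integer screw
    powers whose z-shift keeps part of the box in view, weighting each
    z-plane by how many screw copies actually cover it.  The output is
    invariant under the imposed operations (up to interpolation).
    """
    vox = volume.voxel_size_A
    data = volume.data.astype(np.float64)
    n = sym.cyclic_order

    # cubic interpolation here: the symmetrized map is the final product
    # and its invariance under the imposed operations is part of the
    # contract; linear interpolation would smooth a little on every pass
    csum = data.copy()
    for k in range(1, n):
        csum += rotate_volume_z(volume.data, k * 360.0 / n, order=3)
    cavg = (csum / n).astype(np.float32)

    N = data.shape[0]
    rise_px = sym.rise_A / vox
    i_max = int(np.floor((N - 1) / rise_px))
    acc = cavg.astype(np.float64)
    wt = np.ones(N)
    z_idx = np.arange(N)
    for i in range(-i_max, i_max + 1):
        if i == 0:
            continue
        shifted = screw_transform_volume(cavg, i * sym.twist_deg, i * rise_px, order=3)
        src_z = z_idx - i * rise_px
        valid = (src_z >= 0) & (src_z <= N - 1)
        acc += shifted
        wt += valid
    out = acc / wt[:, None, None]
    return DensityVolume(out.astype(np.float32), vox)


def make_cylinder_volume(
    box_px: int,
    voxel_A: float,
    radius_A: float = 40.0,
    soft_A: float = 6.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> DensityVolume:
    """Soft-edged cylinder, the standard IHRSR starting volume.

    ``noise_sd`` adds seeded white noise inside the cylinder; a small
    random texture breaks the azimuthal degeneracy of the start and
    speeds up the spontaneous symmetry breaking of the refinement.
    """
    c0 = (box_px - 1) / 2.0
    y = (np.arange(box_px) - c0) * voxel_A
    r = np.sqrt(y[:, None] ** 2 + y[None, :] ** 2)
    profile = 0.5 * (1.0 - np.tanh((r - radius_A) / max(soft_A, 1e-6)))
    data = np.ascontiguousarray(
        np.broadcast_to(profile[None, :, :], (box_px, box_px, box_px))
    ).astype(np.float32)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        data = data * (1.0 + noise_sd * rng.standard_normal(data.shape).astype(np.float32))
    return DensityVolume(data, voxel_A)


def ihrsr(
    stack: SegmentStack,
    init_volume: DensityVolume,
    init_sym: HelicalSymmetry,
    max_iter: int = 10,
    tol_twist_deg: float = 0.05,
    tol_rise_A: float = 0.02,
    angular_step_deg: float = 4.0,
    acq: AcquisitionParams | None = None,
    twist_search_deg: float = 2.0,
    rise_search_A: float = 1.0,
    search_symmetry: bool = True,
    verbose: bool = False,
) -> ReconstructionState:
    """Run the IHRSR cycle until the symmetry parameters stop moving.

    Each iteration: make references -> align segments -> back-project ->
    search helical symmetry -> impose it.  The symmetry search scores
    candidate screws by the covariance between even- and odd-segment
    half-reconstructions (see :func:`symmetry_search_split`), which
    stays well-behaved at the low per-segment SNR where a
    self-consistency residual on the full reconstruction is swamped by
    noise.  Convergence is declared when both |d twist| <
    ``tol_twist_deg`` and |d rise| < ``tol_rise_A`` between consecutive
    iterations; otherwise the state is returned with
    ``converged=False`` after ``max_iter`` iterations.  The axial shift
    search is bounded by one rise.  ``search_symmetry=False`` holds
    ``init_sym`` fixed (used e.g. to build an unsorted reference
    reconstruction for two-class sorting).
    """
    sym = init_sym
    volume = init_volume
    history = [(sym.twist_deg, sym.rise_A)]
    alignment = None
    converged = False
    n_seg = len(stack)
    even = np.arange(0, n_seg, 2)
    odd = np.arange(1, n_seg, 2)
    it = 0
    for it in range(1, max_iter + 1):
        refs = make_references(volume, sym, angular_step_deg)
        rise_px = sym.rise_A / stack.pixel_size_A
        # No axial search on the first pass: against a (near-)featureless
        # start the z-shift is unconstrained, and random axial shifts
        # would wash out the layer periodicity the symmetry search needs.
        # Afterwards +/- rise/2 suffices (larger offsets are equivalent to
        # an azimuth change by the helical degeneracy).
        dz = 0.0 if it == 1 else np.ceil(rise_px / 2.0)
        alignment = align_segments(stack, refs, (dz, 4.0))
        volume = backproject(stack, alignment, acq=acq)
        if search_symmetry:
            half_a = backproject(stack.subset(even), _subset_params(alignment, even), acq=acq)
            half_b = backproject(stack.subset(odd), _subset_params(alignment, odd), acq=acq)
            # the search window stays anchored at init_sym: a walking
            # window can drift to a self-consistent wrong symmetry before
            # azimuthal lock-in.  On the first pass the azimuths are still
            # essentially random, so only the rise (the layer periodicity,
            # which survives azimuthal averaging) is identifiable: hold the
            # twist and search the rise alone.
            if it == 1:
                result = symmetry_search_split(
                    half_a, half_b, init_sym, 1e-6, rise_search_A, grid=(1, 9)
                )
                result = SymmetrySearchResult(
                    HelicalSymmetry(
                        init_sym.twist_deg, result.symmetry.rise_A, init_sym.cyclic_order
                    ),
                    result.residual,
                    result.degenerate,
                )
            else:
                result = symmetry_search_split(
                    half_a, half_b, init_sym, twist_search_deg, rise_search_A
                )
            new_sym = result.symmetry if not result.degenerate else sym
        else:
            new_sym = sym
        volume = symmetrize(volume, new_sym)
        d_twist = abs(new_sym.twist_deg - sym.twist_deg)
        d_rise = abs(new_sym.rise_A - sym.rise_A)
        at_boundary = (
            abs(new_sym.twist_deg - init_sym.twist_deg) > 0.95 * twist_search_deg
            or abs(new_sym.rise_A - init_sym.rise_A) > 0.95 * rise_search_A
        )
        sym = new_sym
        history.append((sym.twist_deg, sym.rise_A))
        if verbose:
            print(f"  iter {it}: twist {sym.twist_deg:.3f} rise {sym.rise_A:.3f}")
        # an estimate pinned to the search-window edge is a stall, not a
        # converged solution
        if (
            search_symmetry
            and it > 1
            and d_twist < tol_twist_deg
            and d_rise < tol_rise_A
            and not at_boundary
        ):
            converged = True
            break
    return ReconstructionState(volume, sym, it if max_iter > 0 else 0, history, converged, alignment)


def sort_segments(
    stack: SegmentStack,
    sym_a: HelicalSymmetry,
    sym_b: HelicalSymmetry,
    n_cycles: int = 5,
    seed: int = 0,
    angular_step_deg: float = 4.0,
    acq: AcquisitionParams | None = None,
    init_iters: int = 2,
) -> tuple[np.ndarray, DensityVolume, DensityVolume]:
    """Competitive two-class sorting of a segment mixture.

    An unsorted reconstruction (a short fixed-symmetry refinement at the
    mean parameters) is symmetrized once with each candidate symmetry to
    create two references; every cycle then assigns each segment to the
    reference volume giving the higher best correlation (ties go to
    class a) and rebuilds both class reconstructions.  Returns (labels,
    volume_a, volume_b) with labels 0 = a, 1 = b.
    """
    if sym_a.cyclic_order != sym_b.cyclic_order:
        raise ValueError("candidate symmetries must share the cyclic order")
    mean_sym = HelicalSymmetry(
        (sym_a.twist_deg + sym_b.twist_deg) / 2.0,
        (sym_a.rise_A + sym_b.rise_A) / 2.0,
        sym_a.cyclic_order,
    )
    init = make_cylinder_volume(stack.box_px, stack.pixel_size_A)
    state = ihrsr(
        stack, init, mean_sym, max_iter=init_iters,
        angular_step_deg=angular_step_deg, acq=acq, search_symmetry=False,
    )
    unsorted = state.volume
    vol_a = symmetrize(unsorted, sym_a)
    vol_b = symmetrize(unsorted, sym_b)

    labels = np.zeros(len(stack), dtype=int)
    for cycle in range(n_cycles):
        scores = []
        aligns = []
        for sym, vol in ((sym_a, vol_a), (sym_b, vol_b)):
            refs = make_references(vol, sym, angular_step_deg)
            rise_px = sym.rise_A / stack.pixel_size_A
            al = align_segments(stack, refs, (np.ceil(rise_px), 4.0))
            aligns.append(al)
            scores.append(al.score)
        labels = np.where(scores[1] > scores[0], 1, 0)  # ties -> class a
        if labels.min() == labels.max():
            raise RuntimeError(f"sorting emptied one class at cycle {cycle}")
        idx_a = np.nonzero(labels == 0)[0]
        idx_b = np.nonzero(labels == 1)[0]
        vol_a = symmetrize(
            backproject(stack.subset(idx_a), _subset_params(aligns[0], idx_a), acq=acq), sym_a
        )
        vol_b = symmetrize(
            backproject(stack.subset(idx_b), _subset_params(aligns[1], idx_b), acq=acq), sym_b
        )
    return labels, vol_a, vol_b


def _subset_params(params: AlignmentParams, idx: np.ndarray) -> AlignmentParams:
    return AlignmentParams(
        params.azimuth_deg[idx],
        params.inplane_deg[idx],
        params.shift_x_px[idx],
        params.shift_z_px[idx],
        params.score[idx],
    )


def transfer_alignment(
    params: AlignmentParams,
    other_stack: SegmentStack,
    acq: AcquisitionParams | None = None,
) -> DensityVolume:
    """Back-project a paired stack using alignments found on another.

    Emulates applying the Euler angles and shifts determined on
    high-dose segments to the paired low-dose segments, so the final
    reconstruction uses less radiation-damaged signal without
    re-alignment.
    """
    if len(params) != len(other_stack):
        raise ValueError(
            f"alignment length {len(params)} != stack length {len(other_stack)}"
        )
    return backproject(other_stack, params, acq=acq)
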