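"""Helical lattice mathematics.

A helical filament is described by a screw operation (twist about the
helix axis plus an axial rise) together with a Cn point-group symmetry
of each layer.  The same lattice can be read in two equivalent ways:
as a stack of Cn layers related by one screw generator, or as n
interleaved 1-start strands offset by 360/n in azimuth.  Conjugative
F-family pili are C5 filaments with a twist near 28 degrees and a rise
of 12-13 Angstrom, i.e. about 12.8 pilins per turn of each strand.

Conventions: the helix axis is +z, angles are in degrees, a positive
twist generates a right-handed helix, and layer 0 sits at z = 0 with
layer index increasing along +z.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "HelicalSymmetry",
    "ScrewTransform",
    "ScrewDecomposition",
    "subunits_per_turn",
    "rotation_about_z",
    "layer_transforms",
    "strand_lattice_equivalence",
    "screw_decompose",
]


@dataclass(frozen=True)
class HelicalSymmetry:
    """Twist/rise/cyclic-order triple defining a helical lattice.

    twist_deg : signed rotation between successive layers (sign encodes
        handedness); rise_A : axial translation between successive
        layers in Angstrom; cyclic_order : n of the Cn point group.
    """

    twist_deg: float
    rise_A: float
    cyclic_order: int = 1

    def __post_init__(self) -> None:
        if not self.rise_A > 0:
            raise ValueError(f"rise_A must be positive, got {self.rise_A}")
        if not 0 < abs(self.twist_deg) <= 360:
            raise ValueError(
                f"twist_deg must satisfy 0 < |twist| <= 360, got {self.twist_deg}"
            )
        if int(self.cyclic_order) != self.cyclic_order or self.cyclic_order < 1:
            raise ValueError(f"cyclic_order must be a positive integer, got {self.cyclic_order}")

    @property
    def pitch_A(self) -> float:
        """Axial length of one full turn of a strand."""
        return self.rise_A * 360.0 / abs(self.twist_deg)


def subunits_per_turn(sym: HelicalSymmetry) -> float:
    """Number of subunits per full 360-degree turn of one strand.

    For the pED208 pilus (twist 28.2 deg) this is ~12.8.
    """
    if abs(sym.twist_deg) == 0:
        raise ValueError("zero twist: subunits per turn undefined")
    return 360.0 / abs(sym.twist_deg)


def rotation_about_z(angle_deg: float) -> np.ndarray:
    """Right-handed rotation matrix about +z."""
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


@dataclass(frozen=True)
class ScrewDecomposition:
    """Axis/angle/axial-shift reading of a rigid transform."""

    axis: np.ndarray
    angle_deg: float
    axial_shift_A: float
    axis_point: np.ndarray
    pure_translation: bool = False
    identity: bool = False

    @property
    def degenerate(self) -> bool:
        return self.pure_translation or self.identity


@dataclass(frozen=True)
class ScrewTransform:
    """Rigid rotation + translation, with its screw-axis decomposition.

    ``layer`` and ``strand`` carry lattice indices when the transform
    was generated from a :class:`HelicalSymmetry`.
    """

    rotation: np.ndarray
    translation: np.ndarray
    layer: int | None = None
    strand: int | None = None
    _decomp: ScrewDecomposition = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8) or not np.isclose(
            np.linalg.det(R), 1.0, atol=1e-8
        ):
            raise ValueError("rotation must be orthonormal with det +1")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        object.__setattr__(self, "_decomp", screw_decompose(R, t))

    @classmethod
    def from_twist_rise(
        cls, twist_deg: float, rise_A: float, layer: int | None = None, strand: int | None = None
    ) -> "ScrewTransform":
        return cls(rotation_about_z(twist_deg), np.array([0.0, 0.0, rise_A]), layer, strand)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform an (n, 3) array of points."""
        return np.asarray(points) @ self.rotation.T + self.translation

    def compose(self, other: "ScrewTransform") -> "ScrewTransform":
        """self after other: (self o other)(x) = R_s (R_o x + t_o) + t_s."""
        return ScrewTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    @property
    def decomposition(self) -> ScrewDecomposition:
        return self._decomp

    @property
    def angle_deg(self) -> float:
        return self._decomp.angle_deg

    @property
    def axial_shift_A(self) -> float:
        return self._decomp.axial_shift_A

    @property
    def axis(self) -> np.ndarray:
        return self._decomp.axis


def screw_decompose(rotation: np.ndarray, translation: np.ndarray) -> ScrewDecomposition:
    """Decompose a rigid transform into a screw motion.

    Returns the rotation axis (unit vector), rotation angle in degrees,
    translation component along the axis, and a point on the axis (the
    one closest to the origin).  Degenerate cases are flagged rather
    than silently defaulted: a pure translation has no rotation axis
    (the axis is taken along the translation), and the identity has
    neither axis nor shift.
    """
    R = np.asarray(rotation, dtype=float)
    t = np.asarray(translation, dtype=float).reshape(3)
    if not np.allclose(R @ R.T, np.eye(3), atol=1e-8) or not np.isclose(
        np.linalg.det(R), 1.0, atol=1e-8
    ):
        raise ValueError("rotation must be orthonormal with det +1")

    rotvec = Rotation.from_matrix(R).as_rotvec()
    angle = np.linalg.norm(rotvec)
    if angle < 1e-10:  # no rotation at all
        norm_t = np.linalg.norm(t)
        if norm_t < 1e-10:
            return ScrewDecomposition(
                axis=np.array([0.0, 0.0, 1.0]),
                angle_deg=0.0,
                axial_shift_A=0.0,
                axis_point=np.zeros(3),
                identity=True,
            )
        axis = t / norm_t
        return ScrewDecomposition(
            axis=axis,
            angle_deg=0.0,
            axial_shift_A=norm_t,
            axis_point=np.zeros(3),
            pure_translation=True,
        )

    axis = rotvec / angle
    shift = float(t @ axis)
    # Solve (I - R) p = t_perp for the axis point in the plane normal to the axis.
    t_perp = t - shift * axis
    p = np.linalg.lstsq(np.eye(3) - R, t_perp, rcond=None)[0]
    p -= (p @ axis) * axis  # closest point on the axis to the origin
    return ScrewDecomposition(
        axis=axis,
        angle_deg=float(np.rad2deg(angle)),
        axial_shift_A=shift,
        axis_point=p,
    )


def layer_transforms(sym: HelicalSymmetry, n_layers: int) -> list[ScrewTransform]:
    """All lattice transforms for ``n_layers`` layers of a Cn filament.

    Transform for (layer i, strand k) rotates by i*twist + k*360/n about
    z and translates by i*rise along z; (0, 0) is the identity.  The
    list is ordered layer-major, strand-minor.
    """
    if n_layers < 1:
        raise ValueError(f"n_layers must be >= 1, got {n_layers}")
    n = sym.cyclic_order
    out = []
    for i in range(n_layers):
        for k in range(n):
            out.append(
                ScrewTransform(
                    rotation_about_z(i * sym.twist_deg + k * 360.0 / n),
                    np.array([0.0, 0.0, i * sym.rise_A]),
                    layer=i,
                    strand=k,
                )
            )
    return out


def strand_lattice_equivalence(
    sym: HelicalSymmetry,
    n_layers: int = 13,
    strand_phase_perturb_deg: float = 0.0,
    reference_radius_A: float = 20.0,
    tol_A: float = 1e-6,
) -> tuple[bool, np.ndarray, np.ndarray]:
    """Check that the layer-stack and n-start strand descriptions coincide.

    Generates subunit reference points (a marker at ``reference_radius_A``
    on the +x axis) once via the layer-stack transforms and once strand by
    strand (each strand uses the per-subunit screw generator with an
    azimuthal phase of k*360/n, optionally perturbed for strand k=1 to
    exercise the failure mode).  Returns (equivalent, layer_points,
    strand_points); point sets are compared as unordered sets.
    """
    r0 = np.array([reference_radius_A, 0.0, 0.0])
    layer_pts = np.array([T.apply(r0) for T in layer_transforms(sym, n_layers)])

    n = sym.cyclic_order
    strand_pts = []
    for k in range(n):
        phase = k * 360.0 / n
        if k == 1:
            phase += strand_phase_perturb_deg
        for j in range(n_layers):
            Rz = rotation_about_z(j * sym.twist_deg + phase)
            strand_pts.append(Rz @ r0 + np.array([0.0, 0.0, j * sym.rise_A]))
    strand_pts = np.array(strand_pts)

    from scipy.spatial import cKDTree

    tree = cKDTree(strand_pts)
    d, _ = tree.query(layer_pts)
    equivalent = bool(np.max(d) < tol_A)
    return equivalent, layer_pts, strand_pts
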