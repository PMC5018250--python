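"""Filament atomic-model building from a single subunit.

Mirrors the classical superposition/propagation workflow: fit two
copies of the subunit in adjacent positions, extract the relating
rigid transform (least-squares superposition + screw decomposition),
apply successive powers of the screw to generate one strand, then
apply the inter-strand operation (for a Cn filament, the exact
360/n rotation) to build the full n-start pilus — e.g. 5 strands of
16 pilin+lipid units for the conjugative pilus.

Models are `gemmi.Structure` objects throughout; PDB and mmCIF I/O is
gemmi's.  Chain naming for generated assemblies is strand letter +
unit index ("A1".."E16" for proteins; lipid chains get the lowercase
letter), which survives mmCIF round trips; the PDB writer errors when
an assembly exceeds the PDB chain-id space rather than aliasing.
"""

from __future__ import annotations

import string

import gemmi
import numpy as np

from .symmetry import HelicalSymmetry, ScrewTransform, rotation_about_z, screw_decompose

__all__ = [
    "kabsch_superpose",
    "chain_coords",
    "screw_from_chain_pair",
    "propagate_strand",
    "build_full_pilus",
    "read_structure",
    "write_structure",
    "transform_structure",
    "min_interchain_distance",
]


def kabsch_superpose(coords_a: np.ndarray, coords_b: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of matched point sets (a onto b).

    Returns (rotation, translation, rmsd) minimising
    ||R a_i + t - b_i||^2 with a proper rotation (SVD with reflection
    correction).  Requires >= 3 non-collinear points.
    """
    A = np.asarray(coords_a, dtype=float)
    B = np.asarray(coords_b, dtype=float)
    if A.shape != B.shape:
        raise ValueError(f"coordinate sets differ in shape: {A.shape} vs {B.shape}")
    if len(A) < 3:
        raise ValueError("need at least 3 matched points")
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    A0, B0 = A - ca, B - cb
    s = np.linalg.svd(A0, compute_uv=False)
    if s[1] < 1e-9 * max(s[0], 1.0):
        raise ValueError("degenerate (collinear) geometry")
    H = A0.T @ B0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cb - R @ ca
    rmsd = float(np.sqrt(np.mean(np.sum((A @ R.T + t - B) ** 2, axis=1))))
    return R, t, rmsd


def chain_coords(
    structure: gemmi.Structure, chain_name: str, atom_names: tuple[str, ...] = ("CA",)
) -> dict[tuple[int, str], np.ndarray]:
    """(residue seqid, atom name) -> position for one chain."""
    chain = structure[0].find_chain(chain_name)
    if chain is None:
        raise KeyError(f"chain {chain_name!r} not found")
    out = {}
    for res in chain:
        for atom in res:
            if atom_names is None or atom.name in atom_names:
                out[(res.seqid.num, atom.name)] = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
    return out


def screw_from_chain_pair(
    structure: gemmi.Structure,
    chain_i: str,
    chain_j: str,
    atom_names: tuple[str, ...] = ("CA",),
) -> ScrewTransform:
    """Screw transform relating two chains of a model.

    Superposes the matched (residue, atom) selection of ``chain_i``
    onto ``chain_j`` and decomposes the fitted rigid transform into
    axis/angle/axial shift — the per-subunit twist and rise when the
    chains are adjacent along a strand.  Atoms present in only one
    chain are an error (never silently dropped).
    """
    ci = chain_coords(structure, chain_i, atom_names)
    cj = chain_coords(structure, chain_j, atom_names)
    keys = sorted(set(ci) & set(cj))
    missing = sorted(set(ci) ^ set(cj))
    if missing:
        raise ValueError(f"unmatched atoms between {chain_i} and {chain_j}: {missing[:10]}")
    if len(keys) < 3:
        raise ValueError("fewer than 3 matched atoms")
    A = np.array([ci[k] for k in keys])
    B = np.array([cj[k] for k in keys])
    R, t, _ = kabsch_superpose(A, B)
    return ScrewTransform(R, t)


def transform_structure(structure: gemmi.Structure, rotation: np.ndarray, translation: np.ndarray) -> None:
    """Apply a rigid transform to all atoms in place."""
    tr = gemmi.Transform()
    tr.mat.fromlist(np.asarray(rotation, dtype=float).tolist())
    tr.vec.fromlist(list(np.asarray(translation, dtype=float)))
    for model in structure:
        for chain in model:
            for res in chain:
                for atom in res:
                    atom.pos = gemmi.Position(*tr.apply(atom.pos).tolist())


def _clone_chain(chain: gemmi.Chain, new_name: str) -> gemmi.Chain:
    c = chain.clone()
    c.name = new_name
    return c


def propagate_strand(
    unit: gemmi.Structure,
    screw: ScrewTransform,
    count: int,
    strand_letter: str = "A",
) -> gemmi.Structure:
    """Generate one strand: ``count`` copies at successive screw powers.

    The unit may contain several chains (e.g. pilin + lipid); copy m of
    unit chain X becomes chain "<letter>{m+1}" for the first (protein)
    chain and "<lowercase letter>{m+1}" etc. for subsequent chains.
    Copy 0 is the unit itself (identity power).
    """
    if count < 1:
        raise ValueError(f"count must be >= 1, got {count}")
    out = gemmi.Structure()
    out.name = f"strand_{strand_letter}"
    model = gemmi.Model("1")
    unit_chains = list(unit[0])
    R = np.eye(3)
    t = np.zeros(3)
    for m in range(count):
        for ci, chain in enumerate(unit_chains):
            name = _strand_chain_name(strand_letter, m, ci)
            new = _clone_chain(chain, name)
            tr = gemmi.Transform()
            tr.mat.fromlist(R.tolist())
            tr.vec.fromlist(list(t))
            for res in new:
                for atom in res:
                    atom.pos = gemmi.Position(*tr.apply(atom.pos).tolist())
            model.add_chain(new)
        R = screw.rotation @ R
        t = screw.rotation @ t + screw.translation
    out.add_model(model)
    out.setup_entities()
    return out


def _strand_chain_name(strand_letter: str, unit_index: int, chain_index: int) -> str:
    letter = strand_letter if chain_index == 0 else strand_letter.lower()
    suffix = "" if chain_index < 2 else f"x{chain_index}"
    return f"{letter}{unit_index + 1}{suffix}"


def build_full_pilus(
    strand: gemmi.Structure,
    interstrand: ScrewTransform | int,
    clash_warning_A: float = 1.5,
) -> tuple[gemmi.Structure, float]:
    """Replicate a strand into the full n-start filament.

    ``interstrand`` is either an explicit screw transform relating
    adjacent strands or an integer n for the exact Cn rotation (the
    five-strand pilus uses C5).  Strand k keeps its chains renamed to
    the k-th strand letter.  Returns (model, min inter-strand atom
    distance); a separation below ``clash_warning_A`` triggers a
    warning naming the offending pair.
    """
    import warnings

    if isinstance(interstrand, int):
        n = interstrand
        ops = [
            (rotation_about_z(k * 360.0 / n), np.zeros(3)) for k in range(n)
        ]
    else:
        n = None
        dec = interstrand.decomposition
        full = int(round(360.0 / abs(dec.angle_deg))) if dec.angle_deg else 1
        ops = []
        R = np.eye(3)
        t = np.zeros(3)
        for _ in range(max(full, 1)):
            ops.append((R.copy(), t.copy()))
            R = interstrand.rotation @ R
            t = interstrand.rotation @ t + interstrand.translation

    out = gemmi.Structure()
    out.name = "pilus"
    model = gemmi.Model("1")
    letters = string.ascii_uppercase
    for k, (R, t) in enumerate(ops):
        for chain in strand[0]:
            old = chain.name
            new_letter = letters[k % 26]
            name = (new_letter if old[0].isupper() else new_letter.lower()) + old[1:]
            new = _clone_chain(chain, name)
            tr = gemmi.Transform()
            tr.mat.fromlist(R.tolist())
            tr.vec.fromlist(list(t))
            for res in new:
                for atom in res:
                    atom.pos = gemmi.Position(*tr.apply(atom.pos).tolist())
            model.add_chain(new)
    out.add_model(model)
    out.setup_entities()

    min_d, pair = min_interchain_distance(out, strand_of=lambda cn: cn[0].upper())
    if min_d < clash_warning_A:
        warnings.warn(
            f"severe inter-strand clash: {min_d:.2f} A between {pair[0]} and {pair[1]}"
        )
    return out, min_d


def min_interchain_distance(structure: gemmi.Structure, strand_of=None) -> tuple[float, tuple[str, str]]:
    """Minimum atom-atom distance between groups of chains.

    ``strand_of`` maps a chain name to its group label (default: each
    chain is its own group).
    """
    from scipy.spatial import cKDTree

    groups: dict[str, list[np.ndarray]] = {}
    for chain in structure[0]:
        g = strand_of(chain.name) if strand_of else chain.name
        arr = groups.setdefault(g, [])
        for res in chain:
            for atom in res:
                arr.append([atom.pos.x, atom.pos.y, atom.pos.z])
    names = sorted(groups)
    trees = {g: cKDTree(np.array(groups[g])) for g in names}
    best = np.inf
    best_pair = ("", "")
    for i, gi in enumerate(names):
        for gj in names[i + 1 :]:
            d = trees[gi].query(np.array(groups[gj]), k=1)[0].min()
            if d < best:
                best, best_pair = float(d), (gi, gj)
    return best, best_pair


def read_structure(path: str) -> gemmi.Structure:
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    return st


def write_structure(structure: gemmi.Structure, path: str) -> None:
    """Write PDB or mmCIF by extension; PDB checks chain-id capacity."""
    path = str(path)
    if path.endswith(".pdb"):
        for chain in structure[0]:
            if len(chain.name) > 2:
                raise ValueError(
                    f"chain id {chain.name!r} does not fit PDB format; write mmCIF instead"
                )
        structure.write_pdb(path)
    else:
        doc = structure.make_mmcif_document()
        doc.write_file(path)
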