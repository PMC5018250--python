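"""Synthetic pilin + phospholipid unit (pseudo-atomic, generated).

A stand-in for a refined pilin/lipid coordinate set, built entirely
programmatically: a 63-residue three-helix bundle (residues 2-64,
mimicking the TraA pilin's modelled range) oriented radially so that,
when propagated over a C5 lattice with ~28 degree twist and ~12 A
rise, the assembly reproduces the gross architecture of the
conjugative pilus — an ~87 A outer diameter, a ~28 A lumen, N- and
C-termini on the outside, a basic (lysine) loop facing the lumen —
plus a phosphatidylglycerol-like lipid whose phosphate head group sits
at the lumen surface with its two acyl chains buried between subunits.

Geometry is idealized (straight helices, approximate backbone
stereochemistry); it is meant for exercising interface/geometry/
electrostostatics analyses, not as a biophysically refined model.
"""

from __future__ import annotations

import gemmi
import numpy as np

__all__ = ["make_pilin_unit", "DEFAULT_CENTROID_RADIUS_A"]

DEFAULT_CENTROID_RADIUS_A = 29.0

# segment layout along the radial axis u (A): (kind, residues, u_start,
# u_end, (v, w) offset).  u increases outward; v is azimuthal, w axial.
_SEGMENTS = [
    ("helix", (2, 16), 11.0, -11.0, (-5.0, -3.6)),
    ("loop", (17, 20), -11.5, -12.5, (-1.0, 0.5)),
    ("helix", (21, 37), -11.5, 13.0, (5.0, -3.6)),
    ("loop", (38, 41), 13.5, 14.0, (2.0, 1.0)),
    ("helix", (42, 57), 13.0, -10.5, (0.0, 5.0)),
    ("tail", (58, 64), -8.5, 12.0, (3.2, 7.0)),
]

# axial shear: subunits lean so that successive layers interdigitate
_TILT_SLOPE = 0.35

# 63-residue sequence for residues 2..64; lysines in the 17-20 loop face
# the lumen, acidic residues sit on outer segments
_SEQUENCE = (
    "AVSDLMQATGLAELG"  # 2-16  alpha1 (D5 outer)
    "KGTS"  # 17-20 lumen loop (K17 faces the lumen)
    "LAVAGMSLIVTAGLSAM"  # 21-37 alpha2
    "GDSG"  # 38-41 outer loop (D39)
    "ALSTVAGLQSAMTVFN"  # 42-57 alpha3
    "TAGSEMA"  # 58-64 C tail (E62)
)

_THREE = {
    "A": "ALA", "V": "VAL", "S": "SER", "D": "ASP", "L": "LEU", "M": "MET",
    "Q": "GLN", "T": "THR", "G": "GLY", "E": "GLU", "K": "LYS", "I": "ILE",
    "F": "PHE", "N": "ASN", "R": "ARG", "P": "PRO",
}


def _segment_ca(kind: str, n_res: int, u0: float, u1: float, vw: tuple[float, float]) -> np.ndarray:
    """CA trace for one segment in the local (u, v, w) frame."""
    t = np.linspace(0.0, 1.0, n_res)
    axis = np.array([u1 - u0, 0.0, 0.0])
    base = np.array([u0, vw[0], vw[1]]) + t[:, None] * axis[None, :]
    if kind == "helix":
        # ideal helical wobble around the segment axis, 100 deg/residue
        phase = np.deg2rad(100.0 * np.arange(n_res))
        base[:, 1] += 2.3 * np.cos(phase)
        base[:, 2] += 2.3 * np.sin(phase)
    elif kind == "tail":
        phase = np.deg2rad(120.0 * np.arange(n_res))
        base[:, 1] += 1.0 * np.cos(phase)
        base[:, 2] += 1.0 * np.sin(phase)
    base[:, 2] += _TILT_SLOPE * base[:, 0]
    return base


def _protein_atoms() -> list[tuple[int, str, str, str, np.ndarray]]:
    """(seqid, resname, atom name, element, local position) records."""
    ca = {}
    for kind, (r0, r1), u0, u1, vw in _SEGMENTS:
        pts = _segment_ca(kind, r1 - r0 + 1, u0, u1, vw)
        for i, seq in enumerate(range(r0, r1 + 1)):
            ca[seq] = pts[i]
    seqids = sorted(ca)
    records = []
    for idx, seq in enumerate(seqids):
        aa = _SEQUENCE[idx]
        resname = _THREE[aa]
        p = ca[seq]
        nxt = ca[seqids[idx + 1]] if idx + 1 < len(seqids) else p + (p - ca[seqids[idx - 1]])
        prv = ca[seqids[idx - 1]] if idx > 0 else p - (nxt - p)
        step = nxt - p
        # outward direction: away from the local chain axis
        mid = (nxt + prv) / 2.0
        out = p - mid
        nrm = np.linalg.norm(out)
        out = out / nrm if nrm > 1e-6 else np.array([0.0, 0.0, 1.0])
        sdir = step / max(np.linalg.norm(step), 1e-6)
        tang = np.cross(sdir, out)
        lean = 0.35 if idx % 2 == 0 else -0.35  # alternate side-chain lean
        records.append((seq, resname, "N", "N", p - 0.38 * step))
        records.append((seq, resname, "CA", "C", p))
        records.append((seq, resname, "C", "C", p + 0.40 * step))
        records.append((seq, resname, "O", "O", p + 0.40 * step + 1.23 * out))
        if resname != "GLY":
            sc = out + lean * tang
            sc /= np.linalg.norm(sc)
            cb = p + 1.53 * sc
            records.append((seq, resname, "CB", "C", cb))
            if resname in ("LEU", "ILE", "ASN", "ASP", "PRO", "MET", "GLN", "GLU", "LYS", "ARG", "PHE"):
                records.append((seq, resname, "CG", "C", cb + 1.5 * sc + 0.4 * tang))
            if resname in ("MET", "GLN", "GLU", "LYS", "ARG", "PHE"):
                records.append((seq, resname, "CD", "C", cb + 2.9 * sc - 0.3 * tang))
            if resname == "LYS":
                records.append((seq, resname, "NZ", "N", cb + 3.9 * sc))
            elif resname == "ASP":
                records.append((seq, resname, "OD1", "O", cb + 2.3 * sc + 0.6 * tang))
            elif resname == "GLU":
                records.append((seq, resname, "OE1", "O", cb + 3.4 * sc + 0.6 * tang))
            elif resname == "ARG":
                records.append((seq, resname, "NH1", "N", cb + 4.4 * sc))
    return records


def _lipid_atoms() -> list[tuple[str, str, np.ndarray]]:
    """PG-like lipid in the local frame: head at the inner (lumen) end."""
    atoms = []
    head_u = -15.5  # the phosphate is the most lumen-exposed group
    head_vw = np.array([9.0, 2.0])
    P = np.array([head_u, head_vw[0], head_vw[1]])
    atoms.append(("P", "P", P))
    for i, d in enumerate(
        [np.array([0.0, 1.3, 0.8]), np.array([0.0, -1.2, 0.9]), np.array([-1.2, 0.4, -0.9]), np.array([1.3, 0.2, -0.6])]
    ):
        atoms.append((f"O{i+1}", "O", P + d))
    # glycerol backbone
    g0 = P + np.array([2.4, 0.0, 0.0])
    for i in range(3):
        atoms.append((f"C{i+1}", "C", g0 + np.array([1.2 * i, 0.4 * (i % 2), 0.3 * i])))
    # two acyl chains hugging the groove between adjacent subunits; the
    # tilt shear of the protein is followed so the chains stay buried
    for c, (dv, dw) in enumerate([(1.6, -1.2), (-1.0, 1.6)]):
        start = g0 + np.array([1.5, dv, dw])
        for i in range(14):
            zig = 0.55 if i % 2 == 0 else -0.55
            u_off = 1.15 * (i + 1)
            atoms.append(
                (
                    f"C{4 + c * 14 + i}",
                    "C",
                    start
                    + np.array(
                        [u_off, dv * 0.15 * np.sin(0.4 * i) + zig * 0.3 + (0.30 * u_off if c == 1 else 0.0), dw * 0.2 + zig + _TILT_SLOPE * u_off]
                    ),
                )
            )
    return atoms


def make_pilin_unit(centroid_radius_A: float = DEFAULT_CENTROID_RADIUS_A) -> gemmi.Structure:
    """Build the synthetic pilin (chain A) + lipid (chain B) unit.

    The local radial axis u maps to +x, so the unit sits at azimuth 0
    with its centroid ``centroid_radius_A`` from the filament (z) axis.
    Propagating it with twist ~28 deg / rise ~12 A / C5 produces the
    pilus-like assembly this generator is calibrated for.
    """
    st = gemmi.Structure()
    st.name = "synthetic pilin unit"
    model = gemmi.Model("1")

    chain = gemmi.Chain("A")
    current = None
    for seq, resname, aname, elem, p in _protein_atoms():
        if current is None or current.seqid.num != seq:
            current = gemmi.Residue()
            current.name = resname
            current.seqid = gemmi.SeqId(seq, " ")
            chain.add_residue(current)
            current = chain[-1]
        atom = gemmi.Atom()
        atom.name = aname
        atom.element = gemmi.Element(elem)
        atom.pos = gemmi.Position(p[0] + centroid_radius_A, p[1], p[2])
        atom.occ = 1.0
        atom.b_iso = 30.0
        current.add_atom(atom)
    model.add_chain(chain)

    lipid_chain = gemmi.Chain("B")
    res = gemmi.Residue()
    res.name = "PGL"
    res.seqid = gemmi.SeqId(101, " ")
    res.het_flag = "H"
    lipid_chain.add_residue(res)
    res = lipid_chain[-1]
    for aname, elem, p in _lipid_atoms():
        atom = gemmi.Atom()
        atom.name = aname
        atom.element = gemmi.Element(elem)
        atom.pos = gemmi.Position(p[0] + centroid_radius_A, p[1], p[2])
        atom.occ = 1.0
        atom.b_iso = 40.0
        res.add_atom(atom)
    model.add_chain(lipid_chain)

    st.add_model(model)
    st.setup_entities()
    return st
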