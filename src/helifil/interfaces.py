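"""Quantitative filament architecture analysis.

Buried-surface statistics (how much of a pilin or lipid surface is
lost to assembly contacts), contact networks (which subunits touch
which), radial geometry (outer and lumen diameters) and a qualitative
screened-Coulomb model of the lumen electrostatic potential with and
without the bound phospholipids.

SASA is Shrake-Rupley quadrature on a Fibonacci sphere (960 points by
default, probe 1.4 A, standard element radii); buried area of a
component is SASA(isolated) - SASA(in assembly).  Components are
chains: each protein chain is one subunit, each lipid chain one lipid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "VDW_RADII",
    "InterfaceReport",
    "RadialProfile",
    "PotentialGrid",
    "sasa",
    "structure_atoms",
    "component_sasa",
    "buried_fraction",
    "neighbor_count",
    "pairwise_buried_table",
    "radial_geometry",
    "lumen_potential",
]

VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80, "H": 1.20}

PROBE_RADIUS_A = 1.4


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5**0.5) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def sasa(
    coords: np.ndarray,
    radii: np.ndarray,
    probe_radius_A: float = PROBE_RADIUS_A,
    n_sphere_points: int = 960,
    subset: np.ndarray | None = None,
) -> np.ndarray:
    """Shrake-Rupley solvent-accessible surface area per atom (A^2).

    ``subset`` restricts which atoms get an area (all atoms still
    occlude); returned array has one entry per subset atom (or per atom).
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    pts = _fibonacci_sphere(n_sphere_points)
    tree = cKDTree(coords)
    idx = np.arange(len(coords)) if subset is None else np.asarray(subset)
    r_max = radii.max()
    out = np.empty(len(idx))
    for k, i in enumerate(idx):
        ri = radii[i] + probe_radius_A
        cand = tree.query_ball_point(coords[i], ri + r_max + probe_radius_A)
        cand = [j for j in cand if j != i]
        surf = coords[i] + ri * pts
        if cand:
            nb = coords[cand]
            nr = radii[np.asarray(cand)] + probe_radius_A
            d2 = ((surf[:, None, :] - nb[None, :, :]) ** 2).sum(axis=2)
            exposed = np.all(d2 > (nr**2)[None, :], axis=1)
        else:
            exposed = np.ones(n_sphere_points, dtype=bool)
        out[k] = exposed.mean() * 4.0 * np.pi * ri * ri
    return out


def structure_atoms(structure: gemmi.Structure) -> pd.DataFrame:
    """Flat atom table: chain, seqid, resname, atom, element, x/y/z, vdw radius."""
    rows = []
    for chain in structure[0]:
        for res in chain:
            for atom in res:
                el = atom.element.name
                if el not in VDW_RADII:
                    raise ValueError(f"unknown element {el!r} at {chain.name}/{res.seqid.num}/{atom.name}")
                rows.append(
                    (chain.name, res.seqid.num, res.name, atom.name, el,
                     atom.pos.x, atom.pos.y, atom.pos.z, VDW_RADII[el])
                )
    return pd.DataFrame(
        rows, columns=["chain", "seqid", "resname", "atom", "element", "x", "y", "z", "radius"]
    )


def _coords(df: pd.DataFrame) -> np.ndarray:
    return df[["x", "y", "z"]].to_numpy()


def component_sasa(
    atoms: pd.DataFrame,
    component_chains: list[str],
    context_chains: list[str] | None = None,
    n_sphere_points: int = 960,
) -> float:
    """Total SASA of a component, optionally inside a context.

    ``context_chains=None`` computes the isolated component; otherwise
    the component's atoms are evaluated with the context atoms present
    as occluders (the component chains are always included).
    """
    comp_mask = atoms["chain"].isin(component_chains).to_numpy()
    if not comp_mask.any():
        raise ValueError(f"empty component selection: {component_chains}")
    if context_chains is None:
        sub = atoms[comp_mask]
        areas = sasa(_coords(sub), sub["radius"].to_numpy(), n_sphere_points=n_sphere_points)
        return float(areas.sum())
    keep = atoms["chain"].isin(set(component_chains) | set(context_chains)).to_numpy()
    sub = atoms[keep]
    target = sub["chain"].isin(component_chains).to_numpy().nonzero()[0]
    areas = sasa(
        _coords(sub), sub["radius"].to_numpy(), n_sphere_points=n_sphere_points, subset=target
    )
    return float(areas.sum())


def buried_fraction(
    structure: gemmi.Structure | pd.DataFrame,
    component_chains: list[str],
    n_sphere_points: int = 960,
) -> tuple[float, float, float]:
    """(total SASA, buried SASA, buried fraction) of a component in its assembly.

    buried = SASA(component isolated) - SASA(component within the full
    assembly); e.g. ~70% of the lipid surface is buried in the intact
    pilus.
    """
    atoms = structure if isinstance(structure, pd.DataFrame) else structure_atoms(structure)
    all_chains = atoms["chain"].unique().tolist()
    total = component_sasa(atoms, component_chains, None, n_sphere_points)
    in_ctx = component_sasa(atoms, component_chains, all_chains, n_sphere_points)
    buried = max(total - in_ctx, 0.0)
    return total, buried, buried / total if total > 0 else 0.0


def _pair_buried(
    atoms: pd.DataFrame, a: str, b: str, n_sphere_points: int
) -> float:
    iso = component_sasa(atoms, [a], None, n_sphere_points)
    ctx = component_sasa(atoms, [a], [b], n_sphere_points)
    return max(iso - ctx, 0.0)


def _contact_candidates(atoms: pd.DataFrame, reference_chain: str, cutoff_A: float = 6.0) -> list[str]:
    ref = atoms[atoms["chain"] == reference_chain]
    if ref.empty:
        raise ValueError(f"reference chain {reference_chain!r} absent")
    tree = cKDTree(_coords(ref))
    out = []
    for ch, grp in atoms.groupby("chain", sort=False):
        if ch == reference_chain:
            continue
        d = tree.query(_coords(grp), k=1)[0].min()
        if d <= cutoff_A:
            out.append(ch)
    return out


def neighbor_count(
    structure: gemmi.Structure | pd.DataFrame,
    reference_chain: str,
    criterion: str = "buried",
    buried_cutoff_A2: float = 1.0,
    distance_cutoff_A: float = 4.0,
    n_sphere_points: int = 960,
) -> tuple[int, list[str]]:
    """Number (and ids) of components in contact with a reference chain.

    ``criterion='buried'`` counts chains whose pairwise buried area with
    the reference exceeds ``buried_cutoff_A2`` (default 1 A^2);
    ``criterion='distance'`` counts chains with any heavy-atom pair
    within ``distance_cutoff_A``.
    """
    atoms = structure if isinstance(structure, pd.DataFrame) else structure_atoms(structure)
    cands = _contact_candidates(atoms, reference_chain)
    neighbors = []
    if criterion == "distance":
        ref = atoms[atoms["chain"] == reference_chain]
        tree = cKDTree(_coords(ref))
        for ch in cands:
            grp = atoms[atoms["chain"] == ch]
            if tree.query(_coords(grp), k=1)[0].min() <= distance_cutoff_A:
                neighbors.append(ch)
    elif criterion == "buried":
        for ch in cands:
            if _pair_buried(atoms, reference_chain, ch, n_sphere_points) > buried_cutoff_A2:
                neighbors.append(ch)
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    return len(neighbors), sorted(neighbors)


@dataclass
class InterfaceReport:
    """Buried-area breakdown of one reference component."""

    reference: str
    pair_buried_A2: dict[str, float]
    total_sasa_A2: float
    buried_in_assembly_A2: float = 0.0
    buried_fraction: float = 0.0

    def protein_buried_A2(self) -> float:
        return sum(v for c, v in self.pair_buried_A2.items() if c[0].isupper())

    def lipid_buried_A2(self) -> float:
        return sum(v for c, v in self.pair_buried_A2.items() if not c[0].isupper())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.pair_buried_A2.items()), columns=["neighbor", "buried_A2"]
        )


def pairwise_buried_table(
    structure: gemmi.Structure | pd.DataFrame,
    reference_chain: str,
    n_sphere_points: int = 960,
) -> InterfaceReport:
    """Per-neighbor buried areas of a reference subunit, plus totals.

    Also computes the combined (protein + lipid) buried fraction of the
    reference surface within the whole assembly.  Note pairwise buried
    areas can sum to slightly more than the assembly-context buried
    area where three components meet.
    """
    atoms = structure if isinstance(structure, pd.DataFrame) else structure_atoms(structure)
    cands = _contact_candidates(atoms, reference_chain)
    pairs = {}
    for ch in cands:
        b = _pair_buried(atoms, reference_chain, ch, n_sphere_points)
        if b > 0.0:
            pairs[ch] = b
    total, buried, frac = buried_fraction(atoms, [reference_chain], n_sphere_points)
    return InterfaceReport(reference_chain, pairs, total, buried, frac)


@dataclass
class RadialProfile:
    """Per-z-slice radial extrema plus aggregate diameters (A)."""

    z_centers: np.ndarray
    r_min: np.ndarray
    r_max: np.ndarray
    lumen_diameter_A: float
    outer_diameter_A: float
    lumen_diameter_vdw_A: float = 0.0
    outer_diameter_vdw_A: float = 0.0


def radial_geometry(
    structure: gemmi.Structure | pd.DataFrame,
    slice_A: float = 4.0,
    central_fraction: float = 0.5,
) -> RadialProfile:
    """Radial geometry of a filament model in the canonical axis-on-z frame.

    Lumen diameter = twice the largest coaxial empty-cylinder radius,
    taken as the minimum over central slices of the per-slice minimum
    atom-centre radius; outer diameter = twice the 99th percentile of
    atom-centre radii in the central region.  Variants padded by the
    van der Waals radius are also reported (lumen shrinks, outer
    grows); the atom-centre numbers are the headline values.
    """
    atoms = structure if isinstance(structure, pd.DataFrame) else structure_atoms(structure)
    z = atoms["z"].to_numpy()
    r = np.hypot(atoms["x"].to_numpy(), atoms["y"].to_numpy())
    vdw = atoms["radius"].to_numpy()
    edges = np.arange(z.min(), z.max() + slice_A, slice_A)
    if len(edges) < 3:
        raise ValueError("model spans fewer than 2 z-slices")
    which = np.digitize(z, edges) - 1
    centers, rmin, rmax = [], [], []
    for b in range(len(edges) - 1):
        sel = which == b
        if not sel.any():
            continue
        centers.append((edges[b] + edges[b + 1]) / 2.0)
        rmin.append(r[sel].min())
        rmax.append(r[sel].max())
    centers = np.array(centers)
    rmin = np.array(rmin)
    rmax = np.array(rmax)

    z_lo, z_hi = np.quantile(z, [(1 - central_fraction) / 2, (1 + central_fraction) / 2])
    central = (centers >= z_lo) & (centers <= z_hi)
    if not central.any():
        central = np.ones(len(centers), dtype=bool)
    core = (z >= z_lo) & (z <= z_hi)
    lumen = 2.0 * rmin[central].min()
    outer = 2.0 * np.quantile(r[core], 0.99)
    lumen_vdw = 2.0 * max((r[core] - vdw[core]).min(), 0.0)
    outer_vdw = 2.0 * np.quantile(r[core] + vdw[core], 0.99)
    return RadialProfile(centers, rmin, rmax, float(lumen), float(outer), float(lumen_vdw), float(outer_vdw))


@dataclass
class PotentialGrid:
    """Electrostatic potential (kT/e) sampled on a cylindrical shell grid."""

    points: np.ndarray
    potential: np.ndarray
    mean_lumen_potential: float
    shell_radius_A: float


# simplified ionizable-group charges (elementary charges)
_CHARGE_RULES = {
    ("LYS", "NZ"): +1.0,
    ("ARG", "NH1"): +1.0,
    ("ASP", "OD1"): -1.0,
    ("GLU", "OE1"): -1.0,
}
_LIPID_PHOSPHATE_CHARGE = -1.0
_PARAMETERIZED_RESNAMES = {
    "ALA", "VAL", "SER", "ASP", "LEU", "MET", "GLN", "THR", "GLY", "GLU",
    "LYS", "ILE", "PHE", "ASN", "ARG", "PRO", "TYR", "TRP", "HIS", "CYS",
}

BJERRUM_LENGTH_A = 7.0  # water, 298 K
_KAPPA_PER_SQRT_M = 1.0 / 3.04  # 1/A per sqrt(mol/l), 298 K


def _assign_charges(atoms: pd.DataFrame, include_lipids: bool, termini: bool = True) -> pd.DataFrame:
    rows = []
    for ch, grp in atoms.groupby("chain", sort=False):
        protein = grp["resname"].isin(_PARAMETERIZED_RESNAMES)
        if protein.any():
            unknown = set(grp.loc[~protein & (grp["element"] != "H"), "resname"]) - {"PGL"}
            if unknown:
                raise ValueError(
                    f"cannot parameterize residue(s) {sorted(unknown)} in chain {ch}"
                )
            prot = grp[protein]
            for _, row in prot.iterrows():
                q = _CHARGE_RULES.get((row["resname"], row["atom"]))
                if q:
                    rows.append((row["x"], row["y"], row["z"], q))
            if termini:
                first = prot[prot["seqid"] == prot["seqid"].min()]
                n_at = first[first["atom"] == "N"]
                if len(n_at):
                    rows.append((*n_at.iloc[0][["x", "y", "z"]], +1.0))
                last = prot[prot["seqid"] == prot["seqid"].max()]
                o_at = last[last["atom"] == "O"]
                if len(o_at):
                    rows.append((*o_at.iloc[0][["x", "y", "z"]], -1.0))
        else:
            bad = set(grp["resname"]) - {"PGL", "PG", "PGV", "LHG"}
            if bad:
                raise ValueError(f"cannot parameterize residue(s) {sorted(bad)} in chain {ch}")
            if include_lipids:
                p = grp[grp["element"] == "P"]
                for _, row in p.iterrows():
                    rows.append((row["x"], row["y"], row["z"], _LIPID_PHOSPHATE_CHARGE))
    return pd.DataFrame(rows, columns=["x", "y", "z", "q"])


def lumen_potential(
    structure: gemmi.Structure | pd.DataFrame,
    include_lipids: bool = True,
    ionic_strength_M: float = 0.15,
    grid_spacing_A: float = 3.0,
    shell_radius_A: float | None = None,
) -> PotentialGrid:
    """Screened-Coulomb (Debye-Hueckel) potential on the lumen surface.

    Simplified charge set: Arg/Lys +1, Asp/Glu -1, chain termini +/-1,
    lipid phosphate -1 (dropped when ``include_lipids=False``); uniform
    dielectric 80 at 298 K, phi(r) = sum q_i l_B exp(-kappa d)/d in
    kT/e.  The summary is the mean over a cylindrical shell just inside
    the lumen surface (radius from :func:`radial_geometry` unless
    given), over the central half of the filament.  This is a
    qualitative model: the claim it supports is the sign of the lumen
    potential with and without the lipid head groups.
    """
    atoms = structure if isinstance(structure, pd.DataFrame) else structure_atoms(structure)
    charges = _assign_charges(atoms, include_lipids)
    if shell_radius_A is None:
        prof = radial_geometry(atoms)
        shell_radius_A = max(prof.lumen_diameter_A / 2.0 - 1.0, 2.0)
    z = atoms["z"].to_numpy()
    z_lo, z_hi = np.quantile(z, [0.25, 0.75])
    zs = np.arange(z_lo, z_hi, grid_spacing_A)
    n_ang = max(int(2 * np.pi * shell_radius_A / grid_spacing_A), 8)
    ang = np.linspace(0, 2 * np.pi, n_ang, endpoint=False)
    pts = np.array(
        [
            (shell_radius_A * np.cos(a), shell_radius_A * np.sin(a), zz)
            for zz in zs
            for a in ang
        ]
    )
    if len(charges) == 0:
        pot = np.zeros(len(pts))
    else:
        kappa = _KAPPA_PER_SQRT_M * np.sqrt(ionic_strength_M)
        cpos = charges[["x", "y", "z"]].to_numpy()
        q = charges["q"].to_numpy()
        d = np.sqrt(((pts[:, None, :] - cpos[None, :, :]) ** 2).sum(axis=2))
        d = np.maximum(d, 1.0)
        pot = (q[None, :] * BJERRUM_LENGTH_A * np.exp(-kappa * d) / d).sum(axis=1)
    return PotentialGrid(pts, pot, float(pot.mean()), float(shell_radius_A))
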