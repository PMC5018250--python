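"""End-to-end workflows: simulate -> reconstruct -> validate, and
unit -> assembly -> architecture analysis.

A single YAML config (see :class:`RunConfig`) drives every stage; all
stage seeds derive deterministically from one global seed, and every
run emits a provenance block (config hash, seeds, package versions)
sufficient to reproduce its outputs exactly.
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

from .ctf import AcquisitionParams
from .symmetry import HelicalSymmetry
from .volume import DensityVolume

__all__ = [
    "RunConfig",
    "run_demo_reconstruction",
    "run_demo_sorting",
    "run_structure_analysis",
]


@dataclass
class SimulationConfig:
    twist_deg: float = 28.2
    rise_A: float = 12.1
    cyclic_order: int = 5
    box_px: int = 96
    voxel_A: float = 3.0
    n_segments: int = 240
    snr: float = 0.1
    defocus_um_min: float = 0.5
    defocus_um_max: float = 3.5
    tilt_jitter_deg: float = 5.0
    subunit_seed: int = 1
    n_pseudo_atoms: int = 60
    right_handed: bool = True


@dataclass
class ReconstructionConfig:
    init_twist_deg: float = 27.0
    init_rise_A: float = 11.5
    max_iter: int = 10
    angular_step_deg: float = 4.0
    tol_twist_deg: float = 0.05
    tol_rise_A: float = 0.02
    cylinder_radius_A: float = 42.0


@dataclass
class SortingConfig:
    twist_a_deg: float = 28.1
    rise_a_A: float = 12.5
    twist_b_deg: float = 27.9
    rise_b_A: float = 13.2
    fraction_a: float = 0.5
    n_segments: int = 200
    n_cycles: int = 5


@dataclass
class BuildingConfig:
    twist_deg: float = 28.2
    rise_A: float = 12.1
    cyclic_order: int = 5
    units_per_strand: int = 16


@dataclass
class RunConfig:
    """Named sections for each pipeline stage plus a global seed."""

    seed: int = 0
    output_dir: str = "results"
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    reconstruction: ReconstructionConfig = field(default_factory=ReconstructionConfig)
    sorting: SortingConfig = field(default_factory=SortingConfig)
    building: BuildingConfig = field(default_factory=BuildingConfig)

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed below 2**31."""
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31)

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        raw = yaml.safe_load(text) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        sections = {f.name: f for f in fields(cls)}
        kwargs = {}
        for key, value in raw.items():
            if key not in sections:
                raise KeyError(f"unknown config key: {key!r}")
            f = sections[key]
            if f.name in ("seed", "output_dir"):
                kwargs[key] = value
            else:
                sub_cls = f.default_factory  # type: ignore[misc]
                sub_fields = {sf.name for sf in fields(sub_cls)}
                bad = set(value) - sub_fields
                if bad:
                    raise KeyError(f"unknown config key: {key}.{sorted(bad)[0]!r}")
                kwargs[key] = sub_cls(**value)
        return cls(**kwargs)

    def provenance(self) -> dict:
        import scipy

        from . import __version__

        return {
            "config_sha256": hashlib.sha256(self.to_yaml().encode()).hexdigest(),
            "seed": self.seed,
            "stage_seeds": {
                s: self.stage_seed(s) for s in ("simulate", "reconstruct", "sort", "analyze")
            },
            "versions": {
                "helifil": __version__,
                "numpy": np.__version__,
                "scipy": scipy.__version__,
                "python": sys.version.split()[0],
            },
        }


def _log(msg: str) -> None:
    print(msg, file=sys.stderr)


def run_demo_reconstruction(config: RunConfig, write_outputs: bool = True) -> dict:
    """Simulate a filament dataset, run the IHRSR cycle, validate by FSC.

    Returns a report with the recovered symmetry, its error against the
    simulation ground truth, the even/odd half-map resolution (FSC
    0.143) and the model:map resolution (FSC 0.4), runtimes, and the
    provenance block.
    """
    from .fsc import fsc, resolution_at_threshold
    from .reconstruct import (
        backproject,
        ihrsr,
        make_cylinder_volume,
        phase_flip,
        _subset_params,
    )
    from .simulate import make_test_subunit, render_volume, simulate_segment_stack

    sim = config.simulation
    rec = config.reconstruction
    t0 = time.time()
    sign = 1.0 if sim.right_handed else -1.0
    sym_true = HelicalSymmetry(sign * sim.twist_deg, sim.rise_A, sim.cyclic_order)
    acq = AcquisitionParams(pixel_size_A=sim.voxel_A)
    template = make_test_subunit(sim.subunit_seed, sim.n_pseudo_atoms)
    n_layers = int(np.ceil(sim.box_px * sim.voxel_A / sim.rise_A)) + 3
    truth = render_volume(template, sym_true, n_layers, sim.box_px, sim.voxel_A, clip_z=True)
    stack = simulate_segment_stack(
        truth,
        sim.n_segments,
        acq,
        defocus_range_um=(sim.defocus_um_min, sim.defocus_um_max),
        seed=config.stage_seed("simulate"),
        rise_A=sim.rise_A,
        tilt_jitter_deg=sim.tilt_jitter_deg,
        target_snr=sim.snr,
    )
    stack = phase_flip(stack, acq)
    t_sim = time.time() - t0
    _log(f"[simulate] {sim.n_segments} segments, box {sim.box_px}px @ {sim.voxel_A} A/px ({t_sim:.0f}s)")

    t0 = time.time()
    init = make_cylinder_volume(
        sim.box_px, sim.voxel_A, rec.cylinder_radius_A, noise_sd=0.1,
        seed=config.stage_seed("reconstruct"),
    )
    state = ihrsr(
        stack,
        init,
        HelicalSymmetry(sign * rec.init_twist_deg, rec.init_rise_A, sim.cyclic_order),
        max_iter=rec.max_iter,
        tol_twist_deg=rec.tol_twist_deg,
        tol_rise_A=rec.tol_rise_A,
        angular_step_deg=rec.angular_step_deg,
        acq=acq,
    )
    t_rec = time.time() - t0
    _log(
        f"[reconstruct] {state.iteration} iterations -> twist {state.symmetry.twist_deg:.3f} deg,"
        f" rise {state.symmetry.rise_A:.3f} A ({t_rec:.0f}s)"
    )

    # half-map FSC from even/odd segment splits under the final alignment
    t0 = time.time()
    even = np.arange(0, len(stack), 2)
    odd = np.arange(1, len(stack), 2)
    from .reconstruct import symmetrize

    half_a = symmetrize(
        backproject(stack.subset(even), _subset_params(state.alignment, even), acq=acq),
        state.symmetry,
    )
    half_b = symmetrize(
        backproject(stack.subset(odd), _subset_params(state.alignment, odd), acq=acq),
        state.symmetry,
    )
    curve = fsc(half_a, half_b)
    res_half, half_flag = resolution_at_threshold(curve, "half_map")

    # model:map FSC against the ground-truth template rendered as density
    model_map = model_to_density_from_truth(truth)
    curve_mm = fsc(state.volume, model_map)
    res_model, model_flag = resolution_at_threshold(curve_mm, "model_map")
    t_fsc = time.time() - t0
    _log(f"[validate] half-map {res_half:.1f} A (0.143), model:map {res_model:.1f} A (0.4) ({t_fsc:.0f}s)")

    report = {
        "true_twist_deg": sym_true.twist_deg,
        "true_rise_A": sym_true.rise_A,
        "recovered_twist_deg": state.symmetry.twist_deg,
        "recovered_rise_A": state.symmetry.rise_A,
        "twist_error_deg": abs(state.symmetry.twist_deg - sym_true.twist_deg),
        "rise_error_A": abs(state.symmetry.rise_A - sym_true.rise_A),
        "converged": bool(state.converged),
        "iterations": state.iteration,
        "halfmap_resolution_A": res_half,
        "halfmap_never_crossed": half_flag,
        "modelmap_resolution_A": res_model,
        "modelmap_never_crossed": model_flag,
        "runtime_s": {"simulate": round(t_sim, 1), "reconstruct": round(t_rec, 1), "fsc": round(t_fsc, 1)},
        "provenance": config.provenance(),
    }
    if write_outputs:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        state.volume.write_mrc(out / "reconstruction.mrc")
        half_a.write_mrc(out / "half_a.mrc")
        half_b.write_mrc(out / "half_b.mrc")
        np.savetxt(
            out / "fsc_halfmap.txt",
            np.column_stack([curve.frequencies, curve.correlations]),
            header="freq_1_per_A fsc",
        )
        (out / "reconstruction_report.json").write_text(json.dumps(report, indent=2))
    return report


def model_to_density_from_truth(truth: DensityVolume) -> DensityVolume:
    """Stand-in for a refined-model rendering in the synthetic workflow.

    The simulation's noiseless ground-truth volume plays the role the
    stereochemically refined atomic model plays for experimental maps:
    the independent, noise-free reference the reconstruction is
    correlated against shell by shell.
    """
    return truth


def run_fsc_consistency(config: RunConfig) -> dict:
    """Half-map (0.143) vs model:map (0.4) resolution of one reconstruction.

    Builds a synthetic reconstruction with known (ground-truth)
    alignment at the configured SNR, splits it into even/odd half-maps,
    and compares the half-map resolution with the resolution of the
    full map against the noise-free ground-truth structure, which here
    plays the role the stereochemically refined atomic model plays for
    an experimental map.  Known alignment keeps orientation errors out
    of the comparison: after reference-based refinement the half-map
    estimate would carry common-reference noise bias that the map:truth
    correlation does not share (gold-standard refinement, which removes
    that bias, is out of scope).
    """
    from .fsc import fsc, resolution_at_threshold, smooth_fsc_curve
    from .reconstruct import AlignmentParams, backproject, phase_flip, symmetrize, _subset_params
    from .simulate import make_test_subunit, render_volume, simulate_segment_stack

    sim = config.simulation
    sign = 1.0 if sim.right_handed else -1.0
    sym = HelicalSymmetry(sign * sim.twist_deg, sim.rise_A, sim.cyclic_order)
    acq = AcquisitionParams(pixel_size_A=sim.voxel_A)
    n_layers = int(np.ceil(sim.box_px * sim.voxel_A / sim.rise_A)) + 3
    vol = render_volume(
        make_test_subunit(sim.subunit_seed, sim.n_pseudo_atoms),
        sym, n_layers, sim.box_px, sim.voxel_A, clip_z=True,
    )
    truth = symmetrize(vol, sym)
    n = max(sim.n_segments, 40)
    stack = simulate_segment_stack(
        vol, n, acq,
        defocus_range_um=(sim.defocus_um_min, sim.defocus_um_max),
        seed=config.stage_seed("fsc"), rise_A=sim.rise_A,
        tilt_jitter_deg=0.0, target_snr=sim.snr,
    )
    stack = phase_flip(stack, acq)
    az = np.round(stack.meta["azimuth_deg"].to_numpy() / 4) * 4 % 360
    params = AlignmentParams(
        az, np.zeros(n),
        stack.meta["shift_x_px"].to_numpy(), stack.meta["shift_z_px"].to_numpy(),
        np.ones(n),
    )
    even, odd = np.arange(0, n, 2), np.arange(1, n, 2)
    half_a = symmetrize(backproject(stack.subset(even), _subset_params(params, even), acq=acq), sym)
    half_b = symmetrize(backproject(stack.subset(odd), _subset_params(params, odd), acq=acq), sym)
    full = symmetrize(backproject(stack, params, acq=acq), sym)
    curve_half = smooth_fsc_curve(fsc(half_a, half_b))
    curve_model = smooth_fsc_curve(fsc(full, truth))
    res_half, flag_h = resolution_at_threshold(curve_half, "half_map")
    res_model, flag_m = resolution_at_threshold(curve_model, "model_map")
    # the two criteria tell one story when the model:map curve matches the
    # curve predicted from the half-map FSC: C_ref = sqrt(2C/(1+C))
    c_half = np.clip(curve_half.correlations, 0.0, 1.0)
    predicted = np.sqrt(2.0 * c_half / (1.0 + c_half))
    band = curve_half.correlations > 0.2
    curve_deviation = float(np.abs(predicted[band] - curve_model.correlations[band]).mean())
    return {
        "halfmap_resolution_A": res_half,
        "modelmap_resolution_A": res_model,
        "never_crossed": bool(flag_h or flag_m),
        "curve_deviation": curve_deviation,
        "shell_width_invA": 1.0 / (sim.box_px * sim.voxel_A),
        "n_segments": n,
    }


def run_demo_sorting(config: RunConfig, write_outputs: bool = True) -> dict:
    """Two-class rise-mixture workflow with ground-truth confusion matrix."""
    from .reconstruct import phase_flip, sort_segments
    from .simulate import make_test_subunit, simulate_mixture

    sim = config.simulation
    srt = config.sorting
    sign = 1.0 if sim.right_handed else -1.0
    sym_a = HelicalSymmetry(sign * srt.twist_a_deg, srt.rise_a_A, sim.cyclic_order)
    sym_b = HelicalSymmetry(sign * srt.twist_b_deg, srt.rise_b_A, sim.cyclic_order)
    acq = AcquisitionParams(pixel_size_A=sim.voxel_A)
    template = make_test_subunit(sim.subunit_seed, sim.n_pseudo_atoms)

    t0 = time.time()
    stack = simulate_mixture(
        template, sym_a, sym_b, srt.fraction_a, srt.n_segments, acq,
        box_px=sim.box_px, voxel_A=sim.voxel_A,
        seed=config.stage_seed("simulate"),
        defocus_range_um=(sim.defocus_um_min, sim.defocus_um_max),
        tilt_jitter_deg=sim.tilt_jitter_deg, target_snr=sim.snr,
    )
    stack = phase_flip(stack, acq)
    t_sim = time.time() - t0
    _log(f"[simulate] mixture of {srt.n_segments} segments ({t_sim:.0f}s)")

    t0 = time.time()
    labels, vol_a, vol_b = sort_segments(
        stack, sym_a, sym_b, n_cycles=srt.n_cycles,
        seed=config.stage_seed("sort"), acq=acq,
    )
    t_sort = time.time() - t0
    truth = stack.meta["class_label"].to_numpy()
    tp = int(((labels == 0) & (truth == 0)).sum())
    fn = int(((labels == 1) & (truth == 0)).sum())
    fp = int(((labels == 0) & (truth == 1)).sum())
    tn = int(((labels == 1) & (truth == 1)).sum())
    accuracy = (tp + tn) / len(labels)
    _log(f"[sort] accuracy {accuracy:.3f} after {srt.n_cycles} cycles ({t_sort:.0f}s)")

    report = {
        "n_segments": len(labels),
        "confusion": {"a_as_a": tp, "a_as_b": fn, "b_as_a": fp, "b_as_b": tn},
        "accuracy": accuracy,
        "class_counts": {"a": int((labels == 0).sum()), "b": int((labels == 1).sum())},
        "runtime_s": {"simulate": round(t_sim, 1), "sort": round(t_sort, 1)},
        "provenance": config.provenance(),
    }
    if write_outputs:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        vol_a.write_mrc(out / "class_a.mrc")
        vol_b.write_mrc(out / "class_b.mrc")
        (out / "sorting_report.json").write_text(json.dumps(report, indent=2))
    return report


def run_structure_analysis(config: RunConfig, write_outputs: bool = True) -> dict:
    """Build the synthetic pilus model and compute its architecture statistics.

    Emits the layer screw parameters re-extracted from the built model,
    outer/lumen diameters, buried-surface table for an interior subunit
    and lipid, neighbor counts, and the lumen potential with and
    without the phospholipids.
    """
    import warnings

    from .interfaces import (
        buried_fraction,
        lumen_potential,
        neighbor_count,
        pairwise_buried_table,
        radial_geometry,
        structure_atoms,
    )
    from .model import build_full_pilus, propagate_strand, screw_from_chain_pair, write_structure
    from .symmetry import ScrewTransform
    from .synthetic_unit import make_pilin_unit

    bld = config.building
    t0 = time.time()
    unit = make_pilin_unit()
    screw = ScrewTransform.from_twist_rise(bld.twist_deg, bld.rise_A)
    strand = propagate_strand(unit, screw, bld.units_per_strand)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pilus, min_dist = build_full_pilus(strand, bld.cyclic_order)
    n_chains = len(list(pilus[0]))
    n_subunits = sum(1 for c in pilus[0] if c.name[0].isupper())
    back = screw_from_chain_pair(pilus, "A3", "A4")
    t_build = time.time() - t0
    _log(f"[build] {n_subunits} subunits in {n_chains} chains; min inter-strand distance {min_dist:.2f} A ({t_build:.0f}s)")

    t0 = time.time()
    atoms = structure_atoms(pilus)
    mid = bld.units_per_strand // 2
    ref_protein = f"C{mid}"
    ref_lipid = f"c{mid}"
    prof = radial_geometry(atoms)
    p_tot, p_bur, p_frac = buried_fraction(atoms, [ref_protein])
    l_tot, l_bur, l_frac = buried_fraction(atoms, [ref_lipid])
    table = pairwise_buried_table(atoms, ref_protein)
    n_nbr, nbr_ids = neighbor_count(atoms, ref_protein)
    n_lip_nbr, lip_ids = neighbor_count(atoms, ref_lipid)
    pot_with = lumen_potential(atoms, include_lipids=True)
    pot_without = lumen_potential(atoms, include_lipids=False)
    t_ana = time.time() - t0
    _log(f"[analyze] subunit buried {p_frac:.1%}, lipid buried {l_frac:.1%} ({t_ana:.0f}s)")

    protein_nbrs = [c for c in nbr_ids if c[0].isupper()]
    lipid_nbrs_of_protein = [c for c in nbr_ids if not c[0].isupper()]
    report = {
        "n_subunits": n_subunits,
        "residues_per_subunit": sum(1 for _ in pilus[0][ref_protein]),
        "layer_screw_twist_deg": back.angle_deg,
        "layer_screw_rise_A": back.axial_shift_A,
        "min_interstrand_distance_A": min_dist,
        "outer_diameter_A": prof.outer_diameter_A,
        "lumen_diameter_A": prof.lumen_diameter_A,
        "outer_diameter_vdw_A": prof.outer_diameter_vdw_A,
        "lumen_diameter_vdw_A": prof.lumen_diameter_vdw_A,
        "subunit_sasa_A2": p_tot,
        "subunit_buried_A2": p_bur,
        "subunit_buried_fraction": p_frac,
        "lipid_sasa_A2": l_tot,
        "lipid_buried_A2": l_bur,
        "lipid_buried_fraction": l_frac,
        "subunit_protein_buried_A2": table.protein_buried_A2(),
        "subunit_lipid_buried_A2": table.lipid_buried_A2(),
        "protein_neighbors": len(protein_nbrs),
        "lipid_neighbors_of_subunit": len(lipid_nbrs_of_protein),
        "subunits_contacting_lipid": len([c for c in lip_ids if c[0].isupper()]),
        "lumen_potential_with_lipid_kTe": pot_with.mean_lumen_potential,
        "lumen_potential_without_lipid_kTe": pot_without.mean_lumen_potential,
        "runtime_s": {"build": round(t_build, 1), "analyze": round(t_ana, 1)},
        "provenance": config.provenance(),
    }
    if write_outputs:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_structure(pilus, str(out / "pilus.cif"))
        table.to_frame().to_csv(out / "buried_areas.tsv", sep="\t", index=False)
        (out / "structure_report.json").write_text(json.dumps(report, indent=2))
    return report
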