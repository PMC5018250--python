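import warnings

import numpy as np
import pytest

from helifil.ctf import AcquisitionParams
from helifil.simulate import make_test_subunit, render_volume
from helifil.symmetry import HelicalSymmetry


@pytest.fixture(scope="session")
def ped208_sym() -> HelicalSymmetry:
    """pED208 pilus lattice: 28.2 deg twist, 12.1 A rise, C5."""
    return HelicalSymmetry(28.2, 12.1, 5)


@pytest.fixture(scope="session")
def template():
    return make_test_subunit(seed=1)


@pytest.fixture(scope="session")
def acq_desk() -> AcquisitionParams:
    """Desk-scale acquisition: 3 A pixels, otherwise 300 kV defaults."""
    return AcquisitionParams(pixel_size_A=3.0)


@pytest.fixture(scope="session")
def volume64(template, ped208_sym):
    """Small ground-truth filament volume (64 px, 3 A voxels)."""
    return render_volume(template, ped208_sym, 18, 64, 3.0, clip_z=True)


@pytest.fixture(scope="session")
def volume96(template, ped208_sym):
    """Full-size ground-truth filament volume (96 px, 3 A voxels)."""
    return render_volume(template, ped208_sym, 27, 96, 3.0, clip_z=True)


@pytest.fixture(scope="session")
def pilus_model():
    """Synthetic 5x16-unit pilus assembly (80 pilin+lipid copies)."""
    from helifil.model import build_full_pilus, propagate_strand
    from helifil.symmetry import ScrewTransform
    from helifil.synthetic_unit import make_pilin_unit

    unit = make_pilin_unit()
    strand = propagate_strand(unit, ScrewTransform.from_twist_rise(28.2, 12.1), 16)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pilus, _ = build_full_pilus(strand, 5)
    return pilus


@pytest.fixture(scope="session")
def pilus_atoms(pilus_model):
    from helifil.interfaces import structure_atoms

    return structure_atoms(pilus_model)


def corr(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    return float((a * b).sum() / denom) if denom > 0 else 0.0
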