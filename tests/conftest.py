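import numpy as np
import pytest

from allopath import structure_io as sio
from allopath import synthetic_data as sd


def make_topology(n_residues, atoms=("N", "CA", "C", "O", "CB"), chain="A",
                  resname="ALA"):
    """Uniform toy topology: n_residues × the given atom names."""
    top = []
    serial = 1
    for r in range(1, n_residues + 1):
        for name in atoms:
            element = "N" if name == "N" else "O" if name == "O" else "C"
            top.append(sio.AtomRecord(serial=serial, atom_name=name,
                                      element=element, residue_name=resname,
                                      chain_id=chain, residue_number=r))
            serial += 1
    return top


@pytest.fixture(scope="session")
def planted_dimer():
    """Fully persistent planted-path dimer, 10 frames."""
    spec = sd.default_planted_spec(persistence=1.0)
    ensemble, truth = sd.make_planted_path_dimer(spec, 10, seed=11)
    return spec, ensemble, truth


@pytest.fixture(scope="session")
def gnm_small():
    """25-residue GNM ensemble with its analytic correlation matrix."""
    spec = sd.GnmSpec(n_residues=25, n_frames=400, seed=5)
    ensemble, corr = sd.make_gnm_ensemble(spec)
    return spec, ensemble, corr


@pytest.fixture
def two_basin_ensemble():
    """Two conformational basins of 20 frames each; labels are ground truth."""
    rng = np.random.default_rng(42)
    base1 = rng.normal(size=(12, 3)) * 2.0
    base2 = rng.normal(size=(12, 3)) * 2.0
    frames = [base1 + rng.normal(size=(12, 3)) * 0.05 for _ in range(20)]
    frames += [base2 + rng.normal(size=(12, 3)) * 0.05 for _ in range(20)]
    top = make_topology(12, atoms=("CA",))
    return sio.Ensemble(top, np.array(frames)), np.array([0] * 20 + [1] * 20)
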