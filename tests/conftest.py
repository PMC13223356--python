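import numpy as np
import pytest

from cetpdyn import synthetic
from cetpdyn.trajectory import Frame, Structure, TrajectoryEnsemble


@pytest.fixture(scope="session")
def cylinder():
    """Hollow cylinder point cloud (r=0.5 nm, L=5 nm) with its analytic truth."""
    structure, scale, truth = synthetic.gen_tunnel_cloud(0.5, 5.0, 0.1, hydrophobicity=4.5)
    return structure, scale, truth


@pytest.fixture(scope="session")
def cylinder_ensemble(cylinder):
    structure, _, _ = cylinder
    return TrajectoryEnsemble(structure, [Frame(0.0, structure.coords0)], replicate="cyl")


@pytest.fixture(scope="session")
def oscillator_inphase():
    spec = synthetic.OscillatorSpec(n_frames=512, seed=11)
    return synthetic.gen_domain_trajectory(spec, "in_phase")


def toy_structure(coords, names=None, resids=None, resnames=None, elements=None):
    """Small hand-built Structure for geometric unit tests."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    names = np.array(names if names is not None else ["CA"] * n, dtype=object)
    resids = np.asarray(resids if resids is not None else np.arange(1, n + 1))
    resnames = np.array(resnames if resnames is not None else ["GLY"] * n, dtype=object)
    elements = np.array(elements if elements is not None else ["C"] * n, dtype=object)
    _, residue_index = np.unique(resids, return_inverse=True)
    return Structure(
        names=names,
        elements=elements,
        resids=resids.astype(int),
        resnames=resnames,
        chains=np.array(["A"] * n, dtype=object),
        residue_index=residue_index.astype(int),
        coords0=coords,
    )


def toy_ensemble(frames_coords, dt=10.0, **kwargs):
    """Ensemble from a list of coordinate arrays (times = i * dt ps)."""
    structure = toy_structure(frames_coords[0], **kwargs)
    frames = [Frame(i * dt, np.asarray(c, dtype=float)) for i, c in enumerate(frames_coords)]
    return TrajectoryEnsemble(structure, frames)
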