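import numpy as np
import pytest

import biotite.structure as struc

from crossbeta.builder import ScrewParameters, build_fibril


@pytest.fixture(scope="session")
def small_model():
    """A small full-length two-layer fibril (4 strands/layer, 2.0°/strand)."""
    return build_fibril(
        "human", n_per_layer=4, screw=ScrewParameters(twist=2.0), box_margin=12
    )


@pytest.fixture(scope="session")
def core_model():
    """Core-only (17-42) two-layer fibril, 6 strands/layer, untwisted."""
    return build_fibril(
        "human", n_per_layer=6, screw=ScrewParameters(twist=0.0),
        full_length=False, box_margin=10,
    )


def make_ca_trajectory(distances_by_frame, *, res_pair=(1, 42)):
    """Minimal single-strand CA-only trajectory with planted pair distances.

    ``distances_by_frame`` is an (n_frames, n_strands) array; strand s in
    frame f has its two CA atoms ``res_pair`` separated by exactly that
    distance along x.
    """
    import pandas as pd

    distances_by_frame = np.atleast_2d(np.asarray(distances_by_frame, float))
    n_frames, n_strands = distances_by_frame.shape
    n_atoms = 2 * n_strands
    atoms = struc.AtomArray(n_atoms)
    atoms.atom_name = np.array(["CA"] * n_atoms)
    atoms.element = np.array(["C"] * n_atoms)
    atoms.res_name = np.array(["GLY"] * n_atoms)
    atoms.res_id = np.array(list(res_pair) * n_strands)
    atoms.chain_id = np.array(
        [chr(ord("A") + s) for s in range(n_strands) for _ in range(2)]
    )
    atoms.hetero = np.zeros(n_atoms, bool)
    atoms.set_annotation(
        "strand_id", np.array([s for s in range(n_strands) for _ in range(2)])
    )
    coords = np.zeros((n_frames, n_atoms, 3))
    for f in range(n_frames):
        for s in range(n_strands):
            coords[f, 2 * s] = (0.0, 20.0 * s, 0.0)
            coords[f, 2 * s + 1] = (distances_by_frame[f, s], 20.0 * s, 0.0)
    atoms.coord = coords[0].copy()
    topology = pd.DataFrame(
        {
            "strand_id": np.arange(n_strands),
            "chain_id": [chr(ord("A") + s) for s in range(n_strands)],
            "layer": 1,
            "strand_index": np.arange(n_strands),
        }
    )
    from crossbeta.trajectory_io import Trajectory

    return Trajectory(coords=coords, atoms=atoms, topology=topology)
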