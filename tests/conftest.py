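"""Shared fixtures: hand-built micro-frames and synthetic toy trajectories."""

from __future__ import annotations

import numpy as np
import pytest

from ifacedyn.structure_io import AtomRecord, Frame, SelectionSpec, Trajectory
from ifacedyn import synthetic_data as synth


def make_atom(
    chain: str,
    seq: int,
    name: str,
    pos,
    resname: str = "ALA",
    serial: int = 1,
    element: str | None = None,
    water: bool = False,
) -> AtomRecord:
    if element is None:
        element = next(ch for ch in name if ch.isalpha()).upper()
    return AtomRecord(
        serial=serial,
        atom_name=name,
        element=element,
        residue_name="HOH" if water else resname,
        residue_seq=seq,
        chain_id=chain,
        position=np.asarray(pos, dtype=float),
        is_hydrogen=(element == "H"),
        is_water=water,
    )


def make_frame(atoms, **kwargs) -> Frame:
    for i, a in enumerate(atoms):
        a.serial = i + 1
    return Frame(list(atoms), **kwargs)


@pytest.fixture(scope="session")
def side_p() -> SelectionSpec:
    return SelectionSpec.chains("P")


@pytest.fixture(scope="session")
def side_h() -> SelectionSpec:
    return SelectionSpec.chains("H")


@pytest.fixture(scope="session")
def toy() -> tuple:
    """Deterministic 60-frame toy complex with the default bond schedules."""
    spec = synth.ToySpec(n_frames=60, seed=7)
    return synth.generate_toy_complex(spec)


@pytest.fixture(scope="session")
def toy_traj(toy) -> Trajectory:
    return toy[0]


@pytest.fixture(scope="session")
def toy_params(toy):
    return toy[1]


@pytest.fixture(scope="session")
def toy_truth(toy):
    return toy[2]


def random_rigid_transform(rng: np.random.Generator):
    """A random proper rotation + translation for invariance tests."""
    from scipy.spatial.transform import Rotation

    R = Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()
    t = rng.uniform(-20, 20, size=3)
    return R, t


def transform_frame(frame: Frame, R: np.ndarray, t: np.ndarray) -> Frame:
    return frame.with_coords(frame.coords @ R.T + t)
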