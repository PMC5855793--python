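"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from fibrilkit import (
    GeneratorParams,
    PlantedMode,
    Trajectory,
    generate_trajectory,
    make_cterminal_mode,
    sinusoid_amplitudes,
)
from fibrilkit.core import FibrilTopology


@pytest.fixture(scope="session")
def ideal_u() -> Trajectory:
    """Noise-free U-shaped pentamer, 3 identical frames."""
    return generate_trajectory(GeneratorParams(shape="U", n_frames=3))


@pytest.fixture(scope="session")
def ideal_s() -> Trajectory:
    return generate_trajectory(GeneratorParams(shape="S", n_frames=3))


@pytest.fixture(scope="session")
def noisy_u() -> Trajectory:
    """U-shaped pentamer with mild Gaussian disorder (σ = 0.02 nm)."""
    return generate_trajectory(
        GeneratorParams(shape="U", n_frames=30, noise_sigma=0.02, seed=42)
    )


@pytest.fixture(scope="session")
def planted_benchmark():
    """The FMA recovery benchmark: a C-terminal fraying mode drives ordP.

    1000 frames, coordinate noise σ = 0.01 nm, a 15° baseline stacking
    tilt (so the order parameter responds linearly to the mode), and a
    sinusoidal amplitude series on a rigid-projected C-terminal mode.
    """
    planted = make_cterminal_mode(5)
    mode = PlantedMode(
        directions=planted,
        amplitudes=sinusoid_amplitudes(1000, 0.25, cycles=3, jitter=0.01, seed=11),
    )
    traj = generate_trajectory(
        GeneratorParams(
            shape="U",
            n_frames=1000,
            noise_sigma=0.01,
            stack_tilt=15.0,
            planted_mode=mode,
            seed=7,
        )
    )
    return traj, planted


def make_toy_topology(
    atom_names, elements, residue_numbers, chain_ids, chain_order=None
) -> FibrilTopology:
    """Hand-built minimal topology for geometric toy fixtures."""
    chain_ids = np.asarray(chain_ids)
    if chain_order is None:
        chain_order = tuple(dict.fromkeys(chain_ids.tolist()))
    res_names = np.array(["ALA"] * len(atom_names))
    return FibrilTopology(
        atom_name=np.asarray(atom_names),
        element=np.asarray(elements),
        residue_number=np.asarray(residue_numbers),
        residue_name=res_names,
        chain_id=chain_ids,
        chain_order=chain_order,
    )
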