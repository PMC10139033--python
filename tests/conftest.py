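import numpy as np
import pytest

from funnelscreen.synthio import RigidMotion, TrajSimSpec, gen_trajectory

#: small dipeptide-plus-ligand topology used across trajectory tests
PEPTIDE_TEMPLATE = [
    (1, "ALA", "N", "N", True, 14.007),
    (1, "ALA", "CA", "C", True, 12.011),
    (1, "ALA", "CB", "C", False, 12.011),
    (1, "ALA", "C", "C", True, 12.011),
    (1, "ALA", "O", "O", True, 15.999),
    (2, "GLY", "N", "N", True, 14.007),
    (2, "GLY", "H", "H", False, 1.008),
    (2, "GLY", "CA", "C", True, 12.011),
    (2, "GLY", "C", "C", True, 12.011),
    (2, "GLY", "O", "O", True, 15.999),
    (3, "LIG", "C1", "C", False, 12.011),
    (3, "LIG", "O1", "O", False, 15.999),
]

PEPTIDE_COORDS = np.array(
    [
        [0.0, 0.0, 0.0],
        [1.46, 0.0, 0.0],
        [2.0, -1.2, 0.8],
        [2.2, 1.25, 0.1],
        [2.0, 2.4, 0.0],
        [3.5, 1.0, 0.3],
        [3.8, 0.05, 0.35],
        [4.8, 1.9, 0.4],
        [6.2, 1.6, 0.2],
        [7.0, 2.6, 0.1],
        [5.5, -1.5, 1.0],
        [6.5, -1.0, 0.5],
    ]
)


@pytest.fixture
def peptide_traj():
    """100-frame low-noise trajectory with a 60%-scheduled hydrogen bond
    (donor GLY N, hydrogen GLY H, acceptor LIG O1)."""
    spec = TrajSimSpec(
        n_frames=100,
        atom_template=PEPTIDE_TEMPLATE,
        reference_coords=PEPTIDE_COORDS,
        fluct_sd=0.03,
        hbond_schedule=[(5, 6, 11, 0.6)],
        seed=11,
    )
    return gen_trajectory(spec)


@pytest.fixture
def static_traj():
    """Noise-free, motion-free trajectory: every frame equals the reference."""
    spec = TrajSimSpec(
        n_frames=10,
        atom_template=PEPTIDE_TEMPLATE,
        reference_coords=PEPTIDE_COORDS,
        fluct_sd=0.0,
        seed=0,
    )
    return gen_trajectory(spec)


def rigid_motion_schedule(n_frames, seed=0, max_angle=0.5, max_shift=3.0):
    rng = np.random.default_rng(seed)
    return RigidMotion(
        translations=rng.uniform(-max_shift, max_shift, size=(n_frames, 3)),
        rotation_angles=rng.uniform(-max_angle, max_angle, size=n_frames),
        axis=(0.3, -0.5, 0.8),
    )
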