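import pytest

from allodyn import SyntheticSpec, generate_trajectory
from allodyn.trajectory_io import frame_set_from_coords as make_frame_set

__all__ = ["make_frame_set"]


@pytest.fixture(scope="session")
def small_dimer():
    """A quick 60-residue, 100-frame toy dimer with its planted truth."""
    spec = SyntheticSpec(n_res_per_domain=10, n_frames=100, seed=7)
    ens, truth = generate_trajectory(spec)
    return spec, ens, truth
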