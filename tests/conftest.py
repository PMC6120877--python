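import pytest
from hypothesis import HealthCheck, settings

from waterdyn import ReferenceFrameSpec, ShellSimConfig, generate_shell_trajectory

settings.register_profile(
    "deterministic",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def asp_spec() -> ReferenceFrameSpec:
    """Frame spec matching the synthetic anchor residue layout."""
    return ReferenceFrameSpec(
        residue=("A", 1),
        z_subset=("CB", "CG", "OD1", "OD2"),
        x_subset=("OD1", "OD2"),
        neighbor_residue=("A", 2),
    )


@pytest.fixture(scope="session")
def shell_run():
    """A moderately sized shell simulation shared across test modules."""
    cfg = ShellSimConfig(
        n_waters=50,
        n_frames=6000,
        timestep=0.5,
        tau_res=10.0,
        tau_rot=4.0,
        n_shell_slots=6,
        seed=42,
    )
    traj, log = generate_shell_trajectory(cfg)
    return cfg, traj, log
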