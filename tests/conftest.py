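import numpy as np
import pytest

from magnetochain import ModelParams, ParticleState, SystemState


@pytest.fixture
def params() -> ModelParams:
    """Default magnetite/Magnetospirillum parameterisation."""
    return ModelParams()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20318)


def make_particle(position, direction=(1.0, 0.0, 0.0), radius=20.0,
                  moment=None, bound=False) -> ParticleState:
    if moment is None:
        moment = ModelParams().dipole_moment
    return ParticleState(position=np.asarray(position, float),
                         moment_direction=np.asarray(direction, float),
                         radius=radius, moment_magnitude=moment, bound=bound)


def random_state(n: int, params: ModelParams, rng: np.random.Generator,
                 spread: float = 400.0) -> SystemState:
    """Non-overlapping random particles in a blob, random moments,
    random bound flags (used by energy-consistency tests)."""
    positions = []
    while len(positions) < n:
        cand = rng.uniform(-spread, spread, size=3)
        rho = np.hypot(cand[1], cand[2])
        if rho < params.particle_radius + params.membrane_gap / 2.0:
            continue
        if all(np.linalg.norm(cand - q) >= params.contact_distance
               for q in positions):
            positions.append(cand)
    dirs = rng.normal(size=(n, 3))
    dirs /= np.linalg.norm(dirs, axis=1)[:, None]
    return SystemState(
        positions=np.array(positions),
        moment_dirs=dirs,
        moment_mags=np.full(n, params.dipole_moment),
        radii=np.full(n, params.particle_radius),
        bound=rng.random(n) < 0.5,
        field_mT=np.array([10.0, 5.0, 0.0]),
    )
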