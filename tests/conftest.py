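import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


def propagate_chunked(potential, params, total_steps, seed, start=None):
    """Chain propagate() calls so long runs never materialize a huge noise
    array; returns the concatenated CV series (first frame once)."""
    from pacsfe.model_system import EngineState, propagate

    n_chunks = max(int(np.ceil(total_steps / params.n_steps)), 1)
    pos = np.zeros(potential.dimension) if start is None else np.asarray(start, float)
    cvs = []
    t = 0.0
    for c in range(n_chunks):
        seg = propagate(
            potential, EngineState(position=pos, time=t), params, rng_seed=[seed, c]
        )
        cvs.append(seg.cv if c == 0 else seg.cv[1:])
        pos = seg.final_position
        t = seg.times[-1]
    return np.concatenate(cvs)


@pytest.fixture
def random_solvated_factory():
    """Seeded random solvated toy structures for the counting oracles."""
    from pacsfe.model_system import BeadSet, SolvatedSystemSpec, generate_solvated_structure

    def build(seed: int, multipliers=(1.0, 1.0), water_count=400, box=32.0):
        rng = np.random.default_rng(seed)
        centers_a = rng.uniform(10, box - 10, size=(3, 3))
        centers_b = rng.uniform(10, box - 10, size=(3, 3))
        spec = SolvatedSystemSpec(
            solute_bead_sets=(
                BeadSet("A", centers_a, 1.0),
                BeadSet("B", centers_b, 1.0),
            ),
            box=[box] * 3,
            water_count=water_count,
            shell_density_multipliers=multipliers,
            seed=seed,
        )
        return generate_solvated_structure(spec)

    return build
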