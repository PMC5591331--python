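import numpy as np
import pytest

import stepwave as sw


@pytest.fixture(scope="session")
def treadmill_seed1():
    """Default treadmill simulation, seed 1 (shared, read-only)."""
    return sw.simulate_treadmill(sw.GaitSimParams(seed=1))


def make_turn_script(rng: np.random.Generator, n_turns: int = 22,
                     gap: float = 12.0, t0: float = 8.0):
    """Scripted alternating-direction turns of 95-180 degrees, 1-4 s."""
    turns = []
    pos = t0
    for _ in range(n_turns):
        dur = float(rng.uniform(1.0, 4.0))
        exc = float(rng.choice([-1, 1]) * rng.uniform(95.0, 180.0))
        turns.append(sw.TurnInterval(pos, pos + dur, exc))
        pos += gap
    return tuple(turns)


@pytest.fixture(scope="session")
def homelike_seed2():
    """Home-like session with scripted turns, seed 2 (shared, read-only)."""
    rng = np.random.default_rng(1002)
    script = make_turn_script(rng)
    params = sw.GaitSimParams(duration=float(np.ceil(script[-1].end + 10)),
                              fs=128.0, seed=2, turn_script=script)
    return sw.simulate_homelike(params)
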