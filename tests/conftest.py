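import numpy as np
import pytest

from gazedev import GazePair, GazeSession, ProtocolConfig
from gazedev.simulate import CohortSpec, simulate_cohort


def random_session(
    rng: np.random.Generator,
    n_pairs_per_target: int = 10,
    spread: float = 0.3,
    subject_id: str = "rand",
) -> GazeSession:
    """A session of uniformly scattered gaze points around each target.

    Bypasses the acquisition simulator on purpose: tests that compare the
    rasterizer or effectiveness rule against brute-force oracles need inputs
    that are not themselves shaped by the code under test.
    """
    protocol = ProtocolConfig()
    pairs = []
    for t in protocol.targets:
        tx, ty = t.position
        for i in range(1, n_pairs_per_target + 1):
            lx, ly, rx, ry = (float(v) for v in rng.uniform(-spread, spread, size=4))
            pairs.append(
                GazePair(
                    target_index=t.index,
                    sample_index=i,
                    left=(tx + lx, ty + ly),
                    right=(tx + rx, ty + ry),
                    timestamp=i / protocol.sampling_rate,
                )
            )
    return GazeSession(subject_id=subject_id, pairs=pairs, protocol=protocol)


@pytest.fixture(scope="session")
def protocol() -> ProtocolConfig:
    return ProtocolConfig()


@pytest.fixture(scope="session")
def separable_cohort():
    """25 normal vs 17 manifest/intermittent subjects with strong deviations.

    Deviation magnitudes of at least 0.15 normalized units against fixation
    noise of at most 0.02: separable by construction, so both classifiers
    are expected to be near-perfect on it.
    """
    return simulate_cohort(CohortSpec.separable(seed=7))
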