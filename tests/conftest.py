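import numpy as np
import pytest

import bindevol as bv


@pytest.fixture(scope="session")
def small_cohort():
    """Default-condition cohort, small enough for unit tests."""
    cfg = bv.SimulationConfig(n_pairs=200, seq_length=300, seed=1)
    return bv.generate_cohort(cfg)


@pytest.fixture(scope="session")
def twi_pwm():
    return bv.default_pwms()["Twi"]


def random_sequences(rng, n, length, pwm=None, max_sites=0):
    """Uniform-background sequences, optionally with planted PWM matches."""
    seqs = []
    for _ in range(n):
        seq = rng.integers(0, 4, size=length)
        if pwm is not None and max_sites:
            L = len(pwm)
            for _ in range(rng.integers(0, max_sites + 1)):
                pos = rng.integers(0, length - L + 1)
                seq[pos : pos + L] = [
                    rng.choice(4, p=pwm.probs[k]) for k in range(L)
                ]
        seqs.append("".join("ACGT"[b] for b in seq))
    return seqs
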