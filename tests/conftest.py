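import numpy as np
import pytest

import km2ipd as k


@pytest.fixture
def worked_ipd():
    """Four-patient worked example: events at 1, 2, 4; censored at 3."""
    return k.make_ipd([1, 2, 3, 4], [1, 1, 0, 1])


@pytest.fixture
def sim_arm():
    """One moderately sized exponential arm with light dropout."""
    cfg = k.SimTrialConfig(
        arms=(k.ArmSpec("a", 0.01, 400),),
        censor_hazard=0.01,
        admin_censor_time=30.0,
        risk_interval=6.0,
        seed=123,
    )
    return k.simulate_ipd(cfg), cfg


def write_csv(path, rows, header="time,survival"):
    lines = [header] if header else []
    lines += [",".join(str(v) for v in r) for r in rows]
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def csv_writer():
    return write_csv


def seeded_rng(seed=0):
    return np.random.default_rng(seed)
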