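from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort shared by read-only tests."""
    from cnvresp.simulate import SimConfig, simulate_cohort

    return simulate_cohort(SimConfig())


@pytest.fixture()
def table1_calls():
    """Three carriers whose boundaries reproduce the published 2q14.3 geometry:
    one whole-region call plus two calls starting at the interior boundaries."""
    from cnvresp.hmm import CnvCall

    return [
        CnvCall("A", "2", 129_457_798, 129_461_606, 1, 5),
        CnvCall("B", "2", 129_458_197, 129_461_606, 1, 5),
        CnvCall("C", "2", 129_459_141, 129_461_606, 1, 4),
    ]


@pytest.fixture()
def random_probe_signals():
    """Factory for random single-chromosome probe signals."""
    from cnvresp.hmm import ProbeInfo, ProbeSignal

    def make(rng: np.random.Generator, n: int) -> list[ProbeSignal]:
        pos = np.sort(rng.choice(np.arange(1, 10_000_000, 1000), size=n, replace=False))
        return [
            ProbeSignal(
                ProbeInfo(f"p{i}", "1", int(pos[i]), float(rng.uniform(0.05, 0.95))),
                float(rng.normal(0.0, 1.0)),
                float(rng.uniform(0.0, 1.0)),
            )
            for i in range(n)
        ]

    return make
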