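"""Shared fixtures: a session-wide cache of Monte-Carlo scenario runs.

The calibration/power checks examine many cells of the same scenario
runs, so results are computed once per (n, maf, a, noise, null)
combination and reused.  Seeds are derived deterministically from the
scenario parameters.
"""

import zlib

import pytest

from xvartest import ScenarioSpec, run_scenario


def scenario_seed(n, maf, a, noise, null) -> int:
    key = f"scenario:{n}:{maf}:{a}:{noise}:{int(null)}"
    return zlib.crc32(key.encode()) % (2**31)


@pytest.fixture(scope="session")
def scenario_cache():
    cache = {}

    def get(n, maf=0.3, a=0.0, noise=0.0, null=False, replicates=20_000):
        key = (n, maf, a, noise, null, replicates)
        if key not in cache:
            cache[key] = run_scenario(
                ScenarioSpec(
                    n=n,
                    maf=maf,
                    a=a,
                    extra_noise_frac=noise,
                    null_model=null,
                    replicates=replicates,
                    seed=scenario_seed(n, maf, a, noise, null),
                )
            )
        return cache[key]

    return get
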