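"""Shared fixtures: one small and one default-size synthetic time course.

Both are generated fresh from the seed at session start; nothing is stored
on disk.  The small fixture keeps per-test runtimes low; the default-size
fixture carries the planted structure at the scale the recovery tests were
designed for.
"""

import pytest

from hemodyn.simulate import FixtureConfig, generate_fixture

SMALL_PATTERN_COUNTS = {
    "111111": 80, "100000": 60, "000001": 60, "000110": 40, "001000": 40,
    "010000": 30, "000100": 30, "011111": 20, "000011": 20, "110000": 20,
}


def small_config(**overrides) -> FixtureConfig:
    base = dict(
        seed=7,
        chrom_length=1_200_000,
        n_genes=60,
        n_flat_genes=11,
        dhs_pattern_counts=dict(SMALL_PATTERN_COUNTS),
        reprogramming_plan={
            "Tal1": (("HB", 8),), "Lmo2": (("HB", 8),),
            "Gata2": (("HB", 2),), "Fli1": (("HE", 3),),
        },
        n_blood_targets=8,
        deterministic_tracks=True,
    )
    base.update(overrides)
    return FixtureConfig(**base)


@pytest.fixture(scope="session")
def small_fixture():
    return generate_fixture(small_config())


@pytest.fixture(scope="session")
def default_fixture():
    """Default-size zero-noise fixture (2,000 distal DHS, 200 genes)."""
    return generate_fixture(FixtureConfig(seed=1))
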