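"""Shared plumbing for the numbered analysis drivers.

Every driver regenerates the default fixture in memory from a fixed seed
(about one second) rather than reading intermediate files, so each script
can be run on its own.
"""

from pathlib import Path

from hemodyn import dhs as D
from hemodyn.intervals import STAGES
from hemodyn.simulate import FixtureConfig, Fixture, generate_fixture

RESULTS = Path(__file__).resolve().parent.parent / "results"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch"
FIXTURE_SEED = 1


def get_fixture(**overrides) -> Fixture:
    cfg = FixtureConfig(seed=FIXTURE_SEED, **overrides)
    return generate_fixture(cfg)


def reproducible_stage_sets(fx: Fixture) -> dict:
    return {s: D.filter_reproducible(fx.dhs_replicates(s)) for s in STAGES}


def pattern_table(fx: Fixture, classify: bool = True):
    table = D.encode_patterns(reproducible_stage_sets(fx))
    if classify:
        table = D.classify_proximal_distal(table, fx.genes)
    return table


def ensure_dirs() -> None:
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(exist_ok=True)
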