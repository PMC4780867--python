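"""DHS reproducibility filtering, binary pattern encoding, census."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hemodyn import dhs as D
from hemodyn.intervals import STAGES, GeneModel, GenomicInterval


def iv(s, e, chrom="chr1"):
    return GenomicInterval(chrom, s, e)


def _bp_support_oracle(replicates, min_support=2):
    """Per-bp replicate support via a dense array (small coordinates only)."""
    hi = max(v.end for r in replicates for v in r)
    depth = np.zeros(hi + 1, dtype=int)
    for r in replicates:
        cov = np.zeros(hi + 1, dtype=bool)
        for v in r:
            cov[v.start:v.end] = True
        depth += cov
    return depth >= min_support


def test_filter_reproducible_examples():
    both = D.filter_reproducible([[iv(10, 50)], [iv(30, 80)]])
    assert both == [iv(10, 80)]                     # union extent retained
    assert D.filter_reproducible([[iv(10, 50)], [iv(100, 120)]]) == []
    three = D.filter_reproducible([[iv(10, 50)], [iv(30, 80)], [iv(500, 600)]])
    assert three == [iv(10, 80)]                    # 2 of 3 suffices
    with pytest.raises(ValueError):
        D.filter_reproducible([[iv(10, 50)]])


def test_filter_reproducible_matches_bp_support_oracle():
    rng = np.random.default_rng(3)
    for _ in range(20):
        reps = []
        for _r in range(3):
            starts = np.sort(rng.integers(0, 2_000, size=8))
            reps.append([iv(int(s), int(s) + int(rng.integers(20, 120)))
                         for s in starts])
        got = D.filter_reproducible(reps)
        support = _bp_support_oracle(reps)
        from hemodyn.intervals import sort_merge
        union = sort_merge([v for r in reps for v in r])
        expected = [u for u in union if support[u.start:u.end].any()]
        assert got == expected


def _stage_sets(present: dict[str, list[GenomicInterval]]):
    return {s: present.get(s, []) for s in STAGES}


def test_encode_patterns_codes():
    always = iv(100, 200)
    esc_only = iv(1_000, 1_100)
    he_hp = iv(5_000, 5_200)
    sets = _stage_sets({
        "ESC": [always, esc_only], "MES": [always], "HB": [always],
        "HE": [always, he_hp], "HP": [always, he_hp], "MAC": [always],
    })
    table = D.encode_patterns(sets)
    codes = dict(zip(zip(table["start"], table["end"]), table["code"]))
    assert codes[(100, 200)] == "111111"
    assert codes[(1_000, 1_100)] == "100000"
    assert codes[(5_000, 5_200)] == "000110"


def test_encode_patterns_order_invariant_and_missing_stage():
    sets = _stage_sets({"ESC": [iv(0, 10)], "MAC": [iv(50, 60)]})
    a = D.encode_patterns(sets)
    b = D.encode_patterns(dict(reversed(list(sets.items()))))
    assert a.equals(b)
    with pytest.raises(ValueError, match="missing stage"):
        D.encode_patterns({"ESC": []})


@settings(max_examples=30, derandomize=True)
@given(st.lists(st.integers(0, 50), min_size=0, max_size=8))
def test_bit_monotonicity_when_adding_peaks(extra_starts):
    """Adding peaks to one stage can only flip bits 0 -> 1."""
    base = _stage_sets({"ESC": [iv(100, 140)], "HB": [iv(100, 130), iv(400, 440)]})
    before = D.encode_patterns(base)
    richer = dict(base)
    richer["HB"] = richer["HB"] + [iv(1_000 + 60 * s, 1_030 + 60 * s)
                                   for s in extra_starts]
    after = D.encode_patterns(richer)
    merged_before = {(r.chrom, r.start, r.end): r.code for r in before.itertuples()}
    for r in after.itertuples():
        old = merged_before.get((r.chrom, r.start, r.end))
        if old is not None:
            for ob, nb in zip(old, r.code):
                assert not (ob == "1" and nb == "0")


def _genes():
    return [
        GeneModel("A", "chr1", "+", 10_000, iv(10_000, 14_000)),
        GeneModel("B", "chr1", "+", 80_000, iv(80_000, 84_000)),
    ]


def test_classify_proximal_distal_boundary_inclusive():
    table = pd.DataFrame({
        "chrom": ["chr1"] * 3,
        "start": [9_950, 10_800, 50_000],
        "end": [10_050, 11_200, 50_100],
        "code": ["111111"] * 3,
    })
    out = D.classify_proximal_distal(table, _genes())
    assert list(out["klass"]) == ["proximal", "proximal", "distal"]
    assert out.loc[0, "distance"] == 0
    assert abs(out.loc[1, "distance"]) == 1_000      # boundary -> proximal
    assert out.loc[2, "nearest_gene"] == "B"   # 29,950 bp to B vs 40,050 to A


def test_pattern_census_counts_and_strict_eligibility():
    table = pd.DataFrame({
        "chrom": "chr1", "start": range(250), "end": range(1, 251),
        "code": ["100000"] * 101 + ["000001"] * 100 + ["111111"] * 49,
    })
    census = D.pattern_census(table)
    as_map = census.set_index("code")
    assert as_map.loc["100000", "count"] == 101
    assert bool(as_map.loc["100000", "eligible"])
    assert not bool(as_map.loc["000001", "eligible"])   # exactly 100: excluded
    assert census["count"].sum() == len(table)
    assert len(D.pattern_census(table.iloc[:0])) == 0


def test_unique_stage_dhs_selection():
    table = pd.DataFrame({
        "chrom": "chr1", "start": [0, 10, 20], "end": [5, 15, 25],
        "code": ["001000", "111111", "001000"],
        "klass": ["distal", "distal", "proximal"],
    })
    out = D.unique_stage_dhs(table, "HB", "ESC")
    assert list(out["start"]) == [0]                 # distal HB-unique only
    assert len(D.unique_stage_dhs(table, "ESC", "HB")) == 0
    both = D.unique_stage_dhs(table, "HB", "ESC", distal_only=False)
    assert len(both) == 2
    with pytest.raises(ValueError):
        D.unique_stage_dhs(table, "HB", "HB")


def test_fixture_census_matches_manifest(small_fixture):
    from hemodyn.simulate import manifest_census

    fx = small_fixture
    stage_sets = {s: D.filter_reproducible(fx.dhs_replicates(s)) for s in STAGES}
    table = D.encode_patterns(stage_sets)
    census = D.pattern_census(table).set_index("code")["count"].sort_index()
    truth = manifest_census(fx.manifest)["dhs_patterns"].set_index(
        "code")["count"].sort_index()
    assert census.equals(truth)
    # unique-stage rows match a set-algebra recount from the manifest
    table = D.classify_proximal_distal(table, fx.genes)
    got = len(D.unique_stage_dhs(table, "HB", "MAC"))
    truth_rows = [r for r in fx.manifest["dhs"]
                  if r["code"][2] == "1" and r["code"][5] == "0"
                  and r["kind"] == "distal"]
    assert got == len(truth_rows)
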