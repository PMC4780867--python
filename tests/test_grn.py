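"""Stage GRN assembly, rewiring dynamics, reprogramming ranking."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from hemodyn import dhs as D
from hemodyn import grn as G
from hemodyn.enrichment import RegulatoryDomain
from hemodyn.intervals import STAGES, GeneModel, GenomicInterval


def _panel():
    genes = {
        "Tfa": GeneModel("Tfa", "chr1", "+", 100_000,
                         GenomicInterval("chr1", 100_000, 104_000)),
        "Tfb": GeneModel("Tfb", "chr1", "+", 300_000,
                         GenomicInterval("chr1", 300_000, 304_000)),
    }
    domains = {
        "Tfa": RegulatoryDomain("Tfa", "chr1", 0, 200_000),
        "Tfb": RegulatoryDomain("Tfb", "chr1", 200_000, 500_000),
    }
    avail = {"Tfa": ("HB",), "Tfb": ()}
    return genes, domains, avail


def test_build_stage_grn_edges_and_gating():
    genes, domains, avail = _panel()
    peaks = {
        "Tfa": [GenomicInterval("chr1", 301_000, 301_200),   # in Tfb's window
                GenomicInterval("chr1", 100_500, 100_700)],  # self locus
        "Tfb": [GenomicInterval("chr1", 100_500, 100_700)],  # no ChIP: ignored
    }
    g = G.build_stage_grn(
        "HB", peaks, genes, tf_panel=["Tfa", "Tfb"],
        chip_availability=avail, domains=domains)
    assert set(g.edges) == {("Tfa", "Tfb"), ("Tfa", "Tfa")}
    assert g.edges["Tfa", "Tfb"]["n_peaks"] == 1
    assert g.nodes["Tfb"]["has_chip_data"] is False
    assert g.out_degree("Tfb") == 0


def test_build_stage_grn_clips_window_at_domain_boundary():
    genes, domains, avail = _panel()
    # peak within span+50kb of Tfb but outside Tfb's domain (< 200 kb)
    peaks = {"Tfa": [GenomicInterval("chr1", 190_000, 190_200)]}
    g = G.build_stage_grn("HB", peaks, genes, tf_panel=["Tfa", "Tfb"],
                          chip_availability=avail, domains=domains)
    assert ("Tfa", "Tfb") not in g.edges


def test_build_stage_grn_requires_panel_genes():
    genes, domains, avail = _panel()
    with pytest.raises(ValueError, match="absent from gene models"):
        G.build_stage_grn("HB", {}, genes, tf_panel=["Ghost"],
                          chip_availability=avail)


def test_edges_monotone_in_peaks():
    genes, domains, avail = _panel()
    peaks = {"Tfa": [GenomicInterval("chr1", 301_000, 301_200),
                     GenomicInterval("chr1", 100_500, 100_700)]}
    full = G.build_stage_grn("HB", peaks, genes, tf_panel=["Tfa", "Tfb"],
                             chip_availability=avail, domains=domains)
    fewer = G.build_stage_grn("HB", {"Tfa": peaks["Tfa"][:1]}, genes,
                              tf_panel=["Tfa", "Tfb"],
                              chip_availability=avail, domains=domains)
    assert set(fewer.edges) <= set(full.edges)


def _toy_grns(edge_plan):
    """Six stage graphs over a fixed 2-TF panel from {stage: edges}."""
    out = []
    for s in STAGES:
        g = nx.DiGraph(stage=s)
        g.add_nodes_from(["Tfa", "Tfb"])
        g.add_edges_from(edge_plan.get(s, []))
        out.append(g)
    return out


def test_grn_dynamics_gain_loss():
    same = _toy_grns({s: [("Tfa", "Tfb")] for s in STAGES})
    dyn = G.grn_dynamics(same)
    assert all(len(r) == 0 for r in dyn["gained"]) and all(
        len(r) == 0 for r in dyn["lost"])
    hp_only = _toy_grns({"HP": [("Tfa", "Tfb")]})
    dyn = G.grn_dynamics(hp_only)
    as_map = dyn.set_index("transition")
    assert as_map.loc["T4", "gained"] == [("Tfa", "Tfb")]
    assert as_map.loc["T5", "lost"] == [("Tfa", "Tfb")]
    # conservation: retained + gained = out-edges at stage k
    for k in range(1, 6):
        row = dyn.iloc[k - 1]
        assert len(row["retained"]) + len(row["gained"]) == hp_only[k].number_of_edges()
    with pytest.raises(ValueError):
        G.grn_dynamics(hp_only[:3])
    bad = _toy_grns({})
    bad[2].add_node("Intruder")
    with pytest.raises(ValueError, match="panels"):
        G.grn_dynamics(bad)


def test_rank_reprogramming_order_and_exclusions():
    expr = pd.DataFrame(
        {
            "Tfa": [0.1, 0.2, 5, 6, 7, 8],      # activates at HB
            "Tfb": [0.1, 0.1, 0.1, 4, 5, 6],    # activates at HE
            "Tfc": [0.1, 0.2, 5, 6, 7, 8],      # ties with Tfa on both keys
            "Off": [0.1] * 6,                   # never above floor
        },
        index=list(STAGES),
    ).T
    targets = [f"B{i}" for i in range(4)]
    domains = {t: RegulatoryDomain(t, "chr1", 10_000 * i, 10_000 * (i + 1))
               for i, t in enumerate(targets)}
    def pk(i):
        return GenomicInterval("chr1", 10_000 * i + 100, 10_000 * i + 200)
    peaks = {
        "HB": {"Tfa": [pk(0), pk(1), pk(2)], "Tfc": [pk(0), pk(1), pk(2)]},
        "HE": {"Tfb": [pk(0)]},
    }
    grns = _toy_grns({})
    for g in grns:
        g.add_nodes_from(["Tfa", "Tfb", "Tfc", "Off"])
    out = G.rank_reprogramming_candidates(grns, expr, targets, peaks, domains)
    assert list(out["tf"]) == ["Tfa", "Tfc", "Tfb"]     # tie -> lexicographic
    assert list(out["n_targets_bound"]) == [3, 3, 1]
    assert "Off" not in set(out["tf"])
    with pytest.raises(ValueError):
        G.rank_reprogramming_candidates(grns, expr, [], peaks, domains)


def test_fixture_stage_graphs_match_planted_truth(small_fixture):
    fx = small_fixture
    dom = {d.gene_id: d for d in fx.domains}
    panel = fx.config.tf_panel
    grns = []
    for stage in STAGES:
        tf_sets = {
            tf: D.filter_reproducible(fx.tf_replicates(tf, stage))
            for tf in panel
            if stage in fx.config.chip_availability.get(tf, ())
        }
        grns.append(G.build_stage_grn(
            stage, tf_sets, fx.gene_models, tf_panel=panel,
            chip_availability=fx.config.chip_availability,
            promoter_states=fx.promoter_plan, expression=fx.expression,
            domains=dom))
    got = {(u, v, g.graph["stage"]) for g in grns for u, v in g.edges}
    assert got == set(fx.config.grn_truth)
    # node annotations carried through
    hb = grns[2]
    assert hb.nodes["Tal1"]["promoter_state"] == "ACTIVE"
    assert hb.nodes["Tal1"]["expression"] == pytest.approx(
        fx.expression.loc["Tal1", "HB"])


def test_graphml_round_trip_preserves_annotations(small_fixture, tmp_path):
    from hemodyn.intervals import read_graphml, write_graphml

    fx = small_fixture
    g = G.build_stage_grn(
        "HB",
        {tf: fx.tf_peaks.get((tf, "HB"), []) for tf in fx.config.tf_panel},
        fx.gene_models, tf_panel=fx.config.tf_panel,
        chip_availability=fx.config.chip_availability,
        promoter_states=fx.promoter_plan, expression=fx.expression,
        domains={d.gene_id: d for d in fx.domains})
    p = tmp_path / "hb.graphml"
    write_graphml(g, p)
    back = read_graphml(p)
    assert set(back.edges) == set(g.edges)
    for n in g.nodes:
        for key, val in g.nodes[n].items():
            assert back.nodes[n][key] == val
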