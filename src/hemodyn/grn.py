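"""Stage-resolved TF->TF core regulatory network assembly and analysis.

Each stage graph has one node per panel TF, annotated with its expression
level, promoter accessibility and four-state promoter chromatin label.  A
directed edge source -> target exists when the source TF has ChIP data at
that stage and at least one reproducible peak midpoint falls inside the
target gene's locus window (gene span +/- a flank, clipped at the target's
regulatory-domain boundary so each peak supports at most one target).
Self-edges record autoregulation.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd

from .chromstate import LETTER_COARSE, MISSING_LETTER
from .enrichment import RegulatoryDomain
from .intervals import STAGES, GeneModel, GenomicInterval, stage_index

log = logging.getLogger(__name__)

#: Default flank around the gene span for peak-to-locus assignment (bp).
#: The single most consequential free parameter of the network build.
DEFAULT_LOCUS_FLANK = 50_000


def _locus_window(
    gene: GeneModel, domain: RegulatoryDomain | None, flank: int
) -> tuple[int, int]:
    lo = gene.span.start - flank
    hi = gene.span.end + flank
    if domain is not None:
        lo = max(lo, domain.start)
        hi = min(hi, domain.end)
    return max(0, lo), hi


def build_stage_grn(
    stage: str,
    tf_peak_sets: Mapping[str, Sequence[GenomicInterval]],
    gene_models: Mapping[str, GeneModel],
    *,
    tf_panel: Sequence[str],
    chip_availability: Mapping[str, Sequence[str]],
    promoter_states: Mapping[str, str] | None = None,
    dhs_table: pd.DataFrame | None = None,
    expression: pd.DataFrame | None = None,
    domains: Mapping[str, RegulatoryDomain] | None = None,
    locus_flank: int = DEFAULT_LOCUS_FLANK,
    require_dhs: bool = False,
) -> nx.DiGraph:
    """Assemble the TF->TF graph for one developmental stage.

    ``tf_peak_sets`` maps TF name to its reproducible peaks at this stage
    (only TFs with ChIP data listed in ``chip_availability`` contribute
    edges).  ``promoter_states`` maps gene id to its six-letter timeline;
    ``dhs_table`` supplies promoter DHS presence; ``expression`` the FPKM
    matrix.  With ``require_dhs`` the supporting peak must additionally
    overlap a union DHS open at this stage.
    """
    s_idx = stage_index(stage)
    for tf in tf_panel:
        if tf not in gene_models:
            raise ValueError(f"panel TF {tf!r} absent from gene models")
    g = nx.DiGraph(stage=stage)

    open_rows = None
    if dhs_table is not None:
        open_rows = dhs_table[dhs_table["code"].str[s_idx] == "1"]

    def promoter_open(gene: GeneModel) -> bool:
        if open_rows is None:
            return False
        win = gene.promoter()
        sel = (
            (open_rows["chrom"] == win.chrom)
            & (open_rows["start"] < win.end)
            & (open_rows["end"] > win.start)
        )
        return bool(sel.any())

    for tf in tf_panel:
        gene = gene_models[tf]
        timeline = (promoter_states or {}).get(tf, MISSING_LETTER * len(STAGES))
        letter = timeline[s_idx] if s_idx < len(timeline) else MISSING_LETTER
        expr = float("nan")
        if expression is not None and tf in expression.index:
            expr = float(expression.loc[tf, stage])
        g.add_node(
            tf,
            expression=expr,
            promoter_dhs=promoter_open(gene),
            promoter_state=LETTER_COARSE.get(letter, "MISSING"),
            has_chip_data=stage in set(chip_availability.get(tf, ())),
        )

    for source in tf_panel:
        if not g.nodes[source]["has_chip_data"]:
            continue
        peaks = tf_peak_sets.get(source, ())
        for target in tf_panel:
            gene = gene_models[target]
            dom = domains.get(target) if domains is not None else None
            lo, hi = _locus_window(gene, dom, locus_flank)
            support = [
                pk for pk in peaks
                if pk.chrom == gene.chrom and lo <= pk.midpoint < hi
            ]
            if require_dhs and open_rows is not None:
                support = [
                    pk for pk in support
                    if (
                        (open_rows["chrom"] == pk.chrom)
                        & (open_rows["start"] < pk.end)
                        & (open_rows["end"] > pk.start)
                    ).any()
                ]
            if support:
                g.add_edge(
                    source, target,
                    n_peaks=len(support),
                    peaks=";".join(f"{p.chrom}:{p.start}-{p.end}" for p in support),
                )
    return g


def grn_dynamics(grns: Sequence[nx.DiGraph]) -> pd.DataFrame:
    """Edge gain/loss/retention per transition over the six stage graphs.

    Returns one row per transition with the gained, lost and retained edge
    sets plus per-stage out-degree trajectories available via the graphs
    themselves.  All graphs must share the same node panel.
    """
    if len(grns) != len(STAGES):
        raise ValueError(f"expected {len(STAGES)} stage graphs")
    panels = [tuple(sorted(g.nodes)) for g in grns]
    if len(set(panels)) != 1:
        raise ValueError("stage graphs built on different TF panels")
    rows = []
    for k in range(1, len(grns)):
        prev = set(grns[k - 1].edges)
        curr = set(grns[k].edges)
        rows.append({
            "transition": f"T{k}",
            "from_stage": STAGES[k - 1],
            "to_stage": STAGES[k],
            "gained": sorted(curr - prev),
            "lost": sorted(prev - curr),
            "retained": sorted(curr & prev),
        })
    return pd.DataFrame(rows)


def degree_trajectories(grns: Sequence[nx.DiGraph]) -> pd.DataFrame:
    """In/out-degree of every panel TF at every stage."""
    rows = []
    for g in grns:
        stage = g.graph.get("stage")
        for tf in g.nodes:
            rows.append({
                "tf": tf, "stage": stage,
                "out_degree": g.out_degree(tf),
                "in_degree": g.in_degree(tf),
            })
    return pd.DataFrame(rows)


def rank_reprogramming_candidates(
    grns: Sequence[nx.DiGraph],
    expression: pd.DataFrame,
    target_gene_set: Sequence[str],
    tf_peak_sets_by_stage: Mapping[str, Mapping[str, Sequence[GenomicInterval]]],
    domains: Mapping[str, RegulatoryDomain],
    *,
    expression_floor: float = 1.0,
    latest_stage: str = "HE",
) -> pd.DataFrame:
    """Rank TFs as reprogramming candidates.

    The ranking encodes two requirements: the factor must switch on early
    (activation stage = earliest stage with expression >= floor) and it must
    bind many of the loci in ``target_gene_set`` at or before
    ``latest_stage``.  Sort order: earlier activation, then more bound
    targets, then TF name.  Factors never reaching the floor are excluded.
    """
    if not len(target_gene_set):
        raise ValueError("target_gene_set is empty")
    from .enrichment import peak_targets

    cutoff = stage_index(latest_stage)
    panel = sorted(grns[0].nodes) if grns else sorted({
        tf for m in tf_peak_sets_by_stage.values() for tf in m
    })
    rows = []
    for tf in panel:
        if tf not in expression.index:
            continue
        levels = expression.loc[tf, list(STAGES)].to_numpy(dtype=float)
        on = [i for i, v in enumerate(levels) if v >= expression_floor]
        if not on:
            log.info("TF %s never reaches the expression floor; excluded", tf)
            continue
        activation = on[0]
        bound: set[str] = set()
        for stage in STAGES[: cutoff + 1]:
            peaks = tf_peak_sets_by_stage.get(stage, {}).get(tf)
            if peaks:
                doms = [domains[g] for g in target_gene_set if g in domains]
                bound |= peak_targets(peaks, doms) & set(target_gene_set)
        rows.append({
            "tf": tf,
            "activation_stage": STAGES[activation],
            "activation_index": activation,
            "n_targets_bound": len(bound),
        })
    if not rows:
        log.warning("no TF ever activated; empty ranking")
        return pd.DataFrame(columns=["tf", "activation_stage", "activation_index",
                                     "n_targets_bound"])
    out = pd.DataFrame(rows).sort_values(
        by=["activation_index", "n_targets_bound", "tf"],
        ascending=[True, False, True],
    ).reset_index(drop=True)
    return out


def edge_list(grns: Sequence[nx.DiGraph]) -> pd.DataFrame:
    rows = []
    for g in grns:
        for u, v, data in g.edges(data=True):
            rows.append({"source": u, "target": v,
                         "stage": g.graph.get("stage"),
                         "n_peaks": data.get("n_peaks", 0)})
    return pd.DataFrame(rows, columns=["source", "target", "stage", "n_peaks"])
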