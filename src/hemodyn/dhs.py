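"""DNaseI-hypersensitive-site dynamics across the six developmental stages.

Replicate peak sets are reduced to reproducible regions, unified across
stages, and each union DHS is encoded as a six-digit binary presence code in
stage order ESC, MES, HB, HE, HP, MAC (e.g. ``000110`` = open in HE and HP
only).  Union rows are classified proximal/distal relative to the nearest
TSS, censused per code with the >100-population eligibility filter, and
subset into cell-type-unique distal sets for pairwise comparisons.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import (
    STAGES,
    GeneModel,
    GenomicInterval,
    MergedIntervalIndex,
    nearest_tss,
    sort_merge,
    stage_index,
)

log = logging.getLogger(__name__)

#: Proximal/distal cut-off; matches the promoter window radius.
PROXIMAL_CUTOFF = 1000
#: Only pattern populations strictly greater than this enter overlap tests.
MIN_PATTERN_POPULATION = 100

PATTERN_COLUMNS = ["chrom", "start", "end", "code", "klass", "nearest_gene", "distance"]


def filter_reproducible(
    replicates: Sequence[Iterable[GenomicInterval]], min_support: int = 2
) -> list[GenomicInterval]:
    """Regions supported by >= ``min_support`` replicates (>=1 bp overlap).

    Peaks from all replicates are merged into candidate regions; a candidate
    is retained when, somewhere inside it, at least ``min_support`` distinct
    replicates cover the same base pair.  The retained interval is the full
    merged region (union extent), not the replicate intersection.
    """
    reps = [sort_merge(r, gap=0) for r in replicates]
    if len(reps) < 2:
        raise ValueError("need at least 2 replicate peak lists")
    union = sort_merge([iv for r in reps for iv in r], gap=0)
    # per-chromosome coverage sweep over replicate-presence events
    events: dict[str, list[tuple[int, int]]] = {}
    for r in reps:
        for iv in r:
            events.setdefault(iv.chrom, []).append((iv.start, 1))
            events[iv.chrom].append((iv.end, -1))
    supported: dict[str, list[tuple[int, int]]] = {}
    for chrom, evs in events.items():
        evs.sort()
        depth = 0
        seg_start = None
        for pos, delta in evs:
            depth += delta
            if depth >= min_support and seg_start is None:
                seg_start = pos
            elif depth < min_support and seg_start is not None:
                supported.setdefault(chrom, []).append((seg_start, pos))
                seg_start = None
    idx = MergedIntervalIndex(
        GenomicInterval(c, s, e) for c, segs in supported.items() for s, e in segs
    )
    return [iv for iv in union if idx.overlaps_any(iv)]


def encode_patterns(
    stage_sets: Mapping[str, Sequence[GenomicInterval]]
) -> pd.DataFrame:
    """Build the union-DHS table with six-digit binary stage codes.

    ``stage_sets`` maps each of the six stage names to its reproducible DHS
    set.  The union is built by merging all stage peaks (gap 0); bit *s* of a
    union row is 1 iff it overlaps (>= 1 bp) any peak of stage *s*.  The
    result is independent of the order in which stages are supplied.
    """
    missing = [s for s in STAGES if s not in stage_sets]
    if missing:
        raise ValueError(f"missing stage sets: {missing}")
    union = sort_merge([iv for s in STAGES for iv in stage_sets[s]], gap=0)
    indexes = {s: MergedIntervalIndex(sort_merge(stage_sets[s], gap=0)) for s in STAGES}
    rows = []
    for iv in union:
        code = "".join("1" if indexes[s].overlaps_any(iv) else "0" for s in STAGES)
        rows.append((iv.chrom, iv.start, iv.end, code))
    table = pd.DataFrame(rows, columns=["chrom", "start", "end", "code"])
    table["klass"] = pd.NA
    table["nearest_gene"] = pd.NA
    table["distance"] = pd.NA
    return table


def classify_proximal_distal(
    table: pd.DataFrame,
    genes: Sequence[GeneModel],
    cutoff: int = PROXIMAL_CUTOFF,
) -> pd.DataFrame:
    """Annotate union rows with nearest gene and proximal/distal class.

    A row is proximal when |midpoint - nearest TSS| <= ``cutoff`` bp
    (boundary inclusive), distal otherwise.
    """
    table = table.copy()
    klass, names, dists = [], [], []
    for chrom, start, end in zip(table["chrom"], table["start"], table["end"]):
        iv = GenomicInterval(chrom, int(start), int(end))
        gene, signed = nearest_tss(iv, genes)
        names.append(gene.gene_id)
        dists.append(int(signed))
        klass.append("proximal" if abs(signed) <= cutoff else "distal")
    table["klass"] = klass
    table["nearest_gene"] = names
    table["distance"] = dists
    return table


def pattern_census(table: pd.DataFrame) -> pd.DataFrame:
    """Exact per-code population counts with the >100 eligibility flag."""
    if len(table) == 0:
        return pd.DataFrame(columns=["code", "count", "eligible"])
    counts = table["code"].value_counts().sort_index()
    out = pd.DataFrame({"code": counts.index, "count": counts.values})
    out["eligible"] = out["count"] > MIN_PATTERN_POPULATION
    return out.reset_index(drop=True)


def unique_stage_dhs(
    table: pd.DataFrame, stage_a: str, stage_b: str, *, distal_only: bool = True
) -> pd.DataFrame:
    """Rows open in ``stage_a`` and closed in ``stage_b`` (distal by default)."""
    if stage_a == stage_b:
        raise ValueError("stage_a and stage_b must differ")
    ia, ib = stage_index(stage_a), stage_index(stage_b)
    bit_a = table["code"].str[ia] == "1"
    bit_b = table["code"].str[ib] == "0"
    sel = bit_a & bit_b
    if distal_only:
        sel &= table["klass"] == "distal"
    return table[sel].reset_index(drop=True)


def write_pattern_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_pattern_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"code": str})
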