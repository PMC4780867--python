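"""Genomic interval primitives and file I/O shared by every pipeline stage.

Coordinates are BED-style 0-based half-open everywhere inside the package.
GTF input (1-based, inclusive) is converted on read.  Chromosome names are
compared verbatim: mixing ``chr1`` and ``1`` dialects is the caller's error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

log = logging.getLogger(__name__)

#: The six ordered developmental stages: embryonic stem cell, mesoderm,
#: hemangioblast, hemogenic endothelium, hematopoietic progenitor, macrophage.
STAGES: tuple[str, ...] = ("ESC", "MES", "HB", "HE", "HP", "MAC")
STAGE_INDEX: dict[str, int] = {name: i for i, name in enumerate(STAGES)}
#: Transition Tk joins stage k-1 to stage k (T1 = ESC->MES ... T5 = HP->MAC).
TRANSITIONS: tuple[str, ...] = tuple(f"T{k}" for k in range(1, len(STAGES)))


def stage_index(stage: str) -> int:
    """Index of a stage in developmental order; raises on unknown names."""
    try:
        return STAGE_INDEX[stage]
    except KeyError:
        raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES}") from None


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``chrom:[start, end)``."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need end > start >= 0)"
            )
        if self.strand not in (None, "+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        """Anchor used for all distance/assignment purposes."""
        return (self.start + self.end) // 2

    def sort_key(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GeneModel:
    """A gene with its span and the TSS used as the promoter anchor."""

    gene_id: str
    chrom: str
    strand: str
    tss: int
    span: GenomicInterval

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if not (self.span.start <= self.tss <= self.span.end):
            raise ValueError(f"gene {self.gene_id}: TSS outside gene span")
        if self.chrom != self.span.chrom:
            raise ValueError(f"gene {self.gene_id}: chrom mismatch with span")

    def promoter(self, radius: int = 1000) -> GenomicInterval:
        """Promoter window TSS +/- ``radius`` bp (clipped at zero)."""
        return GenomicInterval(self.chrom, max(0, self.tss - radius), self.tss + radius)


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3+ into validated intervals sorted by (chrom, start, end).

    Raises ``ValueError`` with the offending line number on malformed input.
    """
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 tab-separated fields")
            try:
                chrom = fields[0]
                start = int(fields[1])
                end = int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = None
            if len(fields) > 4 and fields[4] != ".":
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: non-numeric score") from exc
            strand = fields[5] if len(fields) > 5 else None
            try:
                out.append(GenomicInterval(chrom, start, end, name, score, strand))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    out.sort(key=GenomicInterval.sort_key)
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    """Write intervals as BED3 or BED6 (BED6 if any optional field is set)."""
    ivs = list(intervals)
    six = any(iv.name is not None or iv.score is not None or iv.strand is not None
              for iv in ivs)
    with open(path, "w") as fh:
        for iv in ivs:
            if six:
                score = "." if iv.score is None else format(iv.score, "g")
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t"
                    f"{score}\t{iv.strand or '.'}\n"
                )
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def sort_merge(
    intervals: Iterable[GenomicInterval], gap: int = 0
) -> list[GenomicInterval]:
    """Sort intervals and merge any two within ``gap`` bp of each other.

    ``gap=0`` merges only overlapping or book-ended intervals.  Optional
    name/score/strand fields are dropped on merge (merged elements are new
    anonymous regions).  Idempotent for any fixed gap.
    """
    if gap < 0:
        raise ValueError("gap must be >= 0")
    ivs = sorted(intervals, key=GenomicInterval.sort_key)
    merged: list[GenomicInterval] = []
    for iv in ivs:
        if merged and iv.chrom == merged[-1].chrom and iv.start <= merged[-1].end + gap:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
            continue
        merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged


def nearest_tss(
    query: GenomicInterval, genes: Sequence[GeneModel]
) -> tuple[GeneModel, int]:
    """Gene whose TSS is nearest the query midpoint, with signed distance.

    Distance is signed relative to gene orientation: positive when the query
    midpoint lies downstream of the TSS (in the direction of transcription).
    Ties on |distance| are broken by the lexicographically smaller gene_id so
    that output is deterministic.  Only genes on the query chromosome are
    considered; an empty candidate list is an error.
    """
    if not genes:
        raise ValueError("gene list is empty")
    candidates = [g for g in genes if g.chrom == query.chrom]
    if not candidates:
        raise ValueError(f"no genes on chromosome {query.chrom!r}")
    mid = query.midpoint
    best = min(candidates, key=lambda g: (abs(mid - g.tss), g.gene_id))
    signed = (mid - best.tss) if best.strand == "+" else (best.tss - mid)
    return best, signed


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

def write_gtf(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models as GTF2.2 ``gene`` features (1-based inclusive)."""
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda g: (g.chrom, g.span.start)):
            attrs = f'gene_id "{g.gene_id}";'
            fh.write(
                f"{g.chrom}\themodyn\tgene\t{g.span.start + 1}\t{g.span.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )


def read_gtf(path: str | Path) -> list[GeneModel]:
    """Read gene models from GTF ``gene``/``transcript`` features.

    The TSS is the strand-aware 5' end of the feature.  Coordinates are
    converted from GTF's 1-based inclusive convention to 0-based half-open.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    for ftype in ("gene", "transcript"):
        for feat in db.features_of_type(ftype):
            start = feat.start - 1
            end = feat.end
            tss = start if feat.strand == "+" else end - 1
            gene_id = feat.attributes.get("gene_id", [feat.id])[0]
            genes.append(
                GeneModel(
                    gene_id=gene_id,
                    chrom=feat.seqid,
                    strand=feat.strand,
                    tss=tss,
                    span=GenomicInterval(feat.seqid, start, end),
                )
            )
        if genes:
            break
    genes.sort(key=lambda g: (g.chrom, g.tss, g.gene_id))
    return genes


# ---------------------------------------------------------------------------
# Graph I/O
# ---------------------------------------------------------------------------

def write_graphml(graph: nx.DiGraph, path: str | Path) -> None:
    """Write a stage GRN to GraphML; round-trips node/edge attributes."""
    nx.write_graphml(graph, str(path))


def read_graphml(path: str | Path) -> nx.DiGraph:
    return nx.read_graphml(str(path))


# ---------------------------------------------------------------------------
# Fast overlap helpers over merged (sorted, disjoint) interval sets
# ---------------------------------------------------------------------------

class MergedIntervalIndex:
    """Overlap lookups against a sorted, non-overlapping interval set."""

    def __init__(self, intervals: Iterable[GenomicInterval]):
        import numpy as np

        self._starts: dict[str, "np.ndarray"] = {}
        self._ends: dict[str, "np.ndarray"] = {}
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in intervals:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        for chrom, ivs in by_chrom.items():
            ivs.sort(key=GenomicInterval.sort_key)
            for a, b in zip(ivs, ivs[1:]):
                if b.start < a.end:
                    raise ValueError("index requires non-overlapping intervals; "
                                     "sort_merge the set first")
            self._starts[chrom] = np.array([iv.start for iv in ivs], dtype=np.int64)
            self._ends[chrom] = np.array([iv.end for iv in ivs], dtype=np.int64)

    def overlaps_any(self, iv: GenomicInterval) -> bool:
        import numpy as np

        starts = self._starts.get(iv.chrom)
        if starts is None or len(starts) == 0:
            return False
        ends = self._ends[iv.chrom]
        i = int(np.searchsorted(starts, iv.end, side="left"))
        return i > 0 and ends[i - 1] > iv.start
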