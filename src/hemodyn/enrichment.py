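"""Region-size-aware overlap significance and H3K27ac bootstrap Z-scores.

Gene-set vs TF-peak overlap is tested against a null that resamples gene
sets with probability proportional to each gene's regulatory-domain length,
so genes with large intergenic territories (which catch peaks by chance) do
not inflate significance.  Domains tile each chromosome, with boundaries at
midpoints between adjacent TSS.  DHS-pattern vs TF-peak overlap uses a
uniform-over-rows null on the union-DHS universe.  Empirical p-values use
the add-one estimator p = (1 + #{null >= observed}) / (n_resamples + 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .dhs import MIN_PATTERN_POPULATION
from .intervals import GeneModel, GenomicInterval, MergedIntervalIndex

log = logging.getLogger(__name__)

#: Fig-3-style significance threshold for the integration matrix (strict <).
SIGNIFICANCE_THRESHOLD = 1e-4


@dataclass(frozen=True)
class RegulatoryDomain:
    """The genomic territory attributed to one gene for peak assignment."""

    gene_id: str
    chrom: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class OverlapResult:
    observed: int
    null_mean: float
    null_sd: float
    p: float
    n_resamples: int


def build_regulatory_domains(
    genes: Sequence[GeneModel], chrom_sizes: Mapping[str, int]
) -> list[RegulatoryDomain]:
    """Tile each chromosome into per-gene domains split at TSS midpoints.

    The first and last domains extend to the chromosome ends; domains never
    overlap and their lengths sum to the chromosome length.
    """
    domains: list[RegulatoryDomain] = []
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        if g.chrom not in chrom_sizes:
            raise ValueError(f"gene {g.gene_id}: unknown chromosome {g.chrom}")
        if g.tss >= chrom_sizes[g.chrom]:
            raise ValueError(f"gene {g.gene_id}: TSS beyond chromosome end")
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom, gs in by_chrom.items():
        gs.sort(key=lambda g: (g.tss, g.gene_id))
        size = chrom_sizes[chrom]
        bounds = [0]
        for a, b in zip(gs, gs[1:]):
            bounds.append((a.tss + b.tss) // 2)
        bounds.append(size)
        for g, lo, hi in zip(gs, bounds, bounds[1:]):
            domains.append(RegulatoryDomain(g.gene_id, chrom, lo, hi))
    return domains


def peak_targets(
    peaks: Iterable[GenomicInterval], domains: Sequence[RegulatoryDomain]
) -> set[str]:
    """Genes whose domain contains at least one peak midpoint."""
    by_chrom: dict[str, list[RegulatoryDomain]] = {}
    for d in domains:
        by_chrom.setdefault(d.chrom, []).append(d)
    starts: dict[str, np.ndarray] = {}
    names: dict[str, list[str]] = {}
    ends: dict[str, np.ndarray] = {}
    for chrom, ds in by_chrom.items():
        ds.sort(key=lambda d: d.start)
        starts[chrom] = np.array([d.start for d in ds])
        ends[chrom] = np.array([d.end for d in ds])
        names[chrom] = [d.gene_id for d in ds]
    hits: set[str] = set()
    for pk in peaks:
        if pk.chrom not in starts:
            continue
        mid = pk.midpoint
        i = int(np.searchsorted(starts[pk.chrom], mid, side="right")) - 1
        if i >= 0 and mid < ends[pk.chrom][i]:
            hits.add(names[pk.chrom][i])
    return hits


def _weighted_sample_counts(
    member_mask: np.ndarray,
    weights: np.ndarray,
    set_size: int,
    n_resamples: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Overlap counts of resampled sets with ``member_mask``.

    Each resample draws ``set_size`` items without replacement with
    probability proportional to ``weights`` (exponential-key trick: the
    ``set_size`` smallest Exp(1)/w keys are a successive weighted sample).
    Returns the count of sampled items falling in ``member_mask`` per
    resample.
    """
    n = len(weights)
    keys = rng.standard_exponential((n_resamples, n)) / weights[None, :]
    idx = np.argpartition(keys, set_size - 1, axis=1)[:, :set_size]
    return member_mask[idx].sum(axis=1)


def overlap_significance(
    gene_set: Iterable[str],
    peaks: Iterable[GenomicInterval],
    domains: Sequence[RegulatoryDomain],
    *,
    n_resamples: int = 100_000,
    seed: int = 0,
    targets: set[str] | None = None,
) -> OverlapResult:
    """Length-weighted resampling test of gene-set vs peak-target overlap.

    ``observed`` counts gene-set members that are peak targets; the null
    redraws gene sets of equal size without replacement, weighted by domain
    length.  ``targets`` may be passed to reuse a precomputed target set.
    """
    gene_set = set(gene_set)
    if not gene_set:
        raise ValueError("gene_set is empty")
    if n_resamples < 1000:
        raise ValueError("n_resamples must be >= 1000")
    universe = [d.gene_id for d in domains]
    missing = gene_set - set(universe)
    if missing:
        raise ValueError(f"gene_set not within gene universe: {sorted(missing)[:5]}")
    if targets is None:
        targets = peak_targets(peaks, domains)
    target_mask = np.array([g in targets for g in universe])
    member = np.array([g in gene_set for g in universe])
    observed = int((target_mask & member).sum())
    weights = np.array([d.length for d in domains], dtype=float)
    rng = np.random.default_rng(seed)
    null = _weighted_sample_counts(target_mask, weights, len(gene_set), n_resamples, rng)
    p = (1 + int((null >= observed).sum())) / (n_resamples + 1)
    return OverlapResult(observed, float(null.mean()), float(null.std(ddof=0)),
                         p, n_resamples)


def dhs_pattern_tf_overlap(
    pattern_table: pd.DataFrame,
    tf_peaks: Sequence[GenomicInterval],
    *,
    n_resamples: int = 100_000,
    seed: int = 0,
    min_population: int = MIN_PATTERN_POPULATION,
) -> dict[str, OverlapResult]:
    """Per-pattern significance of TF-peak overlap on the union-DHS universe.

    Only patterns with population strictly greater than ``min_population``
    are tested (smaller ones are skipped with a logged reason).  The null
    draws equal-size row sets uniformly from all union rows; null overlap
    counts are drawn from the equivalent hypergeometric distribution.
    """
    from .intervals import sort_merge

    idx = MergedIntervalIndex(sort_merge(tf_peaks, gap=0))
    overlapped = np.array([
        idx.overlaps_any(GenomicInterval(c, int(s), int(e)))
        for c, s, e in zip(pattern_table["chrom"], pattern_table["start"],
                           pattern_table["end"])
    ])
    n_rows = len(pattern_table)
    n_good = int(overlapped.sum())
    rng = np.random.default_rng(seed)
    results: dict[str, OverlapResult] = {}
    for code, sub in pattern_table.groupby("code"):
        m = len(sub)
        if m <= min_population:
            log.info("pattern %s skipped: population %d <= %d", code, m, min_population)
            continue
        observed = int(overlapped[sub.index].sum())
        null = rng.hypergeometric(n_good, n_rows - n_good, m, size=n_resamples)
        p = (1 + int((null >= observed).sum())) / (n_resamples + 1)
        results[code] = OverlapResult(observed, float(null.mean()),
                                      float(null.std(ddof=0)), p, n_resamples)
    return results


def site_signal(
    sites: Sequence[GenomicInterval],
    track: Mapping[str, np.ndarray],
    bin_size: int,
) -> np.ndarray:
    """Mean per-bin signal of a binned track over each site."""
    out = np.empty(len(sites))
    for i, iv in enumerate(sites):
        counts = track.get(iv.chrom)
        if counts is None:
            out[i] = np.nan
            continue
        lo = max(0, iv.start // bin_size)
        hi = min(len(counts), -(-iv.end // bin_size))
        out[i] = counts[lo:hi].mean() if hi > lo else np.nan
    return out


def h3k27ac_zscore(
    subset_signal: np.ndarray,
    all_signal: np.ndarray,
    *,
    n_boot: int = 10_000,
    seed: int = 0,
) -> float:
    """Bootstrap Z-score of mean signal in a site subset vs all TF sites.

    ``Z = (mean(subset) - mean(null)) / sd(null)`` where the null is the
    distribution of means of equal-size samples (with replacement) from all
    sites.  A degenerate null (sd = 0) reports Z = 0.  Invariant to affine
    rescaling of the signal.
    """
    subset_signal = np.asarray(subset_signal, dtype=float)
    all_signal = np.asarray(all_signal, dtype=float)
    subset_signal = subset_signal[~np.isnan(subset_signal)]
    all_signal = all_signal[~np.isnan(all_signal)]
    if len(subset_signal) == 0:
        raise ValueError("empty site subset")
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, len(all_signal), size=(n_boot, len(subset_signal)))
    null_means = all_signal[draws].mean(axis=1)
    sd = float(null_means.std(ddof=0))
    if sd == 0:
        log.warning("degenerate bootstrap null (sd=0); reporting Z=0")
        return 0.0
    return float((subset_signal.mean() - null_means.mean()) / sd)


def integration_matrix(
    cluster_genes: Mapping[str, set[str]],
    tf_peak_sets: Mapping[tuple[str, str], Sequence[GenomicInterval]],
    domains: Sequence[RegulatoryDomain],
    ac_tracks: Mapping[str, Mapping[str, np.ndarray]] | None = None,
    bin_size: int | None = None,
    *,
    n_resamples: int = 100_000,
    n_boot: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Cluster x (TF, stage) matrix of overlap p-values and H3K27ac Z-scores.

    For every expression cluster and TF ChIP set, composes the length-
    weighted overlap test with (optionally, when acetylation tracks are
    supplied) the bootstrap Z-score of H3K27ac at the TF sites assigned to
    the cluster's genes.  Stages with no TF data are simply absent.  A cell
    is flagged significant at p < 1e-4 (strict).
    """
    records = []
    for j, ((tf, stage), peaks) in enumerate(sorted(tf_peak_sets.items())):
        targets = peak_targets(peaks, domains)
        dom_by_gene = {d.gene_id: d for d in domains}
        ac = ac_tracks.get(stage) if ac_tracks is not None else None
        all_sig = (site_signal(list(peaks), ac, bin_size)
                   if ac is not None and bin_size else None)
        for i, (cluster, genes) in enumerate(sorted(cluster_genes.items())):
            res = overlap_significance(
                genes, peaks, domains,
                n_resamples=n_resamples, seed=seed + 131 * i + 7 * j,
                targets=targets,
            )
            z = np.nan
            if all_sig is not None:
                sub_idx = [
                    k for k, pk in enumerate(peaks)
                    if pk.chrom in {dom_by_gene[g].chrom for g in genes}
                    and any(
                        dom_by_gene[g].chrom == pk.chrom
                        and dom_by_gene[g].start <= pk.midpoint < dom_by_gene[g].end
                        for g in genes
                    )
                ]
                if sub_idx:
                    z = h3k27ac_zscore(all_sig[sub_idx], all_sig,
                                       n_boot=n_boot, seed=seed + 977 * i + 13 * j)
            records.append({
                "cluster": cluster, "tf": tf, "stage": stage,
                "observed": res.observed, "p": res.p, "z": z,
                "significant": res.p < SIGNIFICANCE_THRESHOLD,
            })
    return pd.DataFrame.from_records(records)
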