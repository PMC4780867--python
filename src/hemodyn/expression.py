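"""Stage-wise expression dynamics: differential calling, standardization,
k-means pattern discovery, and stage-correlation scoring.

Expression is an FPKM-like genes x six-stages matrix.  Genes that change at
any stage transition (fold-change rule with an expression floor) are
standardized on the log10 scale to zero-mean, unit-sd profiles and clustered
into expression patterns; external profiles can be scored against the stage
columns by Pearson correlation with Fisher-z comparison of correlations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, pearsonr
from sklearn.cluster import KMeans

from .intervals import STAGES, TRANSITIONS

log = logging.getLogger(__name__)

#: Pseudocount added before taking log10 of FPKM values.
LOG_PSEUDOCOUNT = 0.01


def _check_matrix(m: pd.DataFrame) -> pd.DataFrame:
    if m.shape[1] < 2:
        raise ValueError("need at least 2 stage columns")
    if (m.values < 0).any():
        raise ValueError("expression values must be non-negative")
    return m


def call_differential_genes(
    m: pd.DataFrame, min_fc: float = 2.0, floor: float = 1.0
) -> dict[str, dict[str, set[str]]]:
    """Per-transition up/down gene sets under a fold-change + floor rule.

    A gene is up at transition Tk when its expression at stage k is at least
    ``floor`` and the ratio to max(previous stage, floor) is >= ``min_fc``;
    down is symmetric.  A gene is *dynamic* when it enters any set.
    """
    _check_matrix(m)
    if min_fc <= 1:
        raise ValueError("min_fc must be > 1")
    if floor < 0:
        raise ValueError("floor must be >= 0")
    out: dict[str, dict[str, set[str]]] = {}
    cols = list(m.columns)
    for k in range(1, len(cols)):
        prev = m[cols[k - 1]].to_numpy(dtype=float)
        curr = m[cols[k]].to_numpy(dtype=float)
        up = (curr >= floor) & (curr / np.maximum(prev, floor) >= min_fc)
        down = (prev >= floor) & (prev / np.maximum(curr, floor) >= min_fc)
        name = f"T{k}"
        out[name] = {
            "up": set(m.index[up]),
            "down": set(m.index[down]),
        }
    return out


def dynamic_genes(de_sets: dict[str, dict[str, set[str]]]) -> set[str]:
    """Genes entering any transition up/down set."""
    out: set[str] = set()
    for sets in de_sets.values():
        out |= sets["up"] | sets["down"]
    return out


@dataclass
class StandardizedProfiles:
    """Zero-mean unit-sd log10 profiles of the dynamic genes."""

    z: pd.DataFrame                 # genes x stages
    excluded: list[str]             # genes dropped for zero variance

    def __post_init__(self) -> None:
        if len(self.z):
            assert np.allclose(self.z.mean(axis=1), 0.0, atol=1e-9)


def standardize(
    m: pd.DataFrame, genes: set[str] | None = None, pseudocount: float = LOG_PSEUDOCOUNT
) -> StandardizedProfiles:
    """Standardize per-gene log10 expression: z_ij = (log x_ij - mean)/sd.

    Restricted to ``genes`` (typically the dynamic set) when given.  Genes
    with zero variance on the log scale are excluded with a logged reason.
    The sd is the population sd (ddof=0) so profiles have unit variance.
    """
    _check_matrix(m)
    sub = m.loc[sorted(genes & set(m.index))] if genes is not None else m
    logx = np.log10(sub.to_numpy(dtype=float) + pseudocount)
    mean = logx.mean(axis=1, keepdims=True)
    sd = logx.std(axis=1, ddof=0, keepdims=True)
    # tolerance absorbs float residue of log-transforming a constant row
    keep = sd[:, 0] > 1e-12
    excluded = list(sub.index[~keep])
    if excluded:
        log.info("standardize: excluded %d constant genes", len(excluded))
    z = (logx[keep] - mean[keep]) / sd[keep]
    return StandardizedProfiles(
        z=pd.DataFrame(z, index=sub.index[keep], columns=sub.columns),
        excluded=excluded,
    )


def cluster_patterns(
    profiles: StandardizedProfiles | pd.DataFrame,
    k: int = 31,
    *,
    restarts: int = 20,
    seed: int = 0,
) -> tuple[pd.Series, pd.DataFrame]:
    """K-means expression-pattern discovery over standardized profiles.

    Runs ``restarts`` k-means++ initializations (seed-deterministic) and
    keeps the solution with the lowest inertia.  Maximin/farthest-point
    seeding was rejected: it deterministically seeds on outlier profiles,
    so restarts collapse onto the same poor optimum whenever a few noisy
    genes pass the differential filter.  Returns (labels, centroids) with
    deterministic labels given the seed.
    """
    z = profiles.z if isinstance(profiles, StandardizedProfiles) else profiles
    X = z.to_numpy(dtype=float)
    n = X.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds number of profiles ({n})")
    km = KMeans(n_clusters=k, init="k-means++", n_init=restarts, max_iter=300,
                random_state=seed % (2 ** 32))
    km.fit(X)
    labels = pd.Series(km.labels_, index=z.index, name="cluster")
    centroids = pd.DataFrame(km.cluster_centers_, columns=z.columns)
    centroids.index.name = "cluster"
    return labels, centroids


def fisher_z_test(r1: float, n1: int, r2: float, n2: int) -> float:
    """Two-sided Fisher z-transform test for two independent correlations."""
    if n1 <= 3 or n2 <= 3:
        raise ValueError("need n > 3 per correlation")
    if r1 == r2:
        return 1.0
    z1 = np.arctanh(np.clip(r1, -1 + 1e-15, 1 - 1e-15))
    z2 = np.arctanh(np.clip(r2, -1 + 1e-15, 1 - 1e-15))
    se = np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    return float(2 * norm.sf(abs(z1 - z2) / se))


def stage_correlation(
    profile: pd.Series, m: pd.DataFrame, pseudocount: float = LOG_PSEUDOCOUNT
) -> tuple[pd.Series, pd.DataFrame]:
    """Correlate an expression profile with each stage column (log scale).

    Returns per-stage Pearson correlations and the matrix of two-sided
    Fisher-z p-values comparing every pair of stage correlations.  Requires
    a shared gene universe of at least 3 genes.
    """
    shared = profile.index.intersection(m.index)
    if len(shared) < 3:
        raise ValueError("profile and matrix share fewer than 3 genes")
    x = np.log10(profile.loc[shared].to_numpy(dtype=float) + pseudocount)
    n = len(shared)
    rs = {}
    for col in m.columns:
        y = np.log10(m.loc[shared, col].to_numpy(dtype=float) + pseudocount)
        if np.std(x) == 0 or np.std(y) == 0:
            rs[col] = np.nan
            continue
        rs[col] = float(pearsonr(x, y).statistic)
    r = pd.Series(rs, name="r")
    cols = list(m.columns)
    pmat = pd.DataFrame(np.ones((len(cols), len(cols))), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            p = fisher_z_test(r[a], n, r[b], n)
            pmat.loc[a, b] = pmat.loc[b, a] = p
    return r, pmat


def read_expression(path) -> pd.DataFrame:
    """Read a TSV expression table (gene_id + stage columns, header row)."""
    m = pd.read_csv(path, sep="\t", index_col=0)
    order = [s for s in STAGES if s in m.columns]
    return m[order] if order else m


def write_expression(m: pd.DataFrame, path) -> None:
    m.to_csv(path, sep="\t", index_label="gene_id")
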