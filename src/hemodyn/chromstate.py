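"""Chromatin-state segmentation over binarized DHS + histone-mark tracks.

A multivariate hidden Markov model with product-Bernoulli emissions is fitted
to binarized bin-level signal for the five marks (DHS, H3K4me3, H3K9ac,
H3K27ac, H3K27me3), Viterbi-decoded into state tracks, and coarse-grained to
a four-state promoter model:

* ACTIVE    -- DHS together with H3K4me3 and acetylated H3,
* REPRESSED -- H3K27me3 without accessibility,
* POISED    -- DHS with H3K27me3 plus H3K4me3 and/or acetylated H3,
* UNMARKED  -- none of the above.

The number of HMM states K is a free parameter; the coarse-graining is what
makes segmentations with different K comparable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.stats import poisson

from .intervals import GeneModel

log = logging.getLogger(__name__)

MARKS: tuple[str, ...] = ("DHS", "H3K4me3", "H3K9ac", "H3K27ac", "H3K27me3")
ACETYL_MARKS: tuple[str, ...] = ("H3K9ac", "H3K27ac")

ACTIVE, REPRESSED, POISED, UNMARKED = "ACTIVE", "REPRESSED", "POISED", "UNMARKED"
COARSE_STATES: tuple[str, ...] = (ACTIVE, REPRESSED, POISED, UNMARKED)
#: Single-letter codes used in per-gene six-stage timelines, e.g. "UUPAAA".
COARSE_LETTER: dict[str, str] = {ACTIVE: "A", REPRESSED: "R", POISED: "P", UNMARKED: "U"}
LETTER_COARSE: dict[str, str] = {v: k for k, v in COARSE_LETTER.items()}
#: Sentinel letter for promoters with no annotated bins.
MISSING_LETTER = "."
#: Majority-vote tie precedence: rarer informative states win.
TIE_PRECEDENCE: tuple[str, ...] = (POISED, ACTIVE, REPRESSED, UNMARKED)


def binarize(counts: np.ndarray, p_threshold: float = 1e-4) -> np.ndarray:
    """Binarize a binned count track against its genome-wide Poisson mean.

    A bin is called present (1) when the upper-tail Poisson probability of
    its count under the track-wide mean rate falls below ``p_threshold``.
    """
    counts = np.asarray(counts)
    if counts.size == 0:
        raise ValueError("empty track")
    if not 0.0 < p_threshold < 1.0:
        raise ValueError("p_threshold must be in (0, 1)")
    mu = float(counts.mean())
    # P(X >= c) under Poisson(mu); sf is P(X > c-1)
    pvals = poisson.sf(counts - 1, mu)
    return (pvals < p_threshold).astype(np.uint8)


@dataclass
class ChromatinStateModel:
    """K-state HMM over M binary marks with product-Bernoulli emissions."""

    emission: np.ndarray          # (K, M) Bernoulli success probabilities
    transition: np.ndarray        # (K, K) row-stochastic
    initial: np.ndarray           # (K,) simplex
    marks: tuple[str, ...] = MARKS
    log_likelihoods: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.emission = np.asarray(self.emission, dtype=float)
        self.transition = np.asarray(self.transition, dtype=float)
        self.initial = np.asarray(self.initial, dtype=float)
        K = self.emission.shape[0]
        if self.transition.shape != (K, K) or self.initial.shape != (K,):
            raise ValueError("inconsistent model dimensions")
        if np.any(self.emission < 0) or np.any(self.emission > 1):
            raise ValueError("emission probabilities outside [0, 1]")
        if not np.allclose(self.transition.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition rows must sum to 1")
        if not np.isclose(self.initial.sum(), 1.0, atol=1e-9):
            raise ValueError("initial distribution must sum to 1")

    @property
    def n_states(self) -> int:
        return self.emission.shape[0]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "marks": list(self.marks),
            "emission": self.emission.tolist(),
            "transition": self.transition.tolist(),
            "initial": self.initial.tolist(),
            "log_likelihoods": self.log_likelihoods,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ChromatinStateModel":
        d = json.loads(Path(path).read_text())
        return cls(
            emission=np.array(d["emission"]),
            transition=np.array(d["transition"]),
            initial=np.array(d["initial"]),
            marks=tuple(d["marks"]),
            log_likelihoods=list(d.get("log_likelihoods", [])),
        )


def _log_emission_matrix(X: np.ndarray, emission: np.ndarray) -> np.ndarray:
    """log P(x_n | state k) for binary rows X (n, M); returns (n, K)."""
    e = np.clip(emission, 1e-10, 1 - 1e-10)
    return X @ np.log(e).T + (1 - X) @ np.log(1 - e).T


def _forward_backward(
    logB: np.ndarray, transition: np.ndarray, initial: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Scaled forward-backward; returns (alpha, beta, scale, loglik)."""
    n, K = logB.shape
    B = np.exp(logB - logB.max(axis=1, keepdims=True))
    shift = logB.max(axis=1)
    alpha = np.empty((n, K))
    beta = np.empty((n, K))
    scale = np.empty(n)
    a = initial * B[0]
    scale[0] = a.sum()
    alpha[0] = a / scale[0]
    for t in range(1, n):
        a = (alpha[t - 1] @ transition) * B[t]
        scale[t] = a.sum()
        alpha[t] = a / scale[t]
    beta[-1] = 1.0
    for t in range(n - 2, -1, -1):
        beta[t] = (transition @ (B[t + 1] * beta[t + 1])) / scale[t + 1]
    loglik = float(np.log(scale).sum() + shift.sum())
    return alpha, beta, scale, loglik


def forward_loglik(model: ChromatinStateModel, X: np.ndarray) -> float:
    """Total log-likelihood of binary observations under the model."""
    logB = _log_emission_matrix(np.asarray(X, dtype=float), model.emission)
    _, _, _, ll = _forward_backward(logB, model.transition, model.initial)
    return ll


def backward_loglik(model: ChromatinStateModel, X: np.ndarray) -> float:
    """Log-likelihood via the backward recursion (cross-check of forward)."""
    X = np.asarray(X, dtype=float)
    logB = _log_emission_matrix(X, model.emission)
    shift = logB.max(axis=1)
    B = np.exp(logB - shift[:, None])
    n, K = logB.shape
    beta = np.ones(K)
    logc = 0.0
    for t in range(n - 1, 0, -1):
        beta = model.transition @ (B[t] * beta)
        c = beta.sum()
        beta /= c
        logc += np.log(c)
    total = float(np.log((model.initial * B[0] * beta).sum()) + logc + shift.sum())
    return total


def _canonical_order(emission: np.ndarray) -> np.ndarray:
    """Deterministic state order: sort by emission rows, descending."""
    keys = [tuple(-row) for row in np.round(emission, 10)]
    return np.array(sorted(range(len(keys)), key=lambda i: keys[i]))


def canonicalize(model: ChromatinStateModel) -> ChromatinStateModel:
    """Relabel states into the emission-sorted canonical order."""
    order = _canonical_order(model.emission)
    return ChromatinStateModel(
        emission=model.emission[order],
        transition=model.transition[np.ix_(order, order)],
        initial=model.initial[order],
        marks=model.marks,
        log_likelihoods=list(model.log_likelihoods),
    )


def fit_hmm(
    X: np.ndarray,
    n_states: int,
    *,
    marks: Sequence[str] = MARKS,
    max_iter: int = 100,
    tol: float = 1e-4,
    seed: int = 0,
    n_restarts: int = 3,
) -> ChromatinStateModel:
    """Baum-Welch EM fit of the product-Bernoulli HMM.

    Emissions are initialized by jittering the empirical per-mark frequencies
    (seed-controlled), transitions start uniform; the best of ``n_restarts``
    runs by final log-likelihood is returned in canonical state order.  The
    recorded per-iteration log-likelihood is non-decreasing (EM guarantee,
    asserted in the test-suite).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be (n_bins, n_marks)")
    n, M = X.shape
    if n_states < 1:
        raise ValueError("n_states must be >= 1")
    n_distinct = len({tuple(row) for row in X.astype(int)})
    if n_states > n_distinct:
        log.warning(
            "requested %d states but only %d distinct observation vectors; "
            "some states will be degenerate", n_states, n_distinct,
        )
    freq = X.mean(axis=0)
    unique_rows = np.unique(X, axis=0)
    best: ChromatinStateModel | None = None
    for restart in range(n_restarts):
        rng = np.random.default_rng([seed, restart])
        # anchor states on observed mark combinations (sampled uniformly over
        # *distinct* vectors so rare states are reachable), shrunk toward the
        # empirical frequency, plus seed-controlled jitter
        anchors = unique_rows[rng.integers(len(unique_rows), size=n_states)]
        emission = np.clip(
            0.6 * anchors + 0.3 * freq[None, :]
            + rng.uniform(0.0, 0.2, size=(n_states, M)),
            0.05, 0.95,
        )
        transition = np.full((n_states, n_states), 1.0 / n_states)
        initial = np.full(n_states, 1.0 / n_states)
        lls: list[float] = []
        prev_ll = -np.inf
        for _ in range(max_iter):
            logB = _log_emission_matrix(X, emission)
            alpha, beta, scale, ll = _forward_backward(logB, transition, initial)
            lls.append(ll)
            gamma = alpha * beta
            gamma /= gamma.sum(axis=1, keepdims=True)
            # xi accumulated over time: xi_sum[i, j] = A[i,j] * sum_t
            #   alpha[t, i] * B[t+1, j] * beta[t+1, j] / scale[t+1]
            B = np.exp(logB - logB.max(axis=1, keepdims=True))
            right = (B[1:] * beta[1:]) / scale[1:, None]
            xi_sum = transition * (alpha[:-1].T @ right)
            initial = gamma[0] / gamma[0].sum()
            transition = xi_sum / np.clip(xi_sum.sum(axis=1, keepdims=True), 1e-300, None)
            # guard against empty rows (unvisited states)
            bad = ~np.isfinite(transition.sum(axis=1)) | (xi_sum.sum(axis=1) < 1e-250)
            transition[bad] = 1.0 / n_states
            denom = gamma.sum(axis=0)[:, None]
            emission = np.clip((gamma.T @ X) / np.clip(denom, 1e-300, None), 1e-6, 1 - 1e-6)
            if ll - prev_ll < tol and np.isfinite(prev_ll):
                break
            prev_ll = ll
        model = ChromatinStateModel(
            emission=emission, transition=transition, initial=initial,
            marks=tuple(marks), log_likelihoods=lls,
        )
        if best is None or model.log_likelihoods[-1] > best.log_likelihoods[-1]:
            best = model
    assert best is not None
    canon = canonicalize(best)
    canon.log_likelihoods = list(best.log_likelihoods)
    return canon


def decode_states(model: ChromatinStateModel, X: np.ndarray,
                  marks: Sequence[str] | None = None) -> np.ndarray:
    """Viterbi decoding: most probable state index per bin."""
    if marks is not None and tuple(marks) != tuple(model.marks):
        raise ValueError(f"mark mismatch: model has {model.marks}, data has {tuple(marks)}")
    X = np.asarray(X, dtype=float)
    logB = _log_emission_matrix(X, model.emission)
    n, K = logB.shape
    logA = np.log(np.clip(model.transition, 1e-300, None))
    delta = np.log(np.clip(model.initial, 1e-300, None)) + logB[0]
    back = np.zeros((n, K), dtype=np.int64)
    for t in range(1, n):
        cand = delta[:, None] + logA
        back[t] = cand.argmax(axis=0)
        delta = cand.max(axis=0) + logB[t]
    path = np.empty(n, dtype=np.int64)
    path[-1] = int(delta.argmax())
    for t in range(n - 2, -1, -1):
        path[t] = back[t + 1][path[t + 1]]
    return path


def match_states(
    reference_emission: np.ndarray, estimated_emission: np.ndarray
) -> np.ndarray:
    """Optimal state matching (Hungarian on L1 emission distance).

    Returns ``perm`` such that estimated state ``perm[i]`` corresponds to
    reference state ``i``.
    """
    ref = np.asarray(reference_emission, dtype=float)
    est = np.asarray(estimated_emission, dtype=float)
    cost = np.abs(ref[:, None, :] - est[None, :, :]).sum(axis=2)
    _, cols = linear_sum_assignment(cost)
    return cols


# ---------------------------------------------------------------------------
# Four-state coarse graining
# ---------------------------------------------------------------------------

def coarse_grain_marks(marks_present: Mapping[str, bool]) -> str:
    """Map direct mark presence calls to one of the four coarse states.

    The rules partition all mark combinations: POISED requires accessibility
    with H3K27me3 plus at least one active mark; ACTIVE requires
    accessibility with H3K4me3 and acetylation; any remaining H3K27me3 is
    REPRESSED; everything else is UNMARKED.
    """
    dhs = bool(marks_present.get("DHS", False))
    k4 = bool(marks_present.get("H3K4me3", False))
    k27me3 = bool(marks_present.get("H3K27me3", False))
    acetyl = any(bool(marks_present.get(m, False)) for m in ACETYL_MARKS)
    if dhs and k27me3 and (k4 or acetyl):
        return POISED
    if dhs and k4 and acetyl:
        return ACTIVE
    if k27me3:
        return REPRESSED
    return UNMARKED


def coarse_grain_emission(
    emission_row: np.ndarray, marks: Sequence[str] = MARKS, threshold: float = 0.5
) -> str:
    """Coarse state of an HMM state from its emission profile (>= threshold)."""
    calls = {m: emission_row[i] >= threshold for i, m in enumerate(marks)}
    return coarse_grain_marks(calls)


def coarse_grain_model(model: ChromatinStateModel, threshold: float = 0.5) -> list[str]:
    """Coarse label for each HMM state."""
    return [coarse_grain_emission(row, model.marks, threshold) for row in model.emission]


# ---------------------------------------------------------------------------
# Promoter state timelines
# ---------------------------------------------------------------------------

def promoter_state_timeline(
    genes: Sequence[GeneModel],
    stage_annotations: Mapping[str, Mapping[str, np.ndarray]],
    bin_size: int,
    *,
    stages: Sequence[str] | None = None,
    promoter_radius: int = 1000,
) -> dict[str, str]:
    """Per-gene six-stage promoter state string, e.g. ``"UUPAAA"``.

    ``stage_annotations[stage][chrom]`` is an array of coarse labels (one of
    ``COARSE_STATES``) per genomic bin.  The promoter label is the majority
    label over the bins covering TSS +/- ``promoter_radius``; ties break by
    ``TIE_PRECEDENCE`` (POISED > ACTIVE > REPRESSED > UNMARKED).  Promoters
    with no covered bins receive the ``.`` sentinel and a logged warning.
    """
    from .intervals import STAGES

    stage_list = list(stages) if stages is not None else list(STAGES)
    timelines: dict[str, str] = {}
    rank = {state: i for i, state in enumerate(TIE_PRECEDENCE)}
    for gene in genes:
        letters = []
        for stage in stage_list:
            per_chrom = stage_annotations.get(stage, {})
            labels = per_chrom.get(gene.chrom)
            if labels is None:
                log.warning("gene %s: no annotation for %s/%s", gene.gene_id, stage, gene.chrom)
                letters.append(MISSING_LETTER)
                continue
            lo = max(0, (gene.tss - promoter_radius) // bin_size)
            hi = min(len(labels), -(-(gene.tss + promoter_radius) // bin_size))
            window = labels[lo:hi]
            if len(window) == 0:
                log.warning("gene %s: promoter overlaps no bins at %s", gene.gene_id, stage)
                letters.append(MISSING_LETTER)
                continue
            counts: dict[str, int] = {}
            for lab in window:
                counts[str(lab)] = counts.get(str(lab), 0) + 1
            best = max(counts.items(), key=lambda kv: (kv[1], -rank.get(kv[0], 99)))[0]
            letters.append(COARSE_LETTER.get(best, MISSING_LETTER))
        timelines[gene.gene_id] = "".join(letters)
    return timelines


def decode_coarse_tracks(
    model: ChromatinStateModel,
    binarized: Mapping[str, np.ndarray],
    threshold: float = 0.5,
) -> dict[str, np.ndarray]:
    """Viterbi-decode per-chromosome binary tracks and coarse-grain them.

    ``binarized[chrom]`` is an (n_bins, M) binary matrix in model mark order.
    Returns per-chromosome arrays of coarse labels.
    """
    state_labels = np.array(coarse_grain_model(model, threshold))
    out: dict[str, np.ndarray] = {}
    for chrom, X in binarized.items():
        path = decode_states(model, X)
        out[chrom] = state_labels[path]
    return out


def rule_coarse_tracks(binarized: Mapping[str, np.ndarray],
                       marks: Sequence[str] = MARKS) -> dict[str, np.ndarray]:
    """Rule-path coarse annotation applied directly to binarized marks."""
    out: dict[str, np.ndarray] = {}
    for chrom, X in binarized.items():
        labels = np.empty(X.shape[0], dtype=object)
        for i, row in enumerate(np.asarray(X)):
            labels[i] = coarse_grain_marks({m: bool(v) for m, v in zip(marks, row)})
        out[chrom] = labels
    return out
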