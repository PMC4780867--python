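"""PWM scanning and relative motif enrichment (RE) between region sets.

Scanning is a standard log-odds scan of both strands; a region "has" a
motif when any window scores at or above the motif threshold (default 80%
of the maximum attainable log-odds score).  RE between two region sets is
the ratio of per-region hit fractions with a small-sample pseudocount, and
its significance is assessed by bootstrap resampling of regions within each
set.  The stage-pair RE matrix compares DHS unique to one cell type against
each other cell type and clusters motif rows hierarchically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import pdist

from .intervals import STAGES, GenomicInterval

log = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Default per-motif hit threshold as a fraction of the maximum score.
DEFAULT_THRESHOLD_FRACTION = 0.8
#: Fixed width regions are standardized to before scanning (length-matching).
DEFAULT_SCAN_WIDTH = 400


@dataclass
class PWM:
    """Position weight matrix with probabilities and a bit-score threshold."""

    motif_id: str
    matrix: np.ndarray                       # (L, 4) base probabilities
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    score_threshold: float | None = None     # bits; default 80% of max

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("matrix must be (L, 4)")
        if self.matrix.shape[0] < 4:
            raise ValueError("motif length must be >= 4")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("each PWM position must sum to 1")
        if self.score_threshold is None:
            self.score_threshold = DEFAULT_THRESHOLD_FRACTION * self.max_score

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        """(L, 5) log2(p/bg) with an extra column scoring N as p=0.25."""
        p = np.clip(self.matrix, 1e-9, None)
        lo = np.log2(p / self.background[None, :])
        n_col = np.full((self.length, 1), np.log2(0.25 / float(self.background.mean())))
        return np.hstack([lo, n_col])

    @property
    def max_score(self) -> float:
        return float(np.log2(np.clip(self.matrix, 1e-9, None)
                             / self.background[None, :]).max(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=1))


def pwm_from_consensus(
    motif_id: str, consensus: str, match_prob: float = 0.7
) -> PWM:
    """Build a PWM concentrating ``match_prob`` on each consensus base."""
    off = (1.0 - match_prob) / 3.0
    mat = np.full((len(consensus), 4), off)
    for i, b in enumerate(consensus.upper()):
        mat[i, _BASE_INDEX[b]] = match_prob
    return PWM(motif_id, mat)


# ---------------------------------------------------------------------------
# MEME minimal format
# ---------------------------------------------------------------------------

def write_meme(pwms: Iterable[PWM], path) -> None:
    """Write motifs in MEME minimal format."""
    pwms = list(pwms)
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        bg = pwms[0].background if pwms else np.full(4, 0.25)
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} {f:.5f}" for b, f in zip(BASES, bg)) + "\n\n")
        for p in pwms:
            fh.write(f"MOTIF {p.motif_id}\n")
            fh.write(
                f"letter-probability matrix: alphabet= ACGT w= {p.length} "
                f"nsites= 20 E= 0\n"
            )
            for row in p.matrix:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")


def read_meme(path) -> list[PWM]:
    """Read a MEME minimal motif library (via Bio.motifs)."""
    from Bio import motifs as bio_motifs

    with open(path) as fh:
        records = bio_motifs.parse(fh, "minimal")
    out = []
    for m in records:
        mat = np.array([[m.pwm[b][i] for b in BASES] for i in range(m.length)])
        mat /= mat.sum(axis=1, keepdims=True)
        bg = np.array([m.background[b] for b in BASES])
        out.append(PWM(m.name, mat, bg))
    return out


# ---------------------------------------------------------------------------
# Scanning
# ---------------------------------------------------------------------------

def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.int64)  # default: N
    for b, i in _BASE_INDEX.items():
        out[arr == ord(b)] = i
    return out


def _window_scores(codes: np.ndarray, log_odds: np.ndarray) -> np.ndarray:
    L = log_odds.shape[0]
    n = len(codes) - L + 1
    if n <= 0:
        return np.empty(0)
    scores = np.zeros(n)
    for j in range(L):
        scores += log_odds[j][codes[j:j + n]]
    return scores


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def scan_pwm(
    sequences: Mapping[str, str], pwm: PWM, threshold: float | None = None
) -> pd.DataFrame:
    """Scan sequences on both strands; hits score >= the motif threshold.

    Returns a frame with columns (sequence_id, offset, strand, score); the
    offset of a minus-strand hit is the start of the motif footprint on the
    forward strand.  Sequences shorter than the motif yield no hits.
    """
    thr = pwm.score_threshold if threshold is None else threshold
    lo = pwm.log_odds
    rows = []
    for sid, seq in sequences.items():
        codes = _encode(seq)
        fwd = _window_scores(codes, lo)
        for off in np.nonzero(fwd >= thr)[0]:
            rows.append((sid, int(off), "+", float(fwd[off])))
        rc = _encode(reverse_complement(seq))
        rev = _window_scores(rc, lo)
        L = pwm.length
        for off in np.nonzero(rev >= thr)[0]:
            rows.append((sid, len(seq) - L - int(off), "-", float(rev[off])))
    return pd.DataFrame(rows, columns=["sequence_id", "offset", "strand", "score"])


def hit_indicator(sequences: Mapping[str, str], pwm: PWM) -> np.ndarray:
    """Boolean per-region presence of at least one motif hit."""
    hits = scan_pwm(sequences, pwm)
    with_hit = set(hits["sequence_id"])
    return np.array([sid in with_hit for sid in sequences], dtype=bool)


# ---------------------------------------------------------------------------
# Relative enrichment
# ---------------------------------------------------------------------------

@dataclass
class MotifEnrichmentResult:
    motif_id: str
    set_a_hit_fraction: float
    set_b_hit_fraction: float
    re: float
    log2_re: float
    p: float
    ci_low: float
    ci_high: float
    n_boot: int
    no_signal: bool = False


def relative_enrichment(
    set_a_seqs: Mapping[str, str],
    set_b_seqs: Mapping[str, str],
    pwm: PWM,
    *,
    n_boot: int = 10_000,
    seed: int = 0,
) -> MotifEnrichmentResult:
    """Relative motif enrichment of set A over set B with bootstrap p.

    RE = (f_a + eps) / (f_b + eps) with eps = 1 / (2 * min(n_a, n_b)).  The
    bootstrap resamples regions with replacement within each set; the
    one-sided p for an enrichment claim is the fraction of resamples with
    RE <= 1.  The 95% CI is the percentile interval of the bootstrap RE.
    With both hit fractions zero, RE = 1 by pseudocount and the result is
    flagged ``no_signal``.
    """
    if not set_a_seqs or not set_b_seqs:
        raise ValueError("both region sets must be non-empty")
    hits_a = hit_indicator(set_a_seqs, pwm)
    hits_b = hit_indicator(set_b_seqs, pwm)
    na, nb = len(hits_a), len(hits_b)
    eps = 1.0 / (2 * min(na, nb))
    fa, fb = float(hits_a.mean()), float(hits_b.mean())
    re = (fa + eps) / (fb + eps)
    rng = np.random.default_rng(seed)
    # region bootstrap of 0/1 indicators == binomial resampling of hit counts
    boot_fa = rng.binomial(na, fa, size=n_boot) / na
    boot_fb = rng.binomial(nb, fb, size=n_boot) / nb
    boot_re = (boot_fa + eps) / (boot_fb + eps)
    p = float((boot_re <= 1.0).mean())
    lo, hi = np.percentile(boot_re, [2.5, 97.5])
    no_signal = hits_a.sum() == 0 and hits_b.sum() == 0
    if no_signal:
        log.info("motif %s: no hits in either set", pwm.motif_id)
    return MotifEnrichmentResult(
        pwm.motif_id, fa, fb, float(re), float(np.log2(re)), p,
        float(lo), float(hi), n_boot, no_signal,
    )


def region_sequences(
    regions: Iterable[GenomicInterval],
    genome: Mapping[str, str],
    width: int = DEFAULT_SCAN_WIDTH,
) -> dict[str, str]:
    """Midpoint-centered fixed-width sequences for a region set.

    Standardizing width before scanning keeps the two sides of an RE
    comparison length-matched.  ``genome`` maps chromosome name to sequence
    (a ``pyfaidx.Fasta`` works too).
    """
    out: dict[str, str] = {}
    for i, iv in enumerate(regions):
        mid = iv.midpoint
        lo = max(0, mid - width // 2)
        hi = lo + width
        seq = genome[iv.chrom][lo:hi]
        out[f"{iv.chrom}:{lo}-{hi}#{i}"] = str(seq)
    return out


def re_matrix(
    pattern_table: pd.DataFrame,
    pwm_library: Sequence[PWM],
    genome: Mapping[str, str],
    *,
    expressed: Mapping[str, Sequence[str]] | None = None,
    width: int = DEFAULT_SCAN_WIDTH,
    n_boot: int = 2_000,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    """Motifs x 30 ordered stage-pair matrix of log2 RE, with clustering.

    For each ordered pair (a, b), set A holds the distal DHS open in *a* and
    closed in *b*, set B the reverse, and each motif's log2 RE(A, B) fills
    the (motif, a-vs-b) cell.  When ``expressed`` maps each stage to the
    motifs of TFs expressed there, motifs not expressed in the focal stage
    *a* are left missing.  Rows are clustered by average linkage on
    Euclidean distance (missing values treated as 0 for the distance);
    returns (matrix, linkage, leaf-ordered motif ids).
    """
    from .dhs import unique_stage_dhs

    cols = [f"{a}-vs-{b}" for a in STAGES for b in STAGES if a != b]
    mat = pd.DataFrame(np.nan, index=[p.motif_id for p in pwm_library], columns=cols)
    seq_cache: dict[tuple[str, str], dict[str, str]] = {}

    def seqs_for(a: str, b: str) -> dict[str, str]:
        if (a, b) not in seq_cache:
            rows = unique_stage_dhs(pattern_table, a, b)
            ivs = [GenomicInterval(c, int(s), int(e))
                   for c, s, e in zip(rows["chrom"], rows["start"], rows["end"])]
            seq_cache[(a, b)] = region_sequences(ivs, genome, width)
        return seq_cache[(a, b)]

    for a in STAGES:
        allowed = set(expressed[a]) if expressed is not None else None
        for b in STAGES:
            if a == b:
                continue
            col = f"{a}-vs-{b}"
            sa, sb = seqs_for(a, b), seqs_for(b, a)
            if not sa or not sb:
                log.info("empty unique-DHS set for %s; column left missing", col)
                continue
            for k, pwm in enumerate(pwm_library):
                if allowed is not None and pwm.motif_id not in allowed:
                    continue
                res = relative_enrichment(sa, sb, pwm, n_boot=n_boot,
                                          seed=seed + 37 * k)
                mat.loc[pwm.motif_id, col] = res.log2_re
    filled = mat.fillna(0.0).to_numpy()
    if len(mat) > 1:
        linkage = average(pdist(filled, metric="euclidean"))
        order = [mat.index[i] for i in leaves_list(linkage)]
    else:
        linkage = np.empty((0, 4))
        order = list(mat.index)
    return mat, linkage, order


def motif_colocalization(
    tf_peaks: Sequence[GenomicInterval],
    pwm: PWM,
    genome: Mapping[str, str],
    background_regions: Sequence[GenomicInterval],
    *,
    width: int = DEFAULT_SCAN_WIDTH,
    n_boot: int = 10_000,
    seed: int = 0,
    alpha: float = 0.01,
) -> tuple[MotifEnrichmentResult, bool]:
    """Is a motif enriched (co-localized) inside a TF's ChIP peaks?

    Compares motif hit fractions in length-matched peak vs background
    windows via ``relative_enrichment``; significant iff bootstrap p <
    ``alpha``.  A background smaller than the peak set is used as-is (the
    bootstrap resamples with replacement) with a logged note.
    """
    if not len(tf_peaks):
        raise ValueError("empty peak set")
    if not len(background_regions):
        raise ValueError("empty background set")
    if len(background_regions) < len(tf_peaks):
        log.info("background smaller than peak set; bootstrap resamples with replacement")
    res = relative_enrichment(
        region_sequences(tf_peaks, genome, width),
        region_sequences(background_regions, genome, width),
        pwm, n_boot=n_boot, seed=seed,
    )
    return res, bool(res.p < alpha and not res.no_signal)
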