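"""Chromatin-state model: binarization, EM, decoding, coarse graining."""

import itertools

import numpy as np
import pytest
from scipy.stats import poisson

from hemodyn import chromstate as C
from hemodyn.intervals import GeneModel, GenomicInterval
from hemodyn.simulate import generate_hmm_fixture


def test_binarize_examples():
    assert C.binarize(np.full(100, 5)).sum() == 0          # all equal
    counts = np.ones(10_000)
    counts[0] = 20
    out = C.binarize(counts, 1e-4)
    mu = counts.mean()
    assert poisson.sf(19, mu) < 1e-4                        # exact tail oracle
    assert out[0] == 1 and out[1:].sum() == 0
    assert C.binarize(np.array([0, 5, 5, 5]), 0.5)[0] == 0  # zero never called
    with pytest.raises(ValueError):
        C.binarize(np.array([]))
    with pytest.raises(ValueError):
        C.binarize(np.ones(5), 1.5)


def _two_state():
    em = np.array([[0.9, 0.9, 0.1, 0.1, 0.1],
                   [0.1, 0.1, 0.9, 0.9, 0.9]])
    return generate_hmm_fixture(10_000, seed=5, emission=em), em


def test_fit_hmm_recovers_planted_two_state_model():
    (X, states, em, tr), _ = _two_state()
    model = C.fit_hmm(X, 2, seed=1)
    lls = np.array(model.log_likelihoods)
    assert (np.diff(lls) >= -1e-8).all()                    # EM monotonicity
    perm = C.match_states(em, model.emission)
    assert np.abs(model.emission[perm] - em).max() < 0.05
    # decoding accuracy on the planted path
    inv = np.empty(2, dtype=int)
    inv[perm] = np.arange(2)
    acc = (inv[C.decode_states(model, X)] == states).mean()
    assert acc >= 0.95
    # determinism
    again = C.fit_hmm(X, 2, seed=1)
    assert np.array_equal(again.emission, model.emission)


def test_fit_hmm_k1_matches_empirical_frequency():
    rng = np.random.default_rng(0)
    X = (rng.random((2_000, 3)) < [0.2, 0.5, 0.8]).astype(float)
    model = C.fit_hmm(X, 1, marks=("a", "b", "c"), seed=0)
    assert np.allclose(model.emission[0], X.mean(axis=0), atol=1e-6)


def test_fit_hmm_warns_on_degenerate_states(caplog):
    X = np.zeros((50, 2))
    with caplog.at_level("WARNING"):
        C.fit_hmm(X, 3, marks=("a", "b"), seed=0, max_iter=5)
    assert any("degenerate" in r.message for r in caplog.records)


def test_forward_backward_likelihoods_agree():
    (X, _, em, _), _ = _two_state()
    model = C.fit_hmm(X[:1_000], 2, seed=2, max_iter=20)
    f = C.forward_loglik(model, X[:1_000])
    b = C.backward_loglik(model, X[:1_000])
    assert abs(f - b) <= 1e-8 * abs(f)


def test_likelihood_matches_hmmlearn_categorical_oracle():
    """Independent route: encode the M binary marks as 2^M categorical
    symbols and compare total log-likelihood with hmmlearn."""
    from hmmlearn.hmm import CategoricalHMM

    (X, _, em, tr), _ = _two_state()
    X = X[:2_000]
    model = C.ChromatinStateModel(
        emission=em, transition=tr, initial=np.array([0.5, 0.5]))
    M = em.shape[1]
    combos = np.array(list(itertools.product([0, 1], repeat=M)), dtype=float)
    cat_emission = np.exp(
        combos @ np.log(em).T + (1 - combos) @ np.log(1 - em).T).T
    symbols = (X @ (2 ** np.arange(M - 1, -1, -1))).astype(int)
    hm = CategoricalHMM(n_components=2, init_params="")
    hm.startprob_ = np.array([0.5, 0.5])
    hm.transmat_ = tr
    hm.emissionprob_ = cat_emission
    assert C.forward_loglik(model, X) == pytest.approx(
        hm.score(symbols.reshape(-1, 1)), rel=1e-9)


def test_decode_degenerate_cases():
    em = np.array([[0.01, 0.01], [0.9, 0.9]])
    model = C.ChromatinStateModel(
        emission=em, transition=np.array([[0.9, 0.1], [0.1, 0.9]]),
        initial=np.array([0.5, 0.5]), marks=("a", "b"))
    silent_path = C.decode_states(model, np.zeros((50, 2)))
    assert (silent_path == 0).all()
    # single bin: argmax of initial * emission
    one = C.decode_states(model, np.array([[1.0, 1.0]]))
    assert one[0] == 1
    with pytest.raises(ValueError, match="mark mismatch"):
        C.decode_states(model, np.zeros((5, 2)), marks=("x", "y"))


@pytest.mark.parametrize(
    "marks,expected",
    [
        ({"DHS": 1, "H3K4me3": 1, "H3K9ac": 1, "H3K27me3": 0}, C.ACTIVE),
        ({"DHS": 0, "H3K27me3": 1}, C.REPRESSED),
        ({"DHS": 1, "H3K27me3": 1, "H3K4me3": 1}, C.POISED),
        ({"DHS": 1, "H3K27me3": 1, "H3K27ac": 1}, C.POISED),
        ({}, C.UNMARKED),
        ({"DHS": 1}, C.UNMARKED),
        ({"DHS": 1, "H3K4me3": 1}, C.UNMARKED),   # no acetylation
    ],
)
def test_coarse_grain_rule(marks, expected):
    assert C.coarse_grain_marks(marks) == expected


def test_coarse_grain_is_total_over_all_mark_combinations():
    seen = set()
    for combo in itertools.product([0, 1], repeat=5):
        state = C.coarse_grain_marks(dict(zip(C.MARKS, combo)))
        assert state in C.COARSE_STATES
        seen.add(state)
    assert seen == set(C.COARSE_STATES)


def test_coarse_grain_emission_threshold():
    row = np.array([0.8, 0.7, 0.9, 0.2, 0.1])
    assert C.coarse_grain_emission(row) == C.ACTIVE
    assert C.coarse_grain_emission(np.array([0.2, 0.1, 0.1, 0.1, 0.8])) == C.REPRESSED


def test_promoter_state_timeline_majority_and_sentinel(caplog):
    genes = [
        GeneModel("g1", "chr1", "+", 2_000, GenomicInterval("chr1", 2_000, 4_000)),
        GeneModel("g2", "chr9", "+", 2_000, GenomicInterval("chr9", 2_000, 4_000)),
    ]
    labels = np.array([C.UNMARKED] * 20, dtype=object)
    labels[5:15] = C.ACTIVE     # covers the g1 promoter window bins
    ann = {s: {"chr1": labels} for s in
           ("ESC", "MES", "HB", "HE", "HP", "MAC")}
    with caplog.at_level("WARNING"):
        tl = C.promoter_state_timeline(genes, ann, bin_size=200)
    assert tl["g1"] == "AAAAAA"
    assert tl["g2"] == "......"
    # tie precedence: equal POISED/ACTIVE counts resolve to POISED
    tie = np.array([C.POISED] * 5 + [C.ACTIVE] * 5 + [C.UNMARKED] * 10,
                   dtype=object)
    ann1 = {s: {"chr1": tie} for s in ("ESC", "MES", "HB", "HE", "HP", "MAC")}
    tl = C.promoter_state_timeline(
        [GeneModel("g3", "chr1", "+", 1_000, GenomicInterval("chr1", 900, 2_000))],
        ann1, bin_size=200)
    assert tl["g3"] == "PPPPPP"


def test_rule_path_recovers_planted_promoter_states(small_fixture):
    """Noise-free tracks -> binarize -> rule coarse labels -> timelines
    reproduce every planted promoter plan."""
    fx = small_fixture
    ann = {}
    for stage in ("ESC", "MES", "HB", "HE", "HP", "MAC"):
        per_chrom = {
            c: np.stack([C.binarize(fx.tracks[(m, stage)][c]) for m in C.MARKS],
                        axis=1)
            for c in sorted(fx.chrom_sizes)
        }
        ann[stage] = C.rule_coarse_tracks(per_chrom)
    tl = C.promoter_state_timeline(fx.genes, ann, fx.config.bin_size)
    assert all(tl[g.gene_id] == fx.promoter_plan[g.gene_id] for g in fx.genes)


def test_hmm_path_promoter_agreement(small_fixture):
    """Viterbi path of a fitted 8-state model, coarse-grained, agrees with
    >= 90% of planted promoter labels on the zero-noise fixture."""
    fx = small_fixture
    stages = ("ESC", "MES", "HB", "HE", "HP", "MAC")
    binar = {
        s: {c: np.stack([C.binarize(fx.tracks[(m, s)][c]) for m in C.MARKS], axis=1)
            for c in sorted(fx.chrom_sizes)}
        for s in stages
    }
    bs = fx.config.bin_size
    parts = []
    for s in stages:
        for c in sorted(fx.chrom_sizes):
            Xb = binar[s][c]
            sel = np.zeros(len(Xb), bool)
            for g in fx.genes:
                if g.chrom != c:
                    continue
                lo = max(0, (g.tss - 2_000) // bs)
                hi = min(len(Xb), -(-(g.tss + 2_000) // bs))
                sel[lo:hi] = True
            parts.append(Xb[sel])
            parts.append(Xb[~sel][::20])
    model = C.fit_hmm(np.vstack(parts), 8, seed=11, n_restarts=3, max_iter=60)
    ann = {s: C.decode_coarse_tracks(model, binar[s]) for s in stages}
    tl = C.promoter_state_timeline(fx.genes, ann, bs)
    pairs = [(a, b) for g in fx.genes
             for a, b in zip(tl[g.gene_id], fx.promoter_plan[g.gene_id])]
    agreement = sum(a == b for a, b in pairs) / len(pairs)
    assert agreement >= 0.90
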