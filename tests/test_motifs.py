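"""PWM scanning and relative motif enrichment."""

import numpy as np
import pytest

from hemodyn import motifs as M
from hemodyn.intervals import GenomicInterval
from hemodyn.simulate import MOTIF_CONSENSUS


def _random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def _brute_scores(seq, pwm):
    """Exhaustive per-window scoring oracle (forward strand)."""
    lo = pwm.log_odds
    idx = {b: i for i, b in enumerate("ACGTN")}
    L = pwm.length
    out = []
    for s in range(len(seq) - L + 1):
        out.append(sum(lo[j][idx.get(seq[s + j].upper(), 4)] for j in range(L)))
    return np.array(out)


def test_pwm_construction_and_validation():
    pwm = M.pwm_from_consensus("X", "ACGTACGTACGT")
    assert pwm.length == 12
    assert pwm.consensus == "ACGTACGTACGT"
    assert pwm.score_threshold == pytest.approx(0.8 * pwm.max_score)
    with pytest.raises(ValueError):
        M.PWM("bad", np.full((3, 4), 0.25))          # too short
    with pytest.raises(ValueError):
        M.PWM("bad", np.full((6, 4), 0.3))           # rows don't sum to 1


def test_scan_finds_planted_consensus_once():
    rng = np.random.default_rng(0)
    pwm = M.pwm_from_consensus("T", MOTIF_CONSENSUS["TEAD"])
    background = _random_seq(rng, 300)
    seq = background[:120] + pwm.consensus + background[120:]
    hits = M.scan_pwm({"s": seq}, pwm, threshold=0.9 * pwm.max_score)
    assert len(hits) == 1
    assert hits.iloc[0]["offset"] == 120 and hits.iloc[0]["strand"] == "+"


def test_scan_reverse_complement_strand():
    rng = np.random.default_rng(1)
    pwm = M.pwm_from_consensus("T", MOTIF_CONSENSUS["GATA"])
    rc = M.reverse_complement(pwm.consensus)
    seq = _random_seq(rng, 80) + rc + _random_seq(rng, 80)
    hits = M.scan_pwm({"s": seq}, pwm, threshold=0.9 * pwm.max_score)
    assert len(hits) == 1
    assert hits.iloc[0]["strand"] == "-" and hits.iloc[0]["offset"] == 80


def test_scan_edge_cases():
    pwm = M.pwm_from_consensus("T", "ACGTACGTAC")
    assert len(M.scan_pwm({}, pwm)) == 0
    assert len(M.scan_pwm({"short": "ACG"}, pwm)) == 0
    hits = M.scan_pwm({"n": "N" * 40}, pwm)   # N never beats the threshold
    assert len(hits) == 0


def test_scan_matches_exhaustive_oracle_on_random_fixtures():
    rng = np.random.default_rng(42)
    for trial in range(50):
        L = int(rng.integers(6, 14))
        cons = "".join("ACGT"[i] for i in rng.integers(0, 4, size=L))
        pwm = M.pwm_from_consensus(f"m{trial}", cons,
                                   match_prob=float(rng.uniform(0.5, 0.9)))
        seq = _random_seq(rng, int(rng.integers(L, 120)))
        thr = float(rng.uniform(0.4, 0.95)) * pwm.max_score
        hits = M.scan_pwm({"s": seq}, pwm, threshold=thr)
        fwd = _brute_scores(seq, pwm)
        rev = _brute_scores(M.reverse_complement(seq), pwm)
        expected = int((fwd >= thr).sum() + (rev >= thr).sum())
        assert len(hits) == expected
        for _, h in hits[hits.strand == "+"].iterrows():
            assert fwd[int(h.offset)] == pytest.approx(h.score)


def test_relative_enrichment_identity_and_no_signal():
    rng = np.random.default_rng(3)
    pwm = M.pwm_from_consensus("T", MOTIF_CONSENSUS["TEAD"])
    seqs = {f"r{i}": _random_seq(rng, 200) for i in range(50)}
    same = M.relative_enrichment(seqs, dict(seqs), pwm, n_boot=2_000, seed=0)
    assert same.re == pytest.approx(1.0)
    assert same.log2_re == pytest.approx(0.0)
    if same.set_a_hit_fraction == 0:
        assert same.no_signal
    with pytest.raises(ValueError):
        M.relative_enrichment({}, seqs, pwm)


def test_relative_enrichment_detects_planted_difference():
    rng = np.random.default_rng(4)
    pwm = M.pwm_from_consensus("T", MOTIF_CONSENSUS["TEAD"])
    def build(n, frac):
        out = {}
        for i in range(n):
            seq = _random_seq(rng, 200)
            if i < frac * n:
                seq = seq[:90] + pwm.consensus + seq[90 + pwm.length:]
            out[f"s{i}"] = seq
        return out
    a, b = build(200, 0.5), build(200, 0.05)
    res = M.relative_enrichment(a, b, pwm, n_boot=5_000, seed=1)
    assert res.p < 0.01
    assert res.ci_low <= 10.0 <= res.ci_high      # planted ratio in 95% CI
    # reciprocal comparison multiplies to 1 (equal set sizes)
    rev = M.relative_enrichment(b, a, pwm, n_boot=5_000, seed=2)
    assert res.re * rev.re == pytest.approx(1.0, rel=1e-9)


def test_bootstrap_p_monotone_in_enrichment_strength():
    rng = np.random.default_rng(5)
    pwm = M.pwm_from_consensus("T", MOTIF_CONSENSUS["TEAD"])
    def build(n, frac, tag):
        out = {}
        for i in range(n):
            seq = _random_seq(rng, 200)
            if i < frac * n:
                seq = seq[:50] + pwm.consensus + seq[50 + pwm.length:]
            out[f"{tag}{i}"] = seq
        return out
    b = build(300, 0.05, "b")
    ps = []
    for fa in (0.05, 0.1, 0.2, 0.4):
        res = M.relative_enrichment(build(300, fa, "a"), b, pwm,
                                    n_boot=4_000, seed=6)
        ps.append(res.p)
    assert all(x >= y for x, y in zip(ps, ps[1:]))


def test_meme_round_trip(tmp_path):
    pwms = [M.pwm_from_consensus(m, c) for m, c in sorted(MOTIF_CONSENSUS.items())]
    path = tmp_path / "lib.meme"
    M.write_meme(pwms, path)
    back = M.read_meme(path)
    assert [p.motif_id for p in back] == [p.motif_id for p in pwms]
    for orig, rt in zip(pwms, back):
        assert np.allclose(orig.matrix, rt.matrix, atol=1e-4)


def test_re_matrix_planted_motif_and_leaf_determinism(small_fixture):
    from hemodyn import dhs as D
    from hemodyn.intervals import STAGES

    fx = small_fixture
    stage_sets = {s: D.filter_reproducible(fx.dhs_replicates(s)) for s in STAGES}
    table = D.classify_proximal_distal(D.encode_patterns(stage_sets), fx.genes)
    lib = [p for p in fx.pwms if p.motif_id in ("TEAD", "GATA")]
    mat, linkage, order = M.re_matrix(table, lib, fx.genome, n_boot=500, seed=0)
    # TEAD was planted in HB-unique DHS: its HB-vs-MAC cell beats GATA's
    assert mat.loc["TEAD", "HB-vs-MAC"] > 1.0
    assert mat.loc["TEAD", "HB-vs-MAC"] > mat.loc["GATA", "HB-vs-MAC"]
    assert set(order) == {"TEAD", "GATA"}
    mat2, _, order2 = M.re_matrix(table, lib, fx.genome, n_boot=500, seed=0)
    assert order2 == order and mat2.equals(mat)


def test_motif_colocalization_planted_vs_background(small_fixture):
    fx = small_fixture
    tead = next(p for p in fx.pwms if p.motif_id == "TEAD")
    peaks = fx.tf_peaks[("Tal1", "HB")]
    background_rows = fx.dhs_truth[fx.dhs_truth["code"] == "111111"]
    background = [GenomicInterval(c, int(s), int(e)) for c, s, e in
                  zip(background_rows["chrom"], background_rows["start"],
                      background_rows["end"])]
    res, sig = M.motif_colocalization(peaks, tead, fx.genome, background,
                                      n_boot=4_000, seed=1)
    assert sig                                   # TEAD planted in 40% of peaks
    _, sig_b = M.motif_colocalization(
        fx.tf_peaks[("Cebpb", "MAC")], tead, fx.genome, background,
        n_boot=4_000, seed=2)
    assert not sig_b                             # TEAD only at background rate
    with pytest.raises(ValueError):
        M.motif_colocalization([], tead, fx.genome, background)
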