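"""Log-odds scoring, exact p-values (DP vs enumeration) and site calling."""

import itertools

import numpy as np
import pytest

from telochec import pwm
from telochec.pwm import CountMatrix, call_sites, log_odds, pvalue_exact

UNIFORM = np.full(4, 0.25)


def brute_force_pvalue(matrix: np.ndarray, score: float) -> float:
    """Exhaustive exceedance frequency over all 4**L windows (oracle)."""
    L = matrix.shape[1]
    idx = np.array(list(itertools.product(range(4), repeat=L)))
    totals = matrix[idx.T, np.arange(L)[:, None]].sum(axis=0)
    return float((totals >= score).mean())


def test_uniform_matrix_scores_zero():
    m = log_odds(CountMatrix("u", np.ones((4, 1))), UNIFORM, pseudocount=0.0)
    assert np.allclose(m, 0.0)


def test_single_base_column_scores_two_bits():
    counts = np.array([[1.0], [0.0], [0.0], [0.0]])
    m = log_odds(counts, UNIFORM, pseudocount=0.0)
    assert m[0, 0] == pytest.approx(2.0)
    assert np.isneginf(m[1:, 0]).all()


def test_zero_column_total_rejected_without_pseudocount():
    with pytest.raises(ValueError):
        log_odds(np.zeros((4, 2)), UNIFORM, pseudocount=0.0)


def test_expected_column_score_matches_sampling():
    rng = np.random.default_rng(42)
    counts = rng.integers(0, 60, size=(4, 6)).astype(float) + 1
    m = log_odds(counts, UNIFORM)
    closed = (UNIFORM[:, None] * m).sum(axis=0)
    draws = rng.integers(0, 4, size=(200_000, 6))
    sampled = m[draws, np.arange(6)].mean(axis=0)
    assert np.allclose(sampled, closed, atol=0.02)


def test_pvalue_single_column_max_is_quarter():
    counts = np.array([[100.0], [0.0], [0.0], [0.0]])
    m = log_odds(counts, UNIFORM)
    assert pvalue_exact(m, m.max()) == pytest.approx(0.25)


def test_pvalue_below_minimum_is_one():
    m = log_odds(np.ones((4, 3)) + np.eye(4, 3) * 50, UNIFORM)
    assert pvalue_exact(m, m.min(axis=0).sum() - 5.0) == 1.0


@pytest.mark.parametrize("matrix_id", ["MA0363.1", "random"])
def test_dp_pvalue_matches_brute_force(matrix_id):
    """DP tail equals exhaustive enumeration within the score-grid tolerance."""
    if matrix_id == "random":
        rng = np.random.default_rng(7)
        counts = rng.integers(0, 40, size=(4, 5)).astype(float)
        m = log_odds(counts, UNIFORM)
    else:
        m = log_odds(pwm.bundled_matrices()[matrix_id], UNIFORM)
    L = m.shape[1]
    g = pwm.DEFAULT_GRANULARITY
    for q in (0.05, 0.3, 0.6, 0.9, 0.999):
        s = float(np.quantile(
            m[np.random.default_rng(1).integers(0, 4, (4000, L)), np.arange(L)].sum(1), q
        ))
        dp = pvalue_exact(m, s)
        assert brute_force_pvalue(m, s + L * g) <= dp <= brute_force_pvalue(m, s - L * g)


def test_pvalue_monotone_nonincreasing_in_score():
    m = log_odds(pwm.bundled_matrices()["MA0363.1"], UNIFORM)
    scores = np.linspace(m.min(axis=0).sum(), m.max(axis=0).sum(), 25)
    ps = [pvalue_exact(m, s) for s in scores]
    assert all(a >= b for a, b in zip(ps, ps[1:]))
    assert ps[0] == 1.0


def test_consensus_called_on_plus_strand_at_zero():
    mat = pwm.bundled_matrices()["MA0363.1"]
    sites = call_sites(mat.consensus, mat, p_threshold=1e-3)
    assert [(s.position, s.strand) for s in sites] == [(0, "+")]


def test_reverse_complement_called_on_minus_strand():
    mat = pwm.bundled_matrices()["MA0363.1"]
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    rc = "".join(comp[b] for b in reversed(mat.consensus))
    sites = call_sites(rc, mat, p_threshold=1e-3)
    assert [(s.position, s.strand) for s in sites] == [(0, "-")]


def test_strand_symmetry_on_random_sequence():
    rng = np.random.default_rng(3)
    seq = "".join(rng.choice(list("ACGT"), 400))
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    rc = "".join(comp[b] for b in reversed(seq))
    mat = pwm.bundled_matrices()["MA0403.1"]
    fwd = call_sites(seq, mat, p_threshold=0.02)
    rev = call_sites(rc, mat, p_threshold=0.02)
    L = mat.length
    mirrored = sorted((len(seq) - L - s.position, "+-"[s.strand == "+"]) for s in rev)
    assert sorted((s.position, s.strand) for s in fwd) == mirrored


def test_short_sequence_yields_no_calls():
    mat = pwm.bundled_matrices()["MA0403.1"]
    assert call_sites("ACGT", mat) == []


def test_empirical_fpr_matches_exact_tail():
    """Per-window exceedance on uniform background matches pvalue_exact.

    The score distribution is discrete, so the effective false-positive rate
    is the largest attainable tail below the nominal threshold, not the
    threshold itself; the empirical rate must match that tail within
    binomial error.
    """
    rng = np.random.default_rng(9)
    seq = "".join(rng.choice(list("ACGT"), 40_000))
    mat = pwm.bundled_matrices()["MA0363.1"]
    p = 0.01
    m = log_odds(mat, UNIFORM)
    dist, _ = pwm.score_distribution(m, UNIFORM)
    tail = dist[::-1].cumsum()[::-1]
    effective = float(tail[tail < p].max())
    calls = call_sites(seq, mat, p_threshold=p)
    n_windows = 2 * (len(seq) - mat.length + 1)
    rate = len(calls) / n_windows
    sd = np.sqrt(effective * (1 - effective) / n_windows)
    assert abs(rate - effective) < 4 * sd + 5e-4


def test_planted_motifs_recovered_on_synthetic_template():
    from telochec import build_template, synthesize_sequence

    t = build_template("YpTRF")
    seq = synthesize_sequence(t, seed=3)
    mats = pwm.bundled_matrices()
    for kind, mid, thr in [("Tbf1_site", "MA0403.1", 5e-3),
                           ("Reb1_site", "MA0363.1", 1e-3)]:
        starts = {c.position for c in call_sites(seq, mats[mid], thr)}
        for f in t.features_of(kind):
            assert f.start in starts, f"planted {kind} at {f.start} missed"


def test_ambiguity_codes_score_background_average():
    mat = pwm.bundled_matrices()["MA0363.1"]
    m = log_odds(mat, UNIFORM)
    seq_n = "N" * mat.length
    sites = call_sites(seq_n, mat, p_threshold=0.999999)
    expected = float((UNIFORM[:, None] * m).sum())
    assert sites and sites[0].score == pytest.approx(expected, abs=1e-9)
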