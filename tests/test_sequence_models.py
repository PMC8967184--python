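"""PAM250 mean-distance and continuous binomial enrichment scoring."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ddmc import (
    AA_ORDER,
    PAM250,
    BinomialSeqModel,
    binomial_background,
    continuous_binomial_cdf,
    encode_sequences,
    pam250_cluster_score,
    pam250_pairwise,
)
from conftest import make_windows


def binomial_cdf_by_summation(k, n, p):
    """Independent oracle: direct summation of the binomial pmf."""
    return sum(math.comb(n, j) * p**j * (1 - p) ** (n - j) for j in range(k + 1))


class TestPam250Constant:
    def test_matches_biopython_reference(self):
        from Bio.Align import substitution_matrices

        ref = substitution_matrices.load("PAM250")
        expected = np.array([[ref[a][b] for b in AA_ORDER] for a in AA_ORDER])
        np.testing.assert_array_equal(PAM250, expected)

    def test_symmetric(self):
        np.testing.assert_array_equal(PAM250, PAM250.T)


class TestPam250Pairwise:
    def test_identical_pentapeptides_score_ten(self):
        # 4 x PAM250(A, A) + PAM250(S, S) = 4 x 2 + 2 = 10
        P = pam250_pairwise(make_windows(["AASAA", "AASAA"]))
        assert P[0, 1] == 10

    def test_matches_brute_force_lookup(self):
        rng = np.random.default_rng(0)
        strings = []
        for _ in range(3):
            chars = [AA_ORDER[i] for i in rng.integers(0, 20, size=5)]
            chars[2] = "S"
            strings.append("".join(chars))
        windows = make_windows(strings)
        P = pam250_pairwise(windows)
        for a in range(3):
            for b in range(3):
                expected = sum(
                    PAM250[AA_ORDER.index(x), AA_ORDER.index(y)]
                    for x, y in zip(strings[a], strings[b])
                )
                assert P[a, b] == expected
        np.testing.assert_array_equal(P, P.T)

    def test_padded_positions_contribute_zero(self):
        P_pad = pam250_pairwise(make_windows(["--SAA", "GGSAA"]))
        # overlap is S,A,A at positions 0..+2, same total as the 3-mer A,S,A
        P_ref = pam250_pairwise(make_windows(["ASA", "ASA"]))
        assert P_pad[0, 1] == P_ref[0, 1]


class TestPam250ClusterScore:
    def test_zero_vector_gives_zero(self, toy_windows):
        P = pam250_pairwise(toy_windows)
        np.testing.assert_array_equal(pam250_cluster_score(P, np.zeros(3)), 0.0)

    def test_single_peptide_self_score(self):
        P = pam250_pairwise(make_windows(["AASAA"]))
        w = pam250_cluster_score(P, np.array([1.0]))
        assert w[0] == P[0, 0]

    def test_matches_explicit_loop(self, toy_windows):
        P = pam250_pairwise(toy_windows)
        v = np.array([0.2, 0.3, 0.5])
        w = pam250_cluster_score(P, v)
        expected = [sum(P[a, b] * v[b] for b in range(3)) / 3 for a in range(3)]
        np.testing.assert_allclose(w, expected)

    @given(
        alpha=st.floats(-2, 2),
        beta=st.floats(-2, 2),
        seed=st.integers(0, 100),
    )
    @settings(max_examples=25, deadline=None)
    def test_linear_in_responsibilities(self, alpha, beta, seed):
        rng = np.random.default_rng(seed)
        P = rng.normal(size=(4, 4))
        P = P + P.T
        v1, v2 = rng.random(4), rng.random(4)
        lhs = pam250_cluster_score(P, alpha * v1 + beta * v2)
        rhs = alpha * pam250_cluster_score(P, v1) + beta * pam250_cluster_score(P, v2)
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)


class TestBackground:
    def test_columns_sum_to_one(self, toy_windows):
        G = binomial_background(encode_sequences(toy_windows))
        np.testing.assert_allclose(G.sum(axis=0), 1.0)
        assert np.all(G > 0) and np.all(G < 1)

    def test_hand_counted_frequencies(self):
        windows = make_windows(["AASAA", "AASAA", "GASAA", "GGSAA"])
        G = binomial_background(encode_sequences(windows), pseudocount=0.05)
        a, g = AA_ORDER.index("A"), AA_ORDER.index("G")
        # position -2: A,A,G,G -> (2 + .05)/(4 + 1)
        assert G[a, 0] == pytest.approx((2 + 0.05) / 5)
        assert G[g, 0] == pytest.approx((2 + 0.05) / 5)
        # position -1: A,A,A,G
        assert G[a, 1] == pytest.approx((3 + 0.05) / 5)

    def test_degenerate_column_tends_to_one(self):
        windows = make_windows(["ARSAA", "ARSAA", "ARSAA"])
        G = binomial_background(encode_sequences(windows), pseudocount=1e-12)
        r = AA_ORDER.index("R")
        assert G[r, 1] == pytest.approx(1.0, abs=1e-10)


class TestContinuousBinomial:
    def test_k_zero_closed_form(self):
        # I_{0.5}(1, 1) = 0.5: with no observed counts, M = (1-G)^n
        assert continuous_binomial_cdf(0.0, 1.0, 0.5) == pytest.approx(0.5)
        assert continuous_binomial_cdf(0.0, 3.0, 0.25) == pytest.approx(0.75**3)

    def test_integer_case_matches_summation(self):
        # n=10, k=3, G=0.25
        expected = binomial_cdf_by_summation(3, 10, 0.25)
        assert continuous_binomial_cdf(3.0, 10.0, 0.25) == pytest.approx(expected, rel=1e-12)

    def test_boundary_k_equals_n(self):
        assert continuous_binomial_cdf(5.0, 5.0, 0.3) == 1.0

    @given(
        n=st.integers(1, 50),
        frac=st.floats(0, 1),
        G=st.sampled_from([0.01, 0.05, 0.1, 0.25, 0.5]),
    )
    @settings(max_examples=60, deadline=None)
    def test_integer_equivalence_grid(self, n, frac, G):
        k = int(round(frac * n))
        got = float(continuous_binomial_cdf(float(k), float(n), G))
        expected = binomial_cdf_by_summation(k, n, G)
        assert got == pytest.approx(expected, rel=1e-10, abs=1e-12)

    def test_monotone_in_k(self):
        ks = np.linspace(0, 8, 33)
        M = continuous_binomial_cdf(ks, 8.0, 0.3)
        assert np.all(np.diff(M) >= -1e-12)


class TestBinomialSeqModel:
    def test_empty_cluster_rejected(self, toy_windows):
        model = BinomialSeqModel(encode_sequences(toy_windows))
        with pytest.raises(ValueError, match="empty cluster"):
            model.fit_cluster(np.zeros(3))

    def test_score_all_ones_matrix_is_zero(self, toy_windows):
        model = BinomialSeqModel(encode_sequences(toy_windows))
        M = np.ones_like(model.background)
        np.testing.assert_allclose(model.score(M), 0.0)

    def test_score_matches_per_position_loop(self, toy_windows):
        model = BinomialSeqModel(encode_sequences(toy_windows))
        v = np.array([0.9, 0.4, 0.7])
        M = model.fit_cluster(v)
        w = model.score(M)
        for i, win in enumerate(toy_windows):
            expected = 0.0
            for k, p in enumerate(model.tensor.positions):
                res = win.residue_at(p)
                if res != "-":
                    expected += np.log(M[AA_ORDER.index(res), k])
            assert w[i] == pytest.approx(expected)

    def test_identical_sequences_get_identical_scores(self):
        windows = make_windows(["AAAAASAAAAA", "AAAAASAAAAA", "PKLMRTQWERA"])
        tensor = encode_sequences(windows)
        model = BinomialSeqModel(tensor)
        v = np.array([0.5, 0.2, 0.9])
        w_bin = model.score(model.fit_cluster(v))
        assert w_bin[0] == pytest.approx(w_bin[1])
        P = pam250_pairwise(tensor)
        w_pam = pam250_cluster_score(P, v)
        assert w_pam[0] == pytest.approx(w_pam[1])

    def test_hard_assignment_reproduces_integer_binomial(self):
        rng = np.random.default_rng(3)
        strings = []
        for _ in range(12):
            chars = [AA_ORDER[i] for i in rng.integers(0, 4, size=11)]
            chars[5] = "S"
            strings.append("".join(chars))
        tensor = encode_sequences(make_windows(strings))
        model = BinomialSeqModel(tensor)
        v = (rng.random(12) < 0.5).astype(float)
        if v.sum() == 0:
            v[0] = 1.0
        M = model.fit_cluster(v)
        n = int(v.sum())
        counts = np.einsum("ijk,i->jk", tensor.data, v)
        for j in range(20):
            for k in range(11):
                expected = binomial_cdf_by_summation(int(counts[j, k]), n, model.background[j, k])
                assert M[j, k] == pytest.approx(max(expected, 1e-10), rel=1e-10)
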