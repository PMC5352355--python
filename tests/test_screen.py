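"""Marker-screen computations against hand values and brute-force oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from alkscreen.screen import (
    ExpressionMatrix,
    ProbeMatrix,
    ValidationError,
    fold_change,
    match_probe,
    median_polish,
    median_polish_summarize,
    pearson_correlation,
    quantile_normalize,
    sam_two_class,
)


def _expr(values, labels):
    cols = [f"s{i}" for i in range(np.shape(values)[1])]
    return ExpressionMatrix(
        values=pd.DataFrame(values, columns=cols,
                            index=[f"g{i:03d}" for i in range(np.shape(values)[0])]),
        sample_labels=pd.Series(labels, index=cols),
    )


# ---------------------------------------------------------------------------
# quantile normalization
# ---------------------------------------------------------------------------

class TestQuantileNormalize:
    def test_hand_example(self):
        out = quantile_normalize(np.array([[1.0, 4.0], [3.0, 2.0]]))
        assert np.allclose(out, [[1.5, 3.5], [3.5, 1.5]])

    def test_identical_columns_fixed_point(self):
        x = np.tile(np.array([[3.0], [1.0], [2.0]]), (1, 4))
        assert np.allclose(quantile_normalize(x), x)

    def test_single_column_unchanged(self):
        x = np.array([[5.0], [1.0], [3.0]])
        assert np.allclose(quantile_normalize(x), x)

    def test_ties_get_mean_of_reference(self):
        # column 0 has a two-way tie at ranks 1 and 2
        x = np.array([[2.0, 1.0], [2.0, 5.0], [9.0, 6.0]])
        ref = np.sort(x, axis=0).mean(axis=1)
        out = quantile_normalize(x)
        assert out[0, 0] == out[1, 0] == pytest.approx(ref[:2].mean())

    def test_rejects_non_finite(self):
        with pytest.raises(ValidationError):
            quantile_normalize(np.array([[1.0, np.nan], [2.0, 3.0]]))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.floats(-50, 50, allow_nan=False), min_size=24, max_size=24,
            unique=True,
        ).map(lambda v: np.array(v).reshape(6, 4))
    )
    def test_idempotent_and_equal_column_sums(self, x):
        # tie-free input: the tie-averaging rule perturbs the reference
        # distribution, so exact idempotence is a property of distinct values
        once = quantile_normalize(x)
        assert np.allclose(quantile_normalize(once), once, atol=1e-12)
        sums = once.sum(axis=0)
        assert np.allclose(sums, sums[0], atol=1e-9)


# ---------------------------------------------------------------------------
# median polish
# ---------------------------------------------------------------------------

def brute_force_median_polish(x, n_sweeps=500):
    """Independent oracle: plain-Python alternating median sweeps."""
    x = [list(map(float, row)) for row in x]
    n, m = len(x), len(x[0])
    overall, row, col = 0.0, [0.0] * n, [0.0] * m

    def med(vals):
        s = sorted(vals)
        k = len(s)
        return s[k // 2] if k % 2 else (s[k // 2 - 1] + s[k // 2]) / 2.0

    for _ in range(n_sweeps):
        for i in range(n):
            d = med(x[i])
            row[i] += d
            for j in range(m):
                x[i][j] -= d
        d = med(col)
        overall += d
        for j in range(m):
            col[j] -= d
        for j in range(m):
            d = med([x[i][j] for i in range(n)])
            col[j] += d
            for i in range(n):
                x[i][j] -= d
        d = med(row)
        overall += d
        for i in range(n):
            row[i] -= d
    return overall, row, col, x


class TestMedianPolish:
    def test_hand_example_2x2(self):
        overall, row, col, resid = median_polish(np.array([[1.0, 2.0], [3.0, 4.0]]))
        assert overall == pytest.approx(2.5)
        assert np.allclose(row, [-1.0, 1.0])
        assert np.allclose(col, [-0.5, 0.5])
        assert np.allclose(resid, 0.0)
        # summarized expression = overall + column effects
        assert np.allclose(overall + col, [2.0, 3.0])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_random_4x6(self, seed):
        x = np.random.default_rng(seed).normal(size=(4, 6))
        got = median_polish(x, tol=1e-12, max_iter=1000)
        want = brute_force_median_polish(x)
        assert got[0] == pytest.approx(want[0], abs=1e-8)
        assert np.allclose(got[1], want[1], atol=1e-8)
        assert np.allclose(got[2], want[2], atol=1e-8)
        assert np.allclose(got[3], want[3], atol=1e-8)

    @pytest.mark.parametrize("seed", range(3))
    def test_decomposition_and_residual_medians(self, seed):
        x = np.random.default_rng(100 + seed).normal(size=(5, 7))
        overall, row, col, resid = median_polish(x, tol=1e-10)
        recon = overall + row[:, None] + col[None, :] + resid
        assert np.allclose(recon, x, atol=1e-12)
        assert np.abs(np.median(resid, axis=1)).max() < 1e-8
        assert np.abs(np.median(resid, axis=0)).max() < 1e-8

    def test_single_probe_set_returns_probe_row(self):
        values = pd.DataFrame(
            [[1.0, 5.0, 3.0]], index=["p1"], columns=["a", "b", "c"]
        )
        pm = ProbeMatrix(
            values=values,
            probeset_of=pd.Series({"p1": "PS1"}),
            sample_labels=pd.Series(["x", "x", "y"], index=["a", "b", "c"]),
        )
        expr = median_polish_summarize(pm)
        assert np.allclose(expr.values.loc["PS1"], [1.0, 5.0, 3.0])


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------

def exhaustive_sam_oracle(X, pos_mask, s0):
    """Independent q-values by full enumeration of label splits."""
    n = X.shape[1]
    n_pos = int(pos_mask.sum())

    def d_for(mask):
        x1, x2 = X[:, mask], X[:, ~mask]
        r = x1.mean(1) - x2.mean(1)
        ss = ((x1 - x1.mean(1, keepdims=True)) ** 2).sum(1) + (
            (x2 - x2.mean(1, keepdims=True)) ** 2
        ).sum(1)
        s = np.sqrt((1 / x1.shape[1] + 1 / x2.shape[1]) * ss / (n - 2))
        return r / (s + s0)

    d_obs = np.abs(d_for(pos_mask))
    perm_d = []
    for idx in itertools.combinations(range(n), n_pos):
        mask = np.zeros(n, dtype=bool)
        mask[list(idx)] = True
        perm_d.append(np.abs(d_for(mask)))
    perm_d = np.array(perm_d)
    q = np.empty(len(d_obs))
    for i, a in enumerate(d_obs):
        med_false = np.median((perm_d >= a).sum(axis=1))
        q[i] = min(1.0, med_false / (d_obs >= a).sum())
    # monotone in |d| ranking
    order = np.argsort(-d_obs, kind="mergesort")
    qs = q[order]
    qs = np.minimum.accumulate(qs[::-1])[::-1]
    out = np.empty_like(q)
    out[order] = qs
    return out


class TestSam:
    def test_exact_null_gives_zero_d_and_unit_q(self):
        # identical class means per gene, zero within-class variance
        # perturbation beyond a fixed pattern shared by the classes
        base = np.array([1.0, 2.0, 3.0])
        X = np.column_stack([base, base + 0.5, base - 0.5] * 2)
        expr = _expr(X, ["pos", "pos", "pos", "neg", "neg", "neg"])
        res = sam_two_class(expr, "pos", n_perm=50, seed=0)
        assert np.allclose(res["d_stat"], 0.0)
        assert np.allclose(res["q_value"], 1.0)

    def test_q_values_match_exhaustive_enumeration_3v3(self):
        rng = np.random.default_rng(42)
        X = rng.normal(size=(10, 6))
        X[0, :3] += 3.0  # one truly shifted gene
        labels = ["pos"] * 3 + ["neg"] * 3
        expr = _expr(X, labels)
        s0 = 0.1
        res = sam_two_class(expr, "pos", n_perm=1000, seed=0, s0=s0)
        want = exhaustive_sam_oracle(X, np.array([1, 1, 1, 0, 0, 0], bool), s0)
        got = res.sort_index()["q_value"].to_numpy()
        assert np.allclose(got, want, atol=1e-12)

    def test_s0_zero_equal_sizes_proportional_to_t(self):
        from scipy.stats import ttest_ind

        rng = np.random.default_rng(3)
        X = rng.normal(size=(20, 8))
        labels = ["pos"] * 4 + ["neg"] * 4
        expr = _expr(X, labels)
        res = sam_two_class(expr, "pos", n_perm=10, seed=0, s0=0.0).sort_index()
        t = ttest_ind(X[:, :4], X[:, 4:], axis=1).statistic
        ratio = res["d_stat"].to_numpy() / t
        assert np.allclose(ratio, ratio[0])

    def test_rejects_empty_class_and_bad_n_perm(self):
        expr = _expr(np.zeros((3, 4)), ["a"] * 4)
        with pytest.raises(ValidationError):
            sam_two_class(expr, "missing", n_perm=10)
        expr2 = _expr(np.zeros((3, 4)), ["a", "a", "b", "b"])
        with pytest.raises(ValidationError):
            sam_two_class(expr2, "a", n_perm=0)


# ---------------------------------------------------------------------------
# fold change / correlation
# ---------------------------------------------------------------------------

class TestFoldChangeAndCorrelation:
    @pytest.mark.parametrize(
        "diff,expected",
        [(0.0, 1.0), (math.log2(37.4), 37.4), (-1.0, 0.5)],
    )
    def test_fold_change_from_log2_difference(self, diff, expected):
        X = np.zeros((1, 6))
        X[0, :3] = diff
        expr = _expr(X, ["pos"] * 3 + ["neg"] * 3)
        assert fold_change(expr, "pos").iloc[0] == pytest.approx(expected)

    def test_fold_change_location_invariant(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(5, 8))
        labels = ["pos"] * 3 + ["neg"] * 5
        fc = fold_change(_expr(X, labels), "pos")
        fc_shift = fold_change(_expr(X + 4.2, labels), "pos")
        assert np.allclose(fc, fc_shift)

    @pytest.mark.parametrize(
        "x,y,expected",
        [
            ([1, 2, 3], [1, 2, 3], 1.0),
            ([1, 2, 3], [-1, -2, -3], -1.0),
            ([1, 2, 3], [2, 4, 6], 1.0),
        ],
    )
    def test_correlation_known_values(self, x, y, expected):
        assert pearson_correlation(x, y) == pytest.approx(expected)

    def test_correlation_rejects_zero_variance(self):
        with pytest.raises(ValidationError):
            pearson_correlation([1, 1, 1], [1, 2, 3])


# ---------------------------------------------------------------------------
# probe matching
# ---------------------------------------------------------------------------

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def brute_force_scan(probe, transcript, max_mm, both_strands=True):
    """Position-by-position Hamming scan, N matching nothing."""
    hits = []
    seqs = [("+", probe)]
    if both_strands:
        seqs.append(("-", "".join(_COMP[b] for b in reversed(probe))))
    for strand, p in seqs:
        for start in range(len(transcript) - len(p) + 1):
            mm = sum(
                1
                for a, b in zip(p, transcript[start : start + len(p)])
                if a != b or a == "N"
            )
            if mm <= max_mm:
                hits.append((start, strand, mm))
    return sorted(hits)


class TestMatchProbe:
    def test_exact_identity_hit(self):
        hits = match_probe("ACGT", [("t1", "ACGT")], max_mismatch=0)
        fwd = [h for h in hits if h.strand == "+"]
        assert len(fwd) == 1
        assert (fwd[0].start, fwd[0].mismatches) == (0, 0)

    def test_hamming_boundary(self):
        assert any(
            h.mismatches == 1 and h.strand == "+"
            for h in match_probe("ACGT", [("t", "AGGT")], max_mismatch=1)
        )
        assert not match_probe(
            "ACGT", [("t", "AGGT")], max_mismatch=0,
            search_reverse_complement=False,
        )

    def test_n_matches_nothing(self):
        hits = match_probe("ANGT", [("t", "ANGT")], max_mismatch=0,
                           search_reverse_complement=False)
        assert hits == []
        hits = match_probe("ANGT", [("t", "ANGT")], max_mismatch=1,
                           search_reverse_complement=False)
        assert len(hits) == 1 and hits[0].mismatches == 1

    def test_probe_longer_than_transcript_gives_no_hits(self):
        assert match_probe("ACGTACGT", [("t", "ACG")]) == []

    def test_invalid_characters_rejected(self):
        with pytest.raises(ValidationError):
            match_probe("ACGU", [("t", "ACGT")])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_random_sequences(self, seed):
        rng = np.random.default_rng(seed)
        bases = np.array(list("ACGT"))
        transcript = "".join(rng.choice(bases, size=1000))
        probe = "".join(rng.choice(bases, size=25))
        # guarantee at least one planted near-match
        pos = int(rng.integers(0, 975))
        transcript = transcript[:pos] + probe[:12] + "A" + probe[13:] + transcript[pos + 25 :]
        got = [
            (h.start, h.strand, h.mismatches)
            for h in match_probe(probe, [("t", transcript)], max_mismatch=2)
        ]
        assert sorted(got) == brute_force_scan(probe, transcript, 2)
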