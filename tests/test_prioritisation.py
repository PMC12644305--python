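import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from hdps import prioritisation as pri


def brute_force_stats(n, stratum="unexposed", correction=0.1):
    """Independent arithmetic oracle on an E x C x D contingency table.

    ``n[e][c][d]`` are cell counts; everything is computed with explicit
    loops and plain fractions.
    """
    n1 = sum(n[1][c][d] for c in (0, 1) for d in (0, 1))
    n0 = sum(n[0][c][d] for c in (0, 1) for d in (0, 1))
    c1 = sum(n[1][1][d] for d in (0, 1))
    c0 = sum(n[0][1][d] for d in (0, 1))
    p_c1 = c1 / n1
    p_c0 = c0 / n0
    rr_ce = p_c1 / p_c0

    es = (0,) if stratum == "unexposed" else (0, 1)
    d_c1 = sum(n[e][1][1] for e in es)
    n_c1 = sum(n[e][1][d] for e in es for d in (0, 1))
    d_c0 = sum(n[e][0][1] for e in es)
    n_c0 = sum(n[e][0][d] for e in es for d in (0, 1))
    if 0 in (d_c1, n_c1 - d_c1, d_c0, n_c0 - d_c0):
        rr_cd = ((d_c1 + correction) / (n_c1 + 2 * correction)) / \
                ((d_c0 + correction) / (n_c0 + 2 * correction))
    else:
        rr_cd = (d_c1 / n_c1) / (d_c0 / n_c0)
    rr = 1 / rr_cd if rr_cd < 1 else rr_cd
    bias = (p_c1 * (rr - 1) + 1) / (p_c0 * (rr - 1) + 1)
    return p_c1, p_c0, rr_cd, rr_ce, bias, abs(math.log(bias))


def expand(n):
    """Patient-level vectors from an E x C x D count table."""
    e, c, d = [], [], []
    for ee in (0, 1):
        for cc in (0, 1):
            for dd in (0, 1):
                k = n[ee][cc][dd]
                e += [ee] * k
                c += [cc] * k
                d += [dd] * k
    return np.array(c), np.array(e), np.array(d)


def random_table(rng, low=1, high=60):
    return [[[int(rng.integers(low, high)) for _ in range(2)] for _ in range(2)]
            for _ in range(2)]


class TestCrosstabStats:
    def test_independent_covariate_has_unit_rr_ce(self):
        # prevalence 0.3 in both arms
        n = [[[70, 0], [30, 0]], [[70, 0], [30, 0]]]
        c, e, d = expand(n)
        p1, p0, rr_cd, rr_ce = pri.crosstab_stats(c, e, d)
        assert rr_ce == 1.0 and p1 == p0 == 0.3

    def test_rr_cd_from_unexposed_risks(self):
        # among unexposed: risk 0.10 with C=1 (100 patients), 0.05 with C=0 (200)
        n = [[[190, 10], [90, 10]], [[50, 5], [20, 5]]]
        c, e, d = expand(n)
        _, _, rr_cd, _ = pri.crosstab_stats(c, e, d)
        assert rr_cd == pytest.approx(2.0, abs=1e-12)

    def test_matches_brute_force_oracle_on_random_tables(self, rng):
        for _ in range(25):
            n = random_table(rng)
            c, e, d = expand(n)
            got = pri.crosstab_stats(c, e, d)
            exp = brute_force_stats(n)
            for g, x in zip(got, exp[:4]):
                assert g == pytest.approx(x, abs=1e-12)

    def test_vectorised_scorer_agrees_with_scalar_path(self, rng):
        cols, e, d = {}, None, None
        tables = [random_table(rng) for _ in range(10)]
        # use one shared (e, d) layout: expand the first table, then random C
        _, e, d = expand(tables[0])
        for j in range(10):
            cols[f"c{j:02d}"] = rng.integers(0, 2, size=len(e))
        matrix = pd.DataFrame(cols)
        scores = pri.score_covariates(matrix, e, d)
        for _, row in scores.iterrows():
            p1, p0, rr_cd, rr_ce = pri.crosstab_stats(
                matrix[row["covariate_id"]], e, d)
            assert row["p_c1"] == pytest.approx(p1, abs=1e-12)
            assert row["p_c0"] == pytest.approx(p0, abs=1e-12)
            assert row["rr_cd"] == pytest.approx(rr_cd, abs=1e-12)
            assert row["rr_ce"] == pytest.approx(rr_ce, abs=1e-12)

    def test_empty_arm_rejected(self):
        with pytest.raises(ValueError, match="arm"):
            pri.crosstab_stats(np.array([0, 1]), np.array([1, 1]), np.array([0, 0]))


class TestBrossBias:
    def test_equal_prevalence_gives_unit_bias(self):
        bias, abs_log = pri.bross_bias(0.3, 0.3, 7.7)
        assert bias == 1.0 and abs_log == 0.0

    def test_null_outcome_association_gives_unit_bias(self):
        bias, _ = pri.bross_bias(0.6, 0.1, 1.0)
        assert bias == 1.0

    def test_worked_arithmetic_example(self):
        bias, abs_log = pri.bross_bias(0.6, 0.2, 2.0)
        assert bias == pytest.approx(1.6 / 1.2, abs=1e-12)
        assert abs_log == pytest.approx(math.log(4 / 3), abs=1e-12)

    def test_protective_rr_is_inverted(self):
        b_harm, _ = pri.bross_bias(0.4, 0.2, 2.0)
        b_prot, _ = pri.bross_bias(0.4, 0.2, 0.5)
        assert b_harm == pytest.approx(b_prot, abs=1e-12)

    def test_nonpositive_rr_rejected(self):
        with pytest.raises(ValueError):
            pri.bross_bias(0.4, 0.2, 0.0)

    @given(p1=st.floats(0.01, 0.99), p0=st.floats(0.01, 0.99),
           rr=st.floats(0.05, 20))
    def test_swapping_prevalences_inverts_multiplier(self, p1, p0, rr):
        b, al = pri.bross_bias(p1, p0, rr)
        b_swap, al_swap = pri.bross_bias(p0, p1, rr)
        assert b * b_swap == pytest.approx(1.0, rel=1e-9)
        assert al == pytest.approx(al_swap, rel=1e-9)


class TestInstrumentExclusion:
    def make_scores(self, rr_ce, rr_cd):
        return pd.DataFrame({"covariate_id": ["x"], "p_c1": [0.3], "p_c0": [0.1],
                             "rr_ce": [rr_ce], "rr_cd": [rr_cd],
                             "bias_mult": [1.2], "abs_log_bias": [0.18],
                             "iv_flag": [False], "rank": [pd.NA]})

    @pytest.mark.parametrize("rr_ce, rr_cd, flagged", [
        (4.0, 1.2, True),    # |log 4| = 1.386 > 1.1 and |log 1.2| = 0.18 < 0.5
        (4.0, 2.0, False),   # |log 2| = 0.693 >= 0.5
        (1.0, 1.0, False),   # |log 1| = 0
    ])
    def test_cutoff_arithmetic(self, rr_ce, rr_cd, flagged):
        out = pri.exclude_instrument_like(self.make_scores(rr_ce, rr_cd))
        assert bool(out["iv_flag"].iloc[0]) is flagged


class TestRanking:
    def test_descending_with_lexicographic_ties(self):
        scores = pd.DataFrame({
            "covariate_id": ["b", "a", "c"],
            "p_c1": 0.2, "p_c0": 0.1, "rr_ce": 1.5, "rr_cd": 1.5,
            "bias_mult": [1.3, 1.1, 1.3],
            "abs_log_bias": [0.3, 0.1, 0.3],
            "iv_flag": False, "rank": pd.NA})
        ranked = pri.rank_covariates(scores).set_index("covariate_id")
        assert ranked.loc["b", "rank"] == 1  # tie with c, 'b' < 'c'
        assert ranked.loc["c", "rank"] == 2
        assert ranked.loc["a", "rank"] == 3

    def test_ranking_matches_independent_sort(self, rng):
        n = 500
        scores = pd.DataFrame({
            "covariate_id": [f"v{i:03d}" for i in range(n)],
            "p_c1": rng.random(n), "p_c0": rng.random(n),
            "rr_ce": 1.0, "rr_cd": 1.0,
            "bias_mult": 1.0,
            "abs_log_bias": rng.random(n).round(3),  # rounded to force ties
            "iv_flag": False, "rank": pd.NA})
        ranked = pri.rank_covariates(scores)
        oracle = sorted(zip(-scores["abs_log_bias"], scores["covariate_id"]))
        expected_order = [cid for _, cid in oracle]
        got_order = ranked.sort_values("rank")["covariate_id"].tolist()
        assert got_order == expected_order

    def test_flagged_covariates_never_ranked_or_selected(self):
        scores = pd.DataFrame({
            "covariate_id": ["iv", "conf"],
            "p_c1": [0.6, 0.3], "p_c0": [0.1, 0.1],
            "rr_ce": [6.0, 3.0], "rr_cd": [1.0, 3.0],
            "bias_mult": [1.0, 1.5], "abs_log_bias": [0.9, 0.4],
            "iv_flag": [False, False], "rank": pd.NA})
        ranked = pri.rank_covariates(pri.exclude_instrument_like(scores))
        assert pri.top_k_ids(ranked, 2) == ["conf"]

    def test_top_k_beyond_available_warns_and_uses_all(self, caplog):
        scores = pd.DataFrame({
            "covariate_id": ["a", "b"], "p_c1": 0.2, "p_c0": 0.1,
            "rr_ce": 1.5, "rr_cd": 1.5, "bias_mult": 1.2,
            "abs_log_bias": [0.2, 0.1], "iv_flag": False, "rank": pd.NA})
        ranked = pri.rank_covariates(scores)
        with caplog.at_level("WARNING", logger="hdps"):
            ids = pri.top_k_ids(ranked, 10)
        assert ids == ["a", "b"]
        assert any("only" in m for m in caplog.messages)
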