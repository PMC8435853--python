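import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cernaforge.cerna import (
    build_pairs,
    negative_correlation_filter,
    regulation_similarity,
    shared_mirna_hypergeometric,
)
from cernaforge.errors import InputError
from cernaforge.io_formats import ExpressionMatrix


def hypergeometric_tail_bruteforce(m: int, big_k: int, n: int, k: int) -> float:
    """Independent oracle: P(X >= k) by direct combinatorial summation."""
    total = math.comb(m, n)
    acc = 0
    for j in range(k, min(big_k, n) + 1):
        acc += math.comb(big_k, j) * math.comb(m - big_k, n - j)
    return acc / total


class TestHypergeometric:
    def test_zero_overlap_gives_unit_p(self):
        u = {f"m{i}" for i in range(10)}
        assert shared_mirna_hypergeometric({"m0"}, {"m1"}, u) == 1.0

    def test_worked_example(self):
        """Universe 10, sets of 4 and 5 sharing 3: p = 66/252."""
        u = {f"m{i}" for i in range(10)}
        lnc = {"m0", "m1", "m2", "m3"}
        mrna = {"m0", "m1", "m2", "m4", "m5"}
        p = shared_mirna_hypergeometric(lnc, mrna, u)
        assert p == pytest.approx(66 / 252, abs=1e-12)

    def test_full_overlap_degenerate(self):
        u = {f"m{i}" for i in range(6)}
        assert shared_mirna_hypergeometric(u, u, u) == pytest.approx(1.0)

    def test_empty_universe_rejected(self):
        with pytest.raises(InputError):
            shared_mirna_hypergeometric(set(), set(), set())

    def test_sets_must_be_subsets_of_universe(self):
        with pytest.raises(InputError):
            shared_mirna_hypergeometric({"x"}, set(), {"m0"})

    def test_matches_bruteforce_on_sampled_configurations(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            m = int(rng.integers(1, 13))
            big_k = int(rng.integers(0, m + 1))
            n = int(rng.integers(0, m + 1))
            ids = [f"m{i}" for i in range(m)]
            lnc = set(rng.choice(ids, size=big_k, replace=False))
            mrna = set(rng.choice(ids, size=n, replace=False))
            k = len(lnc & mrna)
            expected = hypergeometric_tail_bruteforce(m, big_k, n, k)
            assert shared_mirna_hypergeometric(lnc, mrna, set(ids)) == pytest.approx(
                expected, abs=1e-12
            )


class TestRegulationSimilarity:
    def test_identical_profiles_give_one(self):
        assert regulation_similarity([-0.5, 0.3], [-0.5, 0.3]) == 1.0

    def test_opposite_sign_single_mirna_gives_zero(self):
        assert regulation_similarity([-0.5], [0.5]) == 0.0

    def test_worked_example_two_thirds(self):
        v = regulation_similarity([-0.8, -0.4], [-0.4, -0.8])
        assert v == pytest.approx(2 / 3, abs=1e-12)

    def test_both_zero_term_contributes_zero(self):
        assert regulation_similarity([0.0], [0.0]) == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(InputError):
            regulation_similarity([0.1], [0.1, 0.2])

    def test_vector_corr_formula_requires_three(self):
        with pytest.raises(InputError):
            regulation_similarity([-0.5, -0.4], [-0.5, -0.4], formula="vector_corr")
        v = regulation_similarity([-0.8, -0.5, -0.2], [-0.7, -0.45, -0.3],
                                  formula="vector_corr")
        assert v > 0.9

    @given(
        st.lists(
            st.floats(min_value=-1, max_value=1, allow_nan=False), min_size=1, max_size=8
        )
    )
    @settings(max_examples=200, deadline=None)
    def test_range_and_permutation_invariance(self, cl):
        rng = np.random.default_rng(abs(hash(tuple(cl))) % 2**31)
        cm = rng.uniform(-1, 1, size=len(cl)).tolist()
        v = regulation_similarity(cl, cm)
        assert 0.0 <= v <= 1.0 + 1e-12
        perm = rng.permutation(len(cl))
        v_perm = regulation_similarity(np.asarray(cl)[perm], np.asarray(cm)[perm])
        assert v == pytest.approx(v_perm, abs=1e-12)

    @given(
        st.lists(
            st.floats(min_value=-1, max_value=1, allow_nan=False), min_size=1, max_size=8
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_equals_one_iff_identical(self, cl):
        assert regulation_similarity(cl, cl) == pytest.approx(1.0)
        shifted = [c - 0.3 if c > -0.6 else c + 0.5 for c in cl]
        if any(abs(a - b) > 1e-9 for a, b in zip(cl, shifted)):
            assert regulation_similarity(cl, shifted) < 1.0


def _expr(layer, arr, prefix):
    n = arr.shape[1]
    return ExpressionMatrix(
        layer,
        pd.DataFrame(arr, index=[f"{prefix}{i}" for i in range(arr.shape[0])],
                     columns=[f"s{i}" for i in range(n)]),
    )


class TestNegativeCorrelationFilter:
    def _edges(self, pairs):
        return pd.DataFrame(
            [{"source_id": m, "target_id": t, "target_layer": "mRNA"} for m, t in pairs]
        )

    def test_perfect_anticorrelation_kept_perfect_correlation_dropped(self):
        base = np.linspace(0, 1, 20)
        mir = _expr("miRNA", base[None, :], "m")
        tgt = _expr("mRNA", np.vstack([-base, base]), "g")
        out = negative_correlation_filter(self._edges([("m0", "g0"), ("m0", "g1")]), mir, tgt)
        assert list(out["target_id"]) == ["g0"]
        assert out.loc[0, "r"] == pytest.approx(-1.0)

    def test_zero_variance_edge_dropped(self):
        mir = _expr("miRNA", np.linspace(0, 1, 20)[None, :], "m")
        tgt = _expr("mRNA", np.full((1, 20), 3.0), "g")
        out = negative_correlation_filter(self._edges([("m0", "g0")]), mir, tgt)
        assert out.empty

    def test_planted_edges_survive(self, default_cohort, default_analysis):
        kept = set(zip(default_analysis.mrna_edges["source_id"],
                       default_analysis.mrna_edges["target_id"]))
        planted = default_cohort.truth.planted_mrna_edges
        assert len(planted & kept) / len(planted) >= 0.9


class TestBuildPairs:
    def _edges(self, triples, layer):
        return pd.DataFrame(
            [{"source_id": m, "target_id": t, "target_layer": layer} for m, t in triples]
        )

    def test_recovers_planted_pairs_and_reports_candidates(self, default_cohort,
                                                           default_analysis):
        planted = default_cohort.truth.planted_pairs
        got = {(p.lncrna_id, p.mrna_id) for p in default_analysis.passing_pairs}
        assert len(planted & got) >= 0.8 * len(planted)
        all_keys = {(p.lncrna_id, p.mrna_id) for p in default_analysis.all_pairs}
        assert got <= all_keys

    def test_tied_candidates_both_retained(self):
        """Two mRNAs with identical expression tie on every statistic; both stay."""
        rng = np.random.default_rng(0)
        n = 60
        a = rng.normal(size=n)
        mir = _expr("miRNA", (-a + 0.1 * rng.normal(size=n))[None, :], "m")
        lnc = _expr("lncRNA", (a + 0.1 * rng.normal(size=n))[None, :], "l")
        tgt_row = a + 0.1 * rng.normal(size=n)
        mrna = _expr("mRNA", np.vstack([tgt_row, tgt_row]), "g")
        le = self._edges([("m0", "l0")], "lncRNA")
        me = self._edges([("m0", "g0"), ("m0", "g1")], "mRNA")
        pairs, _ = build_pairs(le, me, lnc, mrna, mir)
        assert len(pairs) == 2
        assert pairs[0].r_lnc_mrna == pytest.approx(pairs[1].r_lnc_mrna)

    def test_monotone_in_thresholds(self, default_cohort, default_analysis):
        a = default_analysis
        _, loose = build_pairs(
            a.lnc_edges, a.mrna_edges, default_cohort.lncrna, default_cohort.mrna,
            default_cohort.mirna, alpha=0.05, reg_sim_min=0.5,
        )
        _, tight_alpha = build_pairs(
            a.lnc_edges, a.mrna_edges, default_cohort.lncrna, default_cohort.mrna,
            default_cohort.mirna, alpha=0.01, reg_sim_min=0.5,
        )
        _, tight_rs = build_pairs(
            a.lnc_edges, a.mrna_edges, default_cohort.lncrna, default_cohort.mrna,
            default_cohort.mirna, alpha=0.05, reg_sim_min=0.9,
        )
        keys = lambda ps: {(p.lncrna_id, p.mrna_id) for p in ps}
        assert keys(tight_alpha) <= keys(loose)
        assert keys(tight_rs) <= keys(loose)
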