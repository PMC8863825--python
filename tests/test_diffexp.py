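"""NB exact test, qCML common dispersion, and BH adjustment, checked
against exhaustive enumeration, simulation truth, statsmodels, and frozen
edgeR 4.0.16 values."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirnapipe import (
    DispersionEstimate,
    NormFactors,
    bh_adjust,
    estimate_common_dispersion,
    exact_test,
    run_all_comparisons,
    tmm_factors,
    two_group_nb_counts,
)
from mirnapipe.diffexp import _cond_loglik, equalize_lib_sizes
from oracles import bh_literal, exact_test_p_enumeration


def _unit_factors(counts, lib=1000.0):
    return NormFactors(
        factors=pd.Series(1.0, index=counts.columns),
        lib_sizes=pd.Series(lib, index=counts.columns),
    )


def _pair_matrix(pairs):
    """2+2 design where gene k has group sums (sa_k, sb_k), equal libraries
    (so pseudo-counts equal raw counts)."""
    rows = [[sa, 0, sb, 0] for sa, sb in pairs]
    return pd.DataFrame(
        rows,
        index=[f"g{k}" for k in range(len(pairs))],
        columns=["a1", "a2", "b1", "b2"],
    )


GROUPS_22 = pd.Series(["A", "A", "B", "B"], index=["a1", "a2", "b1", "b2"])


class TestBH:
    def test_single_p_is_identity(self):
        assert bh_adjust([0.01]) == pytest.approx([0.01])

    def test_step_up_example(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    @settings(deadline=None, max_examples=60)
    def test_matches_literal_definition_and_statsmodels(self, pvals):
        from statsmodels.stats.multitest import multipletests

        ours = bh_adjust(pvals)
        assert np.allclose(ours, bh_literal(pvals), atol=1e-12)
        sm = multipletests(pvals, method="fdr_bh")[1]
        assert np.allclose(ours, sm, atol=1e-12)
        assert ((ours >= 0) & (ours <= 1)).all()

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestEqualization:
    def test_equal_libraries_are_a_fixed_point(self):
        counts = _pair_matrix([(10, 20), (5, 5), (0, 7)])
        pseudo, common = equalize_lib_sizes(
            counts, pd.Series(1000.0, index=counts.columns), 0.1
        )
        assert common == pytest.approx(1000.0)
        assert np.allclose(pseudo, counts, atol=1e-8)

    def test_unequal_libraries_move_counts_toward_common_scale(self):
        counts = pd.DataFrame({"a": [100, 50], "b": [200, 100]})
        pseudo, common = equalize_lib_sizes(
            counts, pd.Series({"a": 1000.0, "b": 2000.0}), 0.1
        )
        assert common == pytest.approx(np.sqrt(2) * 1000.0)
        # the deep sample shrinks, the shallow one grows
        assert (pseudo["b"] < counts["b"]).all()
        assert (pseudo["a"] > counts["a"]).all()


class TestCommonDispersion:
    def test_equal_counts_pair_favors_zero_dispersion(self):
        """With counts (k, k) in one group the conditional likelihood is
        maximized at phi -> 0 (grid evaluation)."""
        block = [np.array([[7.0, 7.0]])]
        grid = [1e-6, 1e-3, 0.01, 0.1, 1.0, 10.0]
        lls = [_cond_loglik(block, g) for g in grid]
        assert np.argmax(lls) == 0

    def test_unequal_pair_favors_positive_dispersion(self):
        block = [np.array([[1.0, 40.0]])]
        grid = [1e-6, 0.01, 0.1, 1.0]
        lls = [_cond_loglik(block, g) for g in grid]
        assert np.argmax(lls) > 0

    def test_poisson_truth_estimates_near_zero(self):
        counts, groups, _, _ = two_group_nb_counts(
            2000, (20, 20), dispersion=0.0, seed=1
        )
        phi = estimate_common_dispersion(counts, groups, tmm_factors(counts)).phi
        assert phi < 0.02

    def test_nb_truth_recovered(self):
        counts, groups, _, _ = two_group_nb_counts(
            2000, (20, 20), dispersion=0.1, seed=2
        )
        phi = estimate_common_dispersion(counts, groups, tmm_factors(counts)).phi
        assert 0.08 <= phi <= 0.12

    def test_all_singletons_abort(self):
        counts = pd.DataFrame({"a": [5, 5], "b": [6, 6]})
        groups = pd.Series(["A", "B"], index=["a", "b"])
        with pytest.raises(ValueError, match="replication"):
            estimate_common_dispersion(counts, groups, _unit_factors(counts))

    def test_negative_phi_rejected(self):
        with pytest.raises(ValueError):
            DispersionEstimate(phi=-0.1)


class TestExactTest:
    def test_symmetric_counts_give_p_one_and_zero_logfc(self):
        counts = _pair_matrix([(12, 12), (0, 0)])
        res = exact_test(
            counts, GROUPS_22, "A", "B", DispersionEstimate(0.1), _unit_factors(counts)
        )
        assert res["PValue"].tolist() == [1.0, 1.0]
        assert res["logFC"].tolist() == [0.0, 0.0]

    def test_sign_convention_b_over_a(self):
        counts = _pair_matrix([(5, 40), (40, 5)])
        res = exact_test(
            counts, GROUPS_22, "A", "B", DispersionEstimate(0.1), _unit_factors(counts)
        )
        assert res["logFC"].iloc[0] > 0 > res["logFC"].iloc[1]

    def test_p_symmetric_under_group_swap(self):
        counts = _pair_matrix([(3, 17), (25, 6), (0, 9)])
        kw = dict(
            dispersion=DispersionEstimate(0.1), factors=_unit_factors(counts)
        )
        ab = exact_test(counts, GROUPS_22, "A", "B", **kw)
        ba = exact_test(counts, GROUPS_22, "B", "A", **kw)
        assert np.allclose(ab["PValue"], ba["PValue"], atol=1e-12)
        assert np.allclose(ab["logFC"], -ba["logFC"], atol=1e-12)

    @pytest.mark.parametrize("phi", [0.01, 0.1, 0.5])
    def test_matches_exhaustive_enumeration(self, phi):
        """Conditional p-values equal brute-force enumeration of NB-sum
        probability masses for a spread of splits."""
        pairs = [(sa, sb) for sa in (0, 1, 3, 8, 15, 30) for sb in (0, 2, 7, 14, 30)]
        counts = _pair_matrix(pairs)
        res = exact_test(
            counts, GROUPS_22, "A", "B", DispersionEstimate(phi), _unit_factors(counts)
        )
        for (sa, sb), p in zip(pairs, res["PValue"]):
            if sa + sb == 0:
                assert p == 1.0
                continue
            assert p == pytest.approx(
                exact_test_p_enumeration(sa, sb, 2, 2, phi), abs=1e-8
            )

    def test_poisson_limit_matches_enumeration(self):
        pairs = [(4, 16), (10, 10), (0, 12)]
        counts = _pair_matrix(pairs)
        res = exact_test(
            counts, GROUPS_22, "A", "B", DispersionEstimate(0.0), _unit_factors(counts)
        )
        for (sa, sb), p in zip(pairs, res["PValue"]):
            assert p == pytest.approx(
                exact_test_p_enumeration(sa, sb, 2, 2, 0.0), abs=1e-6
            )


@pytest.fixture(scope="module")
def edger_setup():
    from test_normalize import _edger_matrix

    counts = _edger_matrix()
    groups = pd.Series(["A"] * 4 + ["B"] * 4, index=counts.columns)
    nf = tmm_factors(counts)
    disp = estimate_common_dispersion(counts, groups, nf)
    return counts, groups, nf, disp


class TestAgainstEdgeR:
    """Frozen outputs of edgeR 4.0.16 (calcNormFactors + estimateCommonDisp
    + exactTest) on the deterministic matrix from test_normalize."""

    EDGER_DISPERSION = 0.20975237
    EDGER_P_HEAD = [
        0.070052768, 0.55354789, 0.031298705, 0.10381312, 0.63377765, 0.91312579,
    ]

    def test_dispersion_close_to_edger(self, edger_setup):
        _, _, _, disp = edger_setup
        assert disp.phi == pytest.approx(self.EDGER_DISPERSION, abs=5e-3)

    def test_pvalues_close_to_edger(self, edger_setup):
        counts, groups, nf, disp = edger_setup
        res = exact_test(counts, groups, "A", "B", disp, nf)
        assert np.allclose(res["PValue"].to_numpy()[:6], self.EDGER_P_HEAD, atol=0.01)


class TestRunAllComparisons:
    def test_three_identical_groups_no_discoveries(self, random_counts):
        counts = pd.concat(
            [random_counts.iloc[:, :3]] * 3, axis=1, keys=None
        )
        counts.columns = [f"s{i}" for i in range(9)]
        groups = pd.Series(
            ["A"] * 3 + ["B"] * 3 + ["C"] * 3, index=counts.columns
        )
        results, union = run_all_comparisons(counts, groups)
        assert union == []
        for res in results.values():
            assert (res["PValue"] == 1.0).all()

    def test_comparison_labels_follow_group_order(self, random_counts):
        counts = random_counts.iloc[:, :6]
        groups = pd.Series(
            ["HA", "HA", "HS", "HS", "SR", "SR"], index=counts.columns
        )
        results, _ = run_all_comparisons(counts, groups)
        assert list(results) == ["HS_vs_HA", "SR_vs_HA", "SR_vs_HS"]

    def test_union_contains_every_per_comparison_hit(self):
        counts, groups3 = _three_group_counts(seed=4)
        results, union = run_all_comparisons(counts, groups3)
        hits = set()
        for res in results.values():
            hits |= set(res.index[res["FDR"] <= 0.05])
        assert hits <= set(union) and len(union) == len(hits)

    def test_null_simulation_rarely_discovers(self):
        pooled = 0
        for seed in range(3):
            counts, groups, _, _ = two_group_nb_counts(
                700, (5, 5), frac_de=0.0, dispersion=0.1, seed=40 + seed
            )
            _, union = run_all_comparisons(counts, groups)
            pooled += len(union)
        assert pooled <= 4


def _three_group_counts(seed=0, n=400):
    rng = np.random.default_rng(seed)
    mu = np.exp(rng.uniform(1, 8, n))
    shift = np.ones((n, 12))
    shift[:20, 8:] = 4.0  # strong effect in the third group
    mean = np.outer(mu, np.ones(12)) * shift
    counts = rng.negative_binomial(10, 10 / (10 + mean))
    df = pd.DataFrame(
        counts,
        index=[f"g{i}" for i in range(n)],
        columns=[f"s{j}" for j in range(12)],
    )
    groups = pd.Series(["A"] * 4 + ["B"] * 4 + ["C"] * 4, index=df.columns)
    return df, groups
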