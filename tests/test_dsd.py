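from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from txdiv import (
    ExpressionMatrix,
    GroupDesign,
    differential_table,
    dsd_log2fc,
    entropy_table,
    gene_proportions,
    group_mean_pse,
    pse,
    shannon_entropy_log2,
    wilcoxon_per_gene,
)
from txdiv.dsd import log2fc_with_epsilon

from conftest import random_tpm_matrix


class TestProportionsAndEntropy:
    def test_direct_normalization(self):
        np.testing.assert_allclose(gene_proportions([600000, 400000]),
                                   [0.6, 0.4])

    def test_zeros_stay_zero_and_scale_invariance(self, rng):
        x = rng.lognormal(0, 1, 20)
        x[[3, 7]] = 0.0
        p = gene_proportions(x)
        assert p[3] == p[7] == 0.0
        np.testing.assert_allclose(p, gene_proportions(17.3 * x))

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            gene_proportions([0.0, 0.0])

    @pytest.mark.parametrize(
        "p,expected",
        [
            ([1.0, 0.0, 0.0], 0.0),            # single-gene library
            ([0.125] * 8, 3.0),                 # uniform over 8 genes
            ([0.5, 0.25, 0.25], 1.5),
        ],
    )
    def test_entropy_bits(self, p, expected):
        assert shannon_entropy_log2(p) == pytest.approx(expected)

    def test_entropy_rejects_non_normalized(self):
        with pytest.raises(ValueError, match="sum to 1"):
            shannon_entropy_log2([0.5, 0.4])


class TestPse:
    def test_unexpressed_gene_has_zero_pse(self):
        out = pse([0.5, 0.25, 0.25, 0.0])
        assert out[3] == 0.0

    def test_equal_entropy_terms_split_evenly(self):
        # h = (0.5, 0.5, 0.5) bits, H = 1.5 -> each PSE 1/3
        np.testing.assert_allclose(pse([0.5, 0.25, 0.25]), [1 / 3] * 3)

    def test_rare_gene_can_dominate_entropy(self):
        out = pse([0.9, 0.1])
        np.testing.assert_allclose(out, [0.2917, 0.7083], atol=5e-5)

    def test_single_gene_library_rejected(self):
        with pytest.raises(ValueError, match="H = 0"):
            pse([1.0, 0.0])

    @given(st.integers(0, 10_000))
    @settings(deadline=None, max_examples=50)
    def test_pse_sums_to_one_and_scale_invariant(self, seed):
        rng = np.random.default_rng(seed)
        tpm = rng.lognormal(0, 2, 30)
        tpm[rng.random(30) < 0.3] = 0.0
        if (tpm > 0).sum() < 2:
            tpm[:2] = 1.0
        p = gene_proportions(tpm)
        out = pse(p)
        assert out.sum() == pytest.approx(1.0, abs=1e-9)
        assert ((out >= 0) & (out <= 1)).all()
        np.testing.assert_allclose(out, pse(gene_proportions(3.7 * tpm)))


class TestEntropyTableAndMeans:
    def test_table_invariants(self, rng):
        tpm = random_tpm_matrix(rng)
        m = ExpressionMatrix(tpm=tpm)
        table = entropy_table(m)
        np.testing.assert_allclose(table.p.sum(axis=0), 1.0, atol=1e-9)
        np.testing.assert_allclose(table.pse.sum(axis=0), 1.0, atol=1e-9)
        np.testing.assert_allclose(table.h.sum(axis=0), table.H)
        assert (table.G == (tpm > 0).sum(axis=0)).all()
        assert (table.H <= np.log2(table.G) + 1e-9).all()

    def test_group_means(self, small_matrix, small_design):
        table = entropy_table(small_matrix)
        means = group_mean_pse(table, small_design)
        expected = table.pse[["a1", "a2"]].mean(axis=1)
        pd.testing.assert_series_equal(means["ctrl"], expected,
                                       check_names=False)
        # gene g3 is zero in all ctrl samples -> mean 0
        assert means.loc["g3", "ctrl"] == 0.0

    def test_unlabelled_sample_rejected(self, small_matrix):
        table = entropy_table(small_matrix)
        design = GroupDesign(assignments=pd.Series({"a1": "x", "a2": "x"}))
        with pytest.raises(ValueError, match="without group label"):
            group_mean_pse(table, design)


class TestLog2FoldChange:
    def test_plain_ratio(self):
        fc, flags = dsd_log2fc([0.004], [0.001], epsilon_policy=1e-12)
        assert fc[0] == pytest.approx(2.0, abs=1e-6)
        assert flags[0] == ""

    def test_equal_means_give_zero(self):
        fc, _ = dsd_log2fc([0.003, 0.1], [0.003, 0.1])
        np.testing.assert_allclose(fc, 0.0)

    def test_control_absent_flagged_and_epsilon_dominated(self):
        fc, flags = dsd_log2fc([0.001], [0.0], epsilon_policy=1e-9)
        assert fc[0] == pytest.approx(np.log2(1.000001e-3 / 1e-9), rel=1e-4)
        assert flags[0] == "control_absent"

    def test_absent_in_both_is_zero_with_flag(self):
        fc, flags = log2fc_with_epsilon([0.0, 1.0], [0.0, 1.0])
        assert fc[0] == 0.0 and flags[0] == "absent_in_both"

    def test_auto_epsilon_is_half_smallest_positive(self):
        fc, _ = log2fc_with_epsilon([0.2], [0.0], epsilon_policy="auto")
        # eps = 0.1 -> log2(0.3/0.1)
        assert fc[0] == pytest.approx(np.log2(3.0))


def brute_force_mannwhitney_p(x, y):
    """Enumerate all group assignments of the pooled values; two-sided p
    doubles the smaller tail probability of the U statistic (capped at 1)."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    u_obs = sum(1 for a in x for b in y if a > b) + \
        0.5 * sum(1 for a in x for b in y if a == b)
    us = []
    for idx in combinations(range(len(pooled)), n1):
        gx = pooled[list(idx)]
        gy = np.delete(pooled, list(idx))
        u = sum(1 for a in gx for b in gy if a > b) + \
            0.5 * sum(1 for a in gx for b in gy if a == b)
        us.append(u)
    us = np.array(us)
    lower = (us <= u_obs + 1e-12).mean()
    upper = (us >= u_obs - 1e-12).mean()
    return min(1.0, 2 * min(lower, upper))


def _design(n1, n2):
    ids = [f"c{i}" for i in range(n1)] + [f"t{i}" for i in range(n2)]
    labels = ["case"] * n1 + ["ctrl"] * n2
    return ids, GroupDesign(assignments=pd.Series(labels, index=ids),
                            groups=["case", "ctrl"], control="ctrl")


class TestWilcoxon:
    def test_textbook_separation(self):
        ids, design = _design(3, 3)
        values = pd.DataFrame([[1, 2, 3, 4, 5, 6]], columns=ids,
                              index=["g"], dtype=float)
        p = wilcoxon_per_gene(values, design, "case", "ctrl")
        assert p["g"] == pytest.approx(0.1)  # 2/20 enumerated assignments

    def test_exact_agrees_with_enumeration(self):
        """Exact small-sample p-values equal brute-force enumeration."""
        rng = np.random.default_rng(7)
        checked = 0
        for n1 in range(2, 6):
            for n2 in range(2, 6):
                for _ in range(7):
                    x = rng.normal(size=n1)
                    y = rng.normal(size=n2) + rng.normal()
                    ids, design = _design(n1, n2)
                    values = pd.DataFrame([np.concatenate([x, y])],
                                          columns=ids, index=["g"])
                    p = wilcoxon_per_gene(values, design, "case", "ctrl")["g"]
                    assert p == pytest.approx(brute_force_mannwhitney_p(x, y),
                                              abs=1e-12)
                    checked += 1
        assert checked >= 100

    def test_constant_gene_gets_p_one(self):
        ids, design = _design(3, 3)
        values = pd.DataFrame([[2.0] * 6], columns=ids, index=["g"])
        assert wilcoxon_per_gene(values, design, "case", "ctrl")["g"] == 1.0

    def test_large_shift_is_powerful(self):
        rng = np.random.default_rng(11)
        ids, design = _design(10, 10)
        hits = 0
        n_sim = 500
        for _ in range(n_sim):
            row = np.concatenate([rng.normal(size=10) + 10,
                                  rng.normal(size=10)])
            values = pd.DataFrame([row], columns=ids, index=["g"])
            if wilcoxon_per_gene(values, design, "case", "ctrl")["g"] < 0.001:
                hits += 1
        assert hits / n_sim > 0.95


class TestDifferentialTable:
    def test_identical_groups_all_ns(self, rng):
        tpm = random_tpm_matrix(rng, n_genes=30, n_samples=2)
        both = pd.concat([tpm, tpm.add_suffix("_b")], axis=1)
        both = both * 1e6 / both.sum(axis=0)
        ids = list(both.columns)
        design = GroupDesign(
            assignments=pd.Series(["ctrl"] * 2 + ["case"] * 2, index=ids),
            groups=["ctrl", "case"], control="ctrl")
        out = differential_table(ExpressionMatrix(tpm=both), design,
                                 "case", "ctrl")
        np.testing.assert_allclose(out["deg"], 0.0, atol=1e-12)
        np.testing.assert_allclose(out["dsd"], 0.0, atol=1e-12)
        assert (out["call_deg"] == "ns").all()
        assert (out["call_dsd"] == "ns").all()

    def test_amplified_genes_recovered(self):
        """Genes amplified 4x in the case group show DEG > 1 almost always."""
        rng = np.random.default_rng(1)
        n_genes, n = 1000, 8
        base = rng.lognormal(2, 1, n_genes)
        amplified = rng.choice(n_genes, 100, replace=False)
        cols = {}
        for i in range(n):
            w = base * rng.lognormal(0, 0.1, n_genes)
            cols[f"c{i}"] = w
        for i in range(n):
            w = base * rng.lognormal(0, 0.1, n_genes)
            w[amplified] *= 4
            cols[f"t{i}"] = w
        tpm = pd.DataFrame(cols, index=[f"g{j}" for j in range(n_genes)])
        tpm = tpm * 1e6 / tpm.sum(axis=0)
        design = GroupDesign(
            assignments=pd.Series(["ctrl"] * n + ["case"] * n,
                                  index=list(cols)),
            groups=["ctrl", "case"], control="ctrl")
        out = differential_table(ExpressionMatrix(tpm=tpm), design,
                                 "case", "ctrl")
        hit = (out["deg"].iloc[amplified] > 1).sum()
        assert hit >= 95
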