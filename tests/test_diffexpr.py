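"""FPKM, expression filtering, BH adjustment and the NB Wald test —
calibration, power, invariances, and an independent DESeq2 cross-check."""

import numpy as np
import pandas as pd
import pytest

from cgiplast.diffexpr import (
    bh_adjust,
    compute_fpkm,
    expression_filter,
    nb_two_group_test,
    size_factors,
)


def _nb(rng, mu, disp, shape):
    size = 1.0 / disp
    return rng.negative_binomial(size, size / (size + mu), size=shape)


class TestFpkm:
    def test_plugin_value(self):
        counts = pd.DataFrame({"s1": [10, 999_990]}, index=["g1", "g2"])
        lengths = pd.Series([1000.0, 1000.0], index=["g1", "g2"])
        fpkm = compute_fpkm(counts, lengths)
        assert fpkm.loc["g1", "s1"] == pytest.approx(10.0)

    def test_zero_count_gives_zero(self):
        counts = pd.DataFrame({"s1": [0, 100]}, index=["g1", "g2"])
        lengths = pd.Series([500.0, 500.0], index=["g1", "g2"])
        assert compute_fpkm(counts, lengths).loc["g1", "s1"] == 0.0

    def test_zero_library_rejected(self):
        counts = pd.DataFrame({"s1": [0, 0]}, index=["g1", "g2"])
        lengths = pd.Series([500.0, 500.0], index=["g1", "g2"])
        with pytest.raises(ValueError, match="library"):
            compute_fpkm(counts, lengths)

    def test_random_matrix_matches_double_loop(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(
            rng.integers(0, 1000, size=(50, 6)),
            index=[f"g{i}" for i in range(50)],
            columns=[f"s{j}" for j in range(6)],
        )
        lengths = pd.Series(rng.integers(200, 5000, size=50).astype(float), index=counts.index)
        fpkm = compute_fpkm(counts, lengths)
        for g in counts.index[::7]:
            for s in counts.columns:
                expected = counts.loc[g, s] * 1e9 / (lengths[g] * counts[s].sum())
                assert fpkm.loc[g, s] == pytest.approx(expected)


class TestExpressionFilter:
    def _mk(self, normal_counts, tumor_counts, tumor_fpkm_above):
        """10 normals, 10 tumors; tumor_fpkm_above = how many tumors clear FPKM>1."""
        genes = ["g1"]
        counts = pd.DataFrame(
            [normal_counts + tumor_counts],
            index=genes,
            columns=[f"n{i}" for i in range(10)] + [f"t{i}" for i in range(10)],
        )
        fpkm = counts.astype(float) * 0.0
        fpkm.iloc[0, 10 : 10 + tumor_fpkm_above] = 2.0
        return counts, fpkm

    def test_exactly_half_fpkm_fails_strict(self):
        counts, fpkm = self._mk([5] * 10, [5] * 10, tumor_fpkm_above=5)
        flags = expression_filter(counts, fpkm, [f"n{i}" for i in range(10)], [f"t{i}" for i in range(10)])
        assert not flags["g1"]

    def test_six_of_ten_fpkm_passes(self):
        counts, fpkm = self._mk([5] * 10, [5] * 10, tumor_fpkm_above=6)
        flags = expression_filter(counts, fpkm, [f"n{i}" for i in range(10)], [f"t{i}" for i in range(10)])
        assert flags["g1"]

    def test_detection_fraction_boundary_is_strict(self):
        # exactly 80% of normals detected -> fails the "> 80%" clause
        counts, fpkm = self._mk([1] * 8 + [0] * 2, [5] * 10, tumor_fpkm_above=10)
        flags = expression_filter(counts, fpkm, [f"n{i}" for i in range(10)], [f"t{i}" for i in range(10)])
        assert not flags["g1"]

    def test_matches_bruteforce_clauses_on_random_cohort(self):
        rng = np.random.default_rng(4)
        genes = [f"g{i}" for i in range(200)]
        normals, tumors = [f"n{i}" for i in range(9)], [f"t{i}" for i in range(17)]
        counts = pd.DataFrame(
            rng.poisson(2, size=(200, 26)), index=genes, columns=normals + tumors
        )
        lengths = pd.Series(1000.0, index=genes)
        fpkm = compute_fpkm(counts, lengths)
        flags = expression_filter(counts, fpkm, normals, tumors)
        for g in genes:
            c1 = (counts.loc[g, normals] > 0).mean() > 0.8
            c2 = (counts.loc[g, tumors] > 0).mean() > 0.8
            c3 = (fpkm.loc[g, tumors] > 1).mean() > 0.5
            assert flags[g] == (c1 and c2 and c3)

    def test_empty_group_rejected(self):
        counts, fpkm = self._mk([5] * 10, [5] * 10, 10)
        with pytest.raises(ValueError):
            expression_filter(counts, fpkm, [], [f"t{i}" for i in range(10)])


def _bruteforce_bh(p):
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    out = np.empty(m)
    prev = np.inf
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(p[i] * m / rank_from_top, prev, 1.0)
        out[i] = val
        prev = val
    return out


class TestBhAdjust:
    def test_closed_form_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    def test_matches_bruteforce_oracle_exactly(self):
        rng = np.random.default_rng(123)
        for _ in range(100):
            p = rng.uniform(size=rng.integers(1, 60))
            assert np.array_equal(bh_adjust(p), _bruteforce_bh(p))

    def test_monotone_in_rank(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=500)
        adj = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= 0).all()


class TestNbTest:
    def test_size_factor_invariance(self):
        rng = np.random.default_rng(10)
        counts = pd.DataFrame(
            _nb(rng, 100, 0.05, (300, 12)),
            index=[f"g{i}" for i in range(300)],
            columns=[f"s{j}" for j in range(12)],
        )
        a, b = list(counts.columns[:6]), list(counts.columns[6:])
        base = nb_two_group_test(counts, a, b)
        scaled = counts.copy()
        scaled["s0"] = scaled["s0"] * 7
        rescaled = nb_two_group_test(scaled, a, b)
        assert np.allclose(base["log2fc"], rescaled["log2fc"], atol=1e-6)

    def test_deterministic_doubling_normalized_away(self):
        rng = np.random.default_rng(11)
        block = _nb(rng, 50, 0.05, (200, 5))
        counts = pd.DataFrame(
            np.hstack([block, 2 * block]),
            index=[f"g{i}" for i in range(200)],
            columns=[f"a{j}" for j in range(5)] + [f"b{j}" for j in range(5)],
        )
        res = nb_two_group_test(counts, [f"a{j}" for j in range(5)], [f"b{j}" for j in range(5)])
        assert np.abs(res["log2fc"]).max() < 0.02

    def test_null_type_one_error_calibrated(self):
        """2000 null genes, 10 vs 10, dispersion 0.1: empirical type-I error
        at alpha=0.05 within [0.03, 0.07]."""
        rng = np.random.default_rng(7)
        n_genes = 2000
        mu = np.exp(rng.uniform(np.log(20), np.log(500), n_genes))
        counts = pd.DataFrame(
            np.hstack([_nb(rng, mu[:, None], 0.1, (n_genes, 10)) for _ in range(2)]),
            index=[f"g{i}" for i in range(n_genes)],
            columns=[f"a{j}" for j in range(10)] + [f"b{j}" for j in range(10)],
        )
        res = nb_two_group_test(counts, [f"a{j}" for j in range(10)], [f"b{j}" for j in range(10)])
        rate = (res["p"] < 0.05).mean()
        assert 0.03 <= rate <= 0.07
        # and BH keeps the null nearly rejection-free
        assert (res["padj"] < 0.05).mean() <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_genes)

    def test_power_and_fc_recovery_at_planted_fold_change(self):
        """fc=4 planted on 10% of genes, 40 tumors vs 10 normals, disp 0.05:
        mean log2fc within 2 +/- 0.15 and >=95% detected."""
        rng = np.random.default_rng(3)
        n_genes = 2000
        mu = np.exp(rng.uniform(np.log(10), np.log(200), n_genes))
        fc = np.ones(n_genes)
        planted = rng.choice(n_genes, 200, replace=False)
        fc[planted] = 4.0
        A = _nb(rng, mu[:, None], 0.05, (n_genes, 10))
        B = _nb(rng, (fc * mu)[:, None], 0.05, (n_genes, 40))
        counts = pd.DataFrame(
            np.hstack([A, B]),
            index=[f"g{i}" for i in range(n_genes)],
            columns=[f"a{j}" for j in range(10)] + [f"b{j}" for j in range(40)],
        )
        res = nb_two_group_test(counts, [f"a{j}" for j in range(10)], [f"b{j}" for j in range(40)])
        sub = res.iloc[planted]
        assert abs(sub["log2fc"].mean() - 2.0) < 0.15
        assert ((sub["padj"] < 0.05) & (sub["log2fc"] > 1)).mean() >= 0.95

    def test_group_too_small_rejected(self):
        counts = pd.DataFrame({"a": [1], "b": [2], "c": [3], "d": [4]}, index=["g"])
        with pytest.raises(ValueError):
            nb_two_group_test(counts, ["a"], ["b", "c", "d"])

    def test_size_factors_match_manual_median_of_ratios(self):
        rng = np.random.default_rng(14)
        counts = pd.DataFrame(
            rng.integers(1, 500, size=(100, 4)),
            index=[f"g{i}" for i in range(100)],
            columns=list("abcd"),
        )
        sf = size_factors(counts)
        x = counts.to_numpy(dtype=float)
        ref = np.exp(np.log(x).mean(axis=1))
        expected = np.median(x / ref[:, None], axis=0)
        expected = expected / np.median(expected)  # median-1 convention
        assert np.allclose(sf.to_numpy(), expected)

    def test_agrees_with_deseq2_on_planted_data(self):
        """Independent cross-check: log2fc closely tracks DESeq2's MLE
        estimates and the strongly planted genes are found by both."""
        pydeseq2 = pytest.importorskip("pydeseq2")
        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats

        rng = np.random.default_rng(21)
        n_genes = 300
        mu = np.exp(rng.uniform(np.log(20), np.log(300), n_genes))
        fc = np.ones(n_genes)
        planted = rng.choice(n_genes, 30, replace=False)
        fc[planted] = 4.0
        A = _nb(rng, mu[:, None], 0.05, (n_genes, 8))
        B = _nb(rng, (fc * mu)[:, None], 0.05, (n_genes, 8))
        genes = [f"g{i}" for i in range(n_genes)]
        cols = [f"a{j}" for j in range(8)] + [f"b{j}" for j in range(8)]
        counts = pd.DataFrame(np.hstack([A, B]), index=genes, columns=cols)

        ours = nb_two_group_test(counts, cols[:8], cols[8:])

        meta = pd.DataFrame({"condition": ["A"] * 8 + ["B"] * 8}, index=cols)
        dds = DeseqDataSet(counts=counts.T, metadata=meta, design="~condition", quiet=True)
        dds.deseq2()
        stats = DeseqStats(dds, contrast=["condition", "B", "A"], quiet=True)
        stats.summary()
        theirs = stats.results_df

        r = np.corrcoef(ours["log2fc"], theirs["log2FoldChange"])[0, 1]
        assert r > 0.98
        ours_hits = set(ours.index[(ours["padj"] < 0.05) & (ours["log2fc"] > 1)])
        theirs_hits = set(
            theirs.index[(theirs["padj"] < 0.05) & (theirs["log2FoldChange"] > 1)]
        )
        planted_ids = {genes[i] for i in planted}
        assert planted_ids <= ours_hits
        assert planted_ids <= theirs_hits
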