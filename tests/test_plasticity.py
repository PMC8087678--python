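"""Plastic genes, cancer-type-restricted genes, PCA distance ratios and
signature/quintile scoring."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cgiplast.classify import HYPER_PRC2, HYPER_PRC2NEG, NONE, UP_PRC2, UP_PRC2NEG
from cgiplast.plasticity import (
    cancer_restricted_genes,
    cd8_signatures,
    pca_distance_ratio,
    plastic_genes,
    signature_score,
    stratified_group_test,
    tf_stratified_target_fc,
)


def test_bundled_cd8_signatures_load():
    sigs = cd8_signatures()
    assert set(sigs) == {"CD8_SIGNATURE_A", "CD8_SIGNATURE_B"}
    assert "CD8A" in sigs["CD8_SIGNATURE_A"]
    assert sigs["CD8_SIGNATURE_B"] == ["GZMA", "PRF1"]


def _calls(rows):
    return pd.DataFrame(rows, columns=["gene_id", "cancer_type", "label"])


class TestPlasticGenes:
    def test_up_in_one_hyper_in_other_is_plastic(self):
        calls = _calls([("g1", "A", UP_PRC2), ("g1", "B", HYPER_PRC2)])
        out = plastic_genes(calls)
        assert out["PRC2_POS"].plastic_genes == ["g1"]

    def test_up_in_two_types_is_not_plastic(self):
        calls = _calls([("g1", "A", UP_PRC2), ("g1", "B", UP_PRC2)])
        assert plastic_genes(calls)["PRC2_POS"].plastic_genes == []

    def test_classes_do_not_mix(self):
        # upregulation in the PRC2+ class and hypermethylation in the PRC2-
        # class are different genes' stories: no cross-class plasticity
        calls = _calls([("g1", "A", UP_PRC2), ("g1", "B", HYPER_PRC2NEG)])
        out = plastic_genes(calls)
        assert out["PRC2_POS"].plastic_genes == []
        assert out["PRC2_NEG"].plastic_genes == []

    def test_single_type_rejected(self):
        with pytest.raises(ValueError):
            plastic_genes(_calls([("g1", "A", UP_PRC2)]))

    def test_percentage_definition(self):
        calls = _calls(
            [
                ("g1", "A", UP_PRC2),
                ("g2", "A", UP_PRC2),
                ("g1", "B", HYPER_PRC2),
                ("g3", "B", UP_PRC2),
            ]
        )
        per_type = plastic_genes(calls)["PRC2_POS"].per_type.set_index("cancer_type")
        assert per_type.loc["A", "pct_plastic"] == pytest.approx(0.5)  # g1 of g1,g2

    def test_matches_bruteforce_pairwise_definition(self):
        rng = np.random.default_rng(31)
        genes = [f"g{i}" for i in range(500)]
        types = list("ABCD")
        labels = rng.choice(
            [UP_PRC2, HYPER_PRC2, UP_PRC2NEG, HYPER_PRC2NEG, NONE],
            p=[0.1, 0.1, 0.1, 0.1, 0.6],
            size=(500, 4),
        )
        calls = _calls(
            [(g, t, labels[i, j]) for i, g in enumerate(genes) for j, t in enumerate(types)]
        )
        out = plastic_genes(calls)
        for key, up_l, hy_l in (
            ("PRC2_POS", UP_PRC2, HYPER_PRC2),
            ("PRC2_NEG", UP_PRC2NEG, HYPER_PRC2NEG),
        ):
            expected = set()
            for i, g in enumerate(genes):
                for ja in range(4):
                    for jb in range(4):
                        if ja != jb and labels[i, ja] == up_l and labels[i, jb] == hy_l:
                            expected.add(g)
            assert set(out[key].plastic_genes) == expected


class TestRestrictedGenes:
    def _fpkm(self):
        rng = np.random.default_rng(41)
        genes = [f"g{i}" for i in range(20)]
        cols = [f"A{i}" for i in range(10)] + [f"B{i}" for i in range(10)]
        fpkm = pd.DataFrame(rng.uniform(4, 6, size=(20, 20)), index=genes, columns=cols)
        fpkm.loc["g0", [c for c in cols if c.startswith("A")]] = 50.0  # restricted to A
        types = pd.Series(["A"] * 10 + ["B"] * 10, index=cols)
        return fpkm, types, genes

    def test_strongly_restricted_gene_found_without_significance(self):
        fpkm, types, genes = self._fpkm()
        out = cancer_restricted_genes(
            fpkm, types, genes, "A", require_significance=False
        )
        assert out == ["g0"]

    def test_saturation_at_unit_cutoff(self):
        fpkm, types, genes = self._fpkm()
        out = cancer_restricted_genes(
            fpkm, types, genes, "A", fc_cutoff=0.0, require_significance=False
        )
        assert out == sorted(genes)

    def test_empty_class_set_gives_empty_result(self):
        fpkm, types, _ = self._fpkm()
        assert cancer_restricted_genes(fpkm, types, [], "A", require_significance=False) == []

    def test_planted_restricted_recall_at_default_effects(self, default_bundle, default_results):
        _, _, truth = default_bundle
        planted = set(truth.flags.index[truth.flags["restricted"]])
        found = set().union(*default_results["restricted"].values())
        recall = len(planted & found) / len(planted)
        assert recall >= 0.9


class TestPcaDistanceRatio:
    def _planted(self, rng, shift):
        genes = [f"g{i}" for i in range(40)]
        cols = [f"A{i}" for i in range(15)] + [f"B{i}" for i in range(15)]
        x = rng.lognormal(2, 0.3, size=(40, 30))
        x[:10, 15:] *= shift  # type-B program on 10 genes
        fpkm = pd.DataFrame(x, index=genes, columns=cols)
        types = pd.Series(["A"] * 15 + ["B"] * 15, index=cols)
        return fpkm, types, genes

    def test_permuted_labels_give_unit_ratio(self):
        rng = np.random.default_rng(51)
        fpkm, types, genes = self._planted(rng, shift=8.0)
        ratios = []
        for _ in range(100):
            perm = pd.Series(rng.permutation(types.to_numpy()), index=types.index)
            ratios.append(pca_distance_ratio(fpkm, perm, genes))
        assert 0.9 <= float(np.mean(ratios)) <= 1.1

    def test_planted_program_separates_types(self):
        rng = np.random.default_rng(52)
        fpkm, types, genes = self._planted(rng, shift=8.0)
        assert pca_distance_ratio(fpkm, types, genes) > 1.5

    def test_zero_intra_distance_reported_as_inf(self):
        genes = ["g1", "g2"]
        fpkm = pd.DataFrame(
            {"A1": [1.0, 0.0], "A2": [1.0, 0.0], "B1": [0.0, 1.0], "B2": [0.0, 1.0]},
            index=genes,
        )
        types = pd.Series(["A", "A", "B", "B"], index=fpkm.columns)
        assert pca_distance_ratio(fpkm, types, genes) == float("inf")

    def test_gene_set_smaller_than_components_rejected(self):
        fpkm = pd.DataFrame({"A1": [1.0], "B1": [2.0]}, index=["g1"])
        types = pd.Series(["A", "B"], index=["A1", "B1"])
        with pytest.raises(ValueError):
            pca_distance_ratio(fpkm, types, ["g1"], n_pcs=2)


class TestSignatureScore:
    def test_single_gene_score_is_its_value(self):
        fpkm = pd.DataFrame({"s1": [3.0]}, index=["g1"])
        assert signature_score(fpkm, ["g1"])["s1"] == pytest.approx(2.0)  # log2(4)

    def test_two_gene_mean(self):
        # log2(FPKM+1) values of 2 and 4 average to 3
        fpkm = pd.DataFrame({"s1": [3.0, 15.0]}, index=["g1", "g2"])
        assert signature_score(fpkm, ["g1", "g2"])["s1"] == pytest.approx(3.0)

    def test_absent_genes_dropped_with_warning(self):
        fpkm = pd.DataFrame({"s1": [3.0]}, index=["g1"])
        with pytest.warns(UserWarning):
            out = signature_score(fpkm, ["g1", "gX"])
        assert out["s1"] == pytest.approx(2.0)

    def test_no_gene_present_rejected(self):
        fpkm = pd.DataFrame({"s1": [3.0]}, index=["g1"])
        with pytest.raises(ValueError):
            signature_score(fpkm, ["gX"])

    def test_random_matrix_matches_bruteforce(self):
        rng = np.random.default_rng(61)
        fpkm = pd.DataFrame(
            rng.uniform(0, 50, size=(10, 6)),
            index=[f"g{i}" for i in range(10)],
            columns=[f"s{j}" for j in range(6)],
        )
        out = signature_score(fpkm, list(fpkm.index))
        expected = np.log2(fpkm.to_numpy() + 1).mean(axis=0)
        assert np.allclose(out.to_numpy(), expected)


class TestStratifiedTest:
    def test_identical_strata_give_half(self):
        strat = pd.Series(np.arange(10.0), index=[f"s{i}" for i in range(10)])
        outcome = pd.Series([1.0, 2.0] * 5, index=strat.index)
        t, p = stratified_group_test(strat, outcome)
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(0.5)

    def test_large_shift_gives_tiny_p(self):
        idx = [f"s{i}" for i in range(20)]
        strat = pd.Series(np.arange(20.0), index=idx)
        outcome = pd.Series(
            np.concatenate([np.random.default_rng(0).normal(0, 1, 16), [50, 51, 52, 53]]),
            index=idx,
        )
        _, p = stratified_group_test(strat, outcome)
        assert p < 1e-6

    def test_rejection_rate_matches_welch_power(self):
        """Shift d=1 at n=30/30: empirical one-sided rejection at alpha=0.05
        tracks the analytic noncentral-t power within +/-0.05."""
        rng = np.random.default_rng(71)
        n, reps, d = 30, 400, 1.0
        rejections = 0
        for _ in range(reps):
            idx = [f"s{i}" for i in range(2 * n)]
            strat = pd.Series(np.arange(2.0 * n), index=idx)
            outcome = pd.Series(
                np.concatenate([rng.normal(0, 1, n), rng.normal(d, 1, n)]),
                index=idx,
            )
            _, p = stratified_group_test(strat, outcome, q=0.5)
            rejections += p < 0.05
        df = 2 * n - 2
        ncp = d / np.sqrt(2 / n)
        power = stats.nct.sf(stats.t.ppf(0.95, df), df, ncp)
        assert abs(rejections / reps - power) < 0.05

    def test_small_stratum_rejected(self):
        strat = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        with pytest.raises(ValueError):
            stratified_group_test(strat, strat, q=0.2)


class TestTfStratification:
    def test_perfectly_coupled_target_is_up(self):
        idx = [f"s{i}" for i in range(20)]
        tf = np.arange(20.0) + 1
        fpkm = pd.DataFrame({"TF": tf, "tgt": 5 * tf, "flat": np.full(20, 7.0)}, index=idx).T
        out = tf_stratified_target_fc(fpkm, "TF", ["tgt", "flat"])
        assert out.loc["tgt", "category"] == "up"
        assert out.loc["flat", "category"] == "unchanged"

    def test_absent_tf_rejected(self):
        fpkm = pd.DataFrame({"s1": [1.0]}, index=["g1"])
        with pytest.raises(ValueError):
            tf_stratified_target_fc(fpkm, "TF", ["g1"])

    def test_planted_tf_coupling_recovered(self, default_bundle):
        from cgiplast.diffexpr import compute_fpkm

        ann, cohorts, truth = default_bundle
        ct = ann.cancer_types[0]
        b = cohorts[ct]
        tumors = list(b.samples.loc[b.samples["condition"] == "tumor", "sample_id"])
        fpkm = compute_fpkm(b.counts, b.gene_lengths)
        out = tf_stratified_target_fc(
            fpkm, ann.tf_genes["TF_A"], truth.tf_targets["TF_A"], tumor_ids=tumors
        )
        assert (out["category"] == "up").mean() >= 0.8
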