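"""NB differential expression, TPM, cis-window reports, clustering."""

import numpy as np
import pandas as pd
import pytest
from oracles import naive_ward

from tuglocus.de import (
    CountMatrix,
    cis_window_report,
    cluster_tissues,
    compute_tpm,
    filter_low_counts,
    jensen_shannon_divergence,
    nb_wald_test,
    recurrence_tally,
    size_factors,
)
from tuglocus.simulate import SimulationParams, simulate_count_matrix


def _cm(counts, lengths=None, genotypes=None):
    counts = pd.DataFrame(counts)
    counts.index = [f"g{i}" for i in range(counts.shape[0])]
    counts.columns = [f"s{i}" for i in range(counts.shape[1])]
    n = counts.shape[1]
    genotypes = genotypes or ["WT"] * (n // 2) + ["KO"] * (n - n // 2)
    design = pd.DataFrame(
        {"genotype": genotypes, "tissue": "testis", "replicate": range(1, n + 1)},
        index=counts.columns,
    )
    lengths = lengths if lengths is not None else np.full(counts.shape[0], 1000)
    meta = pd.DataFrame(
        {
            "chrom": "chr11",
            "start": np.arange(counts.shape[0]) * 10_000,
            "end": np.arange(counts.shape[0]) * 10_000 + 1_000,
            "strand": "+",
            "length": lengths,
        },
        index=counts.index,
    )
    return CountMatrix(counts, design, meta)


class TestFilter:
    def test_all_zero_gene_filtered(self):
        cm = filter_low_counts(_cm([[0, 0, 0, 0], [5, 5, 5, 5]]))
        assert cm.filtered.tolist() == [True, False]

    def test_single_count_of_three_retained(self):
        # "less than three in every replicate": one replicate at 3 keeps it
        cm = filter_low_counts(_cm([[0, 0, 3, 0], [2, 2, 2, 2]]))
        assert cm.filtered.tolist() == [False, True]

    def test_matches_brute_force_row_scan(self, rng):
        mat = rng.integers(0, 6, size=(50, 8))
        cm = filter_low_counts(_cm(mat))
        expected = [max(row) < 3 for row in mat]
        assert cm.filtered.tolist() == expected


class TestTpm:
    def test_single_gene_gets_full_million(self):
        tpm = compute_tpm(_cm([[7, 13, 2, 9]]))
        assert np.allclose(tpm.values, 1e6)

    def test_length_normalization_ratio(self):
        tpm = compute_tpm(_cm([[10, 10, 10, 10], [10, 10, 10, 10]], lengths=[1000, 2000]))
        assert np.allclose(tpm.iloc[0] / tpm.iloc[1], 2.0)

    def test_matches_hand_computed_values(self):
        counts = [[10, 0, 5], [20, 10, 5], [30, 10, 0], [0, 0, 0], [40, 80, 90]]
        lengths = [100, 200, 300, 400, 500]
        tpm = compute_tpm(_cm(counts, lengths=lengths, genotypes=["WT", "WT", "KO"]))
        # frozen from an independent spreadsheet-style evaluation
        rates = np.array(counts, float) / np.array(lengths)[:, None]
        expected = 1e6 * rates / rates.sum(axis=0)
        assert np.allclose(tpm.values, expected)
        assert np.allclose(tpm.sum(axis=0), 1e6)

    def test_all_zero_column_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            compute_tpm(_cm([[1, 0, 2], [3, 0, 4]], genotypes=["WT", "WT", "KO"]))


class TestSizeFactors:
    def test_proportional_columns_recover_constants(self, rng):
        base = rng.integers(50, 500, size=40)
        counts = np.column_stack([base, 2 * base, 4 * base, base])
        sf = size_factors(pd.DataFrame(counts))
        norm = sf / np.exp(np.mean(np.log(sf)))
        expected = np.array([1.0, 2.0, 4.0, 1.0])
        assert np.allclose(norm, expected / np.exp(np.mean(np.log(expected))))


class TestNbWald:
    def test_duplicated_groups_give_exact_zero_lfc(self, rng):
        half = rng.integers(0, 400, size=(100, 4))
        cm = _cm(np.hstack([half, half]))
        de = nb_wald_test(filter_low_counts(cm), ("KO", "WT"))
        kept = de[~de["filtered"]]
        assert (kept["log2fc"] == 0).all()

    def test_null_type_one_error_calibrated(self):
        fracs = []
        for s in range(10):
            p = SimulationParams(seed=90_000 + s, n_genes=2_000, nb_mean=100, mean_spread_sd=0.0)
            cm, _ = simulate_count_matrix(p)
            de = nb_wald_test(filter_low_counts(cm), ("KO", "WT"))
            fracs.append((de["wald_p"] < 0.05).mean())
        assert 0.03 <= np.mean(fracs) <= 0.07

    def test_power_at_large_effect(self):
        detected = 0
        for s in range(20):
            p = SimulationParams(
                seed=91_000 + s, n_genes=500, nb_mean=500, mean_spread_sd=0.0,
                cis_gene_log2fc={"g00000": 2.0},
            )
            cm, _ = simulate_count_matrix(p)
            de = nb_wald_test(filter_low_counts(cm), ("KO", "WT"))
            detected += de.loc["g00000", "fdr_adjusted_p"] < 0.05
        assert detected / 20 >= 0.9

    def test_bh_adjusted_never_below_raw(self):
        p = SimulationParams(seed=17, n_genes=500)
        cm, _ = simulate_count_matrix(p)
        de = nb_wald_test(filter_low_counts(cm), ("KO", "WT"))
        kept = de[~de["filtered"]]
        assert (kept["fdr_adjusted_p"] >= kept["wald_p"] - 1e-15).all()
        assert kept["wald_p"].between(0, 1).all()

    def test_bh_step_up_monotone(self):
        p = SimulationParams(seed=18, n_genes=300)
        cm, _ = simulate_count_matrix(p)
        de = nb_wald_test(filter_low_counts(cm), ("KO", "WT"))
        kept = de[~de["filtered"]].sort_values("wald_p")
        assert kept["fdr_adjusted_p"].is_monotonic_increasing

    def test_filtered_genes_carry_no_pvalues(self):
        cm = _cm([[0, 0, 0, 0], [50, 60, 40, 55]])
        de = nb_wald_test(filter_low_counts(cm), ("KO", "WT"))
        assert np.isnan(de.loc["g0", "wald_p"])
        assert bool(de.loc["g0", "filtered"])

    def test_one_group_design_rejected(self):
        cm = _cm([[5, 5, 5, 5]], genotypes=["WT", "WT", "WT", "WT"])
        with pytest.raises(ValueError, match="degenerate|empty"):
            nb_wald_test(filter_low_counts(cm), ("KO", "WT"))

    def test_agrees_with_pydeseq2_on_effect_genes(self):
        # independent cross-check against the reference NB DE implementation
        p = SimulationParams(
            seed=19, n_genes=200, nb_mean=200, mean_spread_sd=0.5,
            cis_gene_log2fc={"g00000": 2.0, "g00001": -1.5},
        )
        cm, _ = simulate_count_matrix(p)
        de = nb_wald_test(filter_low_counts(cm), ("KO", "WT"))

        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats

        dds = DeseqDataSet(
            counts=cm.counts.T,
            metadata=cm.design.rename(columns={"genotype": "condition"}),
            design="~condition",
            quiet=True,
        )
        dds.deseq2()
        stats = DeseqStats(dds, contrast=["condition", "KO", "WT"], quiet=True)
        stats.summary()
        ref = stats.results_df.reindex(de.index)
        both = (~de["filtered"]) & ref["log2FoldChange"].notna()
        r = np.corrcoef(de.loc[both, "log2fc"], ref.loc[both, "log2FoldChange"])[0, 1]
        assert r > 0.9
        for g in ("g00000", "g00001"):
            assert np.sign(de.loc[g, "log2fc"]) == np.sign(ref.loc[g, "log2FoldChange"])
            assert de.loc[g, "fdr_adjusted_p"] < 0.05 and ref.loc[g, "padj"] < 0.05


class TestCisWindow:
    def _de_with_positions(self, positions, lfc, padj, chrom="chr11"):
        genes = [f"g{i}" for i in range(len(positions))]
        de = pd.DataFrame(
            {
                "log2fc": lfc,
                "fdr_adjusted_p": padj,
                "wald_p": padj,
                "filtered": False,
            },
            index=genes,
        )
        meta = pd.DataFrame(
            {
                "chrom": chrom,
                "start": positions,
                "end": np.asarray(positions) + 1_000,
                "strand": "+",
                "length": 1_000,
            },
            index=genes,
        )
        return de, meta

    def test_empty_window(self):
        de, meta = self._de_with_positions([10_000_000], [2.0], [0.001])
        rep = cis_window_report(de, meta, ("chr11", 100_000), window_bp=1_000_000)
        assert rep.empty

    def test_boundary_midpoint_included(self):
        # gene midpoint exactly at window/2 -> closed boundary keeps it
        de, meta = self._de_with_positions([1_000_000 - 500], [2.0], [0.001])
        rep = cis_window_report(de, meta, ("chr11", 0), window_bp=2_000_000)
        assert list(rep.index) == ["g0"]
        assert bool(rep.loc["g0", "flagged"])

    def test_degenerate_thresholds_return_all_window_genes(self):
        de, meta = self._de_with_positions(
            [100_000, 200_000, 300_000], [0.1, -0.05, 0.0], [0.9, 0.5, 1.0]
        )
        rep = cis_window_report(de, meta, ("chr11", 200_000), fdr=1.1, fc=1.0)
        # every gene in the window reported; fc threshold 1.0 and fdr 1.1
        # flag everything with any nonzero fold change
        assert len(rep) == 3
        assert rep["flagged"].tolist() == [True, True, False]

    def test_sides_and_distance_annotation(self):
        de, meta = self._de_with_positions([100_000, 400_000], [2.0, 2.0], [0.01, 0.01])
        rep = cis_window_report(de, meta, ("chr11", 300_000))
        assert rep.loc["g0", "side"] == "upstream"
        assert rep.loc["g1", "side"] == "downstream"
        assert rep.loc["g1", "distance_to_focal"] == 100_500

    def test_unknown_focal_chromosome_rejected(self):
        de, meta = self._de_with_positions([1], [0.0], [1.0])
        with pytest.raises(ValueError, match="chrY"):
            cis_window_report(de, meta, ("chrY", 100))


class TestRecurrenceTally:
    def _report(self, flags, lfc=None):
        lfc = lfc or [1.0] * len(flags)
        return pd.DataFrame(
            {"flagged": flags, "log2fc": lfc}, index=[f"g{i}" for i in range(len(flags))]
        )

    def test_eight_of_eight_pattern(self):
        reports = {f"t{i}": self._report([True, False]) for i in range(8)}
        tally = recurrence_tally(reports)
        assert tally.loc["g0", "n_tissues"] == 8
        assert tally.loc["g0", "n_up"] == 8
        assert tally.loc["g1", "n_tissues"] == 0

    def test_equals_boolean_matrix_column_sum(self, rng):
        tissues = [f"t{i}" for i in range(5)]
        flags = {t: rng.random(10) < 0.4 for t in tissues}
        reports = {t: self._report(list(flags[t])) for t in tissues}
        tally = recurrence_tally(reports)
        mat = np.column_stack([flags[t] for t in tissues])
        assert tally["n_tissues"].tolist() == mat.sum(axis=1).tolist()


class TestClusterTissues:
    def test_identical_profiles_have_zero_jsd(self):
        p = np.array([0.2, 0.3, 0.5])
        assert jensen_shannon_divergence(p, p) == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_support_has_jsd_one(self):
        p = np.array([1.0, 0.0])
        q = np.array([0.0, 1.0])
        assert jensen_shannon_divergence(p, q) == pytest.approx(1.0)

    def test_four_tissue_linkage_matches_naive_ward(self, rng):
        genes = 30
        tpm = pd.DataFrame(
            rng.gamma(2, 50, size=(genes, 4)),
            columns=["s1", "s2", "s3", "s4"],
        )
        s2t = {f"s{i+1}": f"tissue{i+1}" for i in range(4)}
        newick, dmat = cluster_tissues(tpm, s2t)
        merges = naive_ward(dmat.values)
        # first naive merge pair must be the closest pair and appear as a
        # cherry in the newick string
        i, j = merges[0][0]
        a, b = dmat.index[i], dmat.index[j]
        assert (f"{a}" in newick) and (f"{b}" in newick)
        from scipy.cluster.hierarchy import linkage
        from scipy.spatial.distance import squareform

        link = linkage(squareform(dmat.values, checks=False), method="ward")
        for k, (pair, h) in enumerate(merges):
            assert sorted(link[k, :2].astype(int).tolist()) == pair
            assert link[k, 2] == pytest.approx(h)

    def test_fewer_than_three_tissues_rejected(self, rng):
        tpm = pd.DataFrame(rng.random((5, 2)), columns=["a", "b"])
        with pytest.raises(ValueError, match="three tissues"):
            cluster_tissues(tpm, {"a": "t1", "b": "t2"})

    def test_zero_expression_tissue_rejected(self, rng):
        tpm = pd.DataFrame(
            np.column_stack([rng.random(5), rng.random(5), np.zeros(5)]),
            columns=["a", "b", "c"],
        )
        with pytest.raises(ValueError, match="zero total"):
            cluster_tissues(tpm, {"a": "t1", "b": "t2", "c": "t3"})
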