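"""Region partitioning, per-region CpG frequencies and rank statistics."""

import numpy as np
import pytest
from scipy import stats as sps

import promotercpg as pc
from promotercpg.region_stats import DEFAULT_PARTITION

W = pc.PromoterWindow


def _win(seq, offset=3000, gid="g"):
    return W(gene_id=gid, seq=seq, offset_of_tss=offset, has_full_upstream=True)


class TestRegionPartition:
    def test_default_partition_tiles_the_window(self):
        assert DEFAULT_PARTITION.labels == ("R1", "R2", "R3", "R4")
        assert DEFAULT_PARTITION.span() == (-3000, 500)

    def test_overlapping_regions_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            pc.RegionPartition(regions=(("a", 0, 10), ("b", 5, 20)))

    def test_gapped_regions_rejected(self):
        with pytest.raises(ValueError, match="gaps"):
            pc.RegionPartition(regions=(("a", 0, 10), ("b", 15, 20)))


class TestRegionFrequencyTable:
    def test_known_cpg_count_in_one_region(self):
        # 25 non-adjacent CG pairs inside R2 = [-500, 0): frequency 25/500
        up = ["A"] * 3000
        for k in range(25):
            p = 2500 + 20 * k  # window indices, rel positions -500 + 20k
            up[p], up[p + 1] = "C", "G"
        seq = "".join(up) + "A" * 500
        table = pc.region_frequency_table([_win(seq)])
        r2 = table[table.region == "R2"].iloc[0]
        assert r2.cpg_freq == pytest.approx(25 / 500)
        assert r2.n_positions == 500

    def test_all_a_sequence_is_zero_everywhere(self):
        table = pc.region_frequency_table([_win("A" * 3500)])
        assert (table.cpg_freq == 0).all()
        assert set(table.region) == {"R1", "R2", "R3", "R4"}

    def test_cg_repeat_matches_brute_force(self):
        seq = "A" * 2500 + "CG" * 250 + "A" * 500
        table = pc.region_frequency_table([_win(seq)])
        r2 = table[table.region == "R2"].iloc[0]
        # independent brute-force count over relative positions [-500, 0)
        hits = sum(1 for p in range(2500, 3000) if seq[p : p + 2] == "CG")
        assert r2.cpg_freq == pytest.approx(hits / 500)

    def test_gene_missing_region_gets_no_row(self):
        # window covering only [-200, +500): no R3/R4 rows
        table = pc.region_frequency_table([_win("A" * 700, offset=200)])
        assert set(table.region) == {"R1", "R2"}

    def test_ambiguous_bases_shrink_denominator(self):
        seq = "N" * 3000 + "A" * 500
        table = pc.region_frequency_table([_win(seq)])
        # fully-N upstream regions yield no rows; R1 loses one position to the
        # N|A junction dinucleotide
        assert set(table.region) == {"R1"}


class TestKruskalWallis:
    def test_three_group_oracle(self):
        res = pc.kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert res.statistic == pytest.approx(7.2)
        assert res.pvalue == pytest.approx(sps.chi2.sf(7.2, df=2))

    def test_identical_groups_give_zero(self):
        res = pc.kruskal_wallis([[5, 5], [5, 5]])
        assert res.statistic == 0.0 and res.pvalue == 1.0

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(12)
        groups = [rng.normal(size=8), rng.normal(1, 1, size=8)]
        h1 = pc.kruskal_wallis(groups).statistic
        h2 = pc.kruskal_wallis([np.exp(g) for g in groups]).statistic
        assert h1 == pytest.approx(h2)

    def test_two_group_rejection_agrees_with_exact_wilcoxon(self):
        rng = np.random.default_rng(13)
        agree = 0
        n_trials = 100
        for _ in range(n_trials):
            x = rng.normal(size=10)
            y = rng.normal(rng.uniform(0, 1.5), 1, size=10)
            kw = pc.kruskal_wallis([x, y])
            wx = pc.wilcoxon_rank_sum(x, y, exact_max_n=20)
            agree += (kw.pvalue < 0.05) == (wx.pvalue < 0.05)
        assert agree / n_trials >= 0.95


class TestDunn:
    def test_pairwise_oracle(self):
        res = pc.dunn_posthoc([[1, 2, 3], [4, 5, 6], [7, 8, 9]], labels=list("ABC"))
        pair = {r.groups: r for r in res}
        assert abs(pair[("A", "C")].statistic) == pytest.approx(6 / np.sqrt(5))

    def test_identical_pair_gives_zero(self):
        res = pc.dunn_posthoc([[5, 5], [5, 5]])
        assert res[0].statistic == 0.0 and res[0].pvalue == 1.0

    def test_antisymmetric_under_pair_swap(self):
        rng = np.random.default_rng(14)
        a, b = rng.normal(size=6), rng.normal(1, 1, size=6)
        z_ab = pc.dunn_posthoc([a, b])[0].statistic
        z_ba = pc.dunn_posthoc([b, a])[0].statistic
        assert z_ab == pytest.approx(-z_ba)

    def test_sign_agrees_with_group_shift(self):
        rng = np.random.default_rng(15)
        hits = 0
        for _ in range(50):
            lo = rng.normal(0, 1, size=50)
            hi = rng.normal(1, 1, size=50)
            z = pc.dunn_posthoc([hi, lo])[0].statistic
            hits += z > 0
        assert hits >= 49

    def test_bonferroni_option_scales_pvalues(self):
        res = pc.dunn_posthoc([[1, 2], [3, 4], [5, 6]], adjust="bonferroni")
        for r in res:
            assert r.p_adjusted == pytest.approx(min(1.0, 3 * r.pvalue))

    def test_fewer_than_two_groups_is_error(self):
        with pytest.raises(ValueError):
            pc.dunn_posthoc([[1, 2]])


class TestWilcoxon:
    def test_exact_small_sample_oracle(self):
        res = pc.wilcoxon_rank_sum([1, 2], [3, 4])
        assert res.statistic == 3.0
        assert res.pvalue == pytest.approx(1 / 3)

    def test_identical_samples_give_p_one(self):
        res = pc.wilcoxon_rank_sum([1, 2, 2], [1, 2, 2])
        assert res.pvalue == 1.0

    def test_approximation_close_to_permutation_oracle(self):
        # exhaustive distribution of the rank sum for 8 vs 8 without ties
        from itertools import combinations

        sums = np.array([sum(c) for c in combinations(range(1, 17), 8)])
        mean = 8 * 17 / 2
        rng = np.random.default_rng(16)
        for _ in range(10):
            x, y = rng.normal(size=8), rng.normal(0.8, 1, size=8)
            res = pc.wilcoxon_rank_sum(x, y, exact_max_n=0)  # force the approximation
            p_perm = float(np.mean(np.abs(sums - mean) >= abs(res.statistic - mean)))
            assert abs(res.pvalue - p_perm) < 0.02


class TestBonferroni:
    @pytest.mark.parametrize(
        "p, m, expected", [(0.01, 4, 0.04), (0.5, 4, 1.0), (0.2, 1, 0.2)]
    )
    def test_examples(self, p, m, expected):
        assert pc.bonferroni_adjust([p], m=m)[0] == pytest.approx(expected)

    def test_family_smaller_than_tests_is_error(self):
        with pytest.raises(ValueError):
            pc.bonferroni_adjust([0.1, 0.2], m=1)


def _class_sets(genes, vocab):
    return pc.unique_class_sets({g.gene_id: g.kegg_classes for g in genes}, vocab)


class TestClassRegionAnalysis:
    def test_duplicated_class_is_not_significant(self):
        rng = np.random.default_rng(17)
        vals = rng.uniform(0.02, 0.08, size=40)
        import pandas as pd

        rows = []
        for region in ("R1", "R2", "R3", "R4"):
            for i, v in enumerate(vals):
                rows.append((f"g{i}", region, v, 500))
        table = pd.DataFrame(rows, columns=["gene_id", "region", "cpg_freq", "n_positions"])
        sets = {"A": [f"g{i}" for i in range(20)], "B": [f"g{i}" for i in range(20, 40)]}
        # same generative distribution in both pseudo-classes
        results = pc.class_region_analysis(table, sets)
        assert len(results) == 4
        assert not any(r.significant for r in results)

    def test_elevated_class_flagged_highest_in_far_upstream(self):
        eip = "Environmental Information Processing"
        vocab = pc.DEFAULT_KEGG_CLASSES
        attrs = [({vocab[i % 5]}, False) for i in range(1000)]
        cfg = pc.SyntheticGenomeConfig(
            n_genes=1000,
            class_rho_offsets={eip: (1.2, -3000, -1000)},
            multiclass_fraction=0.0,
            focal_fraction=0.0,
            seed=18,
        )
        windows, genes = pc.simulate_windows(cfg, attrs=attrs)
        table = pc.region_frequency_table(windows)
        results = pc.class_region_analysis(table, _class_sets(genes, vocab))
        r4 = next(r for r in results if r.region == "R4")
        assert r4.significant
        # the elevated class carries the top letter group in R4
        means = (
            table[table.region == "R4"]
            .set_index("gene_id")
            .cpg_freq
        )
        sets = _class_sets(genes, vocab)
        class_means = {c: means.reindex(g).mean() for c, g in sets.items()}
        assert max(class_means, key=class_means.get) == eip
        assert "a" in r4.letters[eip]

    def test_too_few_classes_is_error(self):
        import pandas as pd

        table = pd.DataFrame(columns=["gene_id", "region", "cpg_freq", "n_positions"])
        with pytest.raises(ValueError):
            pc.class_region_analysis(table, {"A": ["g1", "g2"]})


class TestSetRegionAnalysis:
    def test_focal_covering_all_genes_is_error(self, small_dataset):
        table = pc.region_frequency_table(small_dataset.windows)
        with pytest.raises(ValueError, match="complement"):
            pc.set_region_analysis(table, set(table.gene_id.unique()))

    def test_elevated_focal_set_flagged_only_in_target_region(self):
        cfg = pc.SyntheticGenomeConfig(
            n_genes=600,
            focal_fraction=0.1,
            focal_rho_offset=(1.25, -500, 0),
            multiclass_fraction=0.0,
            seed=19,
        )
        windows, genes = pc.simulate_windows(cfg)
        focal = {g.gene_id for g in genes if g.in_focal_set}
        table = pc.region_frequency_table(windows)
        results = pc.set_region_analysis(table, focal)
        flagged = {r.region for r in results if r.significant}
        assert flagged == {"R2"}
        r2 = next(r for r in results if r.region == "R2")
        assert r2.direction == +1
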