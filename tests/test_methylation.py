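import numpy as np
import pandas as pd
import pytest

from amplimeth.align import AmpliconTemplate, align_read, filter_reads
from amplimeth.methylation import (
    MethylationMatrix,
    build_methylation_matrix,
    call_cpg_methylation,
    cluster_markers,
    compare_methylation_groups,
    summarize_assay,
)
from amplimeth.synthetic import default_template, gen_bisulfite_reads


def _call(template, reads):
    alns = [align_read(seq, template, read_id=rid) for rid, seq in reads]
    return call_cpg_methylation(filter_reads(alns), template), alns


class TestCalling:
    def test_counts_give_fraction(self, template):
        # 7 methylated + 3 unmethylated error-free reads at every site
        meth = template.forward_ref.replace("Y", "C")
        unmeth = template.forward_ref.replace("Y", "T")
        reads = [(f"m{i}", meth) for i in range(7)] + [
            (f"u{i}", unmeth) for i in range(3)]
        table, _ = _call(template, reads)
        assert np.allclose(table["fraction"], 0.7)
        assert (table["coverage"] == 10).all()

    def test_zero_coverage_fraction_undefined(self, template):
        table = call_cpg_methylation([], template)
        assert (table["coverage"] == 0).all()
        assert table["fraction"].isna().all()

    def test_matches_simulator_binomial_draws(self, template):
        reads, truth = gen_bisulfite_reads(template, [0.6, 0.2, 0.9],
                                           n_reads=500, seed=8)
        table, _ = _call(template, reads)
        assert list(table["count_C"]) == truth.cpg_methylated_draws
        se = np.sqrt(0.6 * 0.4 / 500)
        assert abs(table["fraction"].iloc[0] - 0.6) < 3 * se

    def test_failing_reads_change_no_counts(self, template):
        reads, _ = gen_bisulfite_reads(template, [0.5] * 3, n_reads=50, seed=2)
        alns = [align_read(seq, template, read_id=rid) for rid, seq in reads]
        passing = filter_reads(alns)
        base = call_cpg_methylation(passing, template)
        junk = align_read("ACGT" * 30, template, read_id="junk")
        filter_reads([junk])
        assert not junk.passed
        again = call_cpg_methylation(passing, template)
        pd.testing.assert_frame_equal(base, again)

    def test_conservation_of_counts(self, template):
        reads, _ = gen_bisulfite_reads(
            template, [0.5] * 3, n_reads=80, sub_rate=0.02, indel_rate=0.02,
            seed=5)
        alns = [align_read(seq, template, read_id=rid) for rid, seq in reads]
        passing = filter_reads(alns)
        table = call_cpg_methylation(passing, template)
        for (name, pos), row in table.iterrows():
            spanning = sum(
                1 for a in passing
                if a.start <= (pos if a.orientation == "forward" else pos + 1) < a.end
            )
            assert row["count_C"] + row["count_T"] + row["count_other"] == spanning

    def test_primer_masked_sites_excluded(self):
        t = default_template()
        masked = AmpliconTemplate("m", t.seq, primer_masks=[(0, 30)])
        reads, _ = gen_bisulfite_reads(masked, [0.5] * 3, n_reads=5, seed=0)
        table, _ = _call(masked, reads)
        assert list(table.index.get_level_values("position")) == [43, 84]

    def test_parameter_recovery_across_truths(self, template):
        """Absolute calling error stays within 3 binomial SE for error-free
        reads across the truth grid (20 seeded replicates per truth here)."""
        failures = 0
        trials = 0
        for p in (0.1, 0.3, 0.5, 0.7, 0.9):
            se = np.sqrt(p * (1 - p) / 300)
            for seed in range(20):
                reads, _ = gen_bisulfite_reads(template, [p] * 3,
                                               n_reads=300, seed=seed)
                table, _ = _call(template, reads)
                trials += 3
                failures += int((np.abs(table["fraction"] - p) >= 3 * se).sum())
        assert failures / trials <= 0.05


class TestSummarize:
    def _table(self, fractions):
        idx = pd.MultiIndex.from_tuples(
            [("a", i) for i in range(len(fractions))],
            names=["template", "position"])
        f = pd.Series(fractions, index=idx)
        return pd.DataFrame({
            "count_C": (f.fillna(0) * 10).astype(int), "count_T": 0,
            "count_other": 0, "coverage": f.notna() * 10, "fraction": f})

    def test_unweighted_mean_percent(self):
        assert summarize_assay(self._table([0.2, 0.4])) == pytest.approx(30.0)

    def test_single_defined_site(self):
        assert summarize_assay(self._table([np.nan, 0.8])) == pytest.approx(80.0)

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError):
            summarize_assay(self._table([0.5]).iloc[:0])


def _mm(values, groups):
    return MethylationMatrix(values, pd.Series(groups))


class TestCompareGroups:
    def _matrix(self, nat, ad, crc):
        cols = {f"NAT{i}": v for i, v in enumerate(nat)}
        cols |= {f"AD{i}": v for i, v in enumerate(ad)}
        cols |= {f"CRC{i}": v for i, v in enumerate(crc)}
        values = pd.DataFrame(cols, index=["assay1"])
        groups = {s: s.rstrip("0123456789") for s in values.columns}
        return _mm(values, groups)

    def test_hypermethylated_pattern(self):
        # the PRIMA1-in-CRC pattern: low NAT, high CRC
        mm = self._matrix([7.0, 7.5, 7.2], [9.5, 10.2, 9.9],
                          [28.5, 29.4, 28.9])
        res = compare_methylation_groups(mm)
        assert res.loc["assay1", "class_CRC"] == "hypermethylated"
        assert res.loc["assay1", "p_N_vs_CRC"] < 0.05

    def test_hypomethylated_pattern(self):
        mm = self._matrix([91.3, 91.4, 91.2], [85.6, 85.7, 85.6],
                          [83.7, 83.8, 83.7])
        res = compare_methylation_groups(mm)
        assert res.loc["assay1", "class_AD"] == "hypomethylated"
        assert res.loc["assay1", "class_CRC"] == "hypomethylated"

    def test_identical_groups_unchanged_p_one(self):
        mm = self._matrix([50.0, 50.0], [50.0, 50.0], [50.0, 50.0])
        res = compare_methylation_groups(mm)
        assert res.loc["assay1", "p_N_vs_CRC"] == pytest.approx(1.0)
        assert res.loc["assay1", "class_CRC"] == "unchanged"

    def test_all_missing_not_evaluable(self):
        values = pd.DataFrame(
            {"NAT1": [np.nan], "NAT2": [np.nan], "AD1": [np.nan],
             "AD2": [np.nan], "CRC1": [np.nan], "CRC2": [np.nan]},
            index=["assay1"])
        groups = {s: s.rstrip("0123456789") for s in values.columns}
        res = compare_methylation_groups(_mm(values, groups))
        assert res.loc["assay1", "class_CRC"] == "not_evaluable"


class TestClustering:
    def _random_mm(self, seed=0, n=6):
        rng = np.random.default_rng(seed)
        values = pd.DataFrame(
            rng.uniform(0, 100, size=(n, 6)),
            index=[f"assay{i}" for i in range(n)],
            columns=[f"s{i}" for i in range(6)])
        groups = {f"s{i}": g for i, g in
                  enumerate(["NAT"] * 2 + ["AD"] * 2 + ["CRC"] * 2)}
        return _mm(values, groups)

    def test_identical_rows_merge_first(self):
        values = pd.DataFrame(
            [[10.0, 10.0, 10.0], [10.0, 10.0, 10.0], [90.0, 90.0, 90.0]],
            index=["a", "b", "c"], columns=["s1", "s2", "s3"])
        groups = {"s1": "NAT", "s2": "AD", "s3": "CRC"}
        res = cluster_markers(_mm(values, groups), k=2)
        assert res["row_linkage"][0, 2] == 0.0  # first merge at distance 0
        assert res["row_clusters"]["a"] == res["row_clusters"]["b"]
        assert res["row_clusters"]["a"] != res["row_clusters"]["c"]

    def test_average_linkage_on_1d_points(self):
        # points {0, 1, 10}: {0,1} merge at distance 1 before 10 joins at
        # average distance (10 + 9)/2 = 9.5
        values = pd.DataFrame(
            [[0.0], [1.0], [10.0]], index=["a", "b", "c"], columns=["s1"])
        res = cluster_markers(_mm(values, {"s1": "NAT"}))
        link = res["row_linkage"]
        assert link[0, 2] == pytest.approx(1.0)
        assert link[1, 2] == pytest.approx(9.5)

    def test_planted_block_separates_at_k2(self):
        rng = np.random.default_rng(4)
        low = rng.uniform(0, 15, size=(4, 6))
        high = rng.uniform(80, 100, size=(3, 6))
        values = pd.DataFrame(
            np.vstack([low, high]),
            index=[f"low{i}" for i in range(4)] + [f"hi{i}" for i in range(3)],
            columns=[f"s{i}" for i in range(6)])
        groups = {f"s{i}": "NAT" for i in range(6)}
        res = cluster_markers(_mm(values, groups), k=2)
        labels = res["row_clusters"]
        assert len({labels[f"low{i}"] for i in range(4)}) == 1
        assert len({labels[f"hi{i}"] for i in range(3)}) == 1
        assert labels["low0"] != labels["hi0"]

    def test_invariant_to_row_order(self):
        mm = self._random_mm(seed=9)
        res1 = cluster_markers(mm, k=3)
        shuffled = MethylationMatrix(
            mm.values.iloc[::-1], mm.groups)
        res2 = cluster_markers(shuffled, k=3)
        part1 = {}
        part2 = {}
        for a in mm.values.index:
            part1.setdefault(res1["row_clusters"][a], set()).add(a)
            part2.setdefault(res2["row_clusters"][a], set()).add(a)
        assert set(map(frozenset, part1.values())) == set(
            map(frozenset, part2.values()))

    def test_all_missing_row_excluded_with_warning(self):
        mm = self._random_mm(seed=1)
        values = mm.values.copy()
        values.loc["assay0"] = np.nan
        with pytest.warns(UserWarning, match="assay0"):
            res = cluster_markers(MethylationMatrix(values, mm.groups))
        assert "assay0" not in res["assays"]


class TestBuildMatrix:
    def test_end_to_end_assembly(self, template):
        per_sample = {}
        for i, (sample, p) in enumerate(
                (("NAT1", 0.1), ("NAT2", 0.1), ("AD1", 0.5),
                 ("AD2", 0.5), ("CRC1", 0.9), ("CRC2", 0.9))):
            reads, _ = gen_bisulfite_reads(template, [p] * 3, n_reads=150,
                                           seed=100 + i)
            table, _ = _call(template, reads)
            per_sample[sample] = table
        groups = pd.Series({s: s.rstrip("0123456789")
                            for s in per_sample})
        mm = build_methylation_matrix(per_sample, groups)
        assert mm.values.shape == (1, 6)
        assert mm.values.loc["sim_amplicon", "CRC1"] > \
            mm.values.loc["sim_amplicon", "NAT1"]
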