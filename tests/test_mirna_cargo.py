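"""Small-RNA cargo statistics: QC, UMI collapse, composition, differential."""

import itertools

import numpy as np
import pandas as pd
import pytest

import secretomics as sx
from secretomics.mirna_cargo import (MirnaCountMatrix, differential_enrichment,
                                     qc_filter, rna_composition, stable_core,
                                     top_n_coverage, umi_collapse)
from secretomics.synthetic_data import MirnaDesign, generate_mirna_reads


def reads_df(rows):
    return pd.DataFrame(rows, columns=["read_id", "insert", "umi",
                                       "adapter_found", "assigned_species"])


class TestQcFilter:
    def test_each_rule_and_tally(self):
        rows = [
            ("r1", "A" * 20, "C" * 12, True, "miR-1"),    # kept
            ("r2", "A" * 15, "C" * 12, True, "miR-1"),    # short insert
            ("r3", "A" * 20, "C" * 9, True, "miR-1"),     # short UMI
            ("r4", "A" * 20, "C" * 12, False, "miR-1"),   # no adapter
            ("r5", "A" * 15, "C" * 9, False, "miR-1"),    # no adapter (first rule)
        ]
        kept, discards = qc_filter(reads_df(rows))
        assert list(kept["read_id"]) == ["r1"]
        assert discards == {"no_adapter": 2, "short_insert": 1, "short_umi": 1}

    def test_boundary_lengths_kept(self):
        rows = [("r1", "A" * 16, "C" * 10, True, "miR-1")]
        kept, _ = qc_filter(reads_df(rows))
        assert len(kept) == 1


class TestUmiCollapse:
    def test_distinct_umi_counting(self):
        rows = [("r1", "A" * 20, "U1", True, "miR-a"),
                ("r2", "A" * 20, "U1", True, "miR-a"),
                ("r3", "A" * 20, "U2", True, "miR-a")]
        m = umi_collapse({"s1": reads_df(rows)})
        assert m.counts.loc["miR-a", "s1"] == 2

    def test_all_distinct_equals_read_count(self):
        rows = [(f"r{i}", "A" * 20, f"U{i}", True, "miR-a") for i in range(7)]
        m = umi_collapse({"s1": reads_df(rows)})
        assert m.counts.loc["miR-a", "s1"] == 7

    def test_invariant_to_read_duplication(self):
        rng = np.random.default_rng(0)
        rows = [(f"r{i}", "A" * 20, f"U{rng.integers(5)}", True,
                 f"miR-{rng.integers(3)}") for i in range(30)]
        base = umi_collapse({"s": reads_df(rows)})
        doubled = umi_collapse({"s": reads_df(rows + rows)})
        pd.testing.assert_frame_equal(base.counts, doubled.counts)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_distinct_count_oracle(self, seed):
        rng = np.random.default_rng(seed)
        rows = [(f"r{i}", "A" * 20, f"U{rng.integers(12)}", True,
                 f"miR-{rng.integers(5)}") for i in range(200)]
        df = reads_df(rows)
        m = umi_collapse({"s": df})
        for sp, grp in df.groupby("assigned_species"):
            assert m.counts.loc[sp, "s"] == len(set(grp["umi"]))


class TestComposition:
    def test_percentages(self):
        counts = pd.DataFrame({"s1": [35, 35, 30]},
                              index=["miR-1", "rRNA-1", "other-1"])
        comp = rna_composition(MirnaCountMatrix(counts))
        assert comp["s1"].to_dict() == pytest.approx(
            {"miRNA": 35.0, "rRNA": 35.0, "other": 30.0})

    def test_single_class_is_100(self):
        comp = rna_composition(MirnaCountMatrix(
            pd.DataFrame({"s1": [4, 6]}, index=["miR-1", "miR-2"])))
        assert comp.loc["miRNA", "s1"] == 100.0

    def test_scale_invariance_and_allzero_warning(self):
        counts = pd.DataFrame({"s1": [10, 30], "s2": [0, 0]},
                              index=["miR-1", "rRNA-1"])
        with pytest.warns(UserWarning, match="all-zero"):
            comp = rna_composition(MirnaCountMatrix(counts))
        scaled = counts.copy()
        scaled["s1"] *= 7
        with pytest.warns(UserWarning):
            comp7 = rna_composition(MirnaCountMatrix(scaled))
        assert comp["s1"].equals(comp7["s1"])
        assert comp["s2"].isna().all()


class TestTopNCoverage:
    def test_arithmetic(self):
        s = pd.Series({"a": 50, "b": 30, "c": 20})
        out = top_n_coverage(s, n=2)
        assert out["coverage"] == pytest.approx(0.8)
        assert out["ranked"] == ["a", "b"]

    def test_n_at_least_species_count_is_one(self):
        s = pd.Series({"a": 5, "b": 1})
        with pytest.warns(UserWarning):
            assert top_n_coverage(s, n=5)["coverage"] == 1.0

    def test_monotone_in_n(self):
        rng = np.random.default_rng(1)
        s = pd.Series(rng.integers(1, 100, size=30),
                      index=[f"m{i}" for i in range(30)])
        covs = [top_n_coverage(s, n)["coverage"] for n in range(1, 31)]
        assert all(b >= a for a, b in zip(covs, covs[1:]))
        assert covs[-1] == pytest.approx(1.0)


class TestDifferential:
    def make_matrix(self, a_vals, b_vals, n_null=0, seed=0):
        rng = np.random.default_rng(seed)
        data = {}
        for i, v in enumerate(a_vals):
            data[f"a{i}"] = [v] + list(rng.poisson(50, n_null))
        for i, v in enumerate(b_vals):
            data[f"b{i}"] = [v] + list(rng.poisson(50, n_null))
        counts = pd.DataFrame(data, index=["miR-x"]
                              + [f"miR-null{j}" for j in range(n_null)])
        return MirnaCountMatrix(counts)

    def test_identical_groups_give_p_one(self):
        m = self.make_matrix([10, 10, 10], [10, 10, 10])
        res = differential_enrichment(m, ["a0", "a1", "a2"],
                                      ["b0", "b1", "b2"], min_mean_count=0)
        assert res.loc["miR-x", "log2fc"] == 0.0
        assert res.loc["miR-x", "p"] == 1.0

    def test_exact_enumeration_matches_brute_force(self):
        # 3+3 samples: all C(6,3)=20 group assignments enumerated
        m = self.make_matrix([40, 55, 47], [12, 9, 16], n_null=3)
        ga, gb = ["a0", "a1", "a2"], ["b0", "b1", "b2"]
        res = differential_enrichment(m, ga, gb, min_mean_count=0)
        lib = m.counts.sum(axis=0)
        log_rpm = np.log2(m.counts.div(lib, axis=1) * 1e6 + 0.5)
        for sp in m.counts.index:
            vals = log_rpm.loc[sp, ga + gb].to_numpy()
            obs = abs(vals[:3].mean() - vals[3:].mean())
            count = sum(
                abs(vals[list(c)].mean()
                    - vals[[i for i in range(6) if i not in c]].mean())
                >= obs - 1e-12
                for c in itertools.combinations(range(6), 3))
            assert res.loc[sp, "p"] == pytest.approx(count / 20)

    def test_minimum_exact_p_is_two_twentieths(self):
        m = self.make_matrix([1000, 1100, 900], [10, 11, 9], n_null=3)
        res = differential_enrichment(m, ["a0", "a1", "a2"],
                                      ["b0", "b1", "b2"], min_mean_count=0)
        assert res.loc["miR-x", "p"] == pytest.approx(2 / 20)

    def test_bh_q_monotone_and_bounded(self, default_mirna):
        _, _, samples, _, matrix = default_mirna
        groups = samples.groupby("stage")["sample"].apply(list)
        res = differential_enrichment(matrix.subset_class("miRNA"),
                                      groups["f"], groups["p"], seed=3)
        ordered = res.sort_values("p")
        assert (ordered["q"].diff().dropna() >= -1e-12).all()
        assert (res["q"] <= 1.0).all() and (res["q"] >= res["p"] - 1e-12).all()

    def test_planted_modulation_recovered_at_stage_contrast(self, default_mirna):
        _, _, samples, truth, matrix = default_mirna
        groups = samples.groupby("stage")["sample"].apply(list)
        res = differential_enrichment(matrix.subset_class("miRNA"),
                                      groups["f"], groups["p"], seed=0)
        found = set(res.index[res["modulated"]])
        planted = set(truth.modulated_mirnas)
        assert len(found & planted) / len(planted) >= 0.90
        # direction agrees with the planted fold
        for sp, info in truth.modulated_mirnas.items():
            if sp in found:
                expect_up = info["up_in"] == "f"
                assert (res.loc[sp, "log2fc"] > 0) == expect_up

    def test_too_few_samples_rejected(self):
        m = self.make_matrix([1], [2, 3])
        with pytest.raises(ValueError):
            differential_enrichment(m, ["a0"], ["b0", "b1"])


class TestStableCore:
    def test_zero_cv_species_is_stable(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(
            rng.integers(50, 400, size=(40, 6)),
            index=[f"miR-{i:02d}" for i in range(40)],
            columns=[f"f-s{i}" for i in range(3)] + [f"p-s{i}" for i in range(3)])
        counts.loc["miR-00"] = 200          # perfectly constant
        samples = pd.DataFrame({
            "sample": counts.columns,
            "stage": ["f"] * 3 + ["p"] * 3})
        # constant counts with equal library sizes -> cv 0 in both stages
        counts.loc["miR-01"] = counts.sum(axis=0).max() - counts.drop(
            index=["miR-01"]).sum(axis=0)   # equalize library sizes
        m = MirnaCountMatrix(counts, samples=samples)
        out = stable_core(m)
        for stage in ("f", "p"):
            rec = out["records"][stage]
            assert rec.loc["miR-00", "cv"] == pytest.approx(0.0)
            assert rec.loc["miR-00", "stable"]
        assert "miR-00" in out["shared_core"]

    def test_shared_core_is_intersection(self, default_mirna):
        _, _, _, truth, matrix = default_mirna
        out = stable_core(matrix.subset_class("miRNA"))
        stables = [set(rec.index[rec["stable"]])
                   for rec in out["records"].values()]
        assert out["shared_core"] == set.intersection(*stables)

    def test_planted_core_species_in_shared_core(self, default_mirna):
        _, _, _, truth, matrix = default_mirna
        out = stable_core(matrix.subset_class("miRNA"))
        assert set(truth.stable_mirnas) <= out["shared_core"]

    def test_cv_invariant_to_depth_doubling(self):
        rng = np.random.default_rng(2)
        counts = pd.DataFrame(rng.integers(10, 300, size=(30, 6)),
                              index=[f"miR-{i:02d}" for i in range(30)],
                              columns=[f"s{i}" for i in range(6)])
        samples = pd.DataFrame({"sample": counts.columns,
                                "stage": ["f"] * 3 + ["p"] * 3})
        base = stable_core(MirnaCountMatrix(counts, samples=samples))
        doubled = stable_core(MirnaCountMatrix(counts * 2, samples=samples))
        for stage in base["records"]:
            pd.testing.assert_series_equal(base["records"][stage]["cv"],
                                           doubled["records"][stage]["cv"])
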