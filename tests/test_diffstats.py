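"""Normalisation, protein correction and the error-propagated ANOVA."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from flipms import io, simulate
from flipms.diffstats import (
    PeptideAnova,
    adjust_bh,
    correct_by_protein,
    group_to_parent,
    median_normalize,
    pairwise_tukey,
    protein_abundance_anova,
)


def propagated_anova_oracle(pep_by_group, prot_by_group, variant):
    """Independent step-by-step transcription of the propagated one-way ANOVA.

    Plain-python evaluation: mean ratio per group, error-propagated sd from
    the raw peptide and protein CVs, between/within mean squares, F and the
    upper-tail p at (C-1, N-C) degrees of freedom.
    """
    groups = sorted(pep_by_group)
    means, sds, ns = {}, {}, {}
    for g in groups:
        pep = pep_by_group[g]
        prot = prot_by_group[g]
        ratios = [a / b for a, b in zip(pep, prot)]
        n = len(ratios)
        mean = sum(ratios) / n
        mu_pep = sum(pep) / len(pep)
        mu_prot = sum(prot) / len(prot)
        sd_pep = math.sqrt(sum((x - mu_pep) ** 2 for x in pep) / (len(pep) - 1))
        sd_prot = math.sqrt(sum((x - mu_prot) ** 2 for x in prot) / (len(prot) - 1))
        sd = mean * math.sqrt((sd_pep / mu_pep) ** 2 + (sd_prot / mu_prot) ** 2)
        means[g], sds[g], ns[g] = mean, sd, n
    C = len(groups)
    N = sum(ns.values())
    if variant == "as_printed":
        grand = sum(means.values()) / N
        ms_between = sum(ns[g] * (means[g] - grand) ** 2 for g in groups) / C
    else:
        grand = sum(ns[g] * means[g] for g in groups) / N
        ms_between = sum(ns[g] * (means[g] - grand) ** 2 for g in groups) / (C - 1)
    ms_within = sum((ns[g] - 1) * sds[g] ** 2 for g in groups) / (N - C)
    F = ms_between / ms_within
    p = float(stats.f.sf(F, C - 1, N - C))
    return {"ms_between": ms_between, "ms_within": ms_within, "F": F, "p": p}


def _tables(pep_by_group, prot_by_group, peptide="PEP", protein="P1"):
    lip_rows, ctrl_rows = [], []
    for g in pep_by_group:
        for r, v in enumerate(pep_by_group[g], start=1):
            lip_rows.append((peptide, protein, g, r, v, "lip"))
        for r, v in enumerate(prot_by_group[g], start=1):
            ctrl_rows.append((protein, protein, g, r, v, "tryptic_control"))
    cols = ["analyte_id", "protein_id", "group", "replicate", "intensity", "sample_type"]
    return pd.DataFrame(lip_rows, columns=cols), pd.DataFrame(ctrl_rows, columns=cols)


class TestMedianNormalize:
    def test_scale_factors_from_sample_medians(self):
        # medians 10 and 20, median of sample medians 15 -> factors 1.5, 0.75
        rows = [
            ("A", "P", "100K", 1, 5.0, "lip"),
            ("B", "P", "100K", 1, 10.0, "lip"),
            ("C", "P", "100K", 1, 20.0, "lip"),
            ("A", "P", "100K", 2, 10.0, "lip"),
            ("B", "P", "100K", 2, 20.0, "lip"),
            ("C", "P", "100K", 2, 40.0, "lip"),
        ]
        cols = ["analyte_id", "protein_id", "group", "replicate", "intensity", "sample_type"]
        out = median_normalize(pd.DataFrame(rows, columns=cols))
        s1 = out[out["replicate"] == 1]["intensity"].tolist()
        s2 = out[out["replicate"] == 2]["intensity"].tolist()
        assert s1 == pytest.approx([7.5, 15.0, 30.0])
        assert s2 == pytest.approx([7.5, 15.0, 30.0])

    def test_equal_medians_identity(self, experiment):
        lip, _ = experiment
        again = median_normalize(median_normalize(lip, "global"), "global")
        once = median_normalize(lip, "global")
        pd.testing.assert_series_equal(
            once.sort_values(["analyte_id", "group", "replicate"])["intensity"].reset_index(drop=True),
            again.sort_values(["analyte_id", "group", "replicate"])["intensity"].reset_index(drop=True),
        )

    def test_per_group_scope_does_not_mix_fractions(self):
        rows = [
            ("A", "P", "100K", 1, 10.0, "lip"),
            ("B", "P", "100K", 1, 30.0, "lip"),
            ("A", "P", "10K", 1, 1000.0, "lip"),
            ("B", "P", "10K", 1, 3000.0, "lip"),
        ]
        cols = ["analyte_id", "protein_id", "group", "replicate", "intensity", "sample_type"]
        out = median_normalize(pd.DataFrame(rows, columns=cols), scope="per_group")
        # single sample per group: per-group target equals its own median
        assert sorted(out["intensity"]) == [10.0, 30.0, 1000.0, 3000.0]


class TestCorrectByProtein:
    def test_simple_ratio(self):
        lip, ctrl = _tables({"100K": [100.0]}, {"100K": [50.0]})
        ratios = correct_by_protein(lip, ctrl)
        assert ratios["ratio"].tolist() == [2.0]

    def test_abundance_correction_invariance(self):
        lip1, ctrl1 = _tables({"100K": [100.0], "10K": [100.0]}, {"100K": [50.0], "10K": [50.0]})
        lip2, ctrl2 = _tables({"100K": [100.0], "10K": [200.0]}, {"100K": [50.0], "10K": [100.0]})
        r1 = correct_by_protein(lip1, ctrl1)["ratio"]
        r2 = correct_by_protein(lip2, ctrl2)["ratio"]
        assert r1.tolist() == r2.tolist()

    def test_missing_protein_record_dropped_and_counted(self):
        lip, ctrl = _tables({"100K": [100.0, 100.0]}, {"100K": [50.0]})
        ratios = correct_by_protein(lip, ctrl)
        assert len(ratios) == 1
        assert ratios.attrs["n_unmatched"] == 1

    def test_zero_noise_planted_marker_is_only_changing_peptide(
        self, proteome, annotations
    ):
        truth = simulate.default_truth(
            proteome, annotations, n_markers=1, cv_peptide=0.0, cv_protein=0.0, seed=21
        )
        lip, ctrl = simulate.simulate_flip_experiment(truth, proteome, annotations)
        ratios = correct_by_protein(lip, ctrl)
        spread = ratios.groupby("peptide_id")["ratio"].agg(lambda x: x.max() / x.min())
        changing = set(spread[spread > 1 + 1e-9].index)
        assert changing == truth.marker_peptides(annotations)


class TestPropagatedAnova:
    def test_null_fixed_point(self):
        # identical ratios in every group: no between- or within-group signal.
        # Holds for the calibrated (textbook) mean squares; the printed form's
        # grand term is not the grand mean whenever replicates exist, so its
        # null value is nonzero by construction.
        lip, ctrl = _tables(
            {"100K": [10.0] * 3, "10K": [10.0] * 3},
            {"100K": [5.0] * 3, "10K": [5.0] * 3},
        )
        res = PeptideAnova(lip, ctrl, variant="textbook").fit(pairwise=False)
        row = res.table.iloc[0]
        assert row["ms_between"] == 0.0
        assert row["F"] == 0.0
        assert row["p"] == 1.0

    @pytest.mark.parametrize("variant", ["as_printed", "textbook"])
    def test_matches_transcription_oracle(self, variant):
        pep = {"100K": [100.0, 110.0, 90.0, 100.0], "10K": [200.0, 190.0, 210.0, 200.0]}
        prot = {"100K": [1.0, 1.01, 0.99, 1.0], "10K": [1.02, 0.98, 1.0, 1.0]}
        expected = propagated_anova_oracle(pep, prot, variant)
        lip, ctrl = _tables(pep, prot)
        res = PeptideAnova(lip, ctrl, variant=variant).fit(pairwise=False)
        row = res.table.iloc[0]
        for key in ("ms_between", "ms_within", "F", "p"):
            assert row[key] == pytest.approx(expected[key], rel=1e-10)

    def test_textbook_equals_classic_anova_when_protein_constant(self):
        rng = np.random.default_rng(0)
        pep = {g: list(rng.normal(100, 10, 4)) for g in ("100K", "50K", "10K")}
        lip, ctrl = _tables(pep, {g: [1.0, 1.0, 1.0, 1.0] for g in pep})
        res = PeptideAnova(lip, ctrl, variant="textbook").fit(pairwise=False)
        f_ref, p_ref = stats.f_oneway(*pep.values())
        row = res.table.iloc[0]
        assert row["F"] == pytest.approx(f_ref, rel=1e-9)
        assert row["p"] == pytest.approx(p_ref, rel=1e-9)

    def test_degenerate_between_without_within(self):
        lip, ctrl = _tables(
            {"100K": [10.0] * 3, "10K": [20.0] * 3},
            {"100K": [5.0] * 3, "10K": [5.0] * 3},
        )
        res = PeptideAnova(lip, ctrl).fit(pairwise=False)
        row = res.table.iloc[0]
        assert row["p"] == 0.0
        assert row["degenerate"]

    def test_max_abs_log2fc_over_group_pairs(self):
        lip, ctrl = _tables(
            {"100K": [100.0] * 3, "50K": [150.0] * 3, "10K": [400.0] * 3},
            {g: [1.0] * 3 for g in ("100K", "50K", "10K")},
        )
        res = PeptideAnova(lip, ctrl).fit(pairwise=False)
        assert res.table.iloc[0]["max_abs_log2fc"] == pytest.approx(2.0)

    def test_as_printed_matches_oracle_on_simulation(self, experiment):
        lip, ctrl = experiment
        res = PeptideAnova(
            lip, ctrl, variant="as_printed", renormalize_ratios=False
        ).fit(pairwise=False)
        ratios = res.ratios
        checked = 0
        for pep in list(res.table.index)[:40]:
            sub = ratios[ratios["peptide_id"] == pep]
            protein = sub["protein_id"].iloc[0]
            pep_by_group, prot_by_group = {}, {}
            for g, v in sub.groupby("group"):
                pep_by_group[g] = v.sort_values("replicate")["intensity_pep"].tolist()
                ctrl_sub = ctrl[(ctrl["analyte_id"] == protein) & (ctrl["group"] == g)]
                prot_by_group[g] = ctrl_sub.sort_values("replicate")["intensity"].tolist()
            expected = propagated_anova_oracle(pep_by_group, prot_by_group, "as_printed")
            row = res.table.loc[pep]
            assert row["F"] == pytest.approx(expected["F"], rel=1e-10)
            assert row["p"] == pytest.approx(expected["p"], rel=1e-10, abs=1e-300)
            checked += 1
        assert checked == 40


class TestBH:
    def test_single_p(self):
        assert adjust_bh([0.04]).tolist() == [0.04]

    def test_properties_on_arbitrary_p_vectors(self):
        from hypothesis import given, settings
        from hypothesis import strategies as st

        @settings(derandomize=True, max_examples=100)
        @given(
            st.lists(st.floats(0.0, 1.0, allow_nan=False), min_size=1, max_size=40)
        )
        def check(p):
            q = adjust_bh(p)
            assert ((q >= np.asarray(p) - 1e-12) & (q <= 1.0 + 1e-12)).all()
            order = np.argsort(p)
            assert (np.diff(q[order]) >= -1e-12).all()

        check()

    def test_hand_computed(self):
        assert adjust_bh([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_all_ones(self):
        assert adjust_bh([1.0, 1.0, 1.0]).tolist() == [1.0, 1.0, 1.0]

    def test_never_decreases_p(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=200)
        q = adjust_bh(p)
        assert (q >= p - 1e-12).all()
        assert ((q >= 0) & (q <= 1)).all()

    def test_order_preserving(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(size=50)
        q = adjust_bh(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestPairwiseTukey:
    def _ratios(self, by_group, peptide="PEP"):
        rows = [
            (peptide, "P1", g, r, v, v, 1.0)
            for g in by_group
            for r, v in enumerate(by_group[g], start=1)
        ]
        return pd.DataFrame(
            rows,
            columns=["peptide_id", "protein_id", "group", "replicate", "ratio",
                     "intensity_pep", "intensity_prot"],
        )

    def test_identical_groups_null(self):
        rng = np.random.default_rng(1)
        vals = list(rng.normal(10, 1, 4))
        out = pairwise_tukey(self._ratios({"A": vals, "B": vals, "C": vals}))
        assert (out["p"] > 0.99).all()

    def test_two_groups_equals_pooled_t(self):
        rng = np.random.default_rng(2)
        a, b = list(rng.normal(10, 1, 4)), list(rng.normal(12, 1, 4))
        out = pairwise_tukey(self._ratios({"A": a, "B": b}))
        _, p_ref = stats.ttest_ind(a, b)
        assert out["p"].iloc[0] == pytest.approx(p_ref, rel=1e-7)

    def test_single_deviant_group(self):
        rng = np.random.default_rng(3)
        base = {g: list(rng.normal(10, 0.1, 4)) for g in ("B", "C")}
        base["A"] = list(rng.normal(20, 0.1, 4))
        out = pairwise_tukey(self._ratios(base))
        sig = {
            frozenset((r.group1, r.group2))
            for r in out[out["p_adj"] < 0.01].itertuples(index=False)
        }
        assert sig == {frozenset(("A", "B")), frozenset(("A", "C"))}

    def test_studentized_range_tail_matches_adaptive_quadrature(self):
        from flipms.diffstats import studentized_range_sf

        q = np.array([0.5, 1.0, 2.0, 3.0, 4.5, 6.0, 8.0])
        for k, df in ((2, 6), (3, 9), (4, 12), (4, 4)):
            mine = studentized_range_sf(q, k, df)
            ref = stats.studentized_range.sf(q, k, df)
            assert np.abs(mine - ref).max() < 1e-9

    def test_matches_scipy_tukey_hsd_oracle(self):
        rng = np.random.default_rng(8)
        by_group = {
            "A": list(rng.normal(10, 1, 4)),
            "B": list(rng.normal(11, 1, 3)),
            "C": list(rng.normal(10.5, 1, 4)),
        }
        out = pairwise_tukey(self._ratios(by_group)).set_index(["group1", "group2"])
        ref = stats.tukey_hsd(*by_group.values())
        for (i, gi) in enumerate(by_group):
            for (j, gj) in enumerate(by_group):
                if i < j:
                    assert out.loc[(gi, gj), "p"] == pytest.approx(
                        ref.pvalue[i, j], rel=1e-6, abs=1e-9
                    )

    def test_pair_with_single_replicate_omitted(self):
        out = pairwise_tukey(
            self._ratios({"A": [1.0, 1.1, 0.9], "B": [2.0], "C": [1.0, 1.2, 1.1]})
        )
        groups = set(out["group1"]) | set(out["group2"])
        assert "B" not in groups


class TestGroupToParent:
    ANN = pd.DataFrame(
        {
            "peptide_id": ["GGSTKLLK", "GSTKLLK", "AAAAK"],
            "protein_id": ["P1", "P1", "P1"],
            "sequence": ["GGSTKLLK", "GSTKLLK", "AAAAK"],
            "start": [10, 11, 30],
            "end": [17, 17, 34],
            "tryptic_type": ["fully_tryptic", "semi_tryptic", "fully_tryptic"],
        }
    )

    def _table(self, peptides, qs):
        return pd.DataFrame(
            {"peptide_id": peptides, "protein_id": "P1", "q": qs, "skipped": False}
        )

    def test_nested_semi_tryptic_merged_with_median_q(self):
        regions = group_to_parent(
            self._table(["GGSTKLLK", "GSTKLLK"], [0.01, 0.03]), self.ANN
        )
        assert len(regions) == 1
        row = regions.iloc[0]
        assert (row["start"], row["end"]) == (10, 17)
        assert row["q_median"] == pytest.approx(0.02)

    def test_singleton_region(self):
        regions = group_to_parent(self._table(["AAAAK"], [0.2]), self.ANN)
        assert len(regions) == 1
        assert regions.iloc[0]["n_peptides"] == 1

    def test_two_parents_two_regions(self):
        regions = group_to_parent(
            self._table(["GGSTKLLK", "AAAAK"], [0.01, 0.2]), self.ANN
        )
        assert len(regions) == 2

    def test_orphan_semi_tryptic_flagged(self):
        regions = group_to_parent(self._table(["GSTKLLK"], [0.05]), self.ANN)
        assert regions.iloc[0]["no_parent"]

    def test_regions_never_overlap_within_protein(self, experiment, annotations):
        lip, ctrl = experiment
        res = PeptideAnova(lip, ctrl, annotations=annotations).fit(pairwise=False)
        for _, sub in res.regions.groupby("protein_id"):
            iv = sorted(zip(sub["start"], sub["end"]))
            for (s1, e1), (s2, e2) in zip(iv, iv[1:]):
                assert e1 < s2


class TestProteinAbundanceAnova:
    def test_two_group_signed_log2fc(self):
        rows = [
            ("P1", "P1", "ctrl", r, 100.0 * (1 + 0.01 * r), "tryptic_control")
            for r in range(1, 5)
        ] + [
            ("P1", "P1", "HU", r, 200.0 * (1 + 0.01 * r), "tryptic_control")
            for r in range(1, 5)
        ]
        cols = ["analyte_id", "protein_id", "group", "replicate", "intensity", "sample_type"]
        out = protein_abundance_anova(
            pd.DataFrame(rows, columns=cols), reference_group="ctrl"
        )
        assert out.iloc[0]["log2fc"] == pytest.approx(1.0, abs=0.01)
        assert out.iloc[0]["q"] < 0.05
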