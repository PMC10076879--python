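"""Integration: DM-DE join, region correlation, quadrants, candidate tables."""

import numpy as np
import pandas as pd
import pytest

from methexpress.annotation import ProbeRecord, manifest_from_records
from methexpress.integration import (
    assign_quadrant,
    classify_dmgs,
    direction_counts,
    filter_reported,
    join_dm_de,
    rank_candidates,
    region_correlation,
)


def records_from_fixtures(hyper_down, hypo_up):
    """Recast the shipped candidate tables as integrated records."""
    both = pd.concat([hyper_down, hypo_up], ignore_index=True)
    return pd.DataFrame({
        "gene": both["Gene"],
        "probe_id": both["Probe_ID"],
        "beta_case_avg": both["beta_case_avg"],
        "beta_control_avg": both["beta_control_avg"],
        "delta_beta": both["delta_beta"],
        "abs_delta_beta": both["abs_delta_beta"],
        "dm_p": 0.01,
        "direction": np.where(both["delta_beta"] > 0, "hyper", "hypo"),
        "region_group": "Promoter",
        "island_relation": both["RELATION_TO_CPG_ISLAND"].replace("", "OpenSea"),
        "promoter_related": True,
        "log2fc": both["log2FoldChange"],
        "padj": both["padj"],
        "quadrant": [
            assign_quadrant(d, l)
            for d, l in zip(both["delta_beta"], both["log2FoldChange"])
        ],
    })


def _dml_row(probe, delta, p, direction=None):
    return {
        "probe_id": probe,
        "beta_case_avg": 0.5 + delta / 2,
        "beta_control_avg": 0.5 - delta / 2,
        "delta_beta": delta,
        "abs_delta_beta": abs(delta),
        "p_value": p,
        "fdr": p,
        "direction": direction or ("hyper" if delta >= 0 else "hypo"),
        "significant": True,
    }


@pytest.fixture()
def toy_manifest():
    records = [
        ProbeRecord("cg00000001", "chr1", 1000, "+", [("GENEA", "TSS200")], "Island"),
        ProbeRecord("cg00000002", "chr1", 2000, "+", [("GENEA", "TSS1500")], "N_Shore"),
        ProbeRecord("cg00000003", "chr1", 9000, "+", [("GENEA", "Body")], "OpenSea"),
        ProbeRecord("cg00000004", "chr2", 5000, "-", [("GENEB", "Body")], "OpenSea"),
        ProbeRecord("cg00000005", "chr2", 100, "+", [], "OpenSea"),
        ProbeRecord("cg00000006", "chr3", 700, "+", [("GENEC", "5UTR")], "S_Shelf"),
    ]
    return manifest_from_records(records)


@pytest.fixture()
def toy_de():
    return pd.DataFrame({
        "gene": ["GENEA", "GENEB"],
        "log2fc": [-2.0, 1.5],
        "padj": [0.001, 0.02],
    })


class TestAssignQuadrant:
    @pytest.mark.parametrize(
        "delta,lfc,expected",
        [
            (0.362096786, -4.7201206, "part4"),  # hypermethylated, downregulated
            (-0.531148922, 2.95333954, "part1"),  # hypomethylated, upregulated
            (0.3, 2.0, "part2"),
            (-0.3, -2.0, "part3"),
            (0.0, 2.0, "boundary"),
            (0.3, 0.0, "boundary"),
        ],
    )
    def test_quadrant_convention(self, delta, lfc, expected):
        assert assign_quadrant(delta, lfc) == expected

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            assign_quadrant(float("nan"), 1.0)

    def test_odd_under_joint_sign_flip(self, rng):
        pair = {"part1": "part4", "part4": "part1", "part2": "part3",
                "part3": "part2", "boundary": "boundary"}
        for _ in range(200):
            d, l = rng.normal(), rng.normal()
            assert assign_quadrant(-d, -l) == pair[assign_quadrant(d, l)]


class TestJoinDmDe:
    def test_max_abs_delta_locus_represents_gene(self, toy_manifest, toy_de):
        dml = pd.DataFrame([
            _dml_row("cg00000001", 0.25, 0.01),
            _dml_row("cg00000002", 0.40, 0.02),
        ])
        rec = join_dm_de(dml, toy_manifest, toy_de)
        assert len(rec) == 1
        assert rec.loc[0, "probe_id"] == "cg00000002"
        assert rec.loc[0, "delta_beta"] == pytest.approx(0.40)
        assert rec.loc[0, "promoter_related"]
        assert rec.loc[0, "quadrant"] == "part4"

    def test_tie_broken_by_lower_p_then_probe_id(self, toy_manifest, toy_de):
        dml = pd.DataFrame([
            _dml_row("cg00000001", 0.30, 0.02),
            _dml_row("cg00000002", 0.30, 0.01),
        ])
        rec = join_dm_de(dml, toy_manifest, toy_de)
        assert rec.loc[0, "probe_id"] == "cg00000002"

    def test_gene_without_expression_dropped_and_counted(self, toy_manifest, toy_de):
        dml = pd.DataFrame([
            _dml_row("cg00000004", 0.30, 0.01),
            _dml_row("cg00000006", 0.30, 0.01),  # GENEC not in DE table
        ])
        rec = join_dm_de(dml, toy_manifest, toy_de)
        assert list(rec["gene"]) == ["GENEB"]
        assert rec.attrs["dropped_no_expression"] == 1

    def test_enhancer_flag_for_non_promoter_locus(self, toy_manifest, toy_de):
        dml = pd.DataFrame([_dml_row("cg00000003", 0.30, 0.01)])
        rec = join_dm_de(dml, toy_manifest, toy_de)
        assert not rec.loc[0, "promoter_related"]
        assert rec.loc[0, "region_group"] == "GeneBody"

    def test_empty_dml_warns(self, toy_manifest, toy_de):
        with pytest.warns(UserWarning):
            rec = join_dm_de(pd.DataFrame(columns=["probe_id"]), toy_manifest, toy_de)
        assert rec.empty

    def test_hyper_and_hypo_loci_yield_separate_records(self, toy_manifest, toy_de):
        dml = pd.DataFrame([
            _dml_row("cg00000001", 0.30, 0.01),
            _dml_row("cg00000003", -0.35, 0.01),
        ])
        rec = join_dm_de(dml, toy_manifest, toy_de)
        assert len(rec) == 2
        assert set(rec["direction"]) == {"hyper", "hypo"}


class TestRegionCorrelation:
    def test_collinear_records_give_minus_one(self):
        rec = pd.DataFrame({
            "region_group": "Promoter",
            "delta_beta": [0.1, 0.2, 0.3],
            "log2fc": [-1.0, -2.0, -3.0],
        })
        out = region_correlation(rec).set_index("region_group")
        assert out.loc["Promoter", "pearson_r"] == pytest.approx(-1.0)
        assert out.loc["Promoter", "n_genes"] == 3

    def test_small_groups_undefined(self):
        rec = pd.DataFrame({
            "region_group": ["5UTR", "5UTR"],
            "delta_beta": [0.1, 0.2],
            "log2fc": [1.0, -1.0],
        })
        out = region_correlation(rec).set_index("region_group")
        assert np.isnan(out.loc["5UTR", "pearson_r"])
        assert out.loc["5UTR", "flag"] == "n<3"

    def test_planted_coupling_recovered(self, small_bundle):
        """With full negative promoter coupling, Promoter-group r < 0, p < 0.05."""
        from methexpress.expression import nb_wald_test
        from methexpress.methylation import call_dml, significant_dml

        b = small_bundle
        dml = call_dml(b["beta"], b["samples"])
        de = nb_wald_test(b["counts"], b["samples"])
        rec = join_dm_de(significant_dml(dml), b["manifest"], de)
        out = region_correlation(rec).set_index("region_group")
        assert out.loc["Promoter", "pearson_r"] < 0
        assert out.loc["Promoter", "p_value"] < 0.05


class TestClassifyDmgs:
    def test_reference_percentage_rounding(self):
        # 235 promoter records, 113 in part4 -> 48.1% (round-half-even of 48.0851)
        rec = pd.DataFrame({
            "promoter_related": [True] * 235,
            "quadrant": ["part4"] * 113 + ["part1"] * 122,
            "log2fc": [-1.0] * 113 + [1.0] * 122,
        })
        out = classify_dmgs(rec)
        row = out[(out["partition"] == "promoter_related")
                  & (out["quadrant"] == "part4")].iloc[0]
        assert row["count"] == 113
        assert row["total"] == 235
        assert row["percent"] == pytest.approx(48.1)

    def test_single_quadrant_gets_everything(self):
        rec = pd.DataFrame({
            "promoter_related": [False] * 4,
            "quadrant": ["part2"] * 4,
            "log2fc": [1.0] * 4,
        })
        out = classify_dmgs(rec)
        row = out[(out["partition"] == "enhancer_related")
                  & (out["quadrant"] == "part2")].iloc[0]
        assert row["percent"] == 100.0

    def test_counts_conserved(self, small_bundle, rng):
        n = 200
        rec = pd.DataFrame({
            "promoter_related": rng.random(n) < 0.4,
            "quadrant": rng.choice(
                ["part1", "part2", "part3", "part4", "boundary"], size=n
            ),
            "log2fc": rng.normal(size=n),
        })
        out = classify_dmgs(rec)
        for partition, sub in out.groupby("partition"):
            assert sub["count"].sum() == sub["total"].iloc[0]
        dc = direction_counts(rec)
        assert set(dc["partition"]) == {"promoter_related", "enhancer_related"}


class TestRankCandidates:
    def test_fixture_order_reproduced(self, fixture_tables):
        """Re-ranking the shipped hyper-down table by |Δβ| returns its printed order."""
        hyper_down, hypo_up = fixture_tables
        rec = records_from_fixtures(hyper_down, hypo_up)
        table_a, table_b = rank_candidates(rec, k=15)
        assert list(table_a["Gene"]) == list(hyper_down["Gene"])
        assert list(table_a["Probe_ID"]) == list(hyper_down["Probe_ID"])
        assert list(table_b["Gene"]) == list(hypo_up["Gene"])

    def test_k1_is_top_hypo_up_row(self, fixture_tables):
        rec = records_from_fixtures(*fixture_tables)
        _, table_b = rank_candidates(rec, k=1)
        assert list(table_b["Gene"]) == ["CASS4"]
        assert table_b["beta_change"].iloc[0] == pytest.approx(0.58500842, abs=5e-9)

    def test_expression_gates_applied(self, fixture_tables):
        rec = records_from_fixtures(*fixture_tables)
        rec.loc[rec["gene"] == "TWIST2", "padj"] = 0.2
        rec.loc[rec["gene"] == "GREM2", "log2fc"] = -0.5
        table_a, _ = rank_candidates(rec, k=15)
        assert "TWIST2" not in set(table_a["Gene"])
        assert "GREM2" not in set(table_a["Gene"])
        assert len(table_a) == 13

    def test_empty_input_gives_empty_tables(self):
        table_a, table_b = rank_candidates(pd.DataFrame())
        assert table_a.empty and table_b.empty


class TestFilterReported:
    def test_empty_exclusion_keeps_table(self, fixture_tables):
        hyper_down, _ = fixture_tables
        out = filter_reported(hyper_down, [])
        pd.testing.assert_frame_equal(out, hyper_down.reset_index(drop=True))

    def test_full_exclusion_empties_table(self, fixture_tables):
        hyper_down, _ = fixture_tables
        out = filter_reported(hyper_down, list(hyper_down["Gene"]))
        assert out.empty
        assert out.attrs["removed"] == sorted(hyper_down["Gene"])

    def test_thirty_row_narrowed_to_ten(self, fixture_tables):
        """A 20-symbol exclusion list keeps 10 of the 30 combined rows."""
        hyper_down, hypo_up = fixture_tables
        combined = pd.concat([hyper_down, hypo_up], ignore_index=True)
        keep = {"TMEM184A", "GREM2", "SFN", "KIR3DX1", "HPGD", "ESR1",
                "CASS4", "BST2", "PIK3CG", "RNASE1"}
        exclusion = [g for g in combined["Gene"] if g not in keep]
        assert len(exclusion) == 20
        out = filter_reported(combined, exclusion)
        assert len(out) == 10
        assert set(out["Gene"]) == keep
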