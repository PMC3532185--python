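import math

import numpy as np
import pandas as pd
import pytest

from seedscape import id_tables
from seedscape.id_tables import (
    MATCH_TYPES,
    MERGED_COLUMNS,
    ReplicateSet,
    apply_min_repeat,
    classify_function,
    dynamic_range_logs,
    keyword_tsp_share,
    match_type_summary,
    merge_replicates,
    per_protein_distributions,
    percent_tsp,
    ppm_fraction_within,
    read_protein_table,
    repeat_rate_summary,
    write_merged_table,
)
from seedscape.synthetic_data import (
    SyntheticDbParams,
    SyntheticRunParams,
    generate_database,
    generate_replicates,
)


def rep_table(rows):
    return pd.DataFrame(
        rows,
        columns=["uniprot_code", "description", "protein_mw", "score", "products",
                 "peptides", "fmol", "ng"],
    )


def four_replicates(pattern: dict[str, list[int]], ng: float = 10.0) -> ReplicateSet:
    """Build a 4-replicate set where each protein appears in the listed replicates."""
    tables = {}
    for rep in range(1, 5):
        rows = [
            (code, f"desc {code}", 1000.0, 50.0, 10.0, 5.0, ng, ng)
            for code, reps in pattern.items() if rep in reps
        ]
        tables[rep] = rep_table(rows)
    return ReplicateSet(protein_tables=tables)


class TestReadProteinTable:
    def test_reference_fixture_loads_113_rows(self, reference_table):
        assert len(reference_table.df) == 113
        assert list(reference_table.df.columns) == MERGED_COLUMNS
        assert reference_table.df["uniprot_code"].iloc[0] == "P04776"
        assert reference_table.df["uniprot_code"].is_unique

    def test_header_only_file(self, tmp_path, caplog):
        path = tmp_path / "empty.tsv"
        path.write_text("uniprot_code\tdescription\tscore\tpeptides\tng\n")
        table = read_protein_table(path)
        assert table.empty

    def test_missing_mandatory_column(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("uniprot_code\tdescription\tscore\tpeptides\nA\tx\t1\t2\n")
        with pytest.raises(ValueError, match="ng"):
            read_protein_table(path)

    def test_non_numeric_cell_reports_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "uniprot_code\tdescription\tscore\tpeptides\tng\n"
            "A\tx\t1.0\t2\t3.0\n"
            "B\ty\toops\t2\t3.0\n"
        )
        with pytest.raises(ValueError, match="line 3"):
            read_protein_table(path)

    def test_comma_delimited_autodetected(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("uniprot_code,description,score,peptides,ng\nA,x,1,2,3\n")
        table = read_protein_table(path)
        assert table["ng"].iloc[0] == 3.0

    def test_blank_ng_is_absent_not_zero(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text(
            "uniprot_code\tdescription\tscore\tpeptides\tng\nA\tx\t1\t2\t\n"
        )
        assert read_protein_table(path)["ng"].isna().all()

    def test_synthetic_row_counts_match_generator(self, tmp_path):
        db, _ = generate_database(SyntheticDbParams(n_proteins=30, seed=2))
        reps, _, manifest = generate_replicates(
            db, SyntheticRunParams(n_true_proteins=30, n_peptides=500, seed=2)
        )
        for rep_id, table in reps.protein_tables.items():
            expected = sum(1 for detected in manifest["detections"].values()
                           if rep_id in detected)
            path = tmp_path / f"r{rep_id}.tsv"
            table.to_csv(path, sep="\t", index=False)
            assert len(read_protein_table(path)) == expected


class TestMergeReplicates:
    def test_constant_replicates(self):
        reps = four_replicates({"P1": [1, 2, 3, 4]}, ng=10.0)
        merged = merge_replicates(reps, min_repeat=2)
        row = merged.df.iloc[0]
        assert row["repeat_rate"] == 4
        assert row["ng_avg"] == pytest.approx(10.0)
        assert row["fmol_variation"] == pytest.approx(0.0)

    def test_min_repeat_filter_drops_singletons(self):
        reps = four_replicates({"P1": [1, 2, 3, 4], "P2": [3]})
        merged = merge_replicates(reps, min_repeat=2)
        assert merged.df["uniprot_code"].tolist() == ["P1"]

    def test_single_observation_has_blank_cv(self):
        reps = four_replicates({"P2": [3]})
        merged = merge_replicates(reps, min_repeat=1)
        assert math.isnan(merged.df["fmol_variation"].iloc[0])

    def test_planted_repeat_rates_recovered(self):
        pattern = {"A": [1, 2, 3, 4], "B": [1, 2], "C": [2, 3, 4], "D": [1, 2, 3, 4]}
        merged = merge_replicates(four_replicates(pattern), min_repeat=2)
        got = dict(zip(merged.df["uniprot_code"], merged.df["repeat_rate"]))
        assert got == {"A": 4, "B": 2, "C": 3, "D": 4}

    def test_permutation_invariant_in_replicate_order(self):
        pattern = {"A": [1, 2, 3, 4], "B": [2, 4]}
        reps = four_replicates(pattern)
        reordered = ReplicateSet(protein_tables={
            1: reps.protein_tables[4], 2: reps.protein_tables[2],
            3: reps.protein_tables[3], 4: reps.protein_tables[1],
        })
        a = merge_replicates(reps, 2).df
        b = merge_replicates(reordered, 2).df
        pd.testing.assert_frame_equal(a, b)

    def test_raising_min_repeat_monotone(self):
        pattern = {"A": [1, 2, 3, 4], "B": [1, 2], "C": [1, 2, 3]}
        reps = four_replicates(pattern)
        rows = [set(merge_replicates(reps, k).df["uniprot_code"]) for k in (1, 2, 3, 4)]
        for smaller, larger in zip(rows[1:], rows):
            assert smaller <= larger

    def test_min_repeat_out_of_range(self):
        reps = four_replicates({"A": [1]})
        with pytest.raises(ValueError):
            merge_replicates(reps, min_repeat=5)
        with pytest.raises(ValueError):
            merge_replicates(reps, min_repeat=0)

    def test_sorted_by_ng_descending(self):
        tables = {
            1: rep_table([("LOW", "d", 1, 1, 1, 1, 1.0, 1.0),
                          ("HIGH", "d", 1, 1, 1, 1, 9.0, 9.0)]),
            2: rep_table([("LOW", "d", 1, 1, 1, 1, 1.0, 1.0),
                          ("HIGH", "d", 1, 1, 1, 1, 9.0, 9.0)]),
        }
        merged = merge_replicates(ReplicateSet(protein_tables=tables), 2)
        assert merged.df["uniprot_code"].tolist() == ["HIGH", "LOW"]


class TestPercentTsp:
    def test_reference_row_p04776(self, reference_table):
        df = percent_tsp(reference_table.df)
        assert df.loc[df["uniprot_code"] == "P04776", "pct_tsp"].iloc[0] == 17.68

    def test_reference_matches_printed_column_everywhere(self, reference_table):
        printed = reference_table.df["pct_tsp"]
        recomputed = percent_tsp(reference_table.df)["pct_tsp"]
        assert (recomputed - printed).abs().max() <= 0.01 + 1e-9

    def test_unrounded_shares_sum_to_100(self, reference_table):
        df = percent_tsp(reference_table.df)
        assert df["pct_tsp_exact"].sum() == pytest.approx(100.0, abs=1e-9)

    def test_single_row(self):
        df = pd.DataFrame({"ng_avg": [5.0]})
        assert percent_tsp(df)["pct_tsp"].iloc[0] == 100.0

    def test_three_to_one(self):
        df = pd.DataFrame({"ng_avg": [3.0, 1.0]})
        assert percent_tsp(df)["pct_tsp"].tolist() == [75.0, 25.0]

    def test_absent_ng_kept_blank(self):
        df = pd.DataFrame({"ng_avg": [3.0, None, 1.0]})
        out = percent_tsp(df)
        assert math.isnan(out["pct_tsp"].iloc[1])
        assert out["pct_tsp"].iloc[0] == 75.0

    def test_all_absent_error(self):
        with pytest.raises(ValueError):
            percent_tsp(pd.DataFrame({"ng_avg": [None, None]}))


class TestRepeatRateSummary:
    def test_reference_rate_four(self, reference_table):
        counts, percents = repeat_rate_summary(reference_table.df)
        assert counts[4] == 98
        assert sum(counts.values()) == 113
        assert percents[4] == 87

    def test_all_rate_four(self):
        df = pd.DataFrame({"repeat_rate": [4, 4, 4]})
        counts, percents = repeat_rate_summary(df)
        assert percents == {4: 100}

    def test_planted_rates(self):
        merged = merge_replicates(
            four_replicates({"A": [1, 2, 3, 4], "B": [1, 3], "C": [1, 2, 4]}), 2
        )
        counts, _ = repeat_rate_summary(merged.df)
        assert counts == {2: 1, 3: 1, 4: 1}

    def test_empty_error(self):
        with pytest.raises(ValueError):
            repeat_rate_summary(pd.DataFrame({"repeat_rate": []}))


class TestDynamicRange:
    def test_reference_three_decades(self, reference_table):
        decades, ratio = dynamic_range_logs(reference_table.df)
        assert decades == 3
        assert ratio == pytest.approx(85.28 / 0.04)

    def test_degenerate_equal(self):
        df = pd.DataFrame({"ng_avg": [5.0, 5.0]})
        assert dynamic_range_logs(df)[0] == 0

    def test_three_decades_exact(self):
        df = pd.DataFrame({"ng_avg": [1.0, 10.0, 1000.0]})
        assert dynamic_range_logs(df)[0] == 3

    def test_zero_rows_excluded_from_min(self):
        df = pd.DataFrame({"ng_avg": [0.0, 1.0, 100.0]})
        assert dynamic_range_logs(df)[0] == 2

    def test_no_positive_error(self):
        with pytest.raises(ValueError):
            dynamic_range_logs(pd.DataFrame({"ng_avg": [0.0, None]}))


class TestKeywordShare:
    def test_reference_glycinin_share(self, reference_table):
        df = percent_tsp(reference_table.df)
        share, matched = keyword_tsp_share(df, "glycinin")
        assert share == 78
        assert len(matched) == 41  # 'conglycinin' matches as a substring

    def test_no_match(self, reference_table):
        df = percent_tsp(reference_table.df)
        share, matched = keyword_tsp_share(df, "zebrafish")
        assert share == 0 and matched.empty

    def test_empty_pattern_matches_all(self, reference_table):
        df = percent_tsp(reference_table.df)
        share, matched = keyword_tsp_share(df, "")
        assert len(matched) == 113
        assert abs(share - 100) <= 1  # rounding slack only

    def test_complement_partition(self, reference_table):
        df = percent_tsp(reference_table.df)
        mask = df["description"].str.contains("glycinin", case=False, regex=False)
        total = df["pct_tsp"].sum()
        assert df.loc[mask, "pct_tsp"].sum() + df.loc[~mask, "pct_tsp"].sum() == \
            pytest.approx(total)

    def test_requires_pct_tsp(self):
        with pytest.raises(ValueError):
            keyword_tsp_share(pd.DataFrame({"description": ["x"]}), "x")


class TestClassifyFunction:
    def test_inhibitor_rule(self):
        df = pd.DataFrame({"description": ["Kunitz trypsin inhibitor OS Glycine max"]})
        summary = classify_function(df, ruleset=[("inhibitor", "defense")])
        assert summary.assignments.iloc[0] == "defense"

    def test_empty_ruleset_error(self):
        with pytest.raises(ValueError):
            classify_function(pd.DataFrame({"description": ["x"]}), ruleset=[])

    def test_first_match_wins_and_default(self):
        df = pd.DataFrame({"description": ["glycinin inhibitor", "mystery protein"]})
        summary = classify_function(
            df, ruleset=[("glycinin", "storage"), ("inhibitor", "defense")]
        )
        assert summary.assignments.tolist() == ["storage", "uncharacterized/other"]

    def test_known_mix_recovered(self):
        rng = np.random.default_rng(7)
        mix = {"storage": 0.5, "defense/inhibitor": 0.3, "energy": 0.2}
        keywords = {"storage": "glycinin", "defense/inhibitor": "inhibitor",
                    "energy": "amylase"}
        cats = rng.choice(list(mix), p=list(mix.values()), size=400)
        df = pd.DataFrame({"description": [f"protein with {keywords[c]}" for c in cats]})
        summary = classify_function(df)
        for cat, frac in mix.items():
            expected = round(100.0 * (cats == cat).mean())
            assert summary.share_by_rows[cat] == pytest.approx(expected, abs=1)


class TestPeptideHitSummaries:
    def test_all_one_type(self):
        hits = pd.DataFrame({"match_type": ["PepFrag1"] * 4, "ppm_error": [0.0] * 4,
                             "parent_code": ["A"] * 4})
        summary = match_type_summary(hits)
        assert summary["PepFrag1"] == 100
        assert sum(summary.values()) == 100

    def test_unknown_type_is_error(self):
        hits = pd.DataFrame({"match_type": ["Mystery"], "ppm_error": [0.0]})
        with pytest.raises(ValueError, match="Mystery"):
            match_type_summary(hits)

    def test_ppm_boundary_strict(self):
        hits = pd.DataFrame({"match_type": ["PepFrag1", "PepFrag1"],
                             "ppm_error": [4.9, 5.1]})
        assert ppm_fraction_within(hits, 5.0) == 0.5

    def test_synthetic_fractions_recovered(self):
        db, _ = generate_database(SyntheticDbParams(n_proteins=100, seed=17))
        params = SyntheticRunParams(n_true_proteins=100, n_peptides=3400, seed=17)
        _, hits, manifest = generate_replicates(db, params)
        n = len(hits)
        summary = match_type_summary(hits)
        se_13 = math.sqrt(0.13 * 0.87 / n)
        assert abs(summary["InSource"] / 100.0 - 0.13) < 3 * se_13
        se_82 = math.sqrt(0.82 * 0.18 / n)
        assert abs(ppm_fraction_within(hits, 5.0) - 0.82) < 3 * se_82

    def test_per_protein_distributions(self):
        hits = pd.DataFrame({
            "match_type": ["PepFrag1"] * 6,
            "ppm_error": [0.0] * 6,
            "parent_code": ["A", "A", "A", "B", "B", "C"],
        })
        result = per_protein_distributions(hits, coverage={"A": 55.0, "B": 20.0})
        assert result["peptides_per_protein"].n_included == 3
        assert result["coverage"].n_included == 2

    def test_empty_hits_error(self):
        empty = pd.DataFrame({"match_type": [], "ppm_error": [], "parent_code": []})
        with pytest.raises(ValueError):
            match_type_summary(empty)
        with pytest.raises(ValueError):
            ppm_fraction_within(empty)


class TestApplyMinRepeatAndIo:
    def test_reference_min_repeat_2_keeps_all(self, reference_table):
        assert len(apply_min_repeat(reference_table.df, 2)) == 113
        assert len(apply_min_repeat(reference_table.df, 4)) == 98

    def test_write_round_trip(self, tmp_path, reference_table):
        path = tmp_path / "merged.tsv"
        write_merged_table(reference_table, path)
        back = read_protein_table(path, merged=True)
        assert len(back) == 113
        assert back["ng_avg"].equals(reference_table.df["ng_avg"])
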