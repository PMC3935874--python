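import numpy as np
import pandas as pd
import pytest

from miratlas import datasets
from miratlas.audit import (
    chi_square_2x2,
    dedupe_and_count,
    normalization_quality,
    read_study_grid,
    replication_stats,
    tally_categories,
    welch_t,
    write_study_grid,
)
from miratlas.plausibility import BiomarkerReport


def calls_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["study_id", "disease", "compartment", "mirna_name",
                 "accession", "direction", "category"],
    )


def test_dedupe_counts_one_mirna_across_two_diseases():
    calls = calls_frame([
        ("S1", "dA", "serum", "m1", "ACC1", "up", "likely"),
        ("S2", "dA", "serum", "m1", "ACC1", "up", "likely"),
        ("S3", "dB", "serum", "m1", "ACC1", "up", "likely"),
    ])
    s = dedupe_and_count(calls)
    assert s.unique_mirnas == 1
    assert s.per_mirna.loc["ACC1", "n_diseases"] == 2
    assert s.per_mirna.loc["ACC1", "n_studies"] == 3
    assert len(s.merged) == 2


def test_promiscuous_set_at_nine_diseases():
    rows = []
    for a in range(6):
        for d in range(9):
            rows.append((f"S{a}_{d}", f"d{d}", "serum", f"m{a}", f"ACC{a}",
                         "up", "ubiquitous"))
    rows.append(("S_x", "d0", "serum", "m9", "ACC9", "up", "likely"))
    s = dedupe_and_count(calls_frame(rows))
    assert s.promiscuous == frozenset(f"ACC{a}" for a in range(6))


def test_merged_conflict_keeps_most_favorable_category():
    calls = calls_frame([
        ("S1", "dA", "serum", "m1", "ACC1", "up", "questionable"),
        ("S2", "dA", "PBMC", "m1", "ACC1", "up", "likely"),
        ("S3", "dA", "serum", "m2", "ACC2", "up", "unknown"),
        ("S4", "dA", "serum", "m2", "ACC2", "up", "unlikely"),
    ])
    s = dedupe_and_count(calls)
    merged = s.merged.set_index("accession")["category"]
    assert merged["ACC1"] == "likely"
    assert merged["ACC2"] == "unlikely"


def test_audit_matches_brute_force_group_by_and_is_order_invariant():
    rng = np.random.default_rng(40)
    rows = []
    for i in range(300):
        rows.append((
            f"S{rng.integers(40)}", f"d{rng.integers(12)}", "serum",
            f"m{rng.integers(60)}", f"ACC{rng.integers(60):03d}", "up",
            ["likely", "questionable", "ubiquitous", "unlikely", "unknown"][
                rng.integers(5)
            ],
        ))
    calls = calls_frame(rows)
    s = dedupe_and_count(calls)
    df = calls
    assert s.unique_mirnas == df["accession"].nunique()
    for acc, sub in df.groupby("accession"):
        assert s.per_mirna.loc[acc, "n_studies"] == sub["study_id"].nunique()
        assert s.per_mirna.loc[acc, "n_diseases"] == sub["disease"].nunique()
    assert len(s.merged) == df.groupby(["accession", "disease"]).ngroups

    shuffled = calls.sample(frac=1, random_state=0).reset_index(drop=True)
    s2 = dedupe_and_count(shuffled)
    pd.testing.assert_frame_equal(s.per_mirna, s2.per_mirna)
    assert s.report_tallies.equals(s2.report_tallies)


def test_disease_synonyms_merge_similar_processes():
    calls = calls_frame([
        ("S1", "myocardial infarction", "serum", "m1", "ACC1", "up", "likely"),
        ("S2", "MI", "serum", "m1", "ACC1", "up", "likely"),
    ])
    s = dedupe_and_count(calls, disease_synonyms={"MI": "myocardial infarction"})
    assert len(s.merged) == 1
    assert s.replication_pooled["n_replicated"] == 1


def test_replication_concordant_and_discordant():
    base = [
        ("SA", "dA", "serum", "mX", "ACCX", "up", "likely"),
        ("SB", "dA", "serum", "mX", "ACCX", "up", "likely"),
    ]
    table, pooled = replication_stats(calls_frame(base))
    assert pooled == {"n_diseases": 1, "n_biomarkers": 1, "n_replicated": 1,
                      "n_opposite": 0}
    flipped = calls_frame(base[:1] + [("SB", "dA", "serum", "mX", "ACCX",
                                       "down", "likely")])
    _, pooled2 = replication_stats(flipped)
    assert pooled2["n_replicated"] == 0 and pooled2["n_opposite"] == 1


def test_single_study_diseases_are_skipped():
    calls = calls_frame([
        ("S1", "dLonely", "serum", "m1", "ACC1", "up", "likely"),
    ])
    table, pooled = replication_stats(calls)
    assert len(table) == 0 and pooled["n_biomarkers"] == 0


def test_mixed_direction_counts_as_discordant():
    calls = calls_frame([
        ("SA", "dA", "serum", "mX", "ACCX", "mixed", "likely"),
        ("SB", "dA", "serum", "mX", "ACCX", "up", "likely"),
    ])
    _, pooled = replication_stats(calls)
    assert pooled["n_opposite"] == 1


def test_tally_counts_and_percentages():
    t = tally_categories(
        ["likely", "questionable", "ubiquitous", "unlikely", "likely"]
    )
    assert t.loc["likely", "count"] == 2
    assert t.loc["likely", "percent"] == 40
    assert t.loc["unknown", "count"] == 0
    assert t["count"].sum() == t.attrs["denominator"]


def test_tally_matches_brute_force_and_percent_sums_to_100():
    rng = np.random.default_rng(41)
    cats = [["likely", "questionable", "ubiquitous", "unlikely", "unknown"][i]
            for i in rng.integers(0, 5, size=500)]
    t = tally_categories(cats)
    for c in set(cats):
        assert t.loc[c, "count"] == cats.count(c)
    assert abs(t["percent"].sum() - 100) <= 1


@pytest.mark.parametrize(
    "method,compartment,expected",
    [
        ("RNU6B", "serum", "poor"),
        ("RNU6B", "plasma", "poor"),
        ("RNU6B", "blood_NOS", "poor"),
        ("RNU6B", "PBMC", "acceptable"),
        ("cel-miR-39 spike-in", "plasma", "acceptable"),
        ("miR-16", "plasma", "acceptable"),
        ("miR-451a", "plasma", "poor"),
        ("", "serum", "poor"),
        ("not reported", "serum", "poor"),
        ("global mean normalization", "serum", "acceptable"),
    ],
)
def test_normalization_quality_rules(method, compartment, expected):
    rep = BiomarkerReport("S1", "dA", compartment, "miR-1", "up",
                          normalization_method=method)
    assert normalization_quality(rep) == expected


def test_normalization_quality_partitions_classifiable_reports():
    rng = np.random.default_rng(42)
    methods = ["RNU6B", "miR-16", "cel-miR-39 spike-in", "miR-451a", ""]
    comps = ["serum", "plasma", "PBMC", "blood_NOS"]
    for _ in range(50):
        rep = BiomarkerReport(
            "S", "d", comps[rng.integers(4)], "miR-1", "up",
            normalization_method=methods[rng.integers(5)],
        )
        assert normalization_quality(rep) in {"poor", "acceptable"}


def test_chi_square_homogeneous_table_is_zero():
    stat, p = chi_square_2x2([[10, 10], [10, 10]])
    assert stat == 0.0
    assert p == pytest.approx(1.0)


def test_chi_square_matches_hand_computation():
    # E = [[30,20],[30,20]]; sum (O-E)^2/E = 100/30+100/20+100/30+100/20
    stat, p = chi_square_2x2([[20, 30], [40, 10]])
    assert stat == pytest.approx(100 / 30 + 100 / 20 + 100 / 30 + 100 / 20)
    assert p < 0.001


def test_chi_square_monotone_in_association_strength():
    # the base table associates row 1 with column 2; pushing k more counts
    # onto that anti-diagonal strengthens the association
    stats_seq = [chi_square_2x2([[20 - k, 30 + k], [40 + k, 10 - k]])[0]
                 for k in range(0, 10, 3)]
    assert all(b >= a for a, b in zip(stats_seq, stats_seq[1:]))


def test_chi_square_rejects_zero_margin():
    with pytest.raises(ValueError):
        chi_square_2x2([[0, 0], [5, 5]])


def test_welch_identical_samples():
    t, p = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert t == 0.0 and p == pytest.approx(1.0)


def test_welch_matches_hand_computation():
    t, p = welch_t([1, 2, 3], [1, 2, 3, 4, 5])
    assert t == pytest.approx(-1.0954451150103324)
    assert p == pytest.approx(0.3161334219, abs=1e-6)


def test_welch_rejects_degenerate_samples():
    with pytest.raises(ValueError):
        welch_t([1.0], [1, 2, 3])
    with pytest.raises(ValueError):
        welch_t([2.0, 2.0], [1, 2, 3])


def test_study_grid_round_trip(tmp_path, study_grid):
    path = tmp_path / "grid.tsv"
    write_study_grid(study_grid, path)
    key = datasets.grid_nomenclature_key()
    back = read_study_grid(path, key)
    a = study_grid.sort_values(["study_id", "mirna_name"]).reset_index(drop=True)
    b = back.sort_values(["study_id", "mirna_name"]).reset_index(drop=True)
    pd.testing.assert_frame_equal(a, b[a.columns])
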