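"""Resight parsing, pair extraction, histories, and distance summaries."""

import io

import numpy as np
import pandas as pd
import pytest

from _oracles import summary_oracle
from philopatry.records import (
    RecordFormatError,
    assign_pupping_site,
    build_first_later_pairs,
    build_lag_pairs,
    build_pupping_history,
    extract_mother_pup_pairs,
    natal_beach_table,
    parse_resights,
    season_year_of,
    summarize_distances,
)
from philopatry.synthetic import SimConfig, simulate_resights


def _csv(text: str) -> io.StringIO:
    return io.StringIO(text.strip() + "\n")


def test_parse_wellformed_rows():
    records, rejects = parse_resights(_csv(
        """
seal_id,date,beach_code
S1,2010-01-05,NP
S2,2010-01-06,TSB
S3,2010-02-07,BBN
"""
    ))
    assert len(records) == 3 and len(rejects) == 0
    assert list(records["season_year"]) == [2010, 2010, 2010]


def test_parse_rejects_bad_rows_with_reasons():
    records, rejects = parse_resights(_csv(
        """
seal_id,date,beach_code
S1,not-a-date,NP
S2,2010-01-06,
,2010-01-07,NP
S4,2010-01-08,TSB
"""
    ))
    assert len(records) == 1
    assert sorted(rejects["reason"]) == ["missing beach code", "missing seal id",
                                         "unparseable date"]


def test_parse_missing_column_is_format_error():
    with pytest.raises(RecordFormatError, match="beach_code"):
        parse_resights(_csv("seal_id,date\nS1,2010-01-05"))


def test_parse_generator_output_has_zero_rejects():
    records_df, truth = simulate_resights(SimConfig(seed=11, n_females=120))
    parsed, rejects = parse_resights(records_df)
    assert len(rejects) == 0
    assert len(parsed) == len(records_df)
    assert len(parsed) > 500


def test_december_observations_roll_into_next_season():
    dates = pd.Series(["2009-12-28", "2010-01-03", "2010-11-30"])
    assert list(season_year_of(dates)) == [2010, 2010, 2010]
    assert list(season_year_of(dates, boundary_month=13)) == [2009, 2010, 2010]


def test_assign_pupping_site_first_beach_and_tie_rules():
    grp = pd.DataFrame(
        {"date": pd.to_datetime(["2010-01-20", "2010-01-05"]),
         "beach_code": ["TSB", "BBN"]}
    )
    assert assign_pupping_site(grp) == "BBN"
    # reversed row order with distinct dates: same answer
    assert assign_pupping_site(grp.iloc[::-1]) == "BBN"
    # same-date tie broken by input row order
    tie = pd.DataFrame(
        {"date": pd.to_datetime(["2010-01-05", "2010-01-05"]),
         "beach_code": ["NP", "TSB"]}
    )
    assert assign_pupping_site(tie) == "NP"
    with pytest.raises(ValueError):
        assign_pupping_site(tie.iloc[0:0])


def _records_frame(rows):
    df = pd.DataFrame(
        rows, columns=["seal_id", "date", "beach_code", "age", "mom_id"]
    )
    records, rejects = parse_resights(df.assign(pup_id=None, sex=None, season_year=None))
    assert len(rejects) == 0
    return records


def test_extraction_qualification_and_reason_codes(toy_colony, toy_matrix):
    rows = [
        # M1: natal A (age-0), pups in 2010 (pup P1 first seen at B)
        ("M1", "2001-01-10", "A", 0, None),
        ("P1", "2010-01-08", "B", 0, "M1"),
        ("P1", "2010-02-01", "C", 0, "M1"),
        # M2: immigrant, natal outside the colony
        ("M2", "2002-01-10", "ELSEWHERE", 0, None),
        ("P2", "2010-01-09", "C", 0, "M2"),
        # M3: natal unknown (no age-0 record)
        ("M3", "2004-02-10", "A", 3, None),
        ("P3", "2010-01-12", "D", 0, "M3"),
    ]
    records = _records_frame(rows)
    pairs, excl = extract_mother_pup_pairs(records, toy_colony, toy_matrix)
    assert len(pairs) == 1
    pair = pairs.iloc[0]
    assert pair["natal_beach"] == "A" and pair["pupping_beach"] == "B"
    assert pair["distance_m"] == pytest.approx(5.0)
    assert pair["mother_age"] == 9  # derived from birth year
    reasons = dict(zip(excl["mom_id"], excl["reason"]))
    assert reasons == {"M2": "immigrant", "M3": "unknown_natal"}
    # accounting: candidates = retained + excluded
    assert 3 == len(pairs) + len(excl)


def test_extraction_excludes_omitted_beaches(study_map, study_matrix):
    rows = [
        ("M1", "2001-01-10", "BBS", 0, None),
        ("P1", "2010-01-08", "APBN", 0, "M1"),  # pup only seen on the omitted name
    ]
    records = _records_frame(rows)
    pairs, excl = extract_mother_pup_pairs(records, study_map, study_matrix)
    assert len(pairs) == 0
    assert list(excl["reason"]) == ["omitted_beach"]


def test_history_flags_repeat_mothers_and_one_pup_per_year():
    pairs = pd.DataFrame(
        {
            "mom_id": ["A", "A", "B"],
            "breeding_year": [2005, 2008, 2010],
            "pupping_beach": ["X", "Y", "X"],
            "mother_age": [5, 8, 4],
        }
    )
    history = build_pupping_history(pairs)
    assert history.loc[history["mom_id"] == "A", "repeat"].all()
    assert not history.loc[history["mom_id"] == "B", "repeat"].any()

    dup = pd.concat([pairs, pairs.iloc[[0]]], ignore_index=True)
    with pytest.raises(ValueError, match="A@2005"):
        build_pupping_history(dup)


def _history(events_by_mom):
    rows = []
    for mom, events in events_by_mom.items():
        for year, beach in events:
            rows.append({"mom_id": mom, "breeding_year": year,
                         "pupping_beach": beach, "mother_age": year - 2000})
    return build_pupping_history(pd.DataFrame(rows))


def test_first_later_and_lag_pair_construction(toy_matrix):
    history = _history({"A": [(2005, "A"), (2006, "B"), (2008, "C")], "B": [(2010, "D")]})
    fl = build_first_later_pairs(history, toy_matrix)
    assert list(zip(fl["year_a"], fl["year_b"])) == [(2005, 2006), (2005, 2008)]
    lag = build_lag_pairs(history, toy_matrix)
    assert sorted(lag["lag_years"]) == [1, 2, 3]
    cons = build_lag_pairs(history, toy_matrix, consecutive_only=True)
    assert sorted(cons["lag_years"]) == [1, 2]
    # first-vs-later pairs form a subset of the all-pairs construction
    fl_keys = set(zip(fl["mom_id"], fl["year_a"], fl["year_b"]))
    lag_keys = set(zip(lag["mom_id"], lag["year_a"], lag["year_b"]))
    assert fl_keys <= lag_keys
    # distances come from the matrix
    assert fl["distance_m"].iloc[0] == pytest.approx(toy_matrix.distance("A", "B"))


def test_pair_counts_sum_over_mothers(toy_matrix):
    # 30 mothers with a mix of event counts: sum(k-1) first-later pairs,
    # sum k(k-1)/2 lag pairs, equal when every mother has exactly 2 events
    events = {}
    ks = [2] * 12 + [3] * 12 + [4] * 6  # 30 mothers, 84 events
    beaches = ["A", "B", "C", "D"]
    for i, k in enumerate(ks):
        events[f"M{i}"] = [(2000 + j, beaches[j % 4]) for j in range(k)]
    history = _history(events)
    fl = build_first_later_pairs(history, toy_matrix)
    lag = build_lag_pairs(history, toy_matrix)
    assert len(fl) == sum(k - 1 for k in ks) == 54
    assert len(lag) == sum(k * (k - 1) // 2 for k in ks)
    assert len(lag) > len(fl)

    two_only = _history({f"M{i}": [(2000, "A"), (2002, "B")] for i in range(5)})
    assert len(build_first_later_pairs(two_only, toy_matrix)) == len(
        build_lag_pairs(two_only, toy_matrix)
    )


def test_single_event_mothers_produce_no_pairs(toy_matrix):
    history = _history({"A": [(2010, "A")], "B": [(2011, "B")]})
    assert len(build_first_later_pairs(history, toy_matrix)) == 0
    assert len(build_lag_pairs(history, toy_matrix)) == 0


def test_natal_beach_uses_first_observation_of_birth_season():
    records = _records_frame(
        [
            ("S1", "2005-01-20", "B", 0, None),
            ("S1", "2005-01-05", "A", 0, None),
            ("S1", "2008-01-05", "C", 3, None),
        ]
    )
    natal = natal_beach_table(records)
    assert natal.iloc[0]["natal_beach"] == "A"
    assert natal.iloc[0]["birth_year"] == 2005


def test_summarize_distances_quantiles_and_oracle():
    zeros = summarize_distances([0.0, 0.0, 0.0])
    assert (zeros.mean_m, zeros.median_m, zeros.q1_m, zeros.q3_m, zeros.max_m) == (
        0, 0, 0, 0, 0)

    s = summarize_distances([100.0, 200.0, 300.0, 400.0])
    assert (s.median_m, s.q1_m, s.q3_m) == (250.0, 175.0, 325.0)

    rng = np.random.default_rng(5)
    for _ in range(10):
        d = rng.exponential(300.0, size=rng.integers(2, 40))
        got = summarize_distances(d).to_dict()
        expected = summary_oracle(d)
        for key, val in expected.items():
            assert got[key] == pytest.approx(val, rel=1e-12), key

    with pytest.raises(ValueError):
        summarize_distances([])
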