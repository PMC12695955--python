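"""Resight-record processing: mother-pup pairs and pupping histories.

The raw input is a long table of field resights (one row per observation of
a tagged seal: date, beach, age, and — during the breeding season — the
linked mother or pup identity).  This module turns that table into the
analysis units of the pipeline:

* mother-pup pairs: a female's own birth (natal) beach versus the beach
  where her pup of a given season was first observed, with the beach-to-
  beach distance attached;
* pupping histories: the ordered pupping events of each mother, from which
  first-versus-later and all-pairs lag comparisons are built.

Records are never silently dropped: rows that fail parsing land in a
rejects table with a reason, and candidate pairs that fail qualification
(immigrant mother, unknown natal site, omitted beach) land in an exclusions
table with a reason code, so the sample-size accounting of an analysis is
always reconstructible.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .geo import ColonyMap, DistanceMatrix

#: mandatory resight CSV columns
REQUIRED_COLUMNS = ("seal_id", "date", "beach_code")
#: full documented column set
ALL_COLUMNS = (
    "seal_id",
    "date",
    "beach_code",
    "age",
    "sex",
    "mom_id",
    "pup_id",
    "season_year",
)

#: exclusion reason codes used by extract_mother_pup_pairs
REASON_UNKNOWN_NATAL = "unknown_natal"
REASON_IMMIGRANT = "immigrant"
REASON_OMITTED_BEACH = "omitted_beach"
REASON_UNKNOWN_BEACH = "unknown_beach"


class RecordFormatError(ValueError):
    """The resight table is missing mandatory structure."""


@dataclass(frozen=True)
class DistanceSummary:
    """Five-number-style summary of a set of pair distances (meters)."""

    n: int
    mean_m: float
    median_m: float
    q1_m: float
    q3_m: float
    max_m: float

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "mean_m": self.mean_m,
            "median_m": self.median_m,
            "q1_m": self.q1_m,
            "q3_m": self.q3_m,
            "max_m": self.max_m,
        }


def season_year_of(dates: pd.Series, boundary_month: int = 12) -> pd.Series:
    """Breeding-season year of each date.

    Females haul out from December through February, so a December birth
    belongs to the season labelled by the following January (default
    ``boundary_month=12``).  Pass ``boundary_month=13`` to disable rollover.
    """
    dates = pd.to_datetime(dates)
    rollover = (dates.dt.month >= boundary_month).astype(int)
    return dates.dt.year + rollover


def parse_resights(
    source: str | Path | pd.DataFrame,
    boundary_month: int = 12,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a resight CSV into a clean records frame plus a rejects frame.

    Returns ``(records, rejects)``.  Rejected rows keep their original
    positional index in column ``row`` and carry a ``reason`` string.
    """
    if isinstance(source, pd.DataFrame):
        raw = source.copy()
    else:
        raw = pd.read_csv(source, dtype={"seal_id": str, "beach_code": str,
                                         "mom_id": str, "pup_id": str})
    missing = set(REQUIRED_COLUMNS) - set(raw.columns)
    if missing:
        raise RecordFormatError(f"resight table missing columns: {sorted(missing)}")

    raw = raw.reset_index(drop=True)
    raw["row"] = raw.index

    reasons = pd.Series("", index=raw.index, dtype=object)
    parsed_dates = pd.to_datetime(raw["date"], errors="coerce", format="mixed")
    reasons[parsed_dates.isna()] = "unparseable date"
    beach = raw["beach_code"].astype(str).str.strip()
    bad_beach = beach.isin(["", "nan", "None"]) | raw["beach_code"].isna()
    reasons[bad_beach & (reasons == "")] = "missing beach code"
    seal = raw["seal_id"].astype(str).str.strip()
    bad_seal = seal.isin(["", "nan", "None"]) | raw["seal_id"].isna()
    reasons[bad_seal & (reasons == "")] = "missing seal id"

    ok = reasons == ""
    rejects = raw.loc[~ok].copy()
    rejects["reason"] = reasons[~ok]

    records = raw.loc[ok].copy()
    records["date"] = parsed_dates[ok]
    records["beach_code"] = beach[ok]
    records["seal_id"] = seal[ok]
    for col in ("age", "sex", "mom_id", "pup_id", "season_year"):
        if col not in records.columns:
            records[col] = np.nan
    derived = season_year_of(records["date"], boundary_month)
    if records["season_year"].isna().all():
        records["season_year"] = derived
    else:
        records["season_year"] = records["season_year"].fillna(derived)
    records["season_year"] = records["season_year"].astype(int)
    return records.reset_index(drop=True), rejects.reset_index(drop=True)


def assign_pupping_site(pup_records: pd.DataFrame) -> str:
    """Beach where a pup was first observed within one season.

    The chronologically earliest observation defines the pupping site; ties
    on the same date are broken by input row order (stable sort).
    """
    if len(pup_records) == 0:
        raise ValueError("assign_pupping_site requires at least one record")
    ordered = pup_records.sort_values("date", kind="stable")
    return str(ordered["beach_code"].iloc[0])


def natal_beach_table(records: pd.DataFrame) -> pd.DataFrame:
    """First-observed beach of each seal in its birth (age-0) season.

    A seal's natal beach is defined from its own pup-of-the-year records:
    the earliest season in which it was resighted at age 0.  Seals with no
    age-0 records have an unknown natal site.
    """
    aged = records[pd.to_numeric(records["age"], errors="coerce") == 0]
    rows = []
    for seal_id, grp in aged.groupby("seal_id", sort=False):
        birth_season = int(grp["season_year"].min())
        in_season = grp[grp["season_year"] == birth_season]
        rows.append(
            {
                "seal_id": seal_id,
                "natal_beach": assign_pupping_site(in_season),
                "birth_year": birth_season,
            }
        )
    return pd.DataFrame(rows, columns=["seal_id", "natal_beach", "birth_year"])


def extract_mother_pup_pairs(
    records: pd.DataFrame,
    colony: ColonyMap,
    matrix: DistanceMatrix,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Qualified mother-pup pairs with natal-to-pupping distances.

    A candidate pair is any (mother, pup, season) linkage present in the
    records.  It qualifies only if the mother's natal beach is known and is
    inside the colony, and the pup's first-observed beach is inside the
    colony; omitted legacy beaches disqualify.  Returns
    ``(pairs, exclusions)`` where exclusions carry reason codes
    (``unknown_natal``, ``immigrant``, ``omitted_beach``, ``unknown_beach``).
    """
    natal = natal_beach_table(records).set_index("seal_id")

    linked = records[records["mom_id"].notna() & (records["mom_id"].astype(str) != "")]
    pairs_out: list[dict] = []
    excl_out: list[dict] = []
    for (mom_id, pup_id, season), grp in linked.groupby(
        ["mom_id", "seal_id", "season_year"], sort=False
    ):
        pup_rows = records[
            (records["seal_id"] == pup_id) & (records["season_year"] == season)
        ]
        pupping_beach = assign_pupping_site(pup_rows)
        base = {
            "mom_id": mom_id,
            "pup_id": pup_id,
            "breeding_year": int(season),
        }
        if mom_id not in natal.index:
            excl_out.append({**base, "reason": REASON_UNKNOWN_NATAL})
            continue
        natal_beach = natal.loc[mom_id, "natal_beach"]
        birth_year = int(natal.loc[mom_id, "birth_year"])
        if colony.is_excluded(natal_beach) or colony.is_excluded(pupping_beach):
            excl_out.append({**base, "reason": REASON_OMITTED_BEACH})
            continue
        if natal_beach not in colony:
            excl_out.append({**base, "reason": REASON_IMMIGRANT})
            continue
        if pupping_beach not in colony:
            excl_out.append({**base, "reason": REASON_UNKNOWN_BEACH})
            continue
        mom_rows = records[
            (records["seal_id"] == mom_id) & (records["season_year"] == season)
        ]
        ages = pd.to_numeric(mom_rows["age"], errors="coerce").dropna()
        mother_age = int(ages.iloc[0]) if len(ages) else int(season) - birth_year
        pairs_out.append(
            {
                **base,
                "natal_beach": natal_beach,
                "pupping_beach": pupping_beach,
                "distance_m": matrix.distance(natal_beach, pupping_beach),
                "mother_age": mother_age,
            }
        )

    pairs = pd.DataFrame(
        pairs_out,
        columns=[
            "mom_id",
            "pup_id",
            "breeding_year",
            "natal_beach",
            "pupping_beach",
            "distance_m",
            "mother_age",
        ],
    )
    exclusions = pd.DataFrame(
        excl_out, columns=["mom_id", "pup_id", "breeding_year", "reason"]
    )
    return pairs, exclusions


def build_pupping_history(pairs: pd.DataFrame) -> pd.DataFrame:
    """Ordered pupping events per mother, flagged for fidelity analysis.

    Raises if a mother has two events in one season (one pup per year).
    Returned frame adds ``n_events`` and ``repeat`` (>= 2 events) columns.
    """
    dup = pairs.duplicated(subset=["mom_id", "breeding_year"])
    if dup.any():
        bad = pairs.loc[dup, ["mom_id", "breeding_year"]].drop_duplicates()
        raise ValueError(
            "mothers with more than one pupping event in a season: "
            + ", ".join(f"{m}@{y}" for m, y in bad.itertuples(index=False))
        )
    events = pairs.sort_values(["mom_id", "breeding_year"], kind="stable")[
        ["mom_id", "breeding_year", "pupping_beach", "mother_age"]
    ].reset_index(drop=True)
    counts = events.groupby("mom_id")["breeding_year"].transform("size")
    events["n_events"] = counts
    events["repeat"] = counts >= 2
    return events


def _fidelity_pairs(
    history: pd.DataFrame,
    matrix: DistanceMatrix | None,
    kind: str,
    first_only: bool,
    consecutive_only: bool = False,
) -> pd.DataFrame:
    rows = []
    for mom_id, grp in history[history["repeat"]].groupby("mom_id", sort=False):
        grp = grp.sort_values("breeding_year")
        events = list(grp[["breeding_year", "pupping_beach"]].itertuples(index=False))
        if first_only:
            combos = [(events[0], later) for later in events[1:]]
        elif consecutive_only:
            combos = list(zip(events[:-1], events[1:]))
        else:
            combos = list(combinations(events, 2))
        for (year_a, beach_a), (year_b, beach_b) in combos:
            rows.append(
                {
                    "mom_id": mom_id,
                    "beach_a": beach_a,
                    "beach_b": beach_b,
                    "year_a": int(year_a),
                    "year_b": int(year_b),
                    "lag_years": int(abs(year_b - year_a)),
                    "kind": kind,
                }
            )
    out = pd.DataFrame(
        rows,
        columns=["mom_id", "beach_a", "beach_b", "year_a", "year_b", "lag_years", "kind"],
    )
    if matrix is not None and len(out):
        out["distance_m"] = matrix.lookup(out["beach_a"], out["beach_b"])
    else:
        out["distance_m"] = pd.Series(dtype=float)
    return out


def build_first_later_pairs(
    history: pd.DataFrame, matrix: DistanceMatrix | None = None
) -> pd.DataFrame:
    """First pupping event versus each later event (k-1 pairs per mother)."""
    return _fidelity_pairs(history, matrix, kind="first_vs_later", first_only=True)


def build_lag_pairs(
    history: pd.DataFrame,
    matrix: DistanceMatrix | None = None,
    consecutive_only: bool = False,
) -> pd.DataFrame:
    """All unordered event pairs per mother with their year lags.

    ``consecutive_only=True`` restricts to successive events instead of the
    default all-pairs construction.
    """
    return _fidelity_pairs(
        history,
        matrix,
        kind="all_pairs_lag",
        first_only=False,
        consecutive_only=consecutive_only,
    )


def summarize_distances(distances) -> DistanceSummary:
    """Mean/median/quartile/max summary with linear-interpolation quantiles."""
    if isinstance(distances, pd.DataFrame):
        d = distances["distance_m"].to_numpy(dtype=float)
    else:
        d = np.asarray(distances, dtype=float)
    if d.size == 0:
        raise ValueError("summarize_distances requires at least one distance")
    q1, med, q3 = np.percentile(d, [25, 50, 75])  # type-7 linear interpolation
    return DistanceSummary(
        n=int(d.size),
        mean_m=float(d.mean()),
        median_m=float(med),
        q1_m=float(q1),
        q3_m=float(q3),
        max_m=float(d.max()),
    )
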