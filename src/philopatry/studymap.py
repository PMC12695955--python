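"""Colony registry for the Año Nuevo mainland study system.

Beach codes, region memberships, and legacy-name alias rules follow the
field program's resight database conventions for the Año Nuevo northern
elephant seal colony: 40 mapped beaches, 12 legacy/ambiguous names that are
assigned coordinates by rule, and one uninterpretable name (``APBN``) that
is omitted, for 52 resolvable sites in total.

SYNTHETIC COORDINATES: the true beach centroids are not public, so this
module lays the mapped beaches along a stand-in coastline of realistic
extent (~3.2 km, UTM zone 10N meters near 37.12N 122.31W).  Every code,
alias rule, and region label is real; every easting/northing is a synthetic
stand-in.  Analyses of real data must load the program's own coordinate
table instead.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .geo import ColonyMap, load_colony_map, resolve_aliases

#: mapped beaches, ordered northernmost to southernmost, with region labels
MAPPED_BEACHES: list[tuple[str, str]] = [
    ("NPC", "Northern"),
    ("NP", "Northern"),
    ("NPGa", "Northern"),
    ("NP0", "Northern"),
    ("NPG0", "Northern"),
    ("NPG1", "Northern"),
    ("NP1", "Northern"),
    ("NP2", "Northern"),
    ("NP3", "Northern"),
    ("NP4", "Northern"),
    ("NPG4", "Northern"),
    ("NPD", "Northern"),
    ("NP5", "Northern"),
    ("NP6", "Northern"),
    ("BBNN", "Central"),
    ("BBN", "Central"),
    ("BBNS", "Central"),
    ("MBBU", "Central"),
    ("MBBL", "Central"),
    ("BMB", "Southern"),
    ("BMNN", "Southern"),
    ("BMD", "Southern"),
    ("BMN", "Southern"),
    ("BMC", "Southern"),
    ("BMS", "Southern"),
    ("BBSU", "Southern"),
    ("BBSL", "Southern"),
    ("APGw", "Southern"),
    ("AP", "Southern"),
    ("APB", "Southern"),  # synthetic 40th mapped code (not in the region lists)
    ("APG", "Southern"),
    ("TSW", "Southern"),
    ("SBW", "Southern"),
    ("SBE", "Southern"),
    ("TSC", "Southern"),
    ("TSD", "Southern"),
    ("TSE", "Southern"),
    ("TSB", "Southern"),
    ("FSB", "Southern"),
    ("P1", "Southern"),
]

#: legacy/ambiguous beach names and the rule that assigns their coordinates
ALIAS_TABLE: list[dict] = [
    # non-specific gully name: center of the two gullies named at the time
    {"alias_code": "NPG", "kind": "midpoint_of_pair", "targets": "NPG0;NPG1"},
    {"alias_code": "NP2/3", "kind": "midpoint_of_pair", "targets": "NP2;NP3"},
    {"alias_code": "MBB", "kind": "midpoint_of_pair", "targets": "MBBL;MBBU"},
    {"alias_code": "BBS", "kind": "midpoint_of_pair", "targets": "BBSL;BBSU"},
    # non-specific name covering a cluster of possible sites
    {
        "alias_code": "BM",
        "kind": "centroid_of_cluster",
        "targets": "BMB;BMNN;BMD;BMN;BMC;BMS",
    },
    # over-specific sub-area names: carry the parent beach's centroid
    {"alias_code": "SBEU", "kind": "subdivision_of", "targets": "SBE"},
    {"alias_code": "SBEL", "kind": "subdivision_of", "targets": "SBE"},
    {"alias_code": "TSBE", "kind": "subdivision_of", "targets": "TSB"},
    # renamed gullies: coordinates taken from historical imagery
    {"alias_code": "NPG2", "kind": "legacy_coordinates", "region": "Northern"},
    {"alias_code": "NPG3", "kind": "legacy_coordinates", "region": "Northern"},
    {"alias_code": "NPG2B", "kind": "legacy_coordinates", "region": "Northern"},
    # typo for NPG3 (itself a legacy name)
    {"alias_code": "NNPG3", "kind": "same_as", "targets": "NPG3"},
    # uninterpretable name: records on it are excluded, not guessed at
    {"alias_code": "APBN", "kind": "omit"},
]

#: stand-in coastline geometry (UTM 10N meters)
_ORIGIN_EASTING = 561_200.0
_ORIGIN_NORTHING = 4_110_400.0
_COAST_LENGTH_M = 3219.0


def study_tables() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Coordinate and alias tables in the CSV dialect the loaders read."""
    n = len(MAPPED_BEACHES)
    # coastline trending SSE with a gentle bow; spacing ~82 m
    t = np.linspace(0.0, 1.0, n)
    along = t * _COAST_LENGTH_M
    bow = 180.0 * np.sin(np.pi * t)
    coords = pd.DataFrame(
        {
            "code": [c for c, _ in MAPPED_BEACHES],
            "easting_m": _ORIGIN_EASTING + 0.45 * along + bow,
            "northing_m": _ORIGIN_NORTHING - 0.893 * along,
            "region": [r for _, r in MAPPED_BEACHES],
        }
    )

    by_code = coords.set_index("code")
    legacy_xy = {
        # stand-ins in the northern gully field, near NPG1/NP2
        "NPG2": ("NPG1", "NP2"),
        "NPG3": ("NP2", "NP3"),
        "NPG2B": ("NPG1", "NP2"),
    }
    rows = []
    for rule in ALIAS_TABLE:
        row = {
            "alias_code": rule["alias_code"],
            "kind": rule["kind"],
            "targets": rule.get("targets", ""),
            "easting_m": np.nan,
            "northing_m": np.nan,
            "region": rule.get("region", ""),
        }
        if rule["kind"] == "legacy_coordinates":
            a, b = legacy_xy[rule["alias_code"]]
            row["easting_m"] = 0.4 * by_code.loc[a, "easting_m"] + 0.6 * by_code.loc[b, "easting_m"]
            row["northing_m"] = 0.4 * by_code.loc[a, "northing_m"] + 0.6 * by_code.loc[b, "northing_m"]
        rows.append(row)
    aliases = pd.DataFrame(rows)
    return coords, aliases


def study_colony(resolved: bool = True) -> ColonyMap:
    """The study colony map (40 mapped + 12 aliased sites when resolved)."""
    coords, aliases = study_tables()
    colony = load_colony_map(coords, aliases)
    return resolve_aliases(colony) if resolved else colony
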