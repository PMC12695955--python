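"""Beach registry, alias resolution, and centroid distance matrices.

A breeding colony is modelled as a set of named beach segments, each with a
centroid in projected (UTM) coordinates and a region label.  Field databases
accumulate legacy or ambiguous beach names over decades of resighting; these
are handled through explicit :class:`AliasRule` records rather than ad-hoc
string fixes, so that every code appearing in the data either resolves to a
site or is flagged for exclusion — never silently dropped.

Distances between beaches are straight-line (Euclidean) distances between
centroids, in meters.  Because animals are located only to the beach level,
all downstream distances are discrete values drawn from this matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist


class Region(str, Enum):
    NORTHERN = "Northern"
    CENTRAL = "Central"
    SOUTHERN = "Southern"


class SiteSource(str, Enum):
    MAPPED = "mapped"
    ALIASED = "aliased"
    INTERPOLATED = "interpolated"


class AliasKind(str, Enum):
    SAME_AS = "same_as"
    MIDPOINT_OF_PAIR = "midpoint_of_pair"
    CENTROID_OF_CLUSTER = "centroid_of_cluster"
    SUBDIVISION_OF = "subdivision_of"
    LEGACY_COORDINATES = "legacy_coordinates"
    OMIT = "omit"


class ColonyMapError(ValueError):
    """Validation failure while building or resolving a colony map."""


class UnknownBeachError(KeyError):
    """A beach code that resolves to no site and is not a flagged omission."""


@dataclass(frozen=True)
class BeachSite:
    code: str
    easting: float
    northing: float
    region: Region
    source: SiteSource = SiteSource.MAPPED

    def __post_init__(self) -> None:
        if not np.isfinite(self.easting) or not np.isfinite(self.northing):
            raise ColonyMapError(f"non-finite coordinates for beach {self.code!r}")


@dataclass(frozen=True)
class AliasRule:
    alias_code: str
    kind: AliasKind
    target_codes: tuple[str, ...] = ()
    easting: float | None = None
    northing: float | None = None
    region: Region | None = None

    def __post_init__(self) -> None:
        if self.kind == AliasKind.OMIT:
            return
        if self.kind == AliasKind.LEGACY_COORDINATES:
            if self.easting is None or self.northing is None:
                raise ColonyMapError(
                    f"alias {self.alias_code!r}: legacy_coordinates rule needs "
                    "explicit easting/northing"
                )
            return
        if not self.target_codes:
            raise ColonyMapError(
                f"alias {self.alias_code!r}: rule of kind {self.kind.value} "
                "requires at least one target code"
            )
        if self.kind == AliasKind.MIDPOINT_OF_PAIR and len(self.target_codes) != 2:
            raise ColonyMapError(
                f"alias {self.alias_code!r}: midpoint_of_pair requires exactly "
                f"two targets, got {len(self.target_codes)}"
            )


@dataclass
class ColonyMap:
    """Registry of beach sites plus (possibly unresolved) alias rules.

    ``excluded_codes`` lists alias codes explicitly omitted from analysis;
    records observed on those beaches are dropped with a reason code rather
    than failing a lookup.
    """

    sites: dict[str, BeachSite]
    alias_rules: tuple[AliasRule, ...] = ()
    excluded_codes: frozenset[str] = frozenset()
    resolved: bool = False

    def __post_init__(self) -> None:
        codes = list(self.sites)
        if len(codes) != len(set(codes)):
            raise ColonyMapError("duplicate site codes in colony map")

    @property
    def codes(self) -> list[str]:
        return list(self.sites)

    def __contains__(self, code: str) -> bool:
        return code in self.sites

    def coordinates(self, code: str) -> tuple[float, float]:
        site = self._lookup(code)
        return site.easting, site.northing

    def region_of(self, code: str) -> Region:
        """Region of a beach; aliases inherit the region of their targets."""
        return self._lookup(code).region

    def is_excluded(self, code: str) -> bool:
        return code in self.excluded_codes

    def _lookup(self, code: str) -> BeachSite:
        try:
            return self.sites[code]
        except KeyError:
            raise UnknownBeachError(f"unknown beach code {code!r}") from None

    # ---- exports -------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "code": [s.code for s in self.sites.values()],
                "easting_m": [s.easting for s in self.sites.values()],
                "northing_m": [s.northing for s in self.sites.values()],
                "region": [s.region.value for s in self.sites.values()],
                "source": [s.source.value for s in self.sites.values()],
            }
        )

    def to_geojson(self) -> dict:
        """Resolved map as a GeoJSON FeatureCollection of Point features."""
        features = []
        for s in self.sites.values():
            features.append(
                {
                    "type": "Feature",
                    "geometry": {
                        "type": "Point",
                        "coordinates": [s.easting, s.northing],
                    },
                    "properties": {
                        "code": s.code,
                        "region": s.region.value,
                        "source": s.source.value,
                    },
                }
            )
        return {"type": "FeatureCollection", "features": features}

    def write_geojson(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_geojson(), indent=1))


@dataclass
class DistanceMatrix:
    """Symmetric beach-to-beach straight-line distance matrix in meters."""

    codes: list[str]
    values: np.ndarray
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.codes)
        if self.values.shape != (n, n):
            raise ColonyMapError("distance matrix shape does not match codes")
        self._index = {c: i for i, c in enumerate(self.codes)}

    def distance(self, code_a: str, code_b: str) -> float:
        try:
            return float(self.values[self._index[code_a], self._index[code_b]])
        except KeyError as exc:
            raise UnknownBeachError(f"unknown beach code {exc.args[0]!r}") from None

    def lookup(self, codes_a: Sequence[str], codes_b: Sequence[str]) -> np.ndarray:
        """Vectorized pairwise distances for two aligned code sequences."""
        ia = np.array([self._index[c] for c in codes_a])
        ib = np.array([self._index[c] for c in codes_b])
        return self.values[ia, ib]

    def index_of(self, code: str) -> int:
        return self._index[code]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.codes, columns=self.codes)

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index_label="code")


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------


def load_colony_map(
    coords: pd.DataFrame,
    alias_rules: pd.DataFrame | Iterable[AliasRule] | None = None,
    region_lookup: Mapping[str, str] | None = None,
) -> ColonyMap:
    """Build an unresolved :class:`ColonyMap` from tabular inputs.

    Parameters
    ----------
    coords
        Mapped-beach table with columns ``code``, ``easting_m``,
        ``northing_m`` and, unless ``region_lookup`` is given, ``region``.
    alias_rules
        Alias-rule table (columns ``alias_code``, ``kind``, ``targets``
        semicolon-separated, optional ``easting_m``/``northing_m``/``region``
        for legacy rules) or an iterable of :class:`AliasRule`.
    region_lookup
        Optional explicit code-to-region mapping overriding/augmenting the
        ``region`` column.  Region membership is an explicit table because
        boundary definitions such as "all beaches north of NPC" are not
        computable from centroids alone.
    """
    required = {"code", "easting_m", "northing_m"}
    missing = required - set(coords.columns)
    if missing:
        raise ColonyMapError(f"coordinate table missing columns: {sorted(missing)}")

    dupes = coords["code"][coords["code"].duplicated()].tolist()
    if dupes:
        raise ColonyMapError(f"duplicate beach code(s) in coordinate table: {dupes}")

    sites: dict[str, BeachSite] = {}
    for row in coords.itertuples(index=False):
        code = str(row.code)
        if region_lookup is not None and code in region_lookup:
            region_val = region_lookup[code]
        elif "region" in coords.columns:
            region_val = getattr(row, "region")
        else:
            region_val = None
        if region_val is None or (isinstance(region_val, float) and np.isnan(region_val)):
            raise ColonyMapError(f"mapped beach {code!r} has no region assignment")
        sites[code] = BeachSite(
            code=code,
            easting=float(row.easting_m),
            northing=float(row.northing_m),
            region=Region(region_val),
            source=SiteSource.MAPPED,
        )

    rules: tuple[AliasRule, ...]
    if alias_rules is None:
        rules = ()
    elif isinstance(alias_rules, pd.DataFrame):
        rules = tuple(_rule_from_row(r) for r in alias_rules.itertuples(index=False))
    else:
        rules = tuple(alias_rules)

    for rule in rules:
        if rule.alias_code in sites:
            raise ColonyMapError(
                f"alias code {rule.alias_code!r} collides with a mapped beach"
            )

    return ColonyMap(sites=sites, alias_rules=rules, resolved=not rules)


def _rule_from_row(row) -> AliasRule:
    targets_raw = getattr(row, "targets", "") or ""
    if isinstance(targets_raw, float):  # NaN from pandas
        targets_raw = ""
    targets = tuple(t.strip() for t in str(targets_raw).split(";") if t.strip())

    def _opt(name):
        val = getattr(row, name, None)
        if val is None or (isinstance(val, float) and np.isnan(val)) or val == "":
            return None
        return val

    region = _opt("region")
    return AliasRule(
        alias_code=str(row.alias_code),
        kind=AliasKind(str(row.kind)),
        target_codes=targets,
        easting=_opt("easting_m"),
        northing=_opt("northing_m"),
        region=Region(region) if region is not None else None,
    )


def resolve_aliases(colony: ColonyMap) -> ColonyMap:
    """Materialize alias rules into sites; omit rules become exclusions.

    Rules may reference other aliases (a renamed gully can itself acquire a
    typo alias), so resolution iterates until a fixed point; a rule whose
    targets never materialize is a validation error.
    """
    sites = dict(colony.sites)
    excluded = set(colony.excluded_codes)
    pending = [r for r in colony.alias_rules if r.alias_code not in sites]

    while pending:
        progressed = False
        still_pending: list[AliasRule] = []
        for rule in pending:
            if rule.kind == AliasKind.OMIT:
                excluded.add(rule.alias_code)
                progressed = True
                continue
            if rule.kind == AliasKind.LEGACY_COORDINATES:
                if rule.region is None:
                    raise ColonyMapError(
                        f"alias {rule.alias_code!r}: legacy_coordinates rule "
                        "needs an explicit region"
                    )
                sites[rule.alias_code] = BeachSite(
                    code=rule.alias_code,
                    easting=float(rule.easting),
                    northing=float(rule.northing),
                    region=rule.region,
                    source=SiteSource.ALIASED,
                )
                progressed = True
                continue
            if not all(t in sites for t in rule.target_codes):
                still_pending.append(rule)
                continue
            targets = [sites[t] for t in rule.target_codes]
            if rule.kind in (AliasKind.SAME_AS, AliasKind.SUBDIVISION_OF):
                parent = targets[0]
                easting, northing = parent.easting, parent.northing
                source = SiteSource.ALIASED
            else:  # midpoint / cluster centroid: arithmetic mean of targets
                easting = float(np.mean([t.easting for t in targets]))
                northing = float(np.mean([t.northing for t in targets]))
                source = SiteSource.INTERPOLATED
            region = rule.region if rule.region is not None else _inherit_region(rule, targets)
            sites[rule.alias_code] = BeachSite(
                code=rule.alias_code,
                easting=easting,
                northing=northing,
                region=region,
                source=source,
            )
            progressed = True
        if not progressed:
            bad = sorted(r.alias_code for r in still_pending)
            raise ColonyMapError(
                f"alias rule(s) reference unknown target beaches: {bad}"
            )
        pending = still_pending

    return ColonyMap(
        sites=sites,
        alias_rules=colony.alias_rules,
        excluded_codes=frozenset(excluded),
        resolved=True,
    )


def _inherit_region(rule: AliasRule, targets: list[BeachSite]) -> Region:
    regions = {t.region for t in targets}
    if len(regions) == 1:
        return regions.pop()
    raise ColonyMapError(
        f"alias {rule.alias_code!r}: targets span several regions "
        f"({sorted(r.value for r in regions)}); give the rule an explicit region"
    )


def build_distance_matrix(colony: ColonyMap) -> DistanceMatrix:
    """Euclidean centroid-to-centroid distances for every resolved beach.

    Coordinates are projected meters (UTM), so straight-line distance is the
    plain Euclidean norm; no geodesic correction is applied at colony scale.
    """
    if not colony.resolved:
        raise ColonyMapError(
            "colony map still has unresolved alias rules; run resolve_aliases first"
        )
    codes = colony.codes
    xy = np.array([[s.easting, s.northing] for s in colony.sites.values()])
    values = squareform(pdist(xy)) if len(codes) > 1 else np.zeros((1, 1))
    return DistanceMatrix(codes=codes, values=values)
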