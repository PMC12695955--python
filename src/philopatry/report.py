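"""End-to-end analysis orchestration and report bundles.

Three analyses run over a resight table and a colony map:

* natal: distances between each qualified mother's natal beach and her
  pupping beach — summary, permutation nulls (mean and median), dip test
  of unimodality, and a median quantile regression on maternal age;
* fidelity: distances between a repeat mother's first and later pupping
  beaches — permutation nulls, bimodality coefficient, and a median
  quantile regression of all-pairs distances on lag years;
* regions: the 3x3 natal-to-pupping region transition table and its
  multinomial regression with relative-risk ratios.

Each bundle is a plain dict (JSON-serializable) that embeds the seeds,
parameters, sample-size accounting, and input checksums needed to re-run
the stage bit-identically.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import models, permtest, records as rec, shape_stats
from .geo import ColonyMap, DistanceMatrix, build_distance_matrix, load_colony_map, resolve_aliases


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the reason."""


@dataclass
class AnalysisConfig:
    resight_csv: str | Path | None = None
    coords_csv: str | Path | None = None
    alias_csv: str | Path | None = None
    out_dir: str | Path | None = None
    n_perm: int = 10_000
    seed: int = 0
    boundary_month: int = 12
    min_level_count: int = 2
    bootstrap_B: int = 2000
    dip_n_boot: int = 2000
    baseline_outcome: str = "Southern"
    reference_predictor: str = "Southern"
    consecutive_lags_only: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        out = {}
        for k, v in self.__dict__.items():
            out[k] = str(v) if isinstance(v, Path) else v
        return out


def _checksum(path) -> str | None:
    if path is None:
        return None
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


@dataclass
class PipelineInputs:
    colony: ColonyMap
    matrix: DistanceMatrix
    records: pd.DataFrame
    rejects: pd.DataFrame
    pairs: pd.DataFrame
    exclusions: pd.DataFrame
    checksums: dict = field(default_factory=dict)

    def accounting(self) -> dict:
        reasons = (
            self.exclusions["reason"].value_counts().to_dict()
            if len(self.exclusions)
            else {}
        )
        return {
            "n_records": int(len(self.records)),
            "n_rejected_rows": int(len(self.rejects)),
            "n_pairs": int(len(self.pairs)),
            "n_excluded_pairs": int(len(self.exclusions)),
            "exclusion_reasons": {str(k): int(v) for k, v in reasons.items()},
        }


def prepare_inputs(
    config: AnalysisConfig,
    colony: ColonyMap | None = None,
    records: pd.DataFrame | None = None,
) -> PipelineInputs:
    """Load and qualify everything the analyses share."""
    if colony is None:
        if config.coords_csv is None:
            raise PipelineError("prepare_inputs: no colony map or coords_csv given")
        coords = pd.read_csv(config.coords_csv)
        aliases = pd.read_csv(config.alias_csv) if config.alias_csv else None
        colony = load_colony_map(coords, aliases)
    if not colony.resolved:
        colony = resolve_aliases(colony)
    matrix = build_distance_matrix(colony)

    source = records if records is not None else config.resight_csv
    if source is None:
        raise PipelineError("prepare_inputs: no resight records given")
    parsed, rejects = rec.parse_resights(source, boundary_month=config.boundary_month)
    pairs, exclusions = rec.extract_mother_pup_pairs(parsed, colony, matrix)
    checksums = {
        "resight_csv": _checksum(config.resight_csv),
        "coords_csv": _checksum(config.coords_csv),
        "alias_csv": _checksum(config.alias_csv),
    }
    return PipelineInputs(
        colony=colony,
        matrix=matrix,
        records=parsed,
        rejects=rejects,
        pairs=pairs,
        exclusions=exclusions,
        checksums=checksums,
    )


def run_natal_analysis(config: AnalysisConfig, inputs: PipelineInputs) -> dict:
    pairs = inputs.pairs
    if len(pairs) == 0:
        raise PipelineError(
            "natal: no qualified mother-pup pairs remain after exclusions "
            f"({inputs.accounting()['exclusion_reasons']})"
        )
    summary = rec.summarize_distances(pairs)
    perm = {
        kind: permtest.permutation_test(
            list(pairs["natal_beach"]),
            list(pairs["pupping_beach"]),
            inputs.matrix,
            statistic_kind=kind,
            n_perm=config.n_perm,
            seed=config.seed,
        )
        for kind in ("mean", "median")
    }
    distances = pairs["distance_m"].to_numpy(dtype=float)
    dip = shape_stats.dip_test(distances, n_boot=config.dip_n_boot, seed=config.seed)
    n_within_natal = int((distances == 0).sum())

    age_fit = None
    try:
        age_fit = models.fit_median_regression(
            pairs["mother_age"],
            pairs["distance_m"],
            min_level_count=config.min_level_count,
            B=config.bootstrap_B,
            seed=config.seed,
        )
    except models.FitError as exc:
        age_fit_error = str(exc)

    bundle = {
        "analysis": "natal",
        "config": config.to_dict(),
        "checksums": inputs.checksums,
        "accounting": inputs.accounting(),
        "distance_summary": summary.to_dict(),
        "n_within_natal_beach": n_within_natal,
        "permutation": {k: v.to_dict() for k, v in perm.items()},
        "dip_test": dip.to_dict(),
        "age_quantile_regression": age_fit.to_dict() if age_fit else {"error": age_fit_error},
    }
    bundle["_objects"] = {"permutation": perm, "dip": dip, "age_fit": age_fit,
                          "distances": distances}
    return bundle


def run_fidelity_analysis(config: AnalysisConfig, inputs: PipelineInputs) -> dict:
    history = rec.build_pupping_history(inputs.pairs)
    if not history["repeat"].any():
        raise PipelineError("fidelity: no mothers with two or more pupping events")
    first_later = rec.build_first_later_pairs(history, inputs.matrix)
    lag_pairs = rec.build_lag_pairs(
        history, inputs.matrix, consecutive_only=config.consecutive_lags_only
    )

    summary = rec.summarize_distances(first_later)
    perm = {
        kind: permtest.permutation_test(
            list(first_later["beach_a"]),
            list(first_later["beach_b"]),
            inputs.matrix,
            statistic_kind=kind,
            n_perm=config.n_perm,
            seed=config.seed,
        )
        for kind in ("mean", "median")
    }
    distances = first_later["distance_m"].to_numpy(dtype=float)
    try:
        bc = shape_stats.bimodality_coefficient(distances)
    except ValueError:  # fewer than 4 pairs, or all distances identical
        bc = None

    lag_fit = None
    lag_fit_error = None
    try:
        lag_fit = models.fit_median_regression(
            lag_pairs["lag_years"],
            lag_pairs["distance_m"],
            min_level_count=config.min_level_count,
            B=config.bootstrap_B,
            seed=config.seed,
        )
    except models.FitError as exc:
        lag_fit_error = str(exc)

    bundle = {
        "analysis": "fidelity",
        "config": config.to_dict(),
        "checksums": inputs.checksums,
        "n_repeat_mothers": int(history.loc[history["repeat"], "mom_id"].nunique()),
        "n_first_later_pairs": int(len(first_later)),
        "n_lag_pairs": int(len(lag_pairs)),
        "distance_summary": summary.to_dict(),
        "permutation": {k: v.to_dict() for k, v in perm.items()},
        "bimodality": bc.to_dict() if bc else None,
        "lag_quantile_regression": lag_fit.to_dict() if lag_fit else {"error": lag_fit_error},
    }
    bundle["_objects"] = {
        "permutation": perm,
        "bc": bc,
        "lag_fit": lag_fit,
        "first_later": first_later,
        "lag_pairs": lag_pairs,
    }
    return bundle


def run_region_analysis(config: AnalysisConfig, inputs: PipelineInputs) -> dict:
    if len(inputs.pairs) == 0:
        raise PipelineError("regions: no qualified pairs")
    table = models.transition_table(inputs.pairs, inputs.colony)
    fit = models.fit_multinomial(
        table,
        baseline_outcome=config.baseline_outcome,
        reference_predictor=config.reference_predictor,
    )
    bundle = {
        "analysis": "regions",
        "config": config.to_dict(),
        "checksums": inputs.checksums,
        "n_pairs": table.n_pairs,
        "counts": {r: {c: int(v) for c, v in row.items()}
                   for r, row in table.counts.iterrows()},
        "natal_percent": {k: float(v) for k, v in table.natal_percent.items()},
        "pupping_percent": {k: float(v) for k, v in table.pupping_percent.items()},
        "multinomial": fit.to_dict(),
        "rrr_description": fit.describe(),
    }
    bundle["_objects"] = {"table": table, "fit": fit}
    return bundle


def run_all(
    config: AnalysisConfig,
    colony: ColonyMap | None = None,
    records: pd.DataFrame | None = None,
) -> dict:
    inputs = prepare_inputs(config, colony=colony, records=records)
    return {
        "natal": run_natal_analysis(config, inputs),
        "fidelity": run_fidelity_analysis(config, inputs),
        "regions": run_region_analysis(config, inputs),
        "_inputs": inputs,
    }


def _strip_objects(bundle: dict) -> dict:
    return {k: v for k, v in bundle.items() if not k.startswith("_")}


def write_bundle(bundle: dict, out_dir: str | Path) -> Path:
    """Write one analysis bundle as JSON (+ CSV side tables) to a directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    name = bundle["analysis"]
    path = out_dir / f"{name}.json"
    path.write_text(json.dumps(_strip_objects(bundle), indent=1, default=float))
    objs = bundle.get("_objects", {})
    if "permutation" in objs:
        for kind, res in objs["permutation"].items():
            pd.DataFrame({"null_value_m": res.null_values}).to_csv(
                out_dir / f"{name}_null_{kind}.csv", index=False
            )
    if "table" in objs:
        objs["table"].counts.to_csv(out_dir / "region_counts.csv")
        objs["table"].to_edge_list().to_csv(out_dir / "region_flows.csv", index=False)
    return path
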