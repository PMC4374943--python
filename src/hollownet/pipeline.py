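"""Full per-site analysis: the report block and multi-site comparison.

``analyze`` runs every stage on one matrix — descriptors, NODF with the CE
null, WNODF with the RC null, Barber modularity (full simulated annealing
for the reported M, budget-matched zero-temperature runs for its
significance), the 25-run core/periphery ensemble and the three extinction
scenarios — and returns a JSON-serializable report shaped like the classic
network-attribute table: N (NODF), WNODF, M (SA), L/S, C, LD, V-ratio,
R RE, R DE1, R DE2.

Every stochastic stage derives its seed deterministically from the global
seed and the stage name, so the same configuration and seed reproduce the
report byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import coreper, descriptors, modularity, nullmodels, robustness
from .matrix import AbundanceMatrix, read_matrix

logger = logging.getLogger(__name__)

TABLE2_FIELDS = (
    "N (NODF)",
    "WNODF",
    "M (SA)",
    "L/S",
    "C",
    "LD",
    "V-ratio",
    "R RE",
    "R DE1",
    "R DE2",
)


def derive_seed(global_seed: int | None, stage: str) -> int:
    """Deterministic per-stage seed from the global seed and stage name."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass(frozen=True)
class AnalysisConfig:
    """Configuration of one full analysis run.

    Defaults mirror the study protocol: 1000 null replicates for the
    nestedness and modularity tests, 25 core/periphery runs with the
    80% / 65% tier thresholds, 100 random-extinction permutations.
    """

    site_name: str = "site"
    nulls: int = 1000
    modularity_nulls: int = 1000
    sa_schedule: modularity.SASchedule = field(default_factory=modularity.SASchedule.default)
    null_sa_schedule: modularity.SASchedule = field(default_factory=modularity.SASchedule.greedy)
    coreper_runs: int = 25
    core_a_min: float = coreper.CORE_A_MIN
    core_b_min: float = coreper.CORE_B_MIN
    robustness_runs: int = 100
    seed: int | None = None

    @classmethod
    def from_mapping(cls, mapping: Mapping, **overrides) -> "AnalysisConfig":
        known = {f for f in cls.__dataclass_fields__}
        kwargs = {k: v for k, v in mapping.items() if k in known}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs.update(overrides)
        return cls(**kwargs)


class StageError(RuntimeError):
    """An analysis stage failed; carries the stage name and cause."""


def _round6(x: float) -> float:
    return float(round(float(x), 6))


def analyze(a: AbundanceMatrix | str | Path, config: AnalysisConfig | None = None) -> dict:
    """Run the complete per-site analysis and return the report dict."""
    config = config or AnalysisConfig()
    if not isinstance(a, AbundanceMatrix):
        a = read_matrix(a)
    a = a.drop_empty()

    report: dict = {
        "site": config.site_name,
        "seed": config.seed,
        "S_insects": a.n_rows,
        "S_hollows": a.n_cols,
        "L": a.links,
        "m": a.individuals,
    }
    stage_seeds: dict[str, int] = {}
    table2: dict[str, float] = {}
    significance: dict[str, dict] = {}

    def run_stage(name: str, fn):
        t0 = time.perf_counter()
        try:
            out = fn()
        except Exception as exc:  # noqa: BLE001 - rewrap with stage context
            raise StageError(f"stage {name!r} failed: {exc}") from exc
        logger.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
        return out

    # descriptors ---------------------------------------------------------
    summary = run_stage("descriptors", lambda: descriptors.summarize(a))
    table2["L/S"] = _round6(summary.links_per_species)
    table2["C"] = _round6(summary.connectance)
    table2["LD"] = _round6(summary.linkage_density)
    table2["V-ratio"] = _round6(summary.variance_ratio)

    # nestedness ----------------------------------------------------------
    stage_seeds["nodf_ce"] = derive_seed(config.seed, "nodf_ce")
    ens = run_stage(
        "nodf_ce",
        lambda: nullmodels.nodf_significance(a, n_rep=config.nulls, seed=stage_seeds["nodf_ce"]),
    )
    table2["N (NODF)"] = _round6(ens.observed)
    significance["NODF"] = {k: _jsonable(v) for k, v in ens.summary().items()}

    stage_seeds["wnodf_rc"] = derive_seed(config.seed, "wnodf_rc")
    ens = run_stage(
        "wnodf_rc",
        lambda: nullmodels.wnodf_significance(a, n_rep=config.nulls, seed=stage_seeds["wnodf_rc"]),
    )
    table2["WNODF"] = _round6(ens.observed)
    significance["WNODF"] = {k: _jsonable(v) for k, v in ens.summary().items()}

    # modularity ----------------------------------------------------------
    stage_seeds["modularity_sa"] = derive_seed(config.seed, "modularity_sa")
    partition = run_stage(
        "modularity_sa",
        lambda: modularity.optimize_sa(
            a.binarize(), config.sa_schedule, seed=stage_seeds["modularity_sa"]
        ),
    )
    table2["M (SA)"] = _round6(partition.modularity)
    stage_seeds["modularity_null"] = derive_seed(config.seed, "modularity_null")
    ens = run_stage(
        "modularity_null",
        lambda: modularity.modularity_significance(
            a,
            n_rand=config.modularity_nulls,
            seed=stage_seeds["modularity_null"],
            schedule=config.null_sa_schedule,
        ),
    )
    significance["M"] = {k: _jsonable(v) for k, v in ens.summary().items()}
    report["n_modules"] = partition.n_modules

    # core/periphery ------------------------------------------------------
    stage_seeds["coreper"] = derive_seed(config.seed, "coreper")
    profile = run_stage(
        "coreper",
        lambda: coreper.fit_ensemble(
            a.binarize(),
            n_runs=config.coreper_runs,
            seed=stage_seeds["coreper"],
            core_a_min=config.core_a_min,
            core_b_min=config.core_b_min,
        ),
    )
    row_tiers = profile.row_tiers
    col_tiers = profile.col_tiers
    report["core"] = {
        "n_core_insects": sum(t != "periphery" for t in row_tiers),
        "n_core_hollows": sum(t != "periphery" for t in col_tiers),
        "core_a_insects": [l for l, t in zip(profile.row_labels, row_tiers) if t == "core_a"],
        "core_b_insects": [l for l, t in zip(profile.row_labels, row_tiers) if t == "core_b"],
        "core_hollows": [l for l, t in zip(profile.col_labels, col_tiers) if t != "periphery"],
        "n_runs": profile.n_runs,
    }

    # robustness ----------------------------------------------------------
    stage_seeds["robustness"] = derive_seed(config.seed, "robustness")
    results = run_stage(
        "robustness",
        lambda: {
            "R RE": robustness.scenario(
                a, "random", n_runs=config.robustness_runs, seed=stage_seeds["robustness"]
            ),
            "R DE1": robustness.scenario(a, "least_connected_first"),
            "R DE2": robustness.scenario(a, "most_connected_first"),
        },
    )
    for key, res in results.items():
        table2[key] = _round6(res.robustness)
    report["robustness_sd_RE"] = _round6(results["R RE"].r_sd or 0.0)

    # node table ----------------------------------------------------------
    node_table = descriptors.degree_and_strength(a)
    tiers = row_tiers + col_tiers
    node_table["core_frequency"] = [
        _round6(f) for f in list(profile.row_frequency) + list(profile.col_frequency)
    ]
    node_table["tier"] = tiers
    node_table["strength"] = node_table["strength"].map(_round6)

    report["table2"] = {k: table2[k] for k in TABLE2_FIELDS}
    report["significance"] = significance
    report["stage_seeds"] = stage_seeds
    report["nodes"] = node_table.to_dict(orient="records")
    return report


def _jsonable(v):
    if isinstance(v, (int, str)) or v is None:
        return v
    return _round6(v)


def report_to_json(report: dict) -> str:
    """Canonical serialization (sorted keys) -> byte-identical under a seed."""
    return json.dumps(report, indent=2, sort_keys=True)


def compare_sites(reports: list[dict]) -> pd.DataFrame:
    """Side-by-side table of >= 2 reports in the classic attribute layout.

    Only ranks are comparable across sites; no cross-site statistics are
    computed.
    """
    if len(reports) < 2:
        raise ValueError("compare_sites needs at least two reports")
    for rep in reports:
        missing = [f for f in TABLE2_FIELDS if f not in rep.get("table2", {})]
        if missing:
            raise ValueError(f"report {rep.get('site')!r} missing fields {missing}")
    data = {rep["site"]: [rep["table2"][f] for f in TABLE2_FIELDS] for rep in reports}
    if len(data) != len(reports):
        raise ValueError("duplicate site names in reports")
    return pd.DataFrame(data, index=list(TABLE2_FIELDS))
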