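"""Configuration files, record tables, mutation exports, and run manifests.

Configs are YAML (JSON, being a YAML subset, is accepted too). Records and
mutation tables are tab-separated text with an explicit ``NA`` token for
undefined values and fixed significant-digit decimals, so outputs diff
cleanly across platforms. All writes go through a write-then-rename so no
output file is ever left partially written.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import tempfile
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .extensions import BdmiSettings, DemographySettings
from .population import Population
from .scenarios import OptimumSchedule, ScenarioConfig, make_config

__all__ = [
    "load_config",
    "save_config",
    "config_to_dict",
    "config_from_dict",
    "write_records",
    "read_records",
    "export_mutations",
    "RunManifest",
    "write_manifest",
]

FLOAT_FORMAT = "%.10g"


def _atomic_write(path: str, text: str) -> None:
    d = os.path.dirname(os.path.abspath(path))
    fd, tmp = tempfile.mkstemp(dir=d, prefix=".tmp-", text=True)
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def config_to_dict(config: ScenarioConfig) -> dict:
    d = {
        "system": config.system,
        "N_pop": config.N_pop,
        "L": config.L,
        "mu": config.mu,
        "r_bp": config.r_bp,
        "n_dims": config.n_dims,
        "lambda_mean": config.lambda_mean,
        "h": config.h,
        "shape_q": config.shape_q,
        "T_parental": config.T_parental,
        "T_novel": config.T_novel,
        "replicates": config.replicates,
        "seed": config.seed,
        "schedule": {
            label: [[gen, list(opt)] for gen, opt in points]
            for label, points in config.schedule.entries.items()
        },
    }
    if config.bdmi is not None:
        d["bdmi"] = {
            "n_pairs": config.bdmi.n_pairs,
            "cost": config.bdmi.cost,
        }
        if config.bdmi.dominance_matrix is not None:
            d["bdmi"]["dominance_matrix"] = [
                list(row) for row in config.bdmi.dominance_matrix
            ]
    if config.demography is not None:
        d["demography"] = {
            "carrying_capacity": config.demography.carrying_capacity,
            "growth_factor": config.demography.growth_factor,
            "extinction_threshold": config.demography.extinction_threshold,
        }
    return d


def config_from_dict(data: dict) -> ScenarioConfig:
    if not isinstance(data, dict):
        raise ValueError("configuration must be a mapping")
    data = dict(data)
    schedule = None
    if "schedule" in data:
        raw = data.pop("schedule")
        entries = {
            label: tuple((int(gen), tuple(opt)) for gen, opt in points)
            for label, points in raw.items()
        }
        schedule = OptimumSchedule(entries=entries)
    if data.get("bdmi") is not None:
        b = data["bdmi"]
        unknown = set(b) - {"n_pairs", "cost", "dominance_matrix"}
        if unknown:
            raise ValueError(f"unknown bdmi keys: {sorted(unknown)}")
        mat = b.get("dominance_matrix")
        data["bdmi"] = BdmiSettings(
            n_pairs=int(b.get("n_pairs", 1)),
            cost=float(b.get("cost", 0.1)),
            dominance_matrix=tuple(tuple(row) for row in mat) if mat is not None else None,
        )
    if data.get("demography") is not None:
        dm = data["demography"]
        unknown = set(dm) - {"carrying_capacity", "growth_factor", "extinction_threshold"}
        if unknown:
            raise ValueError(f"unknown demography keys: {sorted(unknown)}")
        data["demography"] = DemographySettings(
            carrying_capacity=int(dm["carrying_capacity"]),
            growth_factor=float(dm.get("growth_factor", 2.0)),
            extinction_threshold=int(dm.get("extinction_threshold", 0)),
        )
    system = data.pop("system", "diploid")
    try:
        return make_config(system=system, schedule=schedule, **data)
    except TypeError as exc:  # unexpected keyword
        raise ValueError(str(exc)) from exc


def load_config(path: str) -> ScenarioConfig:
    """Read and fully validate a scenario configuration (YAML or JSON).

    Missing values are filled with the standard defaults for the declared
    genetic system; unknown or out-of-range keys raise an error naming the
    offending key.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    return config_from_dict(data)


def save_config(config: ScenarioConfig, path: str) -> None:
    _atomic_write(path, yaml.safe_dump(config_to_dict(config), sort_keys=True))


def write_records(records: pd.DataFrame, path: str) -> None:
    """Write the per-generation record table as deterministic TSV."""
    df = records.sort_values(["replicate", "generation", "population"]).reset_index(
        drop=True
    )
    text = df.to_csv(sep="\t", index=False, na_rep="NA", float_format=FLOAT_FORMAT)
    _atomic_write(path, text)


def read_records(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)


def export_mutations(pop: Population, path: str) -> pd.DataFrame:
    """Export the population's segregating and substituted mutations as TSV."""
    n = pop.params.n_dims
    rows = []
    freqs = pop.allele_frequency_array()
    reg = pop.registry.mutations
    for j, mid in enumerate(pop.mut_ids):
        m = reg[int(mid)]
        rows.append(
            {
                "id": int(mid),
                "position": int(pop.positions[j]),
                "status": "segregating",
                "frequency": float(freqs[j]),
                "origin_generation": m.origin_generation,
                "origin_population": m.origin_population,
                "dominance_h": float(pop.dominance[j]),
                **{f"effect_{k + 1}": float(pop.effects[j, k]) for k in range(n)},
            }
        )
    for m in pop.substitutions:
        rows.append(
            {
                "id": m.id,
                "position": m.position,
                "status": "substitution",
                "frequency": 1.0,
                "origin_generation": m.origin_generation,
                "origin_population": m.origin_population,
                "dominance_h": float(m.effect.dominance_h),
                **{f"effect_{k + 1}": float(m.effect.delta[k]) for k in range(n)},
            }
        )
    cols = [
        "id",
        "position",
        "status",
        "frequency",
        "origin_generation",
        "origin_population",
        "dominance_h",
    ] + [f"effect_{k + 1}" for k in range(n)]
    df = pd.DataFrame(rows, columns=cols).sort_values(["position", "id"]).reset_index(drop=True)
    _atomic_write(path, df.to_csv(sep="\t", index=False, na_rep="NA", float_format=FLOAT_FORMAT))
    return df


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Everything needed to reproduce a run exactly: the config, the root
    seed, the derived per-replicate seed-sequence keys, the software
    version, and a checksummed inventory of output files."""

    config: dict
    root_seed: int
    replicate_spawn_keys: list
    version: str = __version__
    start_generation: int = 0
    end_generation: int = 0
    files: dict = field(default_factory=dict)


def write_manifest(manifest: RunManifest, path: str, files: list[str] | None = None) -> None:
    if files:
        manifest.files = {os.path.basename(f): _sha256(f) for f in files}
    _atomic_write(path, json.dumps(dataclasses.asdict(manifest), indent=2, sort_keys=True) + "\n")
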