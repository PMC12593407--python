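"""Readers and writers for catalogs, records, traces, ensembles and configs.

Catalogs are one CSV per reagent class (header row, identifier first). Records
are one CSV with condition, yield, domain and iteration columns.  Ensembles
serialize to versioned JSON.  Traces are line-delimited JSON.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .ensemble import Ensemble, ForestMember, ReactionRecord, Tree
from .errors import ValidationError
from .loop import CampaignTrace
from .reagent_space import (
    Additive,
    Condition,
    Ligand,
    ReagentCatalog,
    Solvent,
    Substrate,
)
from .synthetic import SyntheticLandscape

CATALOG_FILES = {
    "precatalysts": "precatalysts.csv",
    "ligands": "ligands.csv",
    "additives": "additives.csv",
    "solvents": "solvents.csv",
    "substrates": "substrates.csv",
}

RECORD_COLUMNS = [
    "amine_id", "acid_id", "precatalyst", "ligand", "additive", "solvent",
    "yield_percent", "domain", "iteration",
]


def _read_table(path: Path, min_cols: int, what: str) -> pd.DataFrame:
    if not path.exists():
        raise ValidationError(f"{what} file not found: {path}")
    df = pd.read_csv(path)
    if df.empty:
        raise ValidationError(f"{what} file is empty: {path}")
    if df.shape[1] < min_cols:
        raise ValidationError(
            f"{what} file {path} needs >= {min_cols} columns, found {df.shape[1]}"
        )
    return df


def _descriptor_rows(df: pd.DataFrame, path: Path, what: str):
    ids = df.iloc[:, 0].astype(str).tolist()
    desc = df.iloc[:, 1:]
    for col in desc.columns:
        if not pd.api.types.is_numeric_dtype(desc[col]):
            bad = desc[pd.to_numeric(desc[col], errors="coerce").isna()].index[0]
            raise ValidationError(
                f"non-numeric descriptor in {path} (row {bad + 2}, column {col!r})"
            )
    return ids, [tuple(float(v) for v in row) for row in desc.to_numpy()]


def read_catalog(directory: str | Path) -> ReagentCatalog:
    """Load the five per-class CSV tables from ``directory``."""
    d = Path(directory)
    pre = _read_table(d / CATALOG_FILES["precatalysts"], 1, "precatalyst")
    precatalysts = pre.iloc[:, 0].astype(str).tolist()

    lig_ids, lig_desc = _descriptor_rows(
        _read_table(d / CATALOG_FILES["ligands"], 2, "ligand"),
        d / CATALOG_FILES["ligands"], "ligand",
    )
    ligands = [Ligand(i, t) for i, t in zip(lig_ids, lig_desc)]

    add = _read_table(d / CATALOG_FILES["additives"], 3, "additive")
    additives = []
    for _, row in add.iterrows():
        cation = None if pd.isna(row.iloc[1]) or row.iloc[1] == "" else str(row.iloc[1])
        anion = None if pd.isna(row.iloc[2]) or row.iloc[2] == "" else str(row.iloc[2])
        additives.append(Additive(str(row.iloc[0]), cation, anion))

    sol_ids, sol_desc = _descriptor_rows(
        _read_table(d / CATALOG_FILES["solvents"], 2, "solvent"),
        d / CATALOG_FILES["solvents"], "solvent",
    )
    solvents = [Solvent(i, t) for i, t in zip(sol_ids, sol_desc)]

    sub = _read_table(d / CATALOG_FILES["substrates"], 2, "substrate")
    roles = sub.iloc[:, 1].astype(str)
    bad_roles = set(roles) - {"amine", "acid"}
    if bad_roles:
        raise ValidationError(
            f"substrate roles must be amine|acid, found {sorted(bad_roles)} "
            f"in {d / CATALOG_FILES['substrates']}"
        )
    desc = sub.iloc[:, 2:]
    substrates = [
        Substrate(str(r.iloc[0]), str(r.iloc[1]), tuple(float(v) for v in r.iloc[2:]))
        for _, r in sub.iterrows()
    ]
    return ReagentCatalog(
        precatalysts=precatalysts, ligands=ligands, additives=additives,
        solvents=solvents, substrates=substrates,
    )


def write_catalog(catalog: ReagentCatalog, directory: str | Path) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"id": catalog.precatalysts}).to_csv(
        d / CATALOG_FILES["precatalysts"], index=False
    )

    def desc_frame(items):
        n = len(items[0].descriptors)
        cols = {"id": [x.id for x in items]}
        for j in range(n):
            cols[f"d{j}"] = [x.descriptors[j] for x in items]
        return pd.DataFrame(cols)

    desc_frame(catalog.ligands).to_csv(d / CATALOG_FILES["ligands"], index=False)
    pd.DataFrame(
        {
            "id": [a.id for a in catalog.additives],
            "cation": [a.cation or "" for a in catalog.additives],
            "anion": [a.anion or "" for a in catalog.additives],
        }
    ).to_csv(d / CATALOG_FILES["additives"], index=False)
    desc_frame(catalog.solvents).to_csv(d / CATALOG_FILES["solvents"], index=False)
    n = len(catalog.substrates[0].descriptors)
    cols = {
        "id": [s.id for s in catalog.substrates],
        "role": [s.role for s in catalog.substrates],
    }
    for j in range(n):
        cols[f"d{j}"] = [s.descriptors[j] for s in catalog.substrates]
    pd.DataFrame(cols).to_csv(d / CATALOG_FILES["substrates"], index=False)


def read_records(path: str | Path, catalog: ReagentCatalog | None = None) -> list[ReactionRecord]:
    df = pd.read_csv(path)
    missing = set(RECORD_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"records file {path} missing columns: {sorted(missing)}")
    records = []
    for i, row in df.iterrows():
        y = float(row["yield_percent"])
        if not 0.0 <= y <= 100.0:
            raise ValidationError(
                f"yield {y} outside [0, 100] in {path} (row {i + 2})"
            )
        if row["domain"] not in ("source", "target"):
            raise ValidationError(
                f"domain must be source|target in {path} (row {i + 2}): {row['domain']!r}"
            )
        cond = Condition(
            str(row["precatalyst"]), str(row["ligand"]),
            str(row["additive"]), str(row["solvent"]),
        )
        if catalog is not None:
            catalog.resolve(cond)
        records.append(
            ReactionRecord(
                substrate_pair=(str(row["amine_id"]), str(row["acid_id"])),
                condition=cond,
                yield_percent=y,
                domain=str(row["domain"]),
                iteration=int(row["iteration"]),
            )
        )
    return records


def write_records(records: list[ReactionRecord], path: str | Path) -> None:
    rows = [
        {
            "amine_id": r.substrate_pair[0],
            "acid_id": r.substrate_pair[1],
            **r.condition.as_dict(),
            "yield_percent": r.yield_percent,
            "domain": r.domain,
            "iteration": r.iteration,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=RECORD_COLUMNS).to_csv(path, index=False)


def write_conditions(conditions, path: str | Path) -> None:
    pd.DataFrame([c.as_dict() for c in conditions]).to_csv(path, index=False)


def read_conditions(path: str | Path) -> list[Condition]:
    df = pd.read_csv(path)
    need = ["precatalyst", "ligand", "additive", "solvent"]
    missing = set(need) - set(df.columns)
    if missing:
        raise ValidationError(f"condition file {path} missing columns: {sorted(missing)}")
    return [Condition(*(str(row[c]) for c in need)) for _, row in df.iterrows()]


# -- ensemble / landscape / trace serialization ------------------------------

ENSEMBLE_FORMAT_VERSION = 1


def ensemble_to_json(ensemble: Ensemble) -> dict:
    return {
        "format_version": ENSEMBLE_FORMAT_VERSION,
        "n_features": ensemble.n_features,
        "members": [
            {
                "generation": m.generation,
                "seed": m.seed,
                "trees": [dataclasses.asdict(t) for t in m.trees],
            }
            for m in ensemble.members
        ],
    }


def ensemble_from_json(obj: dict) -> Ensemble:
    if obj.get("format_version") != ENSEMBLE_FORMAT_VERSION:
        raise ValidationError(f"unsupported ensemble format: {obj.get('format_version')}")
    members = [
        ForestMember(
            generation=m["generation"],
            seed=m["seed"],
            trees=tuple(
                Tree(
                    feature=tuple(t["feature"]),
                    threshold=tuple(t["threshold"]),
                    left=tuple(t["left"]),
                    right=tuple(t["right"]),
                    prob_pos=tuple(t["prob_pos"]),
                )
                for t in m["trees"]
            ),
        )
        for m in obj["members"]
    ]
    return Ensemble(members=members, n_features=obj["n_features"])


def landscape_to_json(landscape: SyntheticLandscape) -> dict:
    return {
        "base_yield": landscape.base_yield,
        "main_effects": landscape.main_effects,
        "interactions": [
            {"a": list(k[0]), "b": list(k[1]), "effect": v}
            for k, v in landscape.interactions.items()
        ],
        "noise_sd": landscape.noise_sd,
        "seed": landscape.seed,
    }


def landscape_from_json(obj: dict) -> SyntheticLandscape:
    return SyntheticLandscape(
        base_yield=obj["base_yield"],
        main_effects=obj["main_effects"],
        interactions={
            (tuple(e["a"]), tuple(e["b"])): e["effect"] for e in obj["interactions"]
        },
        noise_sd=obj["noise_sd"],
        seed=obj["seed"],
    )


def write_trace(trace: CampaignTrace, path: str | Path) -> None:
    """Line-delimited JSON: one object per iteration, then the summary."""
    with open(path, "w") as fh:
        for e in trace.entries:
            fh.write(json.dumps(e, sort_keys=True) + "\n")
        fh.write(json.dumps({"summary": trace.summary}, sort_keys=True) + "\n")


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValidationError(f"config {path} must be a mapping")
    return cfg


def file_checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(
    path: str | Path,
    config: dict,
    seed: int,
    catalog_dir: str | Path | None = None,
    stages: dict[str, float] | None = None,
) -> dict:
    """Record everything needed to replay a run bit-identically."""
    checksums = {}
    if catalog_dir is not None:
        for name, fname in CATALOG_FILES.items():
            p = Path(catalog_dir) / fname
            if p.exists():
                checksums[fname] = file_checksum(p)
    manifest = {
        "package_version": __version__,
        "config": config,
        "seed": seed,
        "catalog_checksums": checksums,
        "stage_timestamps": stages or {},
        "written_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
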