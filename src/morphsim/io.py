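"""TSV/GMT readers and writers.

Everything on disk is tab-separated text.  Output tables carry comment
headers (lines starting with '#') naming the producing stage, units and a
short config hash; readers skip comment lines.  Feature tables travel in
long format (subject_id, region_id, feature, value).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .parcellation import Parcellation
from .synthetic import SubjectFeatures


def config_hash(obj) -> str:
    """Short stable hash of a JSON-serializable configuration."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:8]


def write_tsv(df: pd.DataFrame, path, stage: str, units: str = "dimensionless",
              cfg_hash: str = "", index: bool = True) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# morphsim stage={stage} units={units} config={cfg_hash}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


# -- parcellation -----------------------------------------------------------

def write_parcellation(parc: Parcellation, path, cfg_hash: str = "") -> None:
    write_tsv(parc.table, path, stage="simulate", units="unit-sphere coordinates",
              cfg_hash=cfg_hash, index=False)


def read_parcellation(path) -> Parcellation:
    return Parcellation(read_tsv(path))


# -- cohort design ----------------------------------------------------------

def write_design(design: pd.DataFrame, path, cfg_hash: str = "") -> None:
    write_tsv(design, path, stage="simulate", units="age:years scores:ordinal",
              cfg_hash=cfg_hash, index=False)


def read_design(path) -> pd.DataFrame:
    d = read_tsv(path, dtype={"subject_id": str, "group": str, "sex": str})
    required = {"subject_id", "group", "age", "sex"}
    missing = required - set(d.columns)
    if missing:
        raise ValidationError(f"design table missing columns: {sorted(missing)}")
    return d


# -- feature tables ---------------------------------------------------------

def write_feature_tables(features: list, path, cfg_hash: str = "") -> None:
    """Write per-subject tables as one long-format TSV
    (subject_id, region_id, feature, value)."""
    frames = []
    for sf in features:
        long = sf.values.stack().reset_index()
        long.columns = ["region_id", "feature", "value"]
        long.insert(0, "subject_id", sf.subject_id)
        frames.append(long)
    write_tsv(pd.concat(frames, ignore_index=True), path, stage="simulate",
              units="morphometric (z-scored downstream)", cfg_hash=cfg_hash, index=False)


def read_feature_tables(path, parcellation: Parcellation | None = None) -> list:
    """Read a long-format feature TSV back into per-subject tables.

    Validates a complete region x feature grid per subject; duplicate
    (subject, region, feature) rows, unknown region ids and missing cells
    are itemized in the error message.
    """
    long = read_tsv(path, dtype={"subject_id": str, "feature": str})
    required = {"subject_id", "region_id", "feature", "value"}
    missing = required - set(long.columns)
    if missing:
        raise ValidationError(f"feature table missing columns: {sorted(missing)}")
    problems = []
    dup = long.duplicated(["subject_id", "region_id", "feature"], keep=False)
    if dup.any():
        for _, r in long[dup].drop_duplicates(["subject_id", "region_id", "feature"]).head(5).iterrows():
            problems.append(f"duplicate row subject={r.subject_id} region={r.region_id} feature={r.feature}")
    if parcellation is not None:
        unknown = set(long["region_id"]) - set(parcellation.region_ids.tolist())
        if unknown:
            problems.append(f"unknown region ids: {sorted(unknown)[:5]}")
    if long["value"].isna().any():
        bad = long[long["value"].isna()].head(5)
        for _, r in bad.iterrows():
            problems.append(f"missing value subject={r.subject_id} region={r.region_id} feature={r.feature}")
    if problems:
        raise ValidationError("invalid feature table:\n  " + "\n  ".join(problems))

    regions = np.sort(long["region_id"].unique())
    feat_order = list(dict.fromkeys(long["feature"]))
    tables = []
    for sid, grp in long.groupby("subject_id", sort=True):
        wide = grp.pivot(index="region_id", columns="feature", values="value")
        if wide.isna().any().any():
            holes = np.argwhere(wide.isna().to_numpy())
            r, f = holes[0]
            raise ValidationError(
                f"missing cell subject={sid} region={wide.index[r]} feature={wide.columns[f]}")
        if not np.array_equal(np.sort(wide.index.to_numpy()), regions):
            gone = sorted(set(regions) - set(wide.index))
            raise ValidationError(f"subject {sid} missing regions {gone[:5]}")
        tables.append(SubjectFeatures(str(sid), wide.reindex(index=regions, columns=feat_order)))
    return tables


# -- expression / gene sets -------------------------------------------------

def write_expression(expr: pd.DataFrame, path, cfg_hash: str = "") -> None:
    write_tsv(expr, path, stage="simulate", units="arbitrary expression",
              cfg_hash=cfg_hash, index=True)


def read_expression(path) -> pd.DataFrame:
    expr = read_tsv(path, index_col=0)
    if expr.isna().any().any():
        raise ValidationError("expression matrix contains missing values")
    if expr.columns.duplicated().any():
        dups = expr.columns[expr.columns.duplicated()].tolist()
        raise ValidationError(f"duplicate gene ids: {dups[:5]}")
    return expr


def read_gmt(path) -> dict:
    """Standard GMT: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets: dict = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(f"GMT line {ln}: expected >= 3 tab-separated fields")
            name, _desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            if name in sets:
                raise ValidationError(f"GMT line {ln}: duplicate set name {name!r}")
            if not genes:
                raise ValidationError(f"GMT line {ln}: set {name!r} is empty")
            sets[name] = set(genes)
    return sets


def write_gmt(gene_sets: dict, path, descriptions: dict | None = None) -> None:
    descriptions = descriptions or {}
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for name, genes in gene_sets.items():
            desc = descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *sorted(genes)]) + "\n")


# -- dense matrices ---------------------------------------------------------

def write_matrix(weights: np.ndarray, region_ids: np.ndarray, path, stage: str,
                 cfg_hash: str = "") -> None:
    df = pd.DataFrame(weights, index=pd.Index(region_ids, name="region_id"), columns=region_ids)
    write_tsv(df, path, stage=stage, units="Pearson r", cfg_hash=cfg_hash)


def read_matrix(path) -> pd.DataFrame:
    return read_tsv(path, index_col=0)
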