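"""Readers and writers for the pipeline's plain-text table formats.

All tables travel as TSV (CSV for ELISA plates) with fixed column sets;
writers are the inverse of readers so every generated table survives a
write -> read round trip unchanged up to float formatting.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import pandas as pd

__all__ = [
    "read_compendium", "write_compendium",
    "read_expression_matrix", "write_expression_matrix",
    "read_group_map", "write_group_map",
    "read_evidence", "write_evidence",
    "read_cq_table", "write_cq_table",
    "read_droplet_counts", "write_droplet_counts",
    "read_plasma_panel", "write_plasma_panel",
    "read_elisa_plate",
    "read_gene_list", "write_gene_list",
    "read_ortholog_map", "write_ortholog_map",
    "write_json", "read_json",
]

_SCHEMAS: dict[str, list[str]] = {
    "compendium": ["experiment_id", "gene_id", "log2_ratio"],
    "group_map": ["sample", "group"],
    "evidence": ["gene", "ca", "literature"],
    "cq": ["gene", "sample", "group", "is_reference", "cq"],
    "droplets": ["gene", "sample", "group", "well", "positives", "total"],
    "plasma": ["subject", "group", "age", "sex", "conc_ng_ml", "mrna_level"],
    "orthologs": ["human_gene", "rat_gene"],
}


def _read(path: str | Path, schema: str, **kwargs: Any) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", **kwargs)
    cols = _SCHEMAS[schema]
    missing = set(cols) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)} for {schema} table")
    return df[cols]


def _write(df: pd.DataFrame, path: str | Path, schema: str) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df[_SCHEMAS[schema]].to_csv(path, sep="\t", index=False, float_format="%.10g")
    return path


def read_compendium(path: str | Path) -> pd.DataFrame:
    return _read(path, "compendium")


def write_compendium(df: pd.DataFrame, path: str | Path) -> Path:
    return _write(df, path, "compendium")


def read_expression_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "gene"
    return df


def write_expression_matrix(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", float_format="%.10g")
    return path


def read_group_map(path: str | Path) -> pd.DataFrame:
    return _read(path, "group_map")


def write_group_map(df: pd.DataFrame, path: str | Path) -> Path:
    return _write(df, path, "group_map")


def read_evidence(path: str | Path) -> pd.DataFrame:
    df = _read(path, "evidence")
    for col in ("ca", "literature"):
        df[col] = df[col].astype(bool)
    return df


def write_evidence(df: pd.DataFrame, path: str | Path) -> Path:
    return _write(df, path, "evidence")


def read_cq_table(path: str | Path) -> pd.DataFrame:
    df = _read(path, "cq")
    df["is_reference"] = df["is_reference"].astype(bool)
    return df


def write_cq_table(df: pd.DataFrame, path: str | Path) -> Path:
    return _write(df, path, "cq")


def read_droplet_counts(path: str | Path) -> pd.DataFrame:
    return _read(path, "droplets")


def write_droplet_counts(df: pd.DataFrame, path: str | Path) -> Path:
    return _write(df, path, "droplets")


def read_plasma_panel(path: str | Path) -> pd.DataFrame:
    return _read(path, "plasma")


def write_plasma_panel(df: pd.DataFrame, path: str | Path) -> Path:
    return _write(df, path, "plasma")


def read_elisa_plate(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read an ELISA plate CSV (`role,id,conc_known,absorbance,replicate`).

    Returns (standards, samples); standards carry ``conc_known``.
    """
    df = pd.read_csv(path)
    required = {"role", "id", "conc_known", "absorbance", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    standards = df[df.role == "standard"].reset_index(drop=True)
    samples = df[df.role == "sample"].reset_index(drop=True)
    return standards, samples


def read_gene_list(path: str | Path) -> list[str]:
    text = Path(path).read_text()
    return [line.strip() for line in text.splitlines() if line.strip()]


def write_gene_list(genes: list[str], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text("\n".join(genes) + "\n")
    return path


def read_ortholog_map(path: str | Path) -> pd.DataFrame:
    return _read(path, "orthologs")


def write_ortholog_map(df: pd.DataFrame, path: str | Path) -> Path:
    return _write(df, path, "orthologs")


def write_json(obj: Any, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")
    return path


def read_json(path: str | Path) -> Any:
    return json.loads(Path(path).read_text())
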