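"""Readers/writers and validation for the package's tabular formats.

The single tabular dialect is TSV (UTF-8, '.' decimal); nested results are
JSON and configs may be YAML or JSON.  Validation errors carry 1-based data
row numbers.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .mutation_landscape import Donor, MutantClone, classify_effect, load_annotation_snapshot
from .progenitor_model import CloneRecord, ModelParams

__all__ = [
    "TableValidationError",
    "read_clone_table",
    "write_clone_table",
    "read_mutation_tables",
    "read_params",
    "write_params",
    "write_provenance",
]

CLONE_COLUMNS = ["animal_id", "condition", "t_days", "basal", "suprabasal"]
MUTATION_COLUMNS = ["donor_id", "sample_id", "gene", "aa_change", "consequence", "vaf"]
DONOR_COLUMNS = ["donor_id", "age", "bmi", "n_samples", "sample_area_mm2"]


class TableValidationError(ValueError):
    """A tabular input failed validation; message lists offending rows."""


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise TableValidationError(f"{path}: missing columns {missing}")


def read_clone_table(path: str | Path) -> list[CloneRecord]:
    """Read a lineage-tracing clone table (TSV) into typed records."""
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, CLONE_COLUMNS, path)
    records = []
    for i, row in enumerate(df.itertuples(), start=1):
        for col in ("basal", "suprabasal"):
            v = getattr(row, col)
            if pd.isna(v) or float(v) != int(v):
                raise TableValidationError(f"{path}: row {i}: {col}={v!r} is not an integer")
            if int(v) < 0:
                raise TableValidationError(f"{path}: row {i}: {col}={v!r} is negative")
        if float(row.t_days) < 0:
            raise TableValidationError(f"{path}: row {i}: t_days={row.t_days!r} is negative")
        records.append(CloneRecord(animal_id=str(row.animal_id),
                                   condition=str(row.condition),
                                   t_days=float(row.t_days),
                                   m=int(row.basal), n=int(row.suprabasal)))
    return records


def write_clone_table(records: list[CloneRecord], path: str | Path) -> None:
    df = pd.DataFrame([{"animal_id": r.animal_id, "condition": r.condition,
                        "t_days": r.t_days, "basal": r.m, "suprabasal": r.n}
                       for r in records], columns=CLONE_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_mutation_tables(mutations_path: str | Path, donors_path: str | Path
                         ) -> tuple[list[MutantClone], list[Donor]]:
    """Read and cross-validate the mutant-clone and donor tables."""
    mdf = pd.read_csv(mutations_path, sep="\t")
    ddf = pd.read_csv(donors_path, sep="\t")
    _require_columns(mdf, MUTATION_COLUMNS, mutations_path)
    _require_columns(ddf, DONOR_COLUMNS, donors_path)

    donors = []
    for i, row in enumerate(ddf.itertuples(), start=1):
        if float(row.age) < 0 or float(row.bmi) <= 0:
            raise TableValidationError(f"{donors_path}: row {i}: bad age/bmi")
        donors.append(Donor(donor_id=str(row.donor_id), age=float(row.age),
                            bmi=float(row.bmi), n_samples=int(row.n_samples),
                            sample_area_mm2=float(row.sample_area_mm2)))
    donor_ids = {d.donor_id for d in donors}

    annotation = load_annotation_snapshot()
    clones = []
    offenders = []
    for i, row in enumerate(mdf.itertuples(), start=1):
        if str(row.donor_id) not in donor_ids:
            offenders.append(f"row {i}: unknown donor_id {row.donor_id!r}")
            continue
        vaf = float(row.vaf)
        if not (0 < vaf <= 1):
            offenders.append(f"row {i}: vaf {vaf!r} outside (0, 1]")
            continue
        cls = classify_effect(str(row.aa_change), str(row.gene), annotation,
                              str(row.consequence))
        clones.append(MutantClone(donor_id=str(row.donor_id),
                                  sample_id=str(row.sample_id),
                                  gene=str(row.gene), aa_change=str(row.aa_change),
                                  vaf=vaf, consequence=str(row.consequence),
                                  effect_class=cls))
    if offenders:
        raise TableValidationError(f"{mutations_path}: " + "; ".join(offenders))
    return clones, donors


def read_params(path: str | Path) -> ModelParams:
    """Model parameters from a YAML or JSON mapping (rates per week)."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    return ModelParams.from_dict(data)


def write_params(params: ModelParams, path: str | Path) -> None:
    Path(path).write_text(json.dumps(params.to_dict(), indent=2) + "\n")


def write_provenance(out_dir: str | Path, config: dict) -> Path:
    """Write the machine-readable provenance file every run directory gets."""
    from . import __version__
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = {"package": "clonefate", "version": __version__, "config": config}
    path = out_dir / "provenance.json"
    path.write_text(json.dumps(payload, indent=2, default=str) + "\n")
    return path
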