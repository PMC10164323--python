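"""Readers and writers for molecule tables, predictions and reports.

Molecule tables are CSV/TSV with header columns ``id,smiles,descriptors``;
descriptors are ``;``-separated (configurable).  SDF input is accepted with
descriptors in a named property field.  All outputs are UTF-8, LF,
header-first; floats are written with 10 significant digits so reruns are
diff-stable.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd
from rdkit import Chem

from owsum.model import PredictionResult
from owsum.records import MoleculeRecord

__all__ = [
    "read_molecule_table",
    "write_molecule_table",
    "read_sdf",
    "write_predictions",
]


def read_molecule_table(
    path: str | Path, descriptor_sep: str = ";"
) -> list[MoleculeRecord]:
    """Read a CSV (or TSV, by extension) molecule table.

    Required columns: ``id``, ``smiles``; optional ``descriptors`` with
    ``descriptor_sep``-separated labels.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, dtype=str).fillna("")
    missing = {"id", "smiles"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        desc = (
            frozenset(
                d.strip() for d in str(row.get("descriptors", "")).split(
                    descriptor_sep
                ) if d.strip()
            )
            if "descriptors" in df.columns else frozenset()
        )
        records.append(MoleculeRecord(str(row["id"]), row["smiles"], desc))
    return records


def write_molecule_table(
    records: Sequence[MoleculeRecord],
    path: str | Path,
    descriptor_sep: str = ";",
) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.DataFrame(
        {
            "id": [r.id for r in records],
            "smiles": [r.smiles for r in records],
            "descriptors": [
                descriptor_sep.join(sorted(r.descriptors)) for r in records
            ],
        }
    )
    df.to_csv(path, sep=sep, index=False, lineterminator="\n")


def read_sdf(
    path: str | Path,
    descriptor_property: str = "descriptors",
    descriptor_sep: str = ";",
    id_property: str | None = None,
) -> list[MoleculeRecord]:
    """Read molecules from an SDF; descriptors come from a property field."""
    records = []
    supplier = Chem.SDMolSupplier(str(path))
    for i, mol in enumerate(supplier):
        if mol is None:
            raise ValueError(f"{path}: record {i} failed to parse")
        if id_property and mol.HasProp(id_property):
            mol_id = mol.GetProp(id_property)
        elif mol.HasProp("_Name") and mol.GetProp("_Name").strip():
            mol_id = mol.GetProp("_Name").strip()
        else:
            mol_id = f"mol_{i}"
        desc = frozenset()
        if mol.HasProp(descriptor_property):
            desc = frozenset(
                d.strip()
                for d in mol.GetProp(descriptor_property).split(descriptor_sep)
                if d.strip()
            )
        records.append(MoleculeRecord(mol_id, Chem.MolToSmiles(mol), desc))
    return records


def write_predictions(
    predictions: Sequence[PredictionResult],
    classes: Sequence[str],
    path: str | Path,
    descriptor_sep: str = ";",
) -> None:
    """Write ``id,status,predicted,score_<class>...`` CSV."""
    rows = []
    for p in predictions:
        row = {
            "id": p.object_id,
            "status": p.status,
            "predicted": descriptor_sep.join(sorted(p.predicted)),
        }
        for c in classes:
            row[f"score_{c}"] = float(f"{p.scores.get(c, 0.0):.10g}")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, lineterminator="\n")


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(obj, indent=1, sort_keys=False) + "\n", encoding="utf-8"
    )
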