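"""Molecular parsing, SMARTS feature catalogs and binary occurrence matrices.

Features are SMARTS substructure patterns.  A catalog is built by computing
the maximum common substructure (MCS) over every unordered pair of molecules
in a reference corpus and keeping each distinct MCS with at least
``min_atoms`` atoms.  Matching is presence-only: a molecule either contains
a pattern or it does not; multiplicities are never stored, which prevents an
overrepresentation of small fragments.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFMCS

from owsum.records import MoleculeParseError, MoleculeRecord

__all__ = [
    "parse_molecule",
    "canonical_smiles",
    "canonical_smarts",
    "FeatureCatalog",
    "build_catalog_mcs",
    "match_features",
    "OccurrenceMatrix",
    "build_occurrence_matrix",
    "load_bundled_corpus",
]

logger = logging.getLogger(__name__)


def parse_molecule(smiles: str) -> Chem.Mol:
    """Parse a SMILES string into an RDKit molecule.

    Raises :class:`MoleculeParseError` on malformed input; parsing is never
    deferred, so downstream code can assume valid molecular graphs.
    """
    if not smiles or not smiles.strip():
        raise MoleculeParseError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise MoleculeParseError(f"invalid SMILES {smiles!r}")
    return mol


def canonical_smiles(smiles: str) -> str:
    """Canonical form of a SMILES string (same input, same output)."""
    return Chem.MolToSmiles(parse_molecule(smiles))


class CatalogError(ValueError):
    """Raised for invalid SMARTS in a catalog or unusable corpus input."""


def _canonical_smarts(pattern: str) -> tuple[str, Chem.Mol]:
    """Round-trip a SMARTS through the toolkit's writer for de-duplication.

    Falls back to the exact input string if the round-trip is not stable.
    """
    query = Chem.MolFromSmarts(pattern)
    if query is None:
        raise CatalogError(f"invalid SMARTS pattern {pattern!r}")
    canon = Chem.MolToSmarts(query)
    if canon and Chem.MolFromSmarts(canon) is not None:
        return canon, Chem.MolFromSmarts(canon)
    return pattern, query


def canonical_smarts(pattern: str) -> str:
    """Canonical writer form of a SMARTS pattern (dedup key for catalogs)."""
    return _canonical_smarts(pattern)[0]


@dataclass(frozen=True)
class FeatureCatalog:
    """Ordered, de-duplicated list of SMARTS patterns with stable indices.

    ``provenance`` optionally records, per pattern, the corpus molecule-id
    pairs whose MCS produced it.
    """

    patterns: tuple[str, ...]
    provenance: dict[str, tuple[tuple[str, str], ...]] = field(
        default_factory=dict, compare=False
    )

    def __post_init__(self) -> None:
        object.__setattr__(self, "patterns", tuple(self.patterns))
        seen: set[str] = set()
        queries = []
        for p in self.patterns:
            canon, query = _canonical_smarts(p)
            if canon in seen:
                raise CatalogError(f"duplicate SMARTS pattern {p!r}")
            seen.add(canon)
            queries.append(query)
        object.__setattr__(self, "_queries", tuple(queries))

    def __len__(self) -> int:
        return len(self.patterns)

    @property
    def queries(self) -> tuple[Chem.Mol, ...]:
        return self._queries  # type: ignore[attr-defined]

    @classmethod
    def from_patterns(cls, patterns: Iterable[str]) -> "FeatureCatalog":
        """Build a catalog, canonicalizing and dropping duplicate patterns."""
        out: list[str] = []
        seen: set[str] = set()
        for p in patterns:
            canon, _ = _canonical_smarts(p)
            if canon not in seen:
                seen.add(canon)
                out.append(canon)
        return cls(tuple(out))

    @classmethod
    def from_file(cls, path: str | Path) -> "FeatureCatalog":
        """Read a catalog: UTF-8 text, one SMARTS per line, ``#`` comments."""
        lines = Path(path).read_text(encoding="utf-8").splitlines()
        patterns = [
            ln.strip() for ln in lines
            if ln.strip() and not ln.lstrip().startswith("#")
        ]
        return cls.from_patterns(patterns)

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(
            "".join(p + "\n" for p in self.patterns), encoding="utf-8"
        )


def build_catalog_mcs(
    corpus: Sequence[MoleculeRecord],
    min_atoms: int = 2,
    pair_timeout: float = 5.0,
) -> FeatureCatalog:
    """Build a SMARTS catalog by pairwise maximum common substructure.

    Every unordered pair of corpus molecules contributes its MCS if the MCS
    has at least ``min_atoms`` atoms.  Atoms are compared by element, bonds
    by bond order.  Duplicate patterns (after canonicalization) collapse to
    one entry; output order is first-appearance order over pairs taken in
    corpus order, so identical corpus + parameters give identical catalogs.

    A pair whose MCS search exceeds ``pair_timeout`` seconds is skipped with
    a logged warning rather than aborting the build.
    """
    if len(corpus) < 2:
        raise CatalogError("catalog construction requires at least 2 molecules")
    if min_atoms < 1:
        raise CatalogError("min_atoms must be >= 1")

    mols = [parse_molecule(rec.smiles) for rec in corpus]
    patterns: list[str] = []
    provenance: dict[str, list[tuple[str, str]]] = {}
    seen: set[str] = set()
    for (ia, ib) in combinations(range(len(corpus)), 2):
        res = rdFMCS.FindMCS(
            [mols[ia], mols[ib]], timeout=max(1, int(round(pair_timeout)))
        )
        if res.canceled:
            logger.warning(
                "MCS timed out for pair (%s, %s); skipping",
                corpus[ia].id, corpus[ib].id,
            )
            continue
        if res.numAtoms < min_atoms or not res.smartsString:
            continue
        canon, _ = _canonical_smarts(res.smartsString)
        if canon not in seen:
            seen.add(canon)
            patterns.append(canon)
            provenance[canon] = []
        provenance[canon].append((corpus[ia].id, corpus[ib].id))
    return FeatureCatalog(
        tuple(patterns),
        {p: tuple(v) for p, v in provenance.items()},
    )


def match_features(mol: Chem.Mol, catalog: FeatureCatalog) -> np.ndarray:
    """Binary feature vector: element j is 1 iff pattern j matches ``mol``.

    Repeated matches of the same pattern do not increase the value.
    """
    if len(catalog) == 0:
        raise CatalogError("catalog is empty")
    return np.fromiter(
        (1 if mol.HasSubstructMatch(q) else 0 for q in catalog.queries),
        dtype=np.uint8,
        count=len(catalog),
    )


@dataclass(frozen=True)
class OccurrenceMatrix:
    """Binary objects x features presence matrix.

    Row order follows ``object_ids``; column order follows the catalog's
    pattern order.  Values are strictly 0/1.
    """

    object_ids: tuple[str, ...]
    patterns: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=np.uint8)
        if vals.shape != (len(self.object_ids), len(self.patterns)):
            raise ValueError(
                f"occurrence matrix shape {vals.shape} does not match "
                f"{len(self.object_ids)} objects x {len(self.patterns)} features"
            )
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("occurrence values must be 0/1")
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "object_ids", tuple(self.object_ids))
        object.__setattr__(self, "patterns", tuple(self.patterns))

    def subset(self, rows: Sequence[int]) -> "OccurrenceMatrix":
        rows = list(rows)
        return OccurrenceMatrix(
            tuple(self.object_ids[r] for r in rows),
            self.patterns,
            self.values[rows, :],
        )

    def to_sparse_tsv(self, path: str | Path) -> None:
        """Write sparse coordinate TSV plus a JSON sidecar header.

        The TSV holds one ``object_id<TAB>feature_index<TAB>1`` line per
        present cell; the sidecar (``<path>.header.json``) lists object ids
        and patterns so the matrix round-trips losslessly.
        """
        path = Path(path)
        with path.open("w", encoding="utf-8") as fh:
            for k, oid in enumerate(self.object_ids):
                for j in np.flatnonzero(self.values[k]):
                    fh.write(f"{oid}\t{j}\t1\n")
        sidecar = {
            "object_ids": list(self.object_ids),
            "patterns": list(self.patterns),
        }
        Path(str(path) + ".header.json").write_text(
            json.dumps(sidecar, indent=1), encoding="utf-8"
        )

    @classmethod
    def from_sparse_tsv(cls, path: str | Path) -> "OccurrenceMatrix":
        path = Path(path)
        sidecar = json.loads(
            Path(str(path) + ".header.json").read_text(encoding="utf-8")
        )
        object_ids = tuple(sidecar["object_ids"])
        patterns = tuple(sidecar["patterns"])
        row_of = {oid: k for k, oid in enumerate(object_ids)}
        vals = np.zeros((len(object_ids), len(patterns)), dtype=np.uint8)
        for ln in path.read_text(encoding="utf-8").splitlines():
            if not ln.strip():
                continue
            oid, j, v = ln.split("\t")
            if int(v) == 1:
                vals[row_of[oid], int(j)] = 1
        return cls(object_ids, patterns, vals)


def build_occurrence_matrix(
    molecules: Sequence[MoleculeRecord], catalog: FeatureCatalog
) -> OccurrenceMatrix:
    """Match every molecule against every catalog pattern.

    All parse failures are collected and reported together, so a bad input
    file surfaces every offending record at once.
    """
    mols = []
    failures = []
    for rec in molecules:
        try:
            mols.append(parse_molecule(rec.smiles))
        except MoleculeParseError:
            failures.append(rec.id)
    if failures:
        raise MoleculeParseError(
            "molecules failed to parse: " + ", ".join(failures)
        )
    vals = np.zeros((len(molecules), len(catalog)), dtype=np.uint8)
    for k, mol in enumerate(mols):
        vals[k] = match_features(mol, catalog)
    return OccurrenceMatrix(
        tuple(r.id for r in molecules), catalog.patterns, vals
    )


def load_bundled_corpus() -> list[MoleculeRecord]:
    """Small bundled odorant corpus for catalog construction demos/tests.

    Each line of the packaged ``.smi`` file is ``SMILES<space>id``.
    """
    text = (
        resources.files("owsum.data")
        .joinpath("reference_corpus.smi")
        .read_text(encoding="utf-8")
    )
    records = []
    for ln in text.splitlines():
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        smiles, name = ln.split(None, 1)
        records.append(MoleculeRecord(id=name.strip(), smiles=smiles))
    return records
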