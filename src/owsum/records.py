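"""Core record types: molecules with odor labels, and binary label matrices.

A :class:`MoleculeRecord` couples an identifier, a canonical SMILES string
and a set of odor-descriptor labels.  A :class:`LabelMatrix` is the binary
object x class membership matrix the classifier trains on; objects may
belong to several classes (multilabel).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = ["MoleculeRecord", "LabelMatrix", "MoleculeParseError"]


class MoleculeParseError(ValueError):
    """Raised when a SMILES string cannot be parsed into a molecular graph."""


def _normalize_descriptors(descriptors: Iterable[str]) -> frozenset[str]:
    out = set()
    for d in descriptors:
        d = d.strip()
        if d:
            out.add(d)
    return frozenset(out)


@dataclass(frozen=True)
class MoleculeRecord:
    """One molecule: identifier, canonical SMILES, and its descriptor labels.

    SMILES validity is enforced at construction time via
    :func:`owsum.chem.parse_molecule`; invalid input raises
    :class:`MoleculeParseError` naming the offending record.  The descriptor
    set may be empty for unlabeled prediction inputs.
    """

    id: str
    smiles: str
    descriptors: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        from owsum.chem import canonical_smiles  # local import avoids a cycle

        try:
            canon = canonical_smiles(self.smiles)
        except MoleculeParseError as exc:
            raise MoleculeParseError(
                f"record {self.id!r}: {exc}"
            ) from None
        object.__setattr__(self, "smiles", canon)
        object.__setattr__(
            self, "descriptors", _normalize_descriptors(self.descriptors)
        )


@dataclass(frozen=True)
class LabelMatrix:
    """Binary object x class membership matrix.

    Rows follow ``object_ids``, columns follow ``classes``.  Values are
    strictly 0/1; an object may belong to multiple classes.
    """

    object_ids: tuple[str, ...]
    classes: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=np.uint8)
        if vals.shape != (len(self.object_ids), len(self.classes)):
            raise ValueError(
                f"label matrix shape {vals.shape} does not match "
                f"{len(self.object_ids)} objects x {len(self.classes)} classes"
            )
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("label matrix values must be 0/1")
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "object_ids", tuple(self.object_ids))
        object.__setattr__(self, "classes", tuple(self.classes))

    @classmethod
    def from_records(
        cls,
        records: Sequence[MoleculeRecord],
        classes: Sequence[str] | None = None,
    ) -> "LabelMatrix":
        """Build the membership matrix from molecule records.

        If ``classes`` is omitted, the sorted union of all descriptor labels
        is used, which keeps column order deterministic.
        """
        if classes is None:
            classes = sorted(set().union(*(r.descriptors for r in records)))
        classes = tuple(classes)
        idx = {c: i for i, c in enumerate(classes)}
        vals = np.zeros((len(records), len(classes)), dtype=np.uint8)
        for k, rec in enumerate(records):
            for d in rec.descriptors:
                if d in idx:
                    vals[k, idx[d]] = 1
        return cls(tuple(r.id for r in records), classes, vals)

    def members(self, label: str) -> frozenset[str]:
        """Object ids belonging to ``label``."""
        j = self.classes.index(label)
        return frozenset(
            oid for oid, v in zip(self.object_ids, self.values[:, j]) if v
        )

    def class_sizes(self) -> np.ndarray:
        return self.values.sum(axis=0).astype(np.int64)

    def truth_sets(self) -> list[frozenset[str]]:
        """Per-object sets of true class labels, in row order."""
        out = []
        for row in self.values:
            out.append(
                frozenset(c for c, v in zip(self.classes, row) if v)
            )
        return out

    def subset(self, rows: Sequence[int]) -> "LabelMatrix":
        rows = list(rows)
        return LabelMatrix(
            tuple(self.object_ids[r] for r in rows),
            self.classes,
            self.values[rows, :],
        )
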