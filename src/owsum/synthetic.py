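"""Synthetic molecule datasets with planted structure-odor associations.

The generator assembles chemically valid SMILES from a per-class motif
(e.g. an ester fragment for ``fruity``, a thioether for ``sickening``) plus
random linear-alkyl decoy fragments, then optionally corrupts labels.  It
exists so the whole pipeline — catalog, occurrence matrix, training,
cross-validation — is testable end to end without any external database;
it makes no claim of realistic odorant chemistry.

A deterministic four-molecule toy fixture with hand-checkable counts is
also provided; all worked examples in the documentation refer to it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from owsum.chem import (
    FeatureCatalog,
    OccurrenceMatrix,
    build_occurrence_matrix,
    canonical_smarts,
    canonical_smiles,
)
from owsum.records import LabelMatrix, MoleculeRecord

__all__ = ["SyntheticSpec", "generate_dataset", "default_catalog", "toy_fixture"]


# class motif -> (attachable core SMILES, SMARTS that detects it).
# Cores end in a chain atom so alkyl decoys can be appended by string
# concatenation without destroying the motif; motifs are mutually exclusive
# under linear-alkyl decoration.
MOTIF_LIBRARY: dict[str, tuple[str, str]] = {
    "ester": ("CCOC(=O)C", "[CX3](=[OX1])[OX2][#6]"),
    "thioether": ("CCSC", "[#16X2]"),
    "alcohol": ("OCC", "[OX2H1][CX4]"),
    "alkene": ("C=CC", "[CX3]=[CX3]"),
    "quaternary_alkyl": ("CC(C)(C)C", "[#6]([#6])([#6])([#6])[#6]"),
    "aromatic_ring": ("c1ccccc1", "c1ccccc1"),
    "aldehyde": ("O=CC", "[CX3H1](=[OX1])"),
    "nitrile": ("N#CC", "[NX1]#[CX2]"),
}

# default 6-class study: odor descriptor -> motif, echoing known
# structure-odor associations (esters smell fruity, sulfur sickening, ...)
DEFAULT_CLASS_MOTIFS: dict[str, str] = {
    "fruity": "ester",
    "sickening": "thioether",
    "medicinal": "alcohol",
    "floral": "alkene",
    "woody": "quaternary_alkyl",
    "perfumery": "aromatic_ring",
}

DECOY_FRAGMENTS = ("C", "CC", "CCC", "CCCC")

# generic patterns that appear in (nearly) every generated molecule; they
# carry zero idf and exercise the feature-selection path
GENERIC_PATTERNS = ("[CX4]", "[#6][#6]", "[CH3]")


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one generated dataset.

    ``class_motifs`` maps each odor class to a motif name from
    :data:`MOTIF_LIBRARY`.  With probability ``noise`` a molecule's label is
    replaced by a random other class; with probability ``multilabel`` a
    second random label is added.  ``seed`` fully determines the output.
    """

    class_motifs: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_MOTIFS)
    )
    n_per_class: int = 10
    noise: float = 0.0
    multilabel: float = 0.0
    max_decoys: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.class_motifs:
            raise ValueError("at least one class is required")
        unknown = set(self.class_motifs.values()) - set(MOTIF_LIBRARY)
        if unknown:
            raise ValueError(f"unknown motifs: {sorted(unknown)}")
        if not (0 <= self.noise <= 1 and 0 <= self.multilabel <= 1):
            raise ValueError("noise and multilabel rates must lie in [0, 1]")
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")


def _assemble(core: str, decoys: Sequence[str]) -> str:
    return core + "".join(decoys)


def generate_dataset(
    spec: SyntheticSpec,
) -> tuple[list[MoleculeRecord], dict[str, str]]:
    """Generate molecules with planted class motifs.

    Returns the molecule records and the ground-truth map
    ``class -> motif SMARTS``.  Every molecule's SMILES contains its
    *structural* class motif regardless of any label corruption: noise and
    multilabel act on labels only, emulating panelist disagreement rather
    than chemistry.
    """
    rng = np.random.default_rng(spec.seed)
    classes = list(spec.class_motifs)
    records: list[MoleculeRecord] = []
    for cls in classes:
        core = MOTIF_LIBRARY[spec.class_motifs[cls]][0]
        for m in range(spec.n_per_class):
            smiles = None
            for _ in range(20):  # bounded retries for invalid assemblies
                n_decoys = int(rng.integers(0, spec.max_decoys + 1))
                decoys = [
                    DECOY_FRAGMENTS[int(i)]
                    for i in rng.integers(0, len(DECOY_FRAGMENTS), n_decoys)
                ]
                candidate = _assemble(core, decoys)
                try:
                    smiles = canonical_smiles(candidate)
                    break
                except ValueError:
                    continue
            if smiles is None:
                raise RuntimeError(
                    f"could not assemble a valid molecule for class {cls!r}"
                )
            labels = {cls}
            if spec.noise > 0 and rng.random() < spec.noise:
                others = [c for c in classes if c != cls]
                labels = {others[int(rng.integers(0, len(others)))]}
            if spec.multilabel > 0 and rng.random() < spec.multilabel:
                others = [c for c in classes if c not in labels]
                if others:
                    labels.add(others[int(rng.integers(0, len(others)))])
            records.append(
                MoleculeRecord(
                    id=f"{cls}_{m:03d}", smiles=smiles,
                    descriptors=frozenset(labels),
                )
            )
    # canonical writer form so patterns compare equal to catalog entries
    motif_map = {
        cls: canonical_smarts(MOTIF_LIBRARY[motif][1])
        for cls, motif in spec.class_motifs.items()
    }
    return records, motif_map


def default_catalog(motif_map: Mapping[str, str]) -> FeatureCatalog:
    """Catalog of the planted motif patterns plus generic decoy patterns.

    The generic patterns occur in essentially every molecule and therefore
    carry zero idf, exercising idf-based feature selection.
    """
    return FeatureCatalog.from_patterns(
        list(dict.fromkeys(motif_map.values())) + list(GENERIC_PATTERNS)
    )


@dataclass(frozen=True)
class ToyFixture:
    """Four molecules, three features, two classes — fully hand-checkable."""

    records: tuple[MoleculeRecord, ...]
    catalog: FeatureCatalog
    occurrence: OccurrenceMatrix
    labels: LabelMatrix
    feature_names: tuple[str, ...]  # f1..f3 aliases for the SMARTS columns


def toy_fixture() -> ToyFixture:
    """The worked 4-molecule example used throughout the documentation.

    ======  =============  ================  =====
    id      molecule       features          class
    ======  =============  ================  =====
    M1      phenol         f1 (OH), f2 (ar)  A
    M2      ethanol        f1 (OH)           A
    M3      acetophenone   f2 (ar), f3 (C=O) B
    M4      acetone        f3 (C=O)          B
    ======  =============  ================  =====

    giving the occurrence matrix [[1,1,0],[1,0,0],[0,1,1],[0,0,1]].
    """
    records = (
        MoleculeRecord("M1", "c1ccccc1O", frozenset({"A"})),
        MoleculeRecord("M2", "CCO", frozenset({"A"})),
        MoleculeRecord("M3", "CC(=O)c1ccccc1", frozenset({"B"})),
        MoleculeRecord("M4", "CC(C)=O", frozenset({"B"})),
    )
    catalog = FeatureCatalog.from_patterns(
        ["[OX2H1]", "c1ccccc1", "[CX3](=[OX1])[#6]"]
    )
    occ = build_occurrence_matrix(records, catalog)
    labels = LabelMatrix.from_records(records, classes=("A", "B"))
    return ToyFixture(records, catalog, occ, labels, ("f1", "f2", "f3"))
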