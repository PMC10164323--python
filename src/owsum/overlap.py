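"""Descriptor-overlap metric and panel-data preprocessing.

Odor panels yield many semantically redundant descriptors.  The overlap of
two descriptors is the number of molecules carrying both divided by the
molecule count of the rarer one: 1 means one descriptor's molecule set
contains the other's, 0 means the sets are disjoint.  Screening out
descriptors with high mean overlap leaves a selective label set the
classifier can learn from.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from owsum.records import LabelMatrix

__all__ = [
    "descriptor_overlap",
    "overlap_matrix",
    "mean_overlap",
    "OverlapMatrix",
    "PreprocessReport",
    "preprocess_panel",
    "read_panel_csv",
]


def _member_masks(labels: LabelMatrix) -> np.ndarray:
    return labels.values.astype(bool)


def descriptor_overlap(desc1: str, desc2: str, labels: LabelMatrix) -> float:
    """Shared-molecule count over the rarer descriptor's molecule count.

    ``|M_desc1 ∩ M_desc2| / min(|M_desc1|, |M_desc2|)``, in [0, 1].
    Raises for a descriptor with zero molecules (undefined).
    """
    masks = _member_masks(labels)
    j1 = labels.classes.index(desc1)
    j2 = labels.classes.index(desc2)
    n1, n2 = int(masks[:, j1].sum()), int(masks[:, j2].sum())
    if n1 == 0 or n2 == 0:
        raise ValueError(
            f"descriptor overlap undefined: {desc1 if n1 == 0 else desc2!r} "
            "has no molecules"
        )
    shared = int((masks[:, j1] & masks[:, j2]).sum())
    return shared / min(n1, n2)


@dataclass(frozen=True)
class OverlapMatrix:
    """Symmetric descriptor x descriptor overlap matrix, values in [0, 1]."""

    descriptors: tuple[str, ...]
    values: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.descriptors, columns=self.descriptors
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index_label="descriptor")


def overlap_matrix(labels: LabelMatrix) -> OverlapMatrix:
    """All pairwise descriptor overlaps (heat-map / chord-diagram input)."""
    if len(labels.classes) < 2:
        raise ValueError("overlap matrix requires at least 2 descriptors")
    masks = _member_masks(labels)
    counts = masks.sum(axis=0)
    if (counts == 0).any():
        empty = [c for c, n in zip(labels.classes, counts) if n == 0]
        raise ValueError(f"descriptors without molecules: {empty}")
    shared = masks.T.astype(np.int64) @ masks.astype(np.int64)
    rarer = np.minimum.outer(counts, counts)
    return OverlapMatrix(labels.classes, shared / rarer)


def mean_overlap(desc: str, matrix: OverlapMatrix) -> float:
    """Mean overlap of a descriptor with every *other* descriptor."""
    if len(matrix.descriptors) < 2:
        raise ValueError("mean overlap undefined for a single descriptor")
    i = matrix.descriptors.index(desc)
    others = [j for j in range(len(matrix.descriptors)) if j != i]
    return float(matrix.values[i, others].mean())


def shared_count_edges(labels: LabelMatrix) -> pd.DataFrame:
    """Chord-diagram edge list: ``desc1, desc2, shared_count`` per pair."""
    masks = _member_masks(labels)
    rows = []
    for a in range(len(labels.classes)):
        for b in range(a + 1, len(labels.classes)):
            rows.append(
                {
                    "desc1": labels.classes[a],
                    "desc2": labels.classes[b],
                    "shared_count": int((masks[:, a] & masks[:, b]).sum()),
                }
            )
    return pd.DataFrame(rows, columns=["desc1", "desc2", "shared_count"])


@dataclass
class PreprocessReport:
    """Counts at every stage of the panel preprocessing pipeline."""

    stages: list[dict] = field(default_factory=list)

    def record(self, stage: str, n_molecules: int, n_descriptors: int,
               dropped: Sequence[str] = ()) -> None:
        self.stages.append(
            {
                "stage": stage,
                "n_molecules": n_molecules,
                "n_descriptors": n_descriptors,
                "dropped": list(dropped),
            }
        )

    def to_dict(self) -> dict:
        return {"stages": self.stages}


def read_panel_csv(
    path: str | Path,
    molecule_column: str | None = None,
    column_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Read a molecules x descriptors percent-applicability table.

    The first column (or ``molecule_column``) indexes molecules; remaining
    columns are descriptors with percent values in [0, 100].  ``column_map``
    renames raw column headers to descriptor labels, accommodating panel
    exports whose headers carry extra annotation.
    """
    df = pd.read_csv(path)
    if molecule_column is None:
        molecule_column = df.columns[0]
    df = df.set_index(molecule_column)
    if column_map:
        df = df.rename(columns=dict(column_map))
    values = df.to_numpy(dtype=float)
    if np.nanmin(values) < 0 or np.nanmax(values) > 100:
        raise ValueError("applicability values must lie in [0, 100]")
    return df


def preprocess_panel(
    raw: pd.DataFrame,
    applicability_min: float = 25.0,
    min_molecules: int = 10,
    mean_overlap_max: float = 0.49,
    manual_drop: Sequence[str] = (),
    iterative_overlap: bool = False,
) -> tuple[dict[str, frozenset[str]], PreprocessReport]:
    """Turn a raw percent-applicability panel into multilabel descriptor sets.

    Pipeline, applied in order:

    1. assign a descriptor to a molecule iff applicability >= ``applicability_min``
       (inclusive);
    2. keep descriptors with >= ``min_molecules`` molecules (inclusive);
    3. drop descriptors whose mean overlap with the other survivors is
       strictly greater than ``mean_overlap_max`` (computed once on the
       post-stage-2 set by default; ``iterative_overlap`` recomputes after
       each single worst-offender drop);
    4. drop ``manual_drop`` labels;
    5. drop molecules left without descriptors.

    Returns a molecule-id -> descriptor-set mapping plus a stage-by-stage
    report of surviving counts.
    """
    if not (0 <= applicability_min <= 100):
        raise ValueError("applicability_min must be in [0, 100]")
    if min_molecules < 1:
        raise ValueError("min_molecules must be >= 1")
    if not (0 <= mean_overlap_max <= 1):
        raise ValueError("mean_overlap_max must be in [0, 1]")

    report = PreprocessReport()
    report.record("input", len(raw.index), len(raw.columns))

    # stage 1: binarize at the applicability threshold
    binary = (raw.fillna(0.0) >= applicability_min)
    with_any = binary.any(axis=1)
    report.record(
        "applicability_threshold",
        int(with_any.sum()),
        int(binary.any(axis=0).sum()),
    )

    # stage 2: descriptor support filter
    support = binary.sum(axis=0)
    kept = [c for c in binary.columns if support[c] >= min_molecules]
    dropped2 = [c for c in binary.columns if support[c] < min_molecules]
    binary = binary[kept]
    report.record(
        "min_molecules",
        int(binary.any(axis=1).sum()),
        len(kept),
        dropped=dropped2,
    )

    # stage 3: mean-overlap screen on the surviving descriptor set
    def _labels_from(binary_df: pd.DataFrame) -> LabelMatrix:
        return LabelMatrix(
            tuple(str(i) for i in binary_df.index),
            tuple(binary_df.columns),
            binary_df.to_numpy(dtype=np.uint8),
        )

    dropped3: list[str] = []
    if len(binary.columns) >= 2:
        if iterative_overlap:
            while len(binary.columns) >= 2:
                mat = overlap_matrix(_labels_from(binary))
                means = {
                    d: mean_overlap(d, mat) for d in binary.columns
                }
                worst = max(means, key=lambda d: means[d])
                if means[worst] <= mean_overlap_max:
                    break
                dropped3.append(worst)
                binary = binary.drop(columns=[worst])
        else:
            mat = overlap_matrix(_labels_from(binary))
            dropped3 = [
                d for d in binary.columns
                if mean_overlap(d, mat) > mean_overlap_max
            ]
            binary = binary.drop(columns=dropped3)
    report.record(
        "mean_overlap",
        int(binary.any(axis=1).sum()),
        len(binary.columns),
        dropped=dropped3,
    )

    # stage 4: manual drops
    dropped4 = [d for d in manual_drop if d in binary.columns]
    binary = binary.drop(columns=dropped4)
    report.record(
        "manual_drop",
        int(binary.any(axis=1).sum()),
        len(binary.columns),
        dropped=dropped4,
    )

    # stage 5: molecules left without any descriptor
    binary = binary.loc[binary.any(axis=1)]
    report.record("nonempty_molecules", len(binary.index), len(binary.columns))

    assignments = {
        str(mol): frozenset(
            d for d in binary.columns if binary.loc[mol, d]
        )
        for mol in binary.index
    }
    return assignments, report
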