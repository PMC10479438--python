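"""Core domain types and file I/O for multi-study 16S count data.

The canonical in-memory orientation for count tables is samples x OTUs;
every downstream operation assumes it.  Trees are :class:`skbio.TreeNode`
objects and pairwise dissimilarities are :class:`skbio.DistanceMatrix`
objects, so the usual scikit-bio toolkit applies directly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

logger = logging.getLogger(__name__)

__all__ = [
    "Phase",
    "CountTable",
    "SampleMetadata",
    "StudyDataset",
    "StudyRegistryRecord",
    "TraitVector",
    "read_count_table",
    "read_metadata",
    "read_registry",
    "assemble_study",
    "read_newick",
    "write_newick",
    "validate_trait_vector",
]


class Phase(str, Enum):
    """Sampling phase relative to the fiber intervention."""

    PRE = "pre"
    POST = "post"

    @classmethod
    def parse(cls, token) -> "Phase":
        if isinstance(token, cls):
            return token
        try:
            return cls(str(token).strip().lower())
        except ValueError:
            raise ValueError(
                f"unknown phase {token!r}; allowed values: 'pre', 'post'"
            ) from None


class ValidationError(ValueError):
    """Raised when an input violates a domain invariant."""


@dataclass(frozen=True)
class CountTable:
    """Integer read counts, rows = samples, columns = OTUs.

    Wraps a pandas DataFrame and enforces non-negativity, integrality
    and id uniqueness at construction time.
    """

    data: pd.DataFrame

    def __post_init__(self):
        df = self.data
        if df.shape[0] < 1 or df.shape[1] < 1:
            raise ValidationError("count table needs at least 1 sample and 1 OTU")
        if df.index.duplicated().any():
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dupes}")
        if df.columns.duplicated().any():
            dupes = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate OTU ids: {dupes}")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("count table body must be numeric")
        if (values < 0).any():
            raise ValidationError("negative counts are not allowed")
        if not np.allclose(values, np.round(values)):
            raise ValidationError("fractional counts are not allowed")
        object.__setattr__(
            self,
            "data",
            pd.DataFrame(
                np.asarray(np.round(values), dtype=np.int64),
                index=df.index.astype(str),
                columns=df.columns.astype(str),
            ),
        )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def counts(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def sample_totals(self) -> pd.Series:
        return self.data.sum(axis=1)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_otus(self) -> int:
        return self.data.shape[1]

    def select_samples(self, sample_ids: Sequence[str]) -> "CountTable":
        return CountTable(self.data.loc[list(sample_ids)])

    def select_otus(self, otu_ids: Sequence[str]) -> "CountTable":
        return CountTable(self.data.loc[:, list(otu_ids)])

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index_label="sample_id")

    def __eq__(self, other) -> bool:
        return isinstance(other, CountTable) and self.data.equals(other.data)


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample annotations used by the paired pre/post analyses."""

    sample_id: str
    subject_id: str
    study_id: str
    timepoint_day: int
    phase: Phase

    def __post_init__(self):
        if self.timepoint_day < 0:
            raise ValidationError(
                f"sample {self.sample_id}: timepoint_day must be >= 0"
            )
        object.__setattr__(self, "phase", Phase.parse(self.phase))


@dataclass(frozen=True)
class StudyDataset:
    """A count table joined with validated metadata for one intervention."""

    study_id: str
    table: CountTable
    metadata: tuple[SampleMetadata, ...]

    def __post_init__(self):
        object.__setattr__(self, "metadata", tuple(self.metadata))
        meta_ids = [m.sample_id for m in self.metadata]
        if len(set(meta_ids)) != len(meta_ids):
            raise ValidationError(f"{self.study_id}: duplicate metadata sample ids")
        if set(meta_ids) != set(self.table.sample_ids):
            missing = set(self.table.sample_ids) - set(meta_ids)
            extra = set(meta_ids) - set(self.table.sample_ids)
            raise ValidationError(
                f"{self.study_id}: metadata/table sample mismatch "
                f"(missing from metadata: {sorted(missing)}; "
                f"absent from table: {sorted(extra)})"
            )
        subjects = {m.subject_id for m in self.metadata}
        if len(subjects) < 2:
            raise ValidationError(f"{self.study_id}: need >= 2 subjects")
        phases = {m.phase for m in self.metadata}
        for phase in Phase:
            if phase not in phases:
                raise ValidationError(f"{self.study_id}: missing phase: {phase.value}")

    @property
    def subjects(self) -> list[str]:
        seen: dict[str, None] = {}
        for m in self.metadata:
            seen.setdefault(m.subject_id, None)
        return list(seen)

    def metadata_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [m.sample_id for m in self.metadata],
                "subject_id": [m.subject_id for m in self.metadata],
                "study_id": [m.study_id for m in self.metadata],
                "timepoint_day": [m.timepoint_day for m in self.metadata],
                "phase": [m.phase.value for m in self.metadata],
            }
        ).set_index("sample_id")

    def samples_for(self, subject_id: str, phase: Phase) -> list[SampleMetadata]:
        return [
            m
            for m in self.metadata
            if m.subject_id == subject_id and m.phase == phase
        ]


@dataclass(frozen=True)
class StudyRegistryRecord:
    """One row of the study registry (design facts for an intervention)."""

    study_id: str
    fiber_type: str
    fiber_grams: float
    duration_days: int
    n_timepoints: int
    n_subjects: int
    n_samples: int

    def __post_init__(self):
        if self.duration_days < 1:
            raise ValidationError(f"{self.study_id}: duration_days must be >= 1")
        if self.n_samples < self.n_subjects:
            raise ValidationError(
                f"{self.study_id}: n_samples ({self.n_samples}) < "
                f"n_subjects ({self.n_subjects})"
            )


#: Binary trait states keyed by OTU id (1 = responder in the analyzed
#: direction, 0 = not).
TraitVector = dict[str, int]


def validate_trait_vector(trait: TraitVector, tree: TreeNode) -> None:
    """Check that trait keys are tree tips and states are binary."""
    tips = {t.name for t in tree.tips()}
    bad_keys = set(trait) - tips
    if bad_keys:
        raise ValidationError(f"trait keys not in tree tips: {sorted(bad_keys)[:5]}")
    bad_vals = {v for v in trait.values() if v not in (0, 1)}
    if bad_vals:
        raise ValidationError(f"trait states must be 0/1, got {sorted(bad_vals)}")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_count_table(
    path: str | Path, orientation: str = "samples_by_otus"
) -> CountTable:
    """Read a TSV count table, returning the canonical samples x OTUs layout.

    Parameters
    ----------
    path
        Tab-separated file with a header row; the first column holds row ids.
    orientation
        ``"samples_by_otus"`` if file rows are samples, ``"otus_by_samples"``
        if file rows are OTUs (the table is transposed on read).
    """
    if orientation not in ("samples_by_otus", "otus_by_samples"):
        raise ValueError(f"unknown orientation: {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        if converted.isna().any() and not df[col].isna().any():
            bad_row = df.index[converted.isna()][0]
            raise ValueError(
                f"non-numeric count at row {bad_row!r}, column {col!r} in {path}"
            )
        df[col] = converted
    if orientation == "otus_by_samples":
        df = df.T
    return CountTable(df)


_METADATA_COLUMNS = ["sample_id", "subject_id", "study_id", "timepoint_day", "phase"]


def read_metadata(path: str | Path) -> list[SampleMetadata]:
    """Read per-sample metadata from TSV, in file order."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"metadata file {path} lacks required columns: {missing}")
    return [
        SampleMetadata(
            sample_id=row.sample_id,
            subject_id=row.subject_id,
            study_id=row.study_id,
            timepoint_day=int(row.timepoint_day),
            phase=Phase.parse(row.phase),
        )
        for row in df.itertuples()
    ]


def write_metadata(metadata: Iterable[SampleMetadata], path: str | Path) -> None:
    rows = [
        (m.sample_id, m.subject_id, m.study_id, m.timepoint_day, m.phase.value)
        for m in metadata
    ]
    pd.DataFrame(rows, columns=_METADATA_COLUMNS).to_csv(path, sep="\t", index=False)


def read_registry(path: str | Path) -> list[StudyRegistryRecord]:
    """Read a study registry TSV (one row per study/intervention)."""
    df = pd.read_csv(path, sep="\t")
    return [
        StudyRegistryRecord(
            study_id=str(row.study_id),
            fiber_type=str(row.fiber_type),
            fiber_grams=float(row.fiber_grams),
            duration_days=int(row.duration_days),
            n_timepoints=int(row.n_timepoints),
            n_subjects=int(row.n_subjects),
            n_samples=int(row.n_samples),
        )
        for row in df.itertuples()
    ]


def assemble_study(
    table: CountTable,
    metadata: Sequence[SampleMetadata],
    study_id: str,
) -> StudyDataset:
    """Join a count table with metadata into a validated StudyDataset.

    Metadata rows for samples absent from the table are dropped with a
    warning; table samples missing from the metadata are an error.
    """
    table_ids = set(table.sample_ids)
    kept, dropped = [], []
    for m in metadata:
        (kept if m.sample_id in table_ids else dropped).append(m)
    if dropped:
        logger.warning(
            "%s: dropping %d metadata rows without table samples: %s",
            study_id,
            len(dropped),
            [m.sample_id for m in dropped],
        )
    missing = table_ids - {m.sample_id for m in kept}
    if missing:
        raise ValidationError(
            f"{study_id}: table samples missing from metadata: {sorted(missing)}"
        )
    return StudyDataset(study_id=study_id, table=table, metadata=tuple(kept))


def read_newick(path: str | Path) -> TreeNode:
    """Read a rooted tree with branch lengths from a Newick file."""
    try:
        tree = TreeNode.read(str(path), format="newick")
    except Exception as exc:  # skbio raises several parse error types
        raise ValueError(f"failed to parse Newick file {path}: {exc}") from exc
    return tree


def write_newick(tree: TreeNode, path: str | Path) -> None:
    """Write a tree as Newick; branch lengths keep 10 significant digits."""
    tree.write(str(path), format="newick")
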