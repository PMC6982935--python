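"""Core in-memory containers shared across the pipeline.

The pipeline turns protein sequences (plus optional per-residue profile
matrices produced by external predictors) into fixed-length feature vectors,
selects informative columns, and fits a classifier.  The containers here are
deliberately thin wrappers around numpy/pandas objects with the invariants the
pipeline relies on checked at construction time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Canonical order of the 20 standard amino acids used for every
#: composition-style feature block (alphabetical one-letter codes).
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

#: Ambiguity codes tolerated on input; all are normalised to ``X``.
AMBIGUITY_CODES: frozenset = frozenset("BZUX")

#: Class labels: single-stranded binders are the positive class.
POSITIVE_LABEL = "SSB"
NEGATIVE_LABEL = "DSB"


class StrandclassError(ValueError):
    """Base class for input/contract violations raised by this package."""


@dataclass(frozen=True)
class ProteinRecord:
    """One protein: an identifier and its amino-acid sequence.

    The sequence is uppercase over the 20 standard one-letter codes plus
    ``X`` (any tolerated ambiguity code is mapped to ``X`` on ingest).
    """

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise StrandclassError("protein record requires a non-empty id")
        if len(self.sequence) < 1:
            raise StrandclassError(f"protein {self.id!r}: empty sequence")
        bad = sorted(set(self.sequence) - set(AMINO_ACIDS) - {"X"})
        if bad:
            raise StrandclassError(
                f"protein {self.id!r}: invalid residue characters {bad}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ResidueProfile:
    """A properties-by-positions numeric matrix for one protein.

    Rows are named properties (PSSM substitution-score columns, surface
    accessibility channels, disorder propensities, physicochemical scales...);
    columns are sequence positions, 1-based position ``j`` stored at column
    index ``j - 1``.
    """

    protein_id: str
    property_names: list
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise StrandclassError(
                f"profile for {self.protein_id!r}: values must be a 2-D matrix"
            )
        if self.values.shape[0] != len(self.property_names):
            raise StrandclassError(
                f"profile for {self.protein_id!r}: {len(self.property_names)} "
                f"property names but {self.values.shape[0]} rows"
            )
        if self.values.shape[0] < 1:
            raise StrandclassError(
                f"profile for {self.protein_id!r}: needs at least one property"
            )
        if not np.all(np.isfinite(self.values)):
            raise StrandclassError(
                f"profile for {self.protein_id!r}: non-finite cells"
            )

    @property
    def n_properties(self) -> int:
        return self.values.shape[0]

    @property
    def length(self) -> int:
        return self.values.shape[1]


@dataclass
class PropertyTable:
    """Map from a key (one-letter residue or k-mer) to named numeric properties."""

    property_names: list
    entries: dict

    def __post_init__(self) -> None:
        width = len(self.property_names)
        if width < 1:
            raise StrandclassError("property table needs at least one property")
        self.entries = {
            k: np.asarray(v, dtype=float).reshape(-1) for k, v in self.entries.items()
        }
        for key, vec in self.entries.items():
            if vec.shape[0] != width:
                raise StrandclassError(
                    f"property table entry {key!r} has {vec.shape[0]} values, "
                    f"expected {width}"
                )

    @property
    def n_properties(self) -> int:
        return len(self.property_names)

    def vector(self, key: str) -> np.ndarray:
        return self.entries[key]

    def column_means(self) -> np.ndarray:
        """Per-property mean over all entries (the imputation value for
        residues/k-mers absent from the table).  Cached; tables are treated
        as immutable once constructed."""
        cached = getattr(self, "_column_means", None)
        if cached is None:
            cached = np.mean(np.stack(list(self.entries.values())), axis=0)
            object.__setattr__(self, "_column_means", cached)
        return cached

    def require_standard_residues(self) -> None:
        missing = sorted(set(AMINO_ACIDS) - set(self.entries))
        if missing:
            raise StrandclassError(
                f"property table missing standard residues: {missing}"
            )


@dataclass
class FeatureBlock:
    """A named fixed-length feature vector produced by one extractor.

    ``source`` names the extractor family (OAAC, dipeptide, PSSM, AAindex,
    DisEMBL, NetSurfP, LSE); ``labels`` are per-column names unique within the
    block and stable across proteins for a fixed configuration.
    """

    source: str
    labels: list
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).reshape(-1)
        if len(self.labels) != self.values.shape[0]:
            raise StrandclassError(
                f"feature block {self.source!r}: {len(self.labels)} labels but "
                f"{self.values.shape[0]} values"
            )
        if len(set(self.labels)) != len(self.labels):
            raise StrandclassError(
                f"feature block {self.source!r}: duplicate column labels"
            )

    def __len__(self) -> int:
        return self.values.shape[0]


def concat_blocks(blocks: Sequence[FeatureBlock]) -> FeatureBlock:
    """Concatenate blocks into one vector, prefixing labels with the source."""
    labels: list = []
    values: list = []
    for b in blocks:
        labels.extend(f"{b.source}:{lab}" for lab in b.labels)
        values.append(b.values)
    return FeatureBlock(
        source="concat",
        labels=labels,
        values=np.concatenate(values) if values else np.empty(0),
    )


@dataclass
class FeatureMatrix:
    """Samples x labelled-columns numeric matrix with per-sample class labels.

    ``labels`` take values in {SSB, DSB} (SSB positive).  Backed by a plain
    numpy array plus explicit id/column lists so round-trips through TSV are
    exact in structure.
    """

    sample_ids: list
    labels: list
    columns: list
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            self.values = self.values.reshape(len(self.sample_ids), -1)
        n, p = self.values.shape
        if n != len(self.sample_ids) or n != len(self.labels):
            raise StrandclassError(
                "feature matrix: sample ids, labels and rows must agree "
                f"(got {len(self.sample_ids)} ids, {len(self.labels)} labels, {n} rows)"
            )
        if p != len(self.columns):
            raise StrandclassError(
                f"feature matrix: {len(self.columns)} column names but {p} columns"
            )
        if len(set(self.columns)) != len(self.columns):
            raise StrandclassError("feature matrix: duplicate column names")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise StrandclassError("feature matrix: duplicate sample ids")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]

    def y(self) -> np.ndarray:
        """Integer class vector: 1 for the positive class (SSB), 0 otherwise."""
        return np.asarray([1 if l == POSITIVE_LABEL else 0 for l in self.labels])

    def subset_columns(self, keep: Iterable[str]) -> "FeatureMatrix":
        keep = list(keep)
        index = {c: i for i, c in enumerate(self.columns)}
        missing = [c for c in keep if c not in index]
        if missing:
            raise StrandclassError(f"unknown columns requested: {missing[:5]}")
        idx = [index[c] for c in keep]
        return FeatureMatrix(
            sample_ids=list(self.sample_ids),
            labels=list(self.labels),
            columns=keep,
            values=self.values[:, idx] if keep else np.empty((self.n_samples, 0)),
        )

    def with_labels(self, labels: Sequence[str]) -> "FeatureMatrix":
        return FeatureMatrix(
            sample_ids=list(self.sample_ids),
            labels=list(labels),
            columns=list(self.columns),
            values=self.values.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.sample_ids, columns=self.columns)
        df.insert(0, "label", self.labels)
        df.index.name = "sample_id"
        return df

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureMatrix):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.labels == other.labels
            and self.columns == other.columns
            and self.values.shape == other.values.shape
            and np.allclose(self.values, other.values, rtol=0, atol=1e-12)
        )


def matrix_from_blocks(
    sample_ids: Sequence[str],
    labels: Sequence[str],
    per_sample_blocks: Sequence[Sequence[FeatureBlock]],
) -> FeatureMatrix:
    """Assemble a FeatureMatrix from per-protein lists of feature blocks.

    Every protein must produce the same block structure (same sources, same
    per-block labels) — guaranteed by the extractors for fixed configuration.
    """
    rows = [concat_blocks(blocks) for blocks in per_sample_blocks]
    if not rows:
        raise StrandclassError("no samples to assemble")
    ref = rows[0].labels
    for sid, row in zip(sample_ids, rows):
        if row.labels != ref:
            raise StrandclassError(
                f"sample {sid!r} produced a different column structure"
            )
    return FeatureMatrix(
        sample_ids=list(sample_ids),
        labels=list(labels),
        columns=list(ref),
        values=np.vstack([r.values for r in rows]),
    )
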