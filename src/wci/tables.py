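"""Core in-memory containers for the WCI pipeline.

Two tables travel through the pipeline: an integer taxon count table
(samples x taxa) and, after total-sum-scaling, a relative-abundance table
of per-sample fractions.  Both carry the binary group label of each sample
and optional numeric covariates (e.g. age).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_CASE_LABEL = "BCa"
DEFAULT_CONTROL_LABEL = "HC"

LEVELS = ("genus", "species")


class ValidationError(ValueError):
    """A table violates one of its structural invariants."""


class FormatError(ValueError):
    """An input file is malformed (non-integer cells, duplicated ids, ...)."""


def _check_labels(labels: pd.Series, index: pd.Index) -> None:
    if not labels.index.equals(index):
        raise ValidationError("labels index does not match sample ids")
    counts = labels.value_counts()
    if len(counts) != 2:
        raise ValidationError(
            f"labels must contain exactly two classes, got {list(counts.index)}"
        )
    if (counts < 2).any():
        raise ValidationError("each class needs at least 2 samples")


@dataclass
class TaxaCountTable:
    """Integer counts per sample x taxon with group labels.

    Parameters
    ----------
    counts
        DataFrame of non-negative integers, rows = samples, columns = taxa.
    labels
        Per-sample group label (two classes, >= 2 samples each).
    covariates
        Optional per-sample numeric covariates (same index as ``counts``).
    level
        Taxonomic level of the columns, ``"genus"`` or ``"species"``.
    case_label
        Which of the two label values denotes the disease group.
    """

    counts: pd.DataFrame
    labels: pd.Series
    covariates: pd.DataFrame | None = None
    level: str = "genus"
    case_label: str = DEFAULT_CASE_LABEL

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ValidationError(f"level must be one of {LEVELS}, got {self.level!r}")
        if self.counts.index.has_duplicates:
            raise FormatError("duplicated sample ids")
        if self.counts.columns.has_duplicates:
            raise FormatError("duplicated taxon ids")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.equal(np.mod(arr, 1), 0)):
                raise FormatError("count table contains non-integer cells")
            self.counts = self.counts.astype(np.int64)
            arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise FormatError("count table contains negative cells")
        if (arr.sum(axis=1) == 0).any():
            bad = list(self.counts.index[arr.sum(axis=1) == 0])
            raise ValidationError(f"samples with zero total counts: {bad}")
        _check_labels(self.labels, self.counts.index)
        if self.case_label not in set(self.labels):
            raise ValidationError(
                f"case label {self.case_label!r} not found among group labels"
            )
        if self.covariates is not None and not self.covariates.index.equals(
            self.counts.index
        ):
            raise ValidationError("covariates index does not match sample ids")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def control_label(self) -> str:
        other = set(self.labels) - {self.case_label}
        return next(iter(other))

    @property
    def is_case(self) -> np.ndarray:
        return (self.labels == self.case_label).to_numpy()

    def subset_taxa(self, taxa: list[str]) -> "TaxaCountTable":
        return TaxaCountTable(
            counts=self.counts[taxa].copy(),
            labels=self.labels,
            covariates=self.covariates,
            level=self.level,
            case_label=self.case_label,
        )

    def subset_samples(self, sample_ids) -> "TaxaCountTable":
        return TaxaCountTable(
            counts=self.counts.loc[sample_ids].copy(),
            labels=self.labels.loc[sample_ids],
            covariates=None
            if self.covariates is None
            else self.covariates.loc[sample_ids],
            level=self.level,
            case_label=self.case_label,
        )

    def equals(self, other: "TaxaCountTable") -> bool:
        return (
            self.counts.equals(other.counts)
            and self.labels.equals(other.labels)
            and self.level == other.level
        )


@dataclass
class AbundanceTable:
    """Per-sample relative abundances (fractions in [0, 1], rows sum to 1)."""

    ra: pd.DataFrame
    labels: pd.Series
    covariates: pd.DataFrame | None = None
    level: str = "genus"
    case_label: str = DEFAULT_CASE_LABEL

    def __post_init__(self) -> None:
        arr = self.ra.to_numpy(dtype=float)
        if (arr < 0).any():
            raise ValidationError("relative abundances must be non-negative")
        if not np.allclose(arr.sum(axis=1), 1.0, atol=1e-12, rtol=0):
            raise ValidationError("relative-abundance rows must sum to 1")
        _check_labels(self.labels, self.ra.index)
        if self.case_label not in set(self.labels):
            raise ValidationError(
                f"case label {self.case_label!r} not found among group labels"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.ra.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.ra.columns)

    @property
    def control_label(self) -> str:
        return next(iter(set(self.labels) - {self.case_label}))

    @property
    def is_case(self) -> np.ndarray:
        return (self.labels == self.case_label).to_numpy()

    def subset_samples(self, sample_ids) -> "AbundanceTable":
        sub = self.ra.loc[sample_ids]
        # renormalise defensively: a row subset keeps sums, a taxon subset would not
        return AbundanceTable(
            ra=sub.copy(),
            labels=self.labels.loc[sample_ids],
            covariates=None
            if self.covariates is None
            else self.covariates.loc[sample_ids],
            level=self.level,
            case_label=self.case_label,
        )

    def group_means(self) -> pd.DataFrame:
        """Mean relative abundance per taxon in each group (columns: case, control)."""
        mask = self.is_case
        return pd.DataFrame(
            {
                "case": self.ra.loc[mask].mean(axis=0),
                "control": self.ra.loc[~mask].mean(axis=0),
            }
        )


@dataclass
class FilterReport:
    """Record of one filtering stage: what was removed and under which thresholds."""

    stage: str
    removed_taxa: list = field(default_factory=list)
    kept_taxa: list = field(default_factory=list)
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = set(self.removed_taxa) & set(self.kept_taxa)
        if overlap:
            raise ValidationError(f"taxa both removed and kept: {sorted(overlap)}")

    def to_dict(self) -> dict:
        return {
            "stage": self.stage,
            "removed_taxa": list(self.removed_taxa),
            "kept_taxa": list(self.kept_taxa),
            "parameters": dict(self.parameters),
        }


def warn(msg: str) -> None:
    warnings.warn(msg, stacklevel=3)
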