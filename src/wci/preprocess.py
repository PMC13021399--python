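"""Count-table loading, filtering and total-sum-scaling normalisation.

The cleaning pipeline mirrors standard marker-gene practice: remove known
laboratory contaminants, drop taxa that never reach a minimal count in a
minimal fraction of samples, drop the least variable taxa (by interquartile
range of raw counts), then convert to relative abundances by total sum
scaling.  Filters operate on counts; TSS is applied last.  No rarefaction
is performed.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .tables import (
    AbundanceTable,
    FilterReport,
    FormatError,
    TaxaCountTable,
    ValidationError,
    warn,
)

DEFAULT_MIN_COUNT = 20
DEFAULT_MIN_PREVALENCE = 0.10
DEFAULT_VARIANCE_PERCENTILE = 10.0


def read_count_table(
    counts_path,
    metadata_path,
    orientation: str = "taxa_rows",
    level: str = "genus",
    case_label: str = "BCa",
    group_col: str = "group",
    sample_col: str = "sample_id",
) -> TaxaCountTable:
    """Load a TSV count table plus sample metadata into a validated table.

    The counts file has taxa as rows and samples as columns (first column =
    taxon id); pass ``orientation="samples_rows"`` for the transpose.
    Metadata needs one row per sample with at least a group column; any
    additional numeric columns (e.g. ``age``) become covariates.  Sample
    order is taken from the metadata; a sample present in only one of the
    two files is an error.
    """
    if orientation not in ("taxa_rows", "samples_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    raw = pd.read_csv(counts_path, sep="\t", index_col=0)
    if orientation == "taxa_rows":
        raw = raw.T  # -> samples x taxa
    raw.index = raw.index.astype(str)
    raw.columns = raw.columns.astype(str)
    if raw.index.has_duplicates:
        raise FormatError("duplicated sample ids in counts file")
    if raw.columns.has_duplicates:
        raise FormatError("duplicated taxon ids in counts file")

    meta = pd.read_csv(metadata_path, sep="\t", dtype={sample_col: str})
    for col in (sample_col, group_col):
        if col not in meta.columns:
            raise FormatError(f"metadata lacks required column {col!r}")
    if meta[sample_col].duplicated().any():
        raise FormatError("duplicated sample ids in metadata")
    meta = meta.set_index(sample_col)

    missing_in_counts = set(meta.index) - set(raw.index)
    missing_in_meta = set(raw.index) - set(meta.index)
    if missing_in_counts or missing_in_meta:
        raise FormatError(
            f"sample sets differ: only in metadata {sorted(missing_in_counts)}, "
            f"only in counts {sorted(missing_in_meta)}"
        )
    counts = raw.loc[meta.index]

    cov_cols = [
        c
        for c in meta.columns
        if c != group_col and pd.api.types.is_numeric_dtype(meta[c])
    ]
    covariates = meta[cov_cols] if cov_cols else None
    return TaxaCountTable(
        counts=counts,
        labels=meta[group_col].astype(str),
        covariates=covariates,
        level=level,
        case_label=case_label,
    )


def write_count_table(
    table: TaxaCountTable, counts_path, metadata_path, orientation: str = "taxa_rows"
) -> None:
    out = table.counts.T if orientation == "taxa_rows" else table.counts
    out.to_csv(counts_path, sep="\t", index_label="taxon")
    meta = pd.DataFrame({"group": table.labels})
    if table.covariates is not None:
        meta = meta.join(table.covariates)
    meta.to_csv(metadata_path, sep="\t", index_label="sample_id")


def write_abundance_table(ab: AbundanceTable, path) -> None:
    ab.ra.T.to_csv(path, sep="\t", index_label="taxon", float_format="%.12g")


def remove_contaminants(
    table: TaxaCountTable, blacklist
) -> tuple[TaxaCountTable, FilterReport]:
    """Drop blacklisted taxa (case-insensitive name match).

    Blacklist entries with no match in the table are ignored (a contaminant
    may simply be absent from this cohort).
    """
    wanted = {str(b).strip().lower() for b in blacklist}
    removed = [t for t in table.taxon_ids if t.lower() in wanted]
    kept = [t for t in table.taxon_ids if t.lower() not in wanted]
    unmatched = wanted - {t.lower() for t in removed}
    if unmatched:
        warn(f"blacklist entries not present in the table: {sorted(unmatched)}")
    report = FilterReport(
        stage="contaminant",
        removed_taxa=removed,
        kept_taxa=kept,
        parameters={"blacklist": sorted(wanted)},
    )
    return (table if not removed else table.subset_taxa(kept)), report


def low_count_filter(
    table: TaxaCountTable,
    min_count: int = DEFAULT_MIN_COUNT,
    min_prevalence: float = DEFAULT_MIN_PREVALENCE,
) -> tuple[TaxaCountTable, FilterReport]:
    """Keep a taxon iff it has >= min_count reads in >= ceil(min_prevalence*n) samples."""
    if min_count < 0:
        raise ValueError("min_count must be >= 0")
    if not (0 < min_prevalence <= 1):
        raise ValueError("min_prevalence must be in (0, 1]")
    n = len(table.sample_ids)
    needed = math.ceil(min_prevalence * n)
    hits = (table.counts >= min_count).sum(axis=0)
    keep_mask = hits >= needed
    kept = list(table.counts.columns[keep_mask])
    removed = list(table.counts.columns[~keep_mask])
    if not kept:
        raise ValidationError(
            f"low-count filter (min_count={min_count}, "
            f"min_prevalence={min_prevalence}) removed every taxon"
        )
    report = FilterReport(
        stage="low_count",
        removed_taxa=removed,
        kept_taxa=kept,
        parameters={
            "min_count": min_count,
            "min_prevalence": min_prevalence,
            "samples_required": needed,
        },
    )
    return (table if not removed else table.subset_taxa(kept)), report


def low_variance_filter(
    table: TaxaCountTable,
    percentile: float = DEFAULT_VARIANCE_PERCENTILE,
    statistic: str = "iqr",
) -> tuple[TaxaCountTable, FilterReport]:
    """Drop taxa whose spread falls strictly below the given percentile.

    Spread is the interquartile range of raw counts across samples by
    default (``statistic="variance"`` switches to the variance); the cutoff
    is the ``percentile``-th percentile of the per-taxon spreads
    (linear-interpolation quantiles).  Taxa exactly at the cutoff are kept.
    Note the cutoff is relative to the current table, so re-applying the
    filter can remove further taxa.
    """
    if not (0 <= percentile < 100):
        raise ValueError("percentile must be in [0, 100)")
    if statistic not in ("iqr", "variance"):
        raise ValueError(f"unknown statistic {statistic!r}")
    if len(table.taxon_ids) < 2:
        warn("low-variance filter skipped: fewer than two taxa")
        report = FilterReport(
            stage="low_variance",
            removed_taxa=[],
            kept_taxa=list(table.taxon_ids),
            parameters={"percentile": percentile, "statistic": statistic},
        )
        return table, report
    arr = table.counts.to_numpy(dtype=float)
    if statistic == "iqr":
        q75, q25 = np.percentile(arr, [75, 25], axis=0, method="linear")
        spread = q75 - q25
    else:
        spread = arr.var(axis=0, ddof=1)
    cutoff = float(np.percentile(spread, percentile, method="linear"))
    keep_mask = spread >= cutoff  # strictly-below removed; ties kept
    kept = list(table.counts.columns[keep_mask])
    removed = list(table.counts.columns[~keep_mask])
    if not kept:
        raise ValidationError(
            f"low-variance filter (percentile={percentile}) removed every taxon"
        )
    report = FilterReport(
        stage="low_variance",
        removed_taxa=removed,
        kept_taxa=kept,
        parameters={
            "percentile": percentile,
            "statistic": statistic,
            "cutoff": cutoff,
        },
    )
    return (table if not removed else table.subset_taxa(kept)), report


def tss_normalize(table: TaxaCountTable) -> AbundanceTable:
    """Total sum scaling: divide each sample's counts by its library size."""
    totals = table.counts.sum(axis=1)
    if (totals == 0).any():
        raise ValidationError("cannot TSS-normalise samples with zero total counts")
    ra = table.counts.div(totals, axis=0)
    return AbundanceTable(
        ra=ra,
        labels=table.labels,
        covariates=table.covariates,
        level=table.level,
        case_label=table.case_label,
    )


def preprocess(
    table: TaxaCountTable,
    blacklist=(),
    min_count: int = DEFAULT_MIN_COUNT,
    min_prevalence: float = DEFAULT_MIN_PREVALENCE,
    variance_percentile: float = DEFAULT_VARIANCE_PERCENTILE,
) -> tuple[AbundanceTable, list[FilterReport]]:
    """Run the full cleaning chain: contaminants -> low count -> low variance -> TSS."""
    reports = []
    table, rep = remove_contaminants(table, blacklist)
    reports.append(rep)
    table, rep = low_count_filter(table, min_count, min_prevalence)
    reports.append(rep)
    table, rep = low_variance_filter(table, variance_percentile)
    reports.append(rep)
    return tss_normalize(table), reports
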