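"""The Weighted Composite Index (WCI).

For a signature with disease-associated taxa T_case (weights w_i) and
control-associated taxa T_ctrl (weights w_j), a sample with relative
abundances RA is scored

    WCI = sum_{i in T_case} RA_i * w_i  -  sum_{j in T_ctrl} RA_j * w_j

Positive scores indicate a shift toward the disease-associated community,
negative scores toward the control-associated one.  The index is linear in
RA, so the mean score of a group equals the score of the group's mean RA
vector.
"""

from __future__ import annotations

from typing import Mapping

import pandas as pd

from .discovery import SignatureModel
from .tables import AbundanceTable, ValidationError, warn


def _subscore(taxa: dict[str, float], ra_row: Mapping, missing: list) -> float:
    total = 0.0
    for taxon, weight in taxa.items():
        ra = ra_row.get(taxon) if hasattr(ra_row, "get") else None
        if ra is None:
            missing.append(taxon)
            continue
        ra = float(ra)
        if not (0.0 <= ra <= 1.0):
            raise ValidationError(
                f"relative abundance of {taxon!r} is {ra}, outside [0, 1] "
                "(percent values must be divided by 100 first)"
            )
        total += ra * weight
    return total


def compute_wci(
    signature: SignatureModel, ra_row: Mapping, strict: bool = False
) -> float:
    """Score one sample; ``ra_row`` maps taxon id to a fraction in [0, 1].

    Signature taxa absent from the row count as zero abundance (with a
    warning); with ``strict=True`` they raise instead, which is useful to
    detect schema drift between discovery and scoring.
    """
    missing: list = []
    case_sub = _subscore(signature.case_taxa, ra_row, missing)
    ctrl_sub = _subscore(signature.control_taxa, ra_row, missing)
    if missing:
        if strict:
            raise ValidationError(f"signature taxa missing from sample: {missing}")
        warn(f"signature taxa missing from sample, treated as RA 0: {missing}")
    return case_sub - ctrl_sub


def score_cohort(
    signature: SignatureModel, ab: AbundanceTable, strict: bool = False
) -> pd.DataFrame:
    """Score every sample; returns one row per sample, order preserved.

    Columns: ``group``, ``wci``, ``case_subscore``, ``control_subscore``
    (wci = case_subscore - control_subscore exactly).
    """
    missing = [t for t in signature.taxa if t not in ab.ra.columns]
    if missing:
        if strict:
            raise ValidationError(f"signature taxa missing from cohort: {missing}")
        warn(f"signature taxa missing from cohort, treated as RA 0: {missing}")
    case_cols = [t for t in signature.case_taxa if t in ab.ra.columns]
    ctrl_cols = [t for t in signature.control_taxa if t in ab.ra.columns]
    if (ab.ra[case_cols + ctrl_cols].to_numpy() > 1.0).any():
        raise ValidationError(
            "relative abundances above 1 — percent values must be divided by 100"
        )
    case_w = pd.Series(signature.case_taxa)[case_cols]
    ctrl_w = pd.Series(signature.control_taxa)[ctrl_cols]
    case_sub = ab.ra[case_cols] @ case_w if case_cols else pd.Series(0.0, ab.ra.index)
    ctrl_sub = ab.ra[ctrl_cols] @ ctrl_w if ctrl_cols else pd.Series(0.0, ab.ra.index)
    return pd.DataFrame(
        {
            "group": ab.labels,
            "wci": case_sub - ctrl_sub,
            "case_subscore": case_sub,
            "control_subscore": ctrl_sub,
        },
        index=ab.ra.index,
    )


def group_summary(scores: pd.DataFrame) -> pd.DataFrame:
    """Per-group mean and SD of the index (what a run log reports)."""
    return scores.groupby("group")["wci"].agg(["mean", "std", "count"])
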