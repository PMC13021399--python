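"""Dirichlet-multinomial synthetic urobiome cohorts.

Each group has a fixed mean composition: named signature taxa at specified
mean relative abundances plus background taxa sharing the residual mass
via a fixed symmetric Dirichlet partition (the same partition in both
groups, so background taxa are near-null).  A sample is drawn by first
perturbing the group composition with a Dirichlet whose concentration is
``composition * theta`` (larger theta = less sample-to-sample variation),
then drawing counts from a multinomial at a library size sampled uniformly
from ``depth_range``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import reference
from .tables import TaxaCountTable, ValidationError

DEFAULT_THETA = 200.0
DEFAULT_DEPTH_RANGE = (20_000, 100_000)
DEFAULT_SEED = 20240101
# floor for taxa whose printed group mean is 0.00% (Dirichlet needs alpha > 0)
RA_FLOOR = 1e-5


@dataclass
class TaxonSpec:
    taxon_id: str
    mean_ra_case: float
    mean_ra_control: float


@dataclass
class SyntheticSpec:
    """Parameters of a two-group compositional cohort."""

    level: str = "genus"
    n_case: int = 27
    n_control: int = 24
    taxa: list[TaxonSpec] = field(default_factory=list)
    n_background_taxa: int = 26
    overdispersion: float = DEFAULT_THETA
    depth_range: tuple[int, int] = DEFAULT_DEPTH_RANGE
    contaminant_taxa: list[str] = field(default_factory=list)
    seed: int = DEFAULT_SEED
    case_label: str = "BCa"
    control_label: str = "HC"

    def __post_init__(self) -> None:
        if self.n_case < 2 or self.n_control < 2:
            raise ValidationError("each group needs at least 2 samples")
        if self.overdispersion <= 0:
            raise ValidationError("overdispersion theta must be > 0")
        if self.depth_range[0] < 100 or self.depth_range[0] > self.depth_range[1]:
            raise ValidationError("depth_range must satisfy 100 <= min <= max")
        for attr in ("mean_ra_case", "mean_ra_control"):
            total = sum(getattr(t, attr) for t in self.taxa)
            if total > 1:
                raise ValidationError(f"named {attr} sums to {total} > 1")
            if total < 1 and self.n_background_taxa < 1:
                raise ValidationError(
                    "residual mass > 0 requires at least one background taxon"
                )

    def to_dict(self) -> dict:
        return {
            "level": self.level,
            "n_case": self.n_case,
            "n_control": self.n_control,
            "taxa": [
                {
                    "taxon_id": t.taxon_id,
                    "mean_ra_case": t.mean_ra_case,
                    "mean_ra_control": t.mean_ra_control,
                }
                for t in self.taxa
            ],
            "n_background_taxa": self.n_background_taxa,
            "overdispersion": self.overdispersion,
            "depth_range": list(self.depth_range),
            "contaminant_taxa": list(self.contaminant_taxa),
            "seed": self.seed,
        }


def table1_spec(
    level: str = "genus",
    n_background: int | None = None,
    theta: float = DEFAULT_THETA,
    n_case: int = 27,
    n_control: int = 24,
    seed: int = DEFAULT_SEED,
    null: bool = False,
) -> SyntheticSpec:
    """Cohort spec seeded from the published signature's group-mean RAs.

    Background taxa fill the residual mass so that the total taxon count
    matches the discovery cohort's post-filter dimensionality (33 genera /
    85 species).  With ``null=True`` the case group copies the control
    composition — a no-effect cohort for calibration checks.
    """
    tab = reference.reference_table(level)
    if n_background is None:
        n_background = reference.N_FEATURES[level] - len(tab)
    taxa = [
        TaxonSpec(
            taxon_id=str(t),
            mean_ra_case=(
                row["mean_ra_control_pct"] if null else row["mean_ra_case_pct"]
            )
            / 100.0,
            mean_ra_control=row["mean_ra_control_pct"] / 100.0,
        )
        for t, row in tab.iterrows()
    ]
    return SyntheticSpec(
        level=level,
        n_case=n_case,
        n_control=n_control,
        taxa=taxa,
        n_background_taxa=n_background,
        overdispersion=theta,
        seed=seed,
    )


def null_spec(level: str = "genus", **kwargs) -> SyntheticSpec:
    """Pure-noise variant of :func:`table1_spec` (case composition = control)."""
    return table1_spec(level=level, null=True, **kwargs)


def _compositions(spec: SyntheticSpec) -> pd.DataFrame:
    """Mean composition per group (rows: taxa, columns: case/control)."""
    named_case = np.array([max(t.mean_ra_case, RA_FLOOR) for t in spec.taxa])
    named_ctrl = np.array([max(t.mean_ra_control, RA_FLOOR) for t in spec.taxa])
    names = [t.taxon_id for t in spec.taxa]
    nb = spec.n_background_taxa
    if nb > 0:
        # one shared partition for both groups: background taxa carry no signal
        # beyond the residual-mass ratio
        part_rng = np.random.default_rng((spec.seed * 2 + 1) % (2**31))
        partition = part_rng.dirichlet(np.ones(nb))
        case = np.concatenate([named_case, (1 - named_case.sum()) * partition])
        ctrl = np.concatenate([named_ctrl, (1 - named_ctrl.sum()) * partition])
        names = names + [f"bg_taxon_{i:03d}" for i in range(nb)]
    else:
        case, ctrl = named_case, named_ctrl
    case = case / case.sum()
    ctrl = ctrl / ctrl.sum()
    return pd.DataFrame({"case": case, "control": ctrl}, index=names)


def make_cohort(spec: SyntheticSpec) -> TaxaCountTable:
    """Draw a cohort: Dirichlet-perturbed compositions, multinomial counts."""
    comp = _compositions(spec)
    rng = np.random.default_rng(spec.seed % (2**31))
    rows, labels, ids = [], [], []
    for group, label, n in (
        ("case", spec.case_label, spec.n_case),
        ("control", spec.control_label, spec.n_control),
    ):
        alpha = comp[group].to_numpy() * spec.overdispersion
        for i in range(n):
            p = rng.dirichlet(alpha)
            depth = int(rng.integers(spec.depth_range[0], spec.depth_range[1] + 1))
            rows.append(rng.multinomial(depth, p))
            labels.append(label)
            ids.append(f"{label}_{i + 1:03d}")
    counts = pd.DataFrame(np.array(rows), index=ids, columns=comp.index)
    table = TaxaCountTable(
        counts=counts,
        labels=pd.Series(labels, index=ids, name="group"),
        level=spec.level,
        case_label=spec.case_label,
    )
    if spec.contaminant_taxa:
        table = spike_contaminants(table, spec.contaminant_taxa)
    return table


def spike_contaminants(
    table: TaxaCountTable, taxa, ra: float = 0.005
) -> TaxaCountTable:
    """Add contaminant taxa at a fixed small relative abundance.

    Counts are ``round(ra * depth)`` per sample, appended additively
    (existing counts are untouched), exercising the contaminant-removal
    stage downstream.
    """
    if not (0 <= ra < 0.05):
        raise ValidationError("contaminant ra must be in [0, 0.05)")
    present = set(table.taxon_ids) & set(taxa)
    if present:
        raise ValidationError(f"taxa already present: {sorted(present)}")
    counts = table.counts.copy()
    depths = counts.sum(axis=1)
    for taxon in taxa:
        counts[taxon] = np.rint(ra * depths).astype(np.int64)
    return TaxaCountTable(
        counts=counts,
        labels=table.labels,
        covariates=table.covariates,
        level=table.level,
        case_label=table.case_label,
    )


def with_ages(
    table: TaxaCountTable,
    mean_case: float = 73.1,
    sd_case: float = 9.5,
    mean_control: float = 61.6,
    sd_control: float = 7.6,
    seed: int = DEFAULT_SEED,
) -> TaxaCountTable:
    """Attach a per-sample age covariate (normal draws per group, years)."""
    rng = np.random.default_rng(seed % (2**31))
    mask = table.is_case
    age = np.where(
        mask,
        rng.normal(mean_case, sd_case, len(mask)),
        rng.normal(mean_control, sd_control, len(mask)),
    ).round(1)
    cov = pd.DataFrame({"age": age}, index=table.counts.index)
    return replace(table, covariates=cov)
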