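"""Random-Forest signature discovery.

Taxa are ranked by out-of-bag permutation importance (mean decrease in
accuracy, MDA), thresholded, weight-normalised, and assigned to the
disease- or control-associated set by comparing group-mean relative
abundances.  The result is a :class:`SignatureModel`, the portable artifact
consumed by the scoring and validation stages.

The MDA here is the classic scaled form: for every tree, the drop in
accuracy on that tree's out-of-bag samples when one feature column is
permuted; the per-tree drops are averaged and divided by their standard
error over trees.  The default selection threshold (MDA > 5) is calibrated
to this scaled form; the raw (unscaled) mean decrease is also reported.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.utils import check_random_state

from .tables import AbundanceTable, ValidationError, warn

DEFAULT_NTREE = 1500
DEFAULT_SEED = 20240101
DEFAULT_MDA_THRESHOLD = 5.0


def compute_mtry(n_features: int) -> int:
    """Number of features tried at each split: floor(sqrt(p)), at least 1."""
    if n_features < 1:
        raise ValueError(f"n_features must be >= 1, got {n_features}")
    return max(1, int(np.floor(np.sqrt(n_features))))


@dataclass
class ImportanceTable:
    """Per-taxon RF importances plus the forest's out-of-bag error."""

    table: pd.DataFrame  # index: taxon; columns: mda, mda_raw, optionally nmda
    oob_error: float
    rf_params: dict = field(default_factory=dict)

    def sorted(self) -> "ImportanceTable":
        return ImportanceTable(
            self.table.sort_values("mda", ascending=False),
            self.oob_error,
            self.rf_params,
        )


@dataclass
class SignatureModel:
    """Discriminant taxa split into disease- and control-associated sets.

    Weights are normalised MDA values; the union of the two sets sums to 1.
    """

    level: str
    case_taxa: dict[str, float]
    control_taxa: dict[str, float]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = set(self.case_taxa) & set(self.control_taxa)
        if overlap:
            raise ValidationError(f"taxa in both groups: {sorted(overlap)}")
        weights = list(self.case_taxa.values()) + list(self.control_taxa.values())
        if not weights:
            raise ValidationError("signature has no taxa")
        if any(w <= 0 for w in weights):
            raise ValidationError("signature weights must be positive")
        if abs(sum(weights) - 1.0) > 1e-12:
            raise ValidationError(f"signature weights sum to {sum(weights)}, not 1")

    @property
    def taxa(self) -> list[str]:
        return list(self.case_taxa) + list(self.control_taxa)

    def swapped(self) -> "SignatureModel":
        return SignatureModel(
            self.level, dict(self.control_taxa), dict(self.case_taxa), self.provenance
        )

    def to_dict(self) -> dict:
        return {
            "level": self.level,
            "taxa": [
                {"id": t, "weight": w, "group": "case"}
                for t, w in self.case_taxa.items()
            ]
            + [
                {"id": t, "weight": w, "group": "control"}
                for t, w in self.control_taxa.items()
            ],
            "provenance": self.provenance,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "SignatureModel":
        case = {t["id"]: t["weight"] for t in d["taxa"] if t["group"] == "case"}
        ctrl = {t["id"]: t["weight"] for t in d["taxa"] if t["group"] == "control"}
        return cls(d["level"], case, ctrl, d.get("provenance", {}))

    @classmethod
    def from_json(cls, path) -> "SignatureModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _bootstrap_oob_mask(tree_random_state, n_samples: int) -> np.ndarray:
    """Out-of-bag mask of one tree, replaying sklearn's bootstrap draw."""
    rnd = check_random_state(tree_random_state)
    sampled = rnd.randint(0, n_samples, n_samples)
    mask = np.ones(n_samples, dtype=bool)
    mask[sampled] = False
    return mask


def fit_importance(
    ab: AbundanceTable,
    ntree: int = DEFAULT_NTREE,
    mtry: int | str = "auto",
    seed: int = DEFAULT_SEED,
    scaled: bool = True,
    check_stability: bool = False,
) -> ImportanceTable:
    """Train a Random Forest on relative abundances and return per-taxon MDA.

    Parameters
    ----------
    ab
        Relative-abundance table with two-class labels.
    ntree
        Number of trees.
    mtry
        Features tried per split; ``"auto"`` means floor(sqrt(n_taxa)).
    seed
        Governs the forest and the per-tree permutations; the run is
        deterministic given the seed.
    scaled
        If True (default) the ``mda`` column is the per-tree mean decrease
        divided by its standard error across trees; the raw mean is always
        available as ``mda_raw``.
    check_stability
        Compare the out-of-bag error at ntree/2 trees against the full
        forest and warn if they differ by more than 0.02.
    """
    X = ab.ra.to_numpy(dtype=np.float64)
    y = ab.is_case.astype(np.int64)
    n, p = X.shape
    if len(np.unique(y)) < 2:
        raise ValidationError("both classes required to fit the forest")
    if mtry == "auto":
        mtry = compute_mtry(p)
    if mtry > p:
        raise ValidationError(f"mtry={mtry} exceeds the number of taxa ({p})")

    rf = RandomForestClassifier(
        n_estimators=int(ntree),
        max_features=int(mtry),
        bootstrap=True,
        oob_score=True,
        random_state=int(seed),
        n_jobs=1,
    )
    rf.fit(X, y)
    oob_error = 1.0 - float(rf.oob_score_)

    if check_stability:
        half = RandomForestClassifier(
            n_estimators=max(1, int(ntree) // 2),
            max_features=int(mtry),
            bootstrap=True,
            oob_score=True,
            random_state=int(seed),
            n_jobs=1,
        ).fit(X, y)
        delta = abs((1.0 - half.oob_score_) - oob_error)
        if delta > 0.02:
            warn(
                f"OOB error not stabilised: |error({ntree // 2}) - error({ntree})|"
                f" = {delta:.3f} > 0.02; consider more trees"
            )

    # per-tree accuracy decrease under single-feature permutation (OOB only)
    X32 = np.ascontiguousarray(X, dtype=np.float32)
    decreases = np.full((len(rf.estimators_), p), np.nan)
    perm_rng = np.random.default_rng(int(seed) % (2**31))
    for t, est in enumerate(rf.estimators_):
        oob = np.flatnonzero(_bootstrap_oob_mask(est.random_state, n))
        if oob.size == 0:
            continue
        Xo = X32[oob]
        m = oob.size
        # one stacked prediction per tree: baseline block + one block per feature
        stacked = np.tile(Xo, (p + 1, 1))
        for f in range(p):
            rows = slice((f + 1) * m, (f + 2) * m)
            stacked[rows, f] = Xo[perm_rng.permutation(m), f]
        proba = est.tree_.predict(np.ascontiguousarray(stacked))
        pred = proba.reshape(stacked.shape[0], -1).argmax(axis=1)
        correct = (pred == y[oob][None, :].repeat(p + 1, axis=0).ravel()).reshape(
            p + 1, m
        )
        acc = correct.mean(axis=1)
        decreases[t] = acc[0] - acc[1:]

    ntrees_used = np.sum(~np.isnan(decreases[:, 0]))
    raw = np.nanmean(decreases, axis=0)
    sd = np.nanstd(decreases, axis=0, ddof=0)
    se = sd / np.sqrt(ntrees_used)
    with np.errstate(divide="ignore", invalid="ignore"):
        scaled_mda = np.where(se > 0, raw / se, 0.0)

    table = pd.DataFrame(
        {
            "mda": scaled_mda if scaled else raw,
            "mda_raw": raw,
            "mda_scaled": scaled_mda,
        },
        index=ab.ra.columns,
    )
    return ImportanceTable(
        table=table,
        oob_error=oob_error,
        rf_params={"ntree": int(ntree), "mtry": int(mtry), "seed": int(seed)},
    )


def select_taxa(
    imp: ImportanceTable, threshold: float = DEFAULT_MDA_THRESHOLD
) -> ImportanceTable:
    """Keep taxa with MDA strictly above ``threshold``, sorted by decreasing MDA."""
    if np.isnan(threshold) or threshold == np.inf:
        raise ValueError("threshold must be finite or -inf")
    kept = imp.table[imp.table["mda"] > threshold].sort_values("mda", ascending=False)
    if kept.empty:
        raise ValidationError(
            f"no taxa with MDA > {threshold}; max observed MDA is "
            f"{imp.table['mda'].max():.3f} — lower the threshold"
        )
    params = dict(imp.rf_params, mda_threshold=threshold)
    return ImportanceTable(table=kept, oob_error=imp.oob_error, rf_params=params)


def normalize_mda(mda: pd.Series) -> pd.Series:
    """nMDA weights: each MDA divided by the sum of MDAs over the selection."""
    if (mda <= 0).any():
        bad = list(mda.index[mda <= 0])
        raise ValidationError(f"non-positive MDA in selection: {bad}")
    return mda / mda.sum()


def normalize_weights(selected: ImportanceTable) -> ImportanceTable:
    """Attach nMDA weights (normalised MDA, summing to 1) to a selection."""
    table = selected.table.copy()
    table["nmda"] = normalize_mda(table["mda"])
    return ImportanceTable(table, selected.oob_error, selected.rf_params)


def assign_groups(selected: ImportanceTable, ab: AbundanceTable) -> SignatureModel:
    """Assign each selected taxon to the group with the larger mean RA.

    Taxa whose group means tie exactly carry no directional signal and are
    excluded with a warning; the remaining weights are renormalised so the
    signature's weights still sum to 1.
    """
    if "nmda" not in selected.table.columns:
        selected = normalize_weights(selected)
    missing = [t for t in selected.table.index if t not in ab.ra.columns]
    if missing:
        raise ValidationError(f"selected taxa absent from abundance table: {missing}")
    means = ab.group_means().loc[selected.table.index]
    tied = means.index[means["case"] == means["control"]]
    if len(tied) > 0:
        warn(
            f"taxa with identical group means excluded from the signature: "
            f"{list(tied)}; remaining weights renormalised"
        )
    keep = selected.table.drop(index=tied)
    if keep.empty:
        raise ValidationError("all selected taxa tied between groups")
    weights = keep["nmda"] / keep["nmda"].sum()
    means = means.drop(index=tied)
    case_mask = means["case"] > means["control"]
    return SignatureModel(
        level=ab.level,
        case_taxa={t: float(weights[t]) for t in keep.index[case_mask]},
        control_taxa={t: float(weights[t]) for t in keep.index[~case_mask]},
        provenance={
            "rf_params": dict(selected.rf_params),
            "oob_error": float(selected.oob_error),
            "n_samples": len(ab.sample_ids),
            "case_label": ab.case_label,
        },
    )


def discover_signature(
    ab: AbundanceTable,
    ntree: int = DEFAULT_NTREE,
    mtry: int | str = "auto",
    mda_threshold: float = DEFAULT_MDA_THRESHOLD,
    seed: int = DEFAULT_SEED,
) -> tuple[SignatureModel, ImportanceTable]:
    """Full discovery step: fit, select, weight, assign. Returns (signature, importances)."""
    imp = fit_importance(ab, ntree=ntree, mtry=mtry, seed=seed)
    selected = normalize_weights(select_taxa(imp, threshold=mda_threshold))
    return assign_groups(selected, ab), imp
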