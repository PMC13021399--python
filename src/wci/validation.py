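"""In-silico validation: repeated stratified k-fold CV and a permutation test.

Two modes of cross-validation are offered.  In ``fixed`` mode (default)
the signature's taxa and weights stay frozen — per-sample scores are then
identical to the full-data scores and only the classification threshold
(Youden, learned on the training folds) varies, so the repetition AUC is
computed on pooled out-of-fold scores while sensitivity and specificity
come from pooled out-of-fold calls.  In ``nested`` mode the whole
discovery step (forest, selection, weighting, group assignment) is re-run
inside every training fold, which removes the optimistic bias of scoring
with a signature derived from the full data.

The permutation test shuffles group labels, repeats one stratified k-fold
CV in fixed mode per shuffle, and reports the fraction of null AUCs at
least as large as the observed one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st
from sklearn.model_selection import StratifiedKFold

from .discovery import SignatureModel, assign_groups, fit_importance, normalize_weights, select_taxa
from .evaluation import auc_from_scores, youden_threshold
from .score import score_cohort
from .tables import AbundanceTable, ValidationError


@dataclass
class CvReport:
    per_repetition: pd.DataFrame  # columns: auc, sensitivity, specificity
    means: dict[str, float]
    cis: dict[str, tuple[float, float]]
    k: int
    repeats: int
    seed: int
    mode: str
    fold_fingerprints: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "per_repetition": self.per_repetition.to_dict(orient="records"),
            "means": dict(self.means),
            "cis": {k: list(v) for k, v in self.cis.items()},
            "k": self.k,
            "repeats": self.repeats,
            "seed": self.seed,
            "mode": self.mode,
        }


@dataclass
class PermutationResult:
    observed_auc: float
    null_aucs: np.ndarray
    p: float
    iterations: int
    seed: int
    smoothed: bool = False

    def to_dict(self) -> dict:
        return {
            "observed_auc": self.observed_auc,
            "p": self.p,
            "iterations": self.iterations,
            "seed": self.seed,
            "smoothed": self.smoothed,
            "null_auc_mean": float(np.mean(self.null_aucs)),
        }


def t_interval(values, level: float = 0.95) -> tuple[float, float]:
    """Mean +/- t-quantile * sd / sqrt(n), with n-1 degrees of freedom."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValidationError("need at least 2 values for a t-interval")
    mean = values.mean()
    sd = values.std(ddof=1)
    if np.ptp(values) == 0:  # constant input: zero-width interval
        return (float(values[0]), float(values[0]))
    tq = st.t.ppf(0.5 + level / 2, df=values.size - 1)
    half = tq * sd / np.sqrt(values.size)
    return (float(mean - half), float(mean + half))


def _check_stratification(y: np.ndarray, test_idx: np.ndarray, k: int) -> None:
    # each fold's class counts stay within 1 of the proportional share
    for cls in (0, 1):
        share = (y == cls).sum() / k
        got = (y[test_idx] == cls).sum()
        assert abs(got - share) <= 1.0, "fold is not stratified"


def repeated_cv(
    ab: AbundanceTable,
    signature: SignatureModel,
    k: int = 5,
    repeats: int = 10,
    seed: int = 0,
    mode: str = "fixed",
    level: float = 0.95,
    rf_params: dict | None = None,
    mda_threshold: float = 5.0,
) -> CvReport:
    """Repeated stratified k-fold cross-validation of the index.

    Per repetition: stratified split; per fold, the Youden threshold is
    learned on the training folds and applied to the held-out fold.  The
    repetition's AUC uses pooled out-of-fold scores; sensitivity and
    specificity use pooled out-of-fold calls.  ``rf_params`` (ntree, mtry,
    seed offsets) only matter in nested mode.
    """
    if mode not in ("fixed", "nested"):
        raise ValueError(f"unknown mode {mode!r}")
    y = ab.is_case.astype(int)
    n = y.size
    for cls, cnt in zip(*np.unique(y, return_counts=True)):
        if cnt < k:
            raise ValidationError(
                f"class {cls} has {cnt} samples < k={k}; use a smaller k"
            )
    rf_params = dict(rf_params or {})
    full_scores = score_cohort(signature, ab)["wci"].to_numpy()

    rows = []
    fingerprints = []
    for r in range(repeats):
        skf = StratifiedKFold(
            n_splits=k, shuffle=True, random_state=int(seed + 7919 * r) % (2**31)
        )
        oof_scores = np.empty(n)
        oof_calls = np.empty(n, dtype=bool)
        for train_idx, test_idx in skf.split(np.zeros((n, 1)), y):
            _check_stratification(y, test_idx, k)
            if mode == "fixed":
                train_scores = full_scores[train_idx]
                test_scores = full_scores[test_idx]
            else:
                sub = ab.subset_samples(np.array(ab.sample_ids)[train_idx])
                imp = fit_importance(
                    sub,
                    ntree=rf_params.get("ntree", 500),
                    mtry=rf_params.get("mtry", "auto"),
                    seed=rf_params.get("seed", seed),
                )
                sel = normalize_weights(select_taxa(imp, threshold=mda_threshold))
                sig_r = assign_groups(sel, sub)
                assert not set(np.array(ab.sample_ids)[test_idx]) & set(
                    sub.sample_ids
                ), "test samples leaked into fold training"
                fingerprints.append(
                    {"repeat": r, "train_idx": sorted(map(int, train_idx))}
                )
                train_scores = score_cohort(sig_r, sub)["wci"].to_numpy()
                test_ab = ab.subset_samples(np.array(ab.sample_ids)[test_idx])
                test_scores = score_cohort(sig_r, test_ab)["wci"].to_numpy()
            thr, _, _ = youden_threshold(
                train_scores[y[train_idx] == 1], train_scores[y[train_idx] == 0]
            )
            oof_scores[test_idx] = test_scores
            oof_calls[test_idx] = test_scores > thr
        auc = auc_from_scores(oof_scores[y == 1], oof_scores[y == 0])
        sens = float(oof_calls[y == 1].mean())
        spec = float((~oof_calls[y == 0]).mean())
        rows.append({"auc": auc, "sensitivity": sens, "specificity": spec})

    per_rep = pd.DataFrame(rows)
    means = {m: float(per_rep[m].mean()) for m in per_rep.columns}
    cis = {m: t_interval(per_rep[m], level) for m in per_rep.columns}
    return CvReport(
        per_repetition=per_rep,
        means=means,
        cis=cis,
        k=k,
        repeats=repeats,
        seed=seed,
        mode=mode,
        fold_fingerprints=fingerprints,
    )


def permutation_test(
    ab: AbundanceTable,
    signature: SignatureModel,
    observed_auc: float,
    iterations: int = 1000,
    seed: int = 0,
    k: int = 5,
    smoothed: bool = False,
) -> PermutationResult:
    """Label-permutation null for the cross-validated AUC.

    Each iteration permutes the group labels (class sizes preserved) and
    records the pooled out-of-fold AUC of one stratified k-fold CV in
    fixed-signature mode.  With a frozen signature the out-of-fold scores
    equal the full-data scores, so that AUC reduces to the full-data AUC
    under the permuted labels, which is what is computed here.  p is the
    raw proportion of null AUCs >= observed (``smoothed`` adds the +1
    correction to numerator and denominator).
    """
    if iterations < 1:
        raise ValidationError("iterations must be >= 1")
    rng = np.random.default_rng(int(seed) % (2**31))
    scores = score_cohort(signature, ab)["wci"].to_numpy()
    y = ab.is_case.astype(int)
    null = np.empty(iterations)
    for i in range(iterations):
        perm = rng.permutation(y)
        null[i] = auc_from_scores(scores[perm == 1], scores[perm == 0])
    count = int((null >= observed_auc).sum())
    p = (count + 1) / (iterations + 1) if smoothed else count / iterations
    return PermutationResult(
        observed_auc=float(observed_auc),
        null_aucs=null,
        p=float(p),
        iterations=iterations,
        seed=seed,
        smoothed=smoothed,
    )


def validate(
    ab: AbundanceTable,
    signature: SignatureModel,
    k: int = 5,
    repeats: int = 10,
    permutations: int = 1000,
    seed: int = 0,
    mode: str = "fixed",
) -> tuple[CvReport, PermutationResult]:
    """Run the full two-step validation battery; permutation is always fixed-mode."""
    cv = repeated_cv(ab, signature, k=k, repeats=repeats, seed=seed, mode=mode)
    perm = permutation_test(
        ab,
        signature,
        observed_auc=cv.means["auc"],
        iterations=permutations,
        seed=seed + 1,
        k=k,
    )
    return cv, perm
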