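"""Fixed-split performance statistics for a scored cohort.

Mann-Whitney group comparison, ROC/AUC with a Youden-optimal cutoff and
Wilson confidence intervals for sensitivity and specificity, per-taxon ROC
curves (to compare the composite index with its individual components),
and an age-adjusted logistic regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st
from statsmodels.stats.proportion import proportion_confint

from .discovery import SignatureModel
from .tables import AbundanceTable, ValidationError, warn


@dataclass
class RocResult:
    auc: float
    auc_ci: tuple[float, float]
    threshold: float
    sensitivity: float
    sensitivity_ci: tuple[float, float]
    specificity: float
    specificity_ci: tuple[float, float]
    n_case: int
    n_control: int
    higher_is_case: bool = True

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "auc_ci": list(self.auc_ci),
            "threshold": self.threshold,
            "sensitivity": self.sensitivity,
            "sensitivity_ci": list(self.sensitivity_ci),
            "specificity": self.specificity,
            "specificity_ci": list(self.specificity_ci),
            "n_case": self.n_case,
            "n_control": self.n_control,
            "higher_is_case": self.higher_is_case,
        }


@dataclass
class AdjustedModelResult:
    coefficients: dict[str, float]
    p_values: dict[str, float]
    converged: bool
    separation: bool = False
    notes: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "coefficients": dict(self.coefficients),
            "p_values": dict(self.p_values),
            "converged": self.converged,
            "separation": self.separation,
            "notes": list(self.notes),
        }


def _split(scores: pd.DataFrame, case_label: str):
    mask = scores["group"] == case_label
    case = scores.loc[mask, "wci"].to_numpy(dtype=float)
    control = scores.loc[~mask, "wci"].to_numpy(dtype=float)
    if len(case) == 0 or len(control) == 0:
        raise ValidationError("both groups must be present")
    return case, control


def mann_whitney(
    scores_case: np.ndarray, scores_control: np.ndarray
) -> tuple[float, float]:
    """Two-sided Mann-Whitney test; U reported for the case group.

    Exact distribution for small samples (both groups <= 8, no ties),
    normal approximation with tie correction otherwise.
    """
    case = np.asarray(scores_case, dtype=float)
    control = np.asarray(scores_control, dtype=float)
    if case.size == 0 or control.size == 0:
        raise ValidationError("both groups must be non-empty")
    pooled = np.concatenate([case, control])
    no_ties = len(np.unique(pooled)) == pooled.size
    method = "exact" if (max(case.size, control.size) <= 8 and no_ties) else "asymptotic"
    res = st.mannwhitneyu(case, control, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def auc_from_scores(case: np.ndarray, control: np.ndarray) -> float:
    """AUC as the normalised pair count: (wins + 0.5 * ties) / (n1 * n2).

    Identical to the trapezoidal area under the empirical ROC curve and to
    U / (n1 * n2) of the Mann-Whitney statistic.
    """
    case = np.asarray(case, dtype=float)[:, None]
    control = np.asarray(control, dtype=float)[None, :]
    wins = (case > control).sum()
    ties = (case == control).sum()
    return float((wins + 0.5 * ties) / (case.size * control.size))


def _delong_ci(case, control, level: float = 0.95) -> tuple[float, float]:
    """DeLong-type normal-approximation CI for the AUC (clipped to [0, 1])."""
    case = np.asarray(case, dtype=float)
    control = np.asarray(control, dtype=float)
    m, n = case.size, control.size
    # placement values
    v10 = np.array(
        [((c > control).sum() + 0.5 * (c == control).sum()) / n for c in case]
    )
    v01 = np.array([((case > d).sum() + 0.5 * (case == d).sum()) / m for d in control])
    auc = v10.mean()
    var = 0.0
    if m > 1:
        var += v10.var(ddof=1) / m
    if n > 1:
        var += v01.var(ddof=1) / n
    z = st.norm.ppf(0.5 + level / 2)
    half = z * np.sqrt(var)
    return (float(max(0.0, auc - half)), float(min(1.0, auc + half)))


def youden_threshold(
    case: np.ndarray, control: np.ndarray, prefer: str = "specificity"
) -> tuple[float, float, float]:
    """Cutoff maximising Youden's J = sensitivity + specificity - 1.

    Candidate thresholds are midpoints between consecutive sorted unique
    scores plus one candidate below the minimum and one above the maximum;
    a sample is called a case when its score exceeds the threshold.  Ties
    in J are broken toward the higher-specificity cutoff by default
    (``prefer="sensitivity"`` flips this).
    """
    if prefer not in ("specificity", "sensitivity"):
        raise ValueError(f"unknown preference {prefer!r}")
    case = np.asarray(case, dtype=float)
    control = np.asarray(control, dtype=float)
    uniq = np.unique(np.concatenate([case, control]))
    if uniq.size == 1:
        warn("constant scores: Youden threshold is degenerate")
        candidates = np.array([uniq[0] - 1.0, uniq[0] + 1.0])
    else:
        mids = (uniq[:-1] + uniq[1:]) / 2.0
        candidates = np.concatenate([[uniq[0] - 1.0], mids, [uniq[-1] + 1.0]])
    best = None
    for thr in candidates:
        sens = float((case > thr).mean())
        spec = float((control <= thr).mean())
        j = sens + spec - 1.0
        key = (j, spec) if prefer == "specificity" else (j, sens)
        if best is None or key > best[0]:
            best = (key, thr, sens, spec)
    _, thr, sens, spec = best
    return float(thr), sens, spec


def wilson_ci(successes: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    if n < 1:
        raise ValidationError("n must be >= 1")
    if not (0 <= successes <= n):
        raise ValidationError("successes must lie in [0, n]")
    lo, hi = proportion_confint(successes, n, alpha=1 - level, method="wilson")
    # boundary cases are exact by construction
    lo = 0.0 if successes == 0 else float(lo)
    hi = 1.0 if successes == n else float(hi)
    return lo, hi


def roc_auc(
    scores: pd.DataFrame,
    case_label: str = "BCa",
    level: float = 0.95,
    prefer: str = "specificity",
) -> RocResult:
    """Full ROC summary of a scored cohort (higher score = case direction)."""
    case, control = _split(scores, case_label)
    if np.unique(np.concatenate([case, control])).size == 1:
        warn("constant scores: AUC is 0.5 by convention")
    auc = auc_from_scores(case, control)
    thr, sens, spec = youden_threshold(case, control, prefer=prefer)
    tp = int((case > thr).sum())
    tn = int((control <= thr).sum())
    return RocResult(
        auc=auc,
        auc_ci=_delong_ci(case, control, level),
        threshold=thr,
        sensitivity=tp / case.size,
        sensitivity_ci=wilson_ci(tp, case.size, level),
        specificity=tn / control.size,
        specificity_ci=wilson_ci(tn, control.size, level),
        n_case=case.size,
        n_control=control.size,
    )


def per_taxon_roc(
    ab: AbundanceTable, signature: SignatureModel, level: float = 0.95
) -> dict[str, RocResult]:
    """One ROC per signature taxon, scored by its relative abundance.

    The score direction follows the taxon's assigned group: for
    control-associated taxa the sign is flipped so that AUC > 0.5 still
    means "discriminates in the expected direction".
    """
    out: dict[str, RocResult] = {}
    mask = ab.is_case
    for taxon in signature.taxa:
        if taxon not in ab.ra.columns:
            warn(f"signature taxon {taxon!r} absent from table, skipped")
            continue
        ra = ab.ra[taxon].to_numpy(dtype=float)
        sign = 1.0 if taxon in signature.case_taxa else -1.0
        df = pd.DataFrame(
            {"group": ab.labels, "wci": sign * ra}, index=ab.ra.index
        )
        res = roc_auc(df, case_label=ab.case_label, level=level)
        res.higher_is_case = sign > 0
        out[taxon] = res
    return out


def adjusted_logistic(
    scores: pd.DataFrame,
    age: pd.Series,
    case_label: str = "BCa",
    standardize: bool = False,
) -> AdjustedModelResult:
    """Logistic regression of group on (WCI, age) with Wald p-values.

    Samples with missing age are dropped listwise with a warning.  Under
    perfect separation the unpenalised fit is unstable; the model is then
    refit with a small L2 ridge, flagged, and p-values reported as NaN.
    """
    import statsmodels.api as sm

    df = scores.join(age.rename("age"))
    n_missing = int(df["age"].isna().sum())
    if n_missing:
        warn(f"{n_missing} samples dropped for missing age")
        df = df.dropna(subset=["age"])
    y = (df["group"] == case_label).astype(float).to_numpy()
    X = df[["wci", "age"]].astype(float)
    notes = []
    if standardize:
        for col in X.columns:
            sd = X[col].std(ddof=1)
            if sd > 0:
                X[col] = (X[col] - X[col].mean()) / sd
            else:
                notes.append(f"{col} constant; not standardised")
    degenerate = [c for c in X.columns if X[c].nunique() == 1]
    if degenerate:
        notes.append(f"non-identifiable constant covariates: {degenerate}")
    Xd = sm.add_constant(X, has_constant="add")

    separation = False
    converged = False
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(y, Xd).fit(disp=0, maxiter=200)
        converged = bool(fit.mle_retvals.get("converged", False))
        coefs = dict(zip(Xd.columns, map(float, fit.params)))
        pvals = dict(zip(Xd.columns, map(float, fit.pvalues)))
        if not converged or max(abs(v) for v in coefs.values()) > 1e3:
            separation = True
    except Exception as exc:  # PerfectSeparationError and numerical failures
        separation = True
        notes.append(f"unpenalised fit failed: {exc}")
        coefs, pvals = {}, {}

    if separation:
        from sklearn.linear_model import LogisticRegression

        notes.append("perfect or quasi-separation: refit with L2 ridge; p-values NaN")
        ridge = LogisticRegression(penalty="l2", C=10.0, max_iter=1000)
        ridge.fit(X.to_numpy(), y)
        coefs = {"const": float(ridge.intercept_[0])}
        coefs.update(dict(zip(X.columns, map(float, ridge.coef_[0]))))
        pvals = {k: float("nan") for k in coefs}
        converged = True

    return AdjustedModelResult(
        coefficients=coefs,
        p_values=pvals,
        converged=converged,
        separation=separation,
        notes=notes,
    )


def evaluate_scores(
    scores: pd.DataFrame,
    case_label: str = "BCa",
    age: pd.Series | None = None,
    level: float = 0.95,
) -> dict:
    """Bundle the fixed-split statistics into one report dictionary."""
    case, control = _split(scores, case_label)
    u, p = mann_whitney(case, control)
    report = {
        "mann_whitney": {"U": u, "p": p},
        "roc": roc_auc(scores, case_label=case_label, level=level).to_dict(),
    }
    if age is not None:
        report["adjusted_logistic"] = adjusted_logistic(
            scores, age, case_label=case_label
        ).to_dict()
    return report


def plot_roc(scores: pd.DataFrame, case_label: str = "BCa", path=None):
    """Empirical ROC curve of the scored cohort (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    case, control = _split(scores, case_label)
    thr = np.unique(np.concatenate([case, control]))[::-1]
    tpr = [(case > t).mean() for t in thr] + [1.0]
    fpr = [(control > t).mean() for t in thr] + [1.0]
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot([0] + fpr, [0] + tpr, drawstyle="steps-post")
    ax.plot([0, 1], [0, 1], ls="--", c="grey")
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.set_title(f"AUC = {auc_from_scores(case, control):.3f}")
    if path is not None:
        fig.savefig(path, bbox_inches="tight")
        plt.close(fig)
    return fig
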