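"""Blood-amplicon CRC classification from CpG-unit methylation.

The amplicon stage measures EpiTyper CpG-unit methylation fractions in whole
blood of colorectal-cancer cases and controls. Per-unit two-sample t-tests
(optionally sex-stratified) check for case-vs-control methylation shifts in
the control-vs-stage-I/II and control-vs-stage-III contrasts. The prediction
model is an unpenalised logistic regression on the unit fractions plus sex
(clinical coding: outcome CRC=0 / normal=1, sex male=1 / female=0), pruned by
backward stepwise selection and assessed by leave-one-out cross-validation
(LOOCV), ROC/AUC, and an odds ratio from the Youden-thresholded confusion
table.
"""

from __future__ import annotations

import dataclasses
import logging
from collections.abc import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.metrics import roc_curve

from .datatypes import SimpoError, UnitMethylation

logger = logging.getLogger(__name__)

EARLY_STAGES = frozenset({"I", "II"})


def unit_group_test(
    units: UnitMethylation,
    contrast: str = "ctrl-vs-early",
    stratify_by_sex: bool = False,
    variant: str = "welch",
) -> pd.DataFrame:
    """Per-unit case-vs-control t-tests on effectively detected samples.

    ``contrast`` is ``ctrl-vs-early`` (controls vs stage I/II cases) or
    ``ctrl-vs-III`` (controls vs stage III cases). The returned frame has one
    row per unit (and per sex stratum when requested) with the t statistic,
    two-sided p, group means, the case-minus-control difference (negative =
    decreased methylation in CRC) and group sizes.
    """
    case_mask = _contrast_case_mask(units, contrast)
    ctrl_mask = units.outcome_code == 1
    strata: list[tuple[str, pd.Series]] = [("pooled", pd.Series(True, index=units.values.index))]
    if stratify_by_sex:
        strata = [("male", units.sex_code == 1), ("female", units.sex_code == 0)]
    equal_var = {"welch": False, "student": True}[variant]

    rows = []
    for stratum, smask in strata:
        if not smask.any():
            logger.warning("unit_group_test: empty stratum %r skipped", stratum)
            continue
        for unit in units.unit_ids:
            v = units.values[unit]
            a = v[case_mask & smask].dropna()
            b = v[ctrl_mask & smask].dropna()
            if len(a) < 2 or len(b) < 2:
                continue
            t, p = stats.ttest_ind(a, b, equal_var=equal_var)
            rows.append(
                {
                    "unit": unit,
                    "stratum": stratum,
                    "t": float(t),
                    "p_value": float(p),
                    "case_mean": float(a.mean()),
                    "control_mean": float(b.mean()),
                    "difference": float(a.mean() - b.mean()),
                    "n_case": len(a),
                    "n_control": len(b),
                }
            )
    return pd.DataFrame(rows)


def _contrast_case_mask(units: UnitMethylation, contrast: str) -> pd.Series:
    cases = units.outcome_code == 0
    if contrast in ("ctrl-vs-early", "early"):
        return cases & units.stage.isin(EARLY_STAGES)
    if contrast in ("ctrl-vs-III", "III"):
        return cases & (units.stage == "III")
    if contrast == "all":
        return cases
    raise SimpoError(f"unknown contrast: {contrast!r}")


def fit_logistic(features: pd.DataFrame, outcome: pd.Series) -> pd.Series:
    """Maximum-likelihood logistic coefficients (intercept first).

    Deterministic Newton fit; raises on complete separation, naming a
    perfectly separating feature when one can be identified.
    """
    X = sm.add_constant(features.to_numpy(dtype=float), has_constant="add")
    y = outcome.to_numpy(dtype=float)
    if features.isna().to_numpy().any():
        raise SimpoError("missing feature values in logistic fit")
    if len(np.unique(y)) < 2:
        raise SimpoError("outcome has a single class")
    sep = _separating_feature(features, outcome)
    if sep is not None:
        # a single feature splitting the classes makes the MLE diverge
        raise SimpoError(f"complete separation by feature {sep!r}")
    try:
        res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except Exception as exc:  # PerfectSeparationError or LinAlgError
        raise SimpoError(
            f"logistic fit failed ({_separating_feature(features, outcome) or exc})"
        ) from exc
    params = np.asarray(res.params, dtype=float)
    scale = np.concatenate([[1.0], features.std(ddof=0).to_numpy(dtype=float)])
    if not np.all(np.isfinite(params)) or np.any(np.abs(params * scale) > 1e3):
        sep = _separating_feature(features, outcome)
        if sep is not None:
            raise SimpoError(f"complete separation by feature {sep!r}")
    return pd.Series(params, index=["intercept", *features.columns])


def _separating_feature(features: pd.DataFrame, outcome: pd.Series) -> str | None:
    y = outcome.to_numpy(dtype=float)
    for col in features.columns:
        x = features[col].to_numpy(dtype=float)
        if x[y == 1].size and x[y == 0].size:
            if x[y == 1].min() > x[y == 0].max() or x[y == 0].min() > x[y == 1].max():
                return str(col)
    return None


def _model_aic(features: pd.DataFrame, outcome: pd.Series, cols: Sequence[str]) -> float:
    X = sm.add_constant(
        features[list(cols)].to_numpy(dtype=float) if cols else np.empty((len(features), 0)),
        has_constant="add",
    )
    res = sm.Logit(outcome.to_numpy(dtype=float), X).fit(disp=0, maxiter=200)
    return float(res.aic)


def backward_stepwise(
    features: pd.DataFrame, outcome: pd.Series, criterion: str = "aic"
) -> list[str]:
    """Backward stepwise feature selection for the logistic model.

    Starts from the model containing all inputs and iteratively removes the
    least useful one. With ``criterion='aic'`` the removal lowering AIC the
    most is taken and selection stops when no removal lowers it; with
    ``criterion='pvalue'`` the feature with the largest Wald p > 0.05 is
    removed. Ties break on the lexicographically smallest feature id.
    """
    if features.shape[1] < 1:
        raise SimpoError("backward stepwise needs at least one candidate feature")
    current = list(features.columns)
    if criterion == "aic":
        best_aic = _model_aic(features, outcome, current)
        while current:
            candidates = []
            for col in sorted(current, key=str):
                cols = [c for c in current if c != col]
                try:
                    candidates.append((_model_aic(features, outcome, cols), str(col), col))
                except Exception:
                    continue
            if not candidates:
                break
            candidates.sort(key=lambda c: (c[0], c[1]))
            aic, _, drop = candidates[0]
            if aic < best_aic - 1e-9:
                best_aic = aic
                current.remove(drop)
            else:
                break
        return current
    if criterion == "pvalue":
        while current:
            X = sm.add_constant(features[current].to_numpy(dtype=float), has_constant="add")
            res = sm.Logit(outcome.to_numpy(dtype=float), X).fit(disp=0, maxiter=200)
            pvals = pd.Series(res.pvalues[1:], index=current)
            worst = pvals.sort_values(ascending=False)
            if worst.empty or worst.iloc[0] <= 0.05:
                break
            # largest p; lexicographic tie-break
            top = worst[worst == worst.iloc[0]].index
            current.remove(sorted(top, key=str)[0])
        return current
    raise SimpoError(f"unknown stepwise criterion: {criterion!r}")


def loocv_predict(
    features: pd.DataFrame, outcome: pd.Series, selected: Sequence[str]
) -> pd.Series:
    """Out-of-fold probability of outcome=1 for each sample under LOOCV.

    Each sample is predicted by a logistic model fitted to the other n-1
    samples on exactly the selected features. Folds whose fit fails yield a
    missing probability (counted in a log message).
    """
    if len(features) < 10:
        raise SimpoError("LOOCV needs at least 10 samples")
    cols = list(selected)
    X = sm.add_constant(
        features[cols].to_numpy(dtype=float) if cols else np.empty((len(features), 0)),
        has_constant="add",
    )
    y = outcome.to_numpy(dtype=float)
    n = len(y)
    probs = np.full(n, np.nan)
    failed = 0
    idx = np.arange(n)
    for i in range(n):
        train = idx != i
        try:
            res = sm.Logit(y[train], X[train]).fit(disp=0, maxiter=200)
            probs[i] = float(res.predict(X[i : i + 1])[0])
        except Exception:
            failed += 1
    if failed:
        logger.warning("loocv_predict: %d of %d folds failed to fit", failed, n)
    return pd.Series(probs, index=features.index, name="oof_probability")


def roc_auc(probabilities: pd.Series, outcome: pd.Series) -> tuple[pd.DataFrame, float]:
    """ROC points and AUC (probabilities score the outcome=1 class).

    AUC uses the Mann–Whitney formulation with ties counted 1/2; the ROC is
    the full set of threshold points (fpr, tpr, threshold).
    """
    ok = probabilities.notna()
    p = probabilities[ok].to_numpy(dtype=float)
    y = outcome[ok].to_numpy(dtype=float)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise SimpoError("ROC needs both outcome classes")
    ranks = stats.rankdata(p)
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    fpr, tpr, thr = roc_curve(y, p, drop_intermediate=False)
    points = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    return points, float(auc)


def odds_ratio(tp: int, fp: int, tn: int, fn: int) -> float:
    """Diagnostic odds ratio (TP*TN)/(FP*FN), Haldane +0.5 on any zero cell."""
    cells = np.array([tp, fp, tn, fn], dtype=float)
    if np.any(cells == 0):
        cells = cells + 0.5
    tp_, fp_, tn_, fn_ = cells
    return float((tp_ * tn_) / (fp_ * fn_))


@dataclasses.dataclass(frozen=True)
class ClassifierReport:
    """Thresholded performance summary of the CRC prediction model."""

    selected_features: tuple[str, ...]
    oof_probabilities: pd.Series
    auc: float
    auc_refit: float
    threshold: float
    sensitivity: float
    specificity: float
    odds_ratio: float
    confusion: dict[str, int]

    def to_dict(self) -> dict:
        return {
            "selected_features": list(self.selected_features),
            "auc": self.auc,
            "auc_refit": self.auc_refit,
            "threshold": self.threshold,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "odds_ratio": self.odds_ratio,
            "confusion": dict(self.confusion),
        }

    def summary(self) -> str:
        lines = [
            "CRC prediction model (logistic, backward stepwise, LOOCV)",
            f"  selected features : {', '.join(self.selected_features) or '(intercept only)'}",
            f"  LOOCV AUC         : {self.auc:.3f}",
            f"  refit (apparent) AUC: {self.auc_refit:.3f}",
            f"  threshold (cancer risk): {self.threshold:.3f}",
            f"  sensitivity       : {self.sensitivity:.3f}",
            f"  specificity       : {self.specificity:.3f}",
            f"  odds ratio        : {self.odds_ratio:.2f}",
            f"  confusion         : TP={self.confusion['tp']} FP={self.confusion['fp']} "
            f"TN={self.confusion['tn']} FN={self.confusion['fn']}",
        ]
        return "\n".join(lines)


def classification_summary(
    probabilities: pd.Series,
    outcome: pd.Series,
    threshold_rule: str = "youden",
    fixed_threshold: float = 0.5,
) -> dict:
    """Sensitivity/specificity/OR at a threshold on the cancer-risk scale.

    ``probabilities`` are model probabilities of outcome=1 (normal); the
    positive class for sensitivity is cancer (outcome=0), scored by risk
    1 - probability. The threshold maximises Youden's J on the ROC by
    default (smallest threshold on ties), or is fixed.
    """
    ok = probabilities.notna()
    risk = 1.0 - probabilities[ok]
    is_cancer = (outcome[ok] == 0).astype(float)
    points, auc = roc_auc(risk, is_cancer)
    if threshold_rule == "youden":
        j = points["tpr"] - points["fpr"]
        best = points.loc[j == j.max(), "threshold"]
        threshold = float(best.min())
    elif threshold_rule == "fixed":
        threshold = float(fixed_threshold)
    else:
        raise SimpoError(f"unknown threshold rule: {threshold_rule!r}")
    pred_cancer = risk >= threshold
    tp = int((pred_cancer & (is_cancer == 1)).sum())
    fp = int((pred_cancer & (is_cancer == 0)).sum())
    tn = int((~pred_cancer & (is_cancer == 0)).sum())
    fn = int((~pred_cancer & (is_cancer == 1)).sum())
    return {
        "auc": auc,
        "threshold": threshold,
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
        "odds_ratio": odds_ratio(tp, fp, tn, fn),
        "confusion": {"tp": tp, "fp": fp, "tn": tn, "fn": fn},
    }


class CRCModel:
    """The full amplicon-to-classifier pipeline as a model object.

    Built from a :class:`UnitMethylation` table; ``fit`` restricts to the
    requested contrast's complete-case samples, runs backward stepwise
    selection on unit fractions (+ sex), assesses the selected model by
    LOOCV, and summarises the thresholded classifier.
    """

    def __init__(self, units: UnitMethylation, include_sex: bool = True):
        self.units = units
        self.include_sex = include_sex

    def design(self, contrast: str = "all") -> tuple[pd.DataFrame, pd.Series]:
        units = self.units.complete_cases()
        if contrast == "early":
            keep = (units.outcome_code == 1) | units.stage.isin(EARLY_STAGES)
        elif contrast == "all":
            keep = pd.Series(True, index=units.values.index)
        else:
            raise SimpoError(f"unknown model contrast: {contrast!r}")
        X = units.values.loc[keep].copy()
        if self.include_sex:
            X["sex"] = units.sex_code.loc[keep]
        return X, units.outcome_code.loc[keep]

    def fit(
        self,
        contrast: str = "all",
        criterion: str = "aic",
        selection: str = "full-data",
        threshold_rule: str = "youden",
    ) -> ClassifierReport:
        """Select features, cross-validate and summarise.

        ``selection='full-data'`` performs stepwise selection once on all
        samples and then assesses that fixed feature list by LOOCV (the
        conventional, optimistic ordering); ``selection='nested'`` repeats
        the selection inside every LOOCV fold (honest but slower).
        """
        X, y = self.design(contrast)
        if selection == "full-data":
            selected = backward_stepwise(X, y, criterion=criterion)
            oof = loocv_predict(X, y, selected)
        elif selection == "nested":
            selected = backward_stepwise(X, y, criterion=criterion)
            oof = _nested_loocv(X, y, criterion)
        else:
            raise SimpoError(f"unknown selection mode: {selection!r}")
        summary = classification_summary(oof, y, threshold_rule=threshold_rule)
        coefs = fit_logistic(X[selected], y)
        refit_prob = _predict(coefs, X[selected])
        _, auc_refit = roc_auc(1.0 - refit_prob, (y == 0).astype(float))
        return ClassifierReport(
            selected_features=tuple(selected),
            oof_probabilities=oof,
            auc=summary["auc"],
            auc_refit=auc_refit,
            threshold=summary["threshold"],
            sensitivity=summary["sensitivity"],
            specificity=summary["specificity"],
            odds_ratio=summary["odds_ratio"],
            confusion=summary["confusion"],
        )


def _predict(coefs: pd.Series, features: pd.DataFrame) -> pd.Series:
    lin = coefs["intercept"] + features.to_numpy(dtype=float) @ coefs.iloc[1:].to_numpy()
    return pd.Series(1.0 / (1.0 + np.exp(-lin)), index=features.index)


def _nested_loocv(X: pd.DataFrame, y: pd.Series, criterion: str) -> pd.Series:
    probs = pd.Series(np.nan, index=X.index, name="oof_probability")
    for i, sample in enumerate(X.index):
        train = X.index != sample
        try:
            sel = backward_stepwise(X.loc[train], y.loc[train], criterion=criterion)
            coefs = fit_logistic(X.loc[train, sel], y.loc[train])
            probs.loc[sample] = _predict(coefs, X.loc[[sample], sel]).iloc[0]
        except SimpoError:
            continue
    return probs
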