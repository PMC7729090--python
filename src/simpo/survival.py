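"""Survival analysis of per-gene methylation scores.

Patients are split into high (top 50%) and low (bottom 50%) score groups at
the median for Kaplan–Meier curves and a two-group log-rank test; a
univariate Cox proportional-hazards fit (Breslow ties by default) gives the
hazard ratio exp(coef) with a Wald 95% confidence interval, on either the
continuous score or the binary group contrast.
"""

from __future__ import annotations

import dataclasses
import logging
from collections.abc import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .datatypes import SimpoError, SurvivalRecord, survival_frame

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class SurvivalResult:
    """Univariate Cox + log-rank summary for one gene's score."""

    gene: str
    hazard_ratio: float
    coef: float
    ci_low: float
    ci_high: float
    cox_p: float
    logrank_p: float
    n: int


def median_split(
    scores: pd.Series, tie_rule: str = "low", seed: int | None = None
) -> pd.Series:
    """Label samples 'high' (score above the median) or 'low' (at or below).

    With ``tie_rule='random'`` samples exactly at the median are assigned to
    either group with equal probability (seeded).
    """
    s = scores.dropna()
    if len(s) < 4:
        raise SimpoError("median split needs at least 4 non-missing scores")
    if np.ptp(s.to_numpy()) == 0:
        raise SimpoError("degenerate split: all scores identical")
    med = float(s.median())
    labels = pd.Series(np.where(s > med, "high", "low"), index=s.index)
    if tie_rule == "random":
        at = s.index[s == med]
        rng = np.random.default_rng(seed)
        labels.loc[at] = rng.choice(["high", "low"], size=len(at))
    elif tie_rule != "low":
        raise SimpoError(f"unknown tie rule: {tie_rule!r}")
    if labels.nunique() < 2:
        raise SimpoError("degenerate split: one group is empty")
    return labels


def km_estimator(records: Sequence[SurvivalRecord]) -> pd.Series:
    """Product-limit survival estimate S(t), indexed by event time.

    Right-continuous and non-increasing; starts at S(0)=1. With no censoring
    it equals the empirical survival function.
    """
    if not records:
        raise SimpoError("no survival records")
    frame = survival_frame(records)
    kmf = KaplanMeierFitter()
    kmf.fit(frame["time"], frame["event"])
    sf = kmf.survival_function_["KM_estimate"]
    sf.index.name = "time"
    return sf


def logrank_test(
    groups: pd.Series, records: Sequence[SurvivalRecord]
) -> tuple[float, float]:
    """Two-group log-rank chi-square (1 df) and two-sided p."""
    frame = survival_frame(records).loc[groups.index]
    labels = groups.unique()
    if len(labels) != 2:
        raise SimpoError(f"log-rank test needs exactly 2 groups, got {len(labels)}")
    a = frame[groups == labels[0]]
    b = frame[groups == labels[1]]
    for name, g in ((labels[0], a), (labels[1], b)):
        if g["event"].sum() == 0:
            logger.warning("log-rank: group %r has zero events", name)
    res = _ll_logrank(a["time"], b["time"], event_observed_A=a["event"],
                      event_observed_B=b["event"])
    return float(res.test_statistic), float(res.p_value)


def cox_univariate(
    covariate: pd.Series,
    records: Sequence[SurvivalRecord],
    gene: str = "",
    ties: str = "breslow",
) -> SurvivalResult:
    """Univariate Cox PH fit of survival on one covariate.

    Returns the hazard ratio exp(coef), its Wald 95% CI and p, plus the
    log-rank p of the median split of the same covariate (NaN if the split
    is degenerate).
    """
    frame = survival_frame(records)
    cov = covariate.reindex(frame.index)
    ok = cov.notna()
    frame = frame.loc[ok]
    cov = cov.loc[ok]
    if np.ptp(cov.to_numpy(dtype=float)) == 0:
        raise SimpoError("constant covariate in Cox fit")
    if frame["event"].sum() < 10:
        logger.warning("cox_univariate: fewer than 10 events (%d)", int(frame["event"].sum()))
    x = cov.to_numpy(dtype=float)
    if ties not in ("breslow", "efron"):
        raise SimpoError(f"unsupported tie handling: {ties!r}")
    coef, se = _cox_newton(
        x, frame["time"].to_numpy(float), frame["event"].to_numpy(int), ties=ties
    )
    from scipy import stats as _st

    p = float(2 * _st.norm.sf(abs(coef / se))) if se > 0 else float("nan")
    if not np.isfinite(coef) or abs(coef) > 50:
        raise SimpoError("monotone partial likelihood (complete separation)")
    try:
        labels = median_split(cov)
        _, lr_p = logrank_test(labels, records)
    except SimpoError:
        lr_p = float("nan")
    return SurvivalResult(
        gene=gene,
        hazard_ratio=float(np.exp(coef)),
        coef=coef,
        ci_low=float(np.exp(coef - 1.959963984540054 * se)),
        ci_high=float(np.exp(coef + 1.959963984540054 * se)),
        cox_p=p,
        logrank_p=lr_p,
        n=len(frame),
    )


def _cox_newton(
    x: np.ndarray, time: np.ndarray, event: np.ndarray, ties: str = "breslow",
    max_iter: int = 100, tol: float = 1e-12,
) -> tuple[float, float]:
    """Newton–Raphson for the single-covariate Cox partial likelihood.

    Breslow uses the full risk-set denominator for every tied event; Efron
    progressively removes the tied deaths' share. The returned standard
    error is the inverse square root of the observed information.
    """
    order = np.argsort(time)
    x, time, event = x[order], time[order], event[order]
    etimes = np.unique(time[event == 1])
    beta = 0.0
    for _ in range(max_iter):
        w = np.exp(beta * x)
        grad = hess = 0.0
        for t in etimes:
            risk = time >= t
            dead = (time == t) & (event == 1)
            d = int(dead.sum())
            sr, ur, wr = w[risk].sum(), (x[risk] * w[risk]).sum(), (x[risk] ** 2 * w[risk]).sum()
            sd, ud, wd = w[dead].sum(), (x[dead] * w[dead]).sum(), (x[dead] ** 2 * w[dead]).sum()
            grad += x[dead].sum()
            for ell in range(d):
                f = ell / d if ties == "efron" else 0.0
                phi = sr - f * sd
                u = ur - f * ud
                v = wr - f * wd
                grad -= u / phi
                hess += v / phi - (u / phi) ** 2
        if hess <= 0:
            raise SimpoError("monotone partial likelihood (complete separation)")
        step = grad / hess
        beta += step
        if abs(step) < tol:
            break
    else:
        raise SimpoError("Cox fit did not converge")
    return float(beta), float(1.0 / np.sqrt(hess))


def survival_screen(
    scores: pd.DataFrame,
    records: Sequence[SurvivalRecord],
    mode: str = "continuous",
) -> pd.DataFrame:
    """Per-gene survival screen over a genes-x-samples score table.

    ``mode='continuous'`` fits Cox on the raw score; ``mode='median-split'``
    on the 0/1 high-vs-low indicator. Genes whose fit fails are skipped.
    """
    if mode not in ("continuous", "median-split"):
        raise SimpoError(f"unknown survival mode: {mode!r}")
    ids = [r.sample_id for r in records]
    shared = scores.columns.intersection(ids)
    if shared.empty:
        raise SimpoError("no overlap between score sample ids and survival records")
    rows = []
    for gene in scores.index:
        s = scores.loc[gene, shared].astype(float)
        try:
            if mode == "median-split":
                cov = (median_split(s) == "high").astype(float)
            else:
                cov = s
            res = cox_univariate(cov, records, gene=gene)
        except SimpoError as exc:
            logger.info("survival screen: gene %s skipped (%s)", gene, exc)
            continue
        rows.append(dataclasses.asdict(res))
    return pd.DataFrame(
        rows,
        columns=["gene", "hazard_ratio", "coef", "ci_low", "ci_high",
                 "cox_p", "logrank_p", "n"],
    )
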