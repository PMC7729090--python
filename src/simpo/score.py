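"""The promoter-vs-other-regions methylation score.

For one gene in one sample, let x be the beta values of its m promoter probes
(TSS1500/TSS200/5'UTR/1stExon) and y the values of its n other-region probes
(gene body/3'UTR). The score is the pooled-variance two-sample t-statistic

    score = (x_bar - y_bar) / (Sw * sqrt(1/m + 1/n)),
    Sw^2  = [(m-1) S1^2 + (n-1) S2^2] / (m + n - 2),

with unbiased sample variances S1^2, S2^2; under the no-difference null it is
t-distributed with m+n-2 degrees of freedom. The raw t-value (not a p-value)
is the gene's methylation characteristic carried downstream.
"""

from __future__ import annotations

import logging
from collections.abc import Sequence

import numpy as np

from .datatypes import BetaMatrix, GeneProbeGroups, SimpoError, SimpoMatrix

logger = logging.getLogger(__name__)


def simpo_score(
    promoter_values: Sequence[float], other_values: Sequence[float]
) -> float:
    """Pooled two-sample t-statistic of promoter vs other-region beta values.

    Positive when promoter methylation exceeds other-region methylation.
    Returns NaN when either group has fewer than 2 non-missing values. With
    zero pooled variance: 0 for equal means, signed infinity otherwise.
    """
    x = np.asarray(promoter_values, dtype=float)
    y = np.asarray(other_values, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    return float(_pooled_t(x.mean() if x.size else np.nan,
                           y.mean() if y.size else np.nan,
                           x.var(ddof=1) if x.size > 1 else np.nan,
                           y.var(ddof=1) if y.size > 1 else np.nan,
                           x.size, y.size))


def _pooled_t(xbar, ybar, s1sq, s2sq, m, n):
    """Vectorized pooled t; inputs may be arrays. NaN where m<2 or n<2."""
    xbar, ybar = np.asarray(xbar, float), np.asarray(ybar, float)
    s1sq, s2sq = np.asarray(s1sq, float), np.asarray(s2sq, float)
    m, n = np.asarray(m, float), np.asarray(n, float)
    with np.errstate(invalid="ignore", divide="ignore"):
        sw = np.sqrt(((m - 1) * s1sq + (n - 1) * s2sq) / (m + n - 2))
        denom = sw * np.sqrt(1.0 / m + 1.0 / n)
        diff = xbar - ybar
        t = diff / denom
        # zero pooled variance: equal means -> 0, unequal -> signed infinity
        zerovar = denom == 0
        t = np.where(zerovar & (diff == 0), 0.0, t)
        t = np.where(zerovar & (diff != 0), np.sign(diff) * np.inf, t)
        t = np.where((m < 2) | (n < 2), np.nan, t)
    return t


def simpo_matrix(beta: BetaMatrix, groups: Sequence[GeneProbeGroups]) -> SimpoMatrix:
    """Score every (gene, sample) pair of a beta matrix.

    Within each sample, probes missing in that sample are dropped before the
    group means and variances are formed, so m and n are recomputed per
    sample; the realised degrees of freedom are kept in ``df_used``. Genes
    scorable in no sample are dropped with a warning.
    """
    if not groups:
        raise SimpoError("no gene probe groups supplied")
    probe_pos = {p: i for i, p in enumerate(beta.probe_ids)}
    missing = [
        p
        for g in groups
        for p in (*g.promoter_probes, *g.other_probes)
        if p not in probe_pos
    ]
    if missing:
        raise SimpoError(f"probes referenced by groups absent from beta matrix: {missing[:5]}")

    n_samples = beta.n_samples
    vals = beta.values
    kept_genes: list[str] = []
    kept_rows: list[np.ndarray] = []
    kept_df: list[np.ndarray] = []
    m_manifest: list[int] = []
    n_manifest: list[int] = []

    for g in groups:
        prom = vals[[probe_pos[p] for p in g.promoter_probes], :]
        other = vals[[probe_pos[p] for p in g.other_probes], :]
        m = np.sum(~np.isnan(prom), axis=0)
        n = np.sum(~np.isnan(other), axis=0)
        xbar = _nanmean_cols(prom, m, n_samples)
        ybar = _nanmean_cols(other, n, n_samples)
        s1 = _nanvar_cols(prom, m)
        s2 = _nanvar_cols(other, n)
        t = _pooled_t(xbar, ybar, s1, s2, m, n)
        if np.all(np.isnan(t)):
            logger.warning("gene %s scored in no sample; dropped", g.gene)
            continue
        kept_genes.append(g.gene)
        kept_rows.append(t)
        kept_df.append(np.where(np.isnan(t), np.nan, m + n - 2.0))
        m_manifest.append(g.m)
        n_manifest.append(g.n)

    if not kept_genes:
        raise SimpoError("no gene could be scored in any sample")
    return SimpoMatrix(
        genes=tuple(kept_genes),
        sample_ids=beta.sample_ids,
        scores=np.vstack(kept_rows),
        m=np.asarray(m_manifest, dtype=int),
        n=np.asarray(n_manifest, dtype=int),
        df_used=np.vstack(kept_df),
    )


def _nanmean_cols(block: np.ndarray, counts: np.ndarray, width: int) -> np.ndarray:
    """Column-wise mean ignoring NaN; NaN where count == 0."""
    out = np.full(width, np.nan)
    ok = counts > 0
    if block.size and np.any(ok):
        out[ok] = np.nanmean(block[:, ok], axis=0)
    return out


def _nanvar_cols(block: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """Column-wise unbiased variance ignoring NaN; NaN where count < 2."""
    out = np.full(block.shape[1], np.nan)
    ok = counts > 1
    if block.size and np.any(ok):
        out[ok] = np.nanvar(block[:, ok], axis=0, ddof=1)
    return out
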