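"""Associating per-gene scores with age group and immune-cell proportions.

Two families of per-gene tests, each followed by multiple-testing adjustment:

* a two-sample t-test of scores between older (>50 y) and middle-aged
  (<=50 y) individuals (Welch by default, Student optional);
* a Spearman or Pearson correlation of scores against one immune-cell
  proportion (or the summed CD8+ T + CD4+ T composite).

Ranked hit lists from the two families are intersected at the top-N level to
nominate genes tied to both aging and immune composition; a generic
hypergeometric over-representation test is provided for user-supplied sets.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
from collections.abc import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import GeneSet, SampleMetadata, SimpoError, SimpoMatrix

logger = logging.getLogger(__name__)

DEFAULT_AGE_CUTOFF = 50.0


@dataclasses.dataclass(frozen=True)
class AssociationResult:
    """One gene's test outcome: statistic (t or rho), p, BH q, sample count."""

    gene: str
    statistic: float
    p_value: float
    q_value: float
    n_samples: int
    method: str


def adjust_pvalues(p: Sequence[float], method: str = "bh") -> np.ndarray:
    """Multiple-testing adjustment preserving input order.

    ``bh`` is the Benjamini–Hochberg step-up FDR, ``bonferroni`` the family-wise
    bound, ``none`` the identity.
    """
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        return arr
    if np.any((arr <= 0) | (arr > 1) | np.isnan(arr)):
        raise SimpoError("p-values must lie in (0, 1]")
    if method == "none":
        return arr.copy()
    if method == "bh":
        return multipletests(arr, method="fdr_bh")[1]
    if method == "bonferroni":
        return multipletests(arr, method="bonferroni")[1]
    raise SimpoError(f"unknown adjustment method: {method!r}")


def age_group_diff(
    simpo: SimpoMatrix,
    meta: SampleMetadata,
    age_cutoff: float = DEFAULT_AGE_CUTOFF,
    variant: str = "welch",
    adjust: str = "bh",
) -> list[AssociationResult]:
    """Per-gene t-test of scores between old (>cutoff) and middle (<=cutoff).

    Samples aged exactly at the cutoff fall in the middle group. Genes with
    fewer than 2 usable scores in either group are skipped (logged); results
    are sorted by ascending p-value with q-values over all tested genes.
    """
    ages = meta.ages(simpo.sample_ids).to_numpy(dtype=float)
    if np.isnan(ages).any():
        raise SimpoError("every scored sample needs an age for the group test")
    old = ages > age_cutoff
    mid = ~old
    if not old.any():
        raise SimpoError("empty old group (no sample older than the cutoff)")
    if not mid.any():
        raise SimpoError("empty middle group (no sample at or below the cutoff)")

    equal_var = {"welch": False, "student": True}.get(variant)
    if equal_var is None:
        raise SimpoError(f"unknown t-test variant: {variant!r}")

    rows, skipped = [], 0
    for gi, gene in enumerate(simpo.genes):
        s = simpo.scores[gi]
        a = s[old]
        b = s[mid]
        a = a[np.isfinite(a)]
        b = b[np.isfinite(b)]
        if a.size < 2 or b.size < 2:
            skipped += 1
            continue
        t, p = stats.ttest_ind(a, b, equal_var=equal_var)
        rows.append((gene, float(t), float(max(p, np.nextafter(0, 1))), a.size + b.size))
    if skipped:
        logger.info("age_group_diff: skipped %d genes with <2 scores per group", skipped)
    return _finalize(rows, "group-t", adjust)


def correlate_cell_proportion(
    simpo: SimpoMatrix,
    meta: SampleMetadata,
    cell_type: str,
    method: str = "pearson",
    adjust: str = "bh",
) -> list[AssociationResult]:
    """Per-gene correlation of scores with one immune-cell proportion.

    ``cell_type`` is one of the six whole-blood cell types or the composite
    ``"CD8T+CD4T"``. Spearman p-values use the t-approximation for n>10 and
    exact permutation enumeration for n<=10.
    """
    prop = meta.cell_proportion(cell_type, simpo.sample_ids).to_numpy(dtype=float)
    if method not in ("spearman", "pearson"):
        raise SimpoError(f"unknown correlation method: {method!r}")
    rows, skipped = [], 0
    for gi, gene in enumerate(simpo.genes):
        s = simpo.scores[gi]
        ok = np.isfinite(s) & np.isfinite(prop)
        if ok.sum() < 3:
            skipped += 1
            continue
        x, y = s[ok], prop[ok]
        if np.ptp(y) == 0:
            raise SimpoError(f"degenerate covariate: {cell_type} constant across samples")
        if np.ptp(x) == 0:
            skipped += 1
            continue
        if method == "pearson":
            rho, p = stats.pearsonr(x, y)
        else:
            rho, p = _spearman(x, y)
        rows.append((gene, float(rho), float(max(p, np.nextafter(0, 1))), int(ok.sum())))
    if skipped:
        logger.info("correlate_cell_proportion: skipped %d degenerate genes", skipped)
    return _finalize(rows, method, adjust)


def _spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    res = stats.spearmanr(x, y)
    n = x.size
    if n > 10:
        return float(res.statistic), float(res.pvalue)
    # exact two-sided permutation p over all n! orderings of y: with rx fixed,
    # |rho| is monotone in |sum(rx*ry_perm) - n*mean(rx)*mean(ry)|
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    center = n * rx.mean() * ry.mean()
    obs = abs(float(rx @ ry) - center)
    it = itertools.permutations(ry)
    count = total = 0
    while True:
        chunk = list(itertools.islice(it, 200_000))
        if not chunk:
            break
        s = np.asarray(chunk) @ rx
        count += int(np.sum(np.abs(s - center) >= obs - 1e-9))
        total += len(chunk)
    return float(res.statistic), count / total


def _finalize(rows, method: str, adjust: str) -> list[AssociationResult]:
    if not rows:
        return []
    p = [r[2] for r in rows]
    q = adjust_pvalues(p, adjust)
    results = [
        AssociationResult(gene, stat, pv, float(qv), n, method)
        for (gene, stat, pv, n), qv in zip(rows, q)
    ]
    return sorted(results, key=lambda r: (r.p_value, r.gene))


def rank_intersect(
    a: Sequence[AssociationResult],
    b: Sequence[AssociationResult],
    top_n: int = 10,
) -> set[str]:
    """Genes appearing in the top-``top_n`` of both significance-ranked lists."""
    if top_n > len(a) or top_n > len(b):
        logger.warning(
            "rank_intersect: top_n=%d exceeds a list length (%d, %d); using full lists",
            top_n, len(a), len(b),
        )
    top_a = {r.gene for r in a[:top_n]}
    top_b = {r.gene for r in b[:top_n]}
    return top_a & top_b


def hypergeometric_enrichment(
    hits: set[str], gene_set: GeneSet, universe: set[str]
) -> tuple[int, float]:
    """Upper-tail hypergeometric over-representation of ``gene_set`` in ``hits``.

    Returns (overlap count, one-sided p of drawing at least that overlap when
    ``len(hits)`` genes are drawn from ``universe`` without replacement).
    """
    if not hits <= universe:
        raise SimpoError("hits must be a subset of the universe")
    in_universe = gene_set.symbols & universe
    if not in_universe:
        raise SimpoError("gene set does not intersect the universe")
    overlap = len(hits & in_universe)
    M, K, N = len(universe), len(in_universe), len(hits)
    p = float(stats.hypergeom.sf(overlap - 1, M, K, N))
    return overlap, min(p, 1.0)


def results_frame(results: Sequence[AssociationResult]) -> pd.DataFrame:
    """Tabular view (gene, statistic, p, q, n, method) for writing as TSV."""
    return pd.DataFrame(
        [dataclasses.asdict(r) for r in results],
        columns=["gene", "statistic", "p_value", "q_value", "n_samples", "method"],
    )
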