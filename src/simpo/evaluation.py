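"""Desk-scale validation studies of the whole pipeline.

Each study regenerates synthetic data under the documented study conditions,
runs the relevant pipeline stage from scratch, and returns summary numbers
(error bounds, type-I rates, recovery rates, AUCs). They are what the
acceptance checks and the reproduction script execute; sizes are chosen so a
full run stays within a few minutes on one CPU.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence`` so any study can be reproduced independently.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve

from .association import age_group_diff, correlate_cell_proportion
from .classifier import CRCModel, loocv_predict, odds_ratio, roc_auc
from .datatypes import BetaMatrix, ProbeAnnotation, build_gene_probe_groups
from .score import simpo_matrix, simpo_score
from .simulate import (
    CohortSimConfig,
    simulate_epityper,
    simulate_methylation_cohort,
    simulate_survival,
    unit_shifts_for_auc,
)
from .survival import cox_univariate, logrank_test


def _child_seeds(seed: int, k: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(k) % (2**31)]


def score_oracle_study(seed: int, n_pairs: int = 1000) -> dict:
    """Compare the score against an independently coded pooled t on random data.

    Also measures the worst-case violation of antisymmetry and of shift/scale
    invariance over the same draws.
    """
    rng = np.random.default_rng(seed)
    max_rel = 0.0
    max_sym = 0.0
    max_inv = 0.0
    for _ in range(n_pairs):
        m = int(rng.integers(5, 51))
        n = int(rng.integers(5, 51))
        x = rng.random(m)
        y = rng.random(n)
        got = simpo_score(x, y)
        # oracle: textbook pooled two-sample t, coded independently
        sw2 = ((m - 1) * x.var(ddof=1) + (n - 1) * y.var(ddof=1)) / (m + n - 2)
        want = (x.mean() - y.mean()) / np.sqrt(sw2 * (1 / m + 1 / n))
        max_rel = max(max_rel, abs(got - want) / max(abs(want), 1e-300))
        max_sym = max(max_sym, abs(simpo_score(y, x) + got))
        # pure shift (kept inside [0,1]) and pure scale; relative error for
        # large scores, absolute for scores below 1
        c = (1.0 - max(x.max(), y.max())) * 0.5
        denom = max(1.0, abs(got))
        max_inv = max(
            max_inv,
            abs(simpo_score(x + c, y + c) - got) / denom,
            abs(simpo_score(x * 0.37, y * 0.37) - got) / denom,
        )
    return {
        "max_rel_error": max_rel,
        "max_antisymmetry_error": max_sym,
        "max_invariance_error": max_inv,
        "n": n_pairs,
    }


def filter_study(seed: int, n_symbols: int = 233, n_with_probes: int = 103) -> dict:
    """Check the >=5/>=5 probe filter against exhaustive per-gene counting.

    Generates a manifest over a curated-symbol-sized universe where a random
    subset of genes receives probes with varying promoter/other counts.
    """
    rng = np.random.default_rng(seed)
    symbols = [f"E3_{i:03d}" for i in range(n_symbols)]
    with_probes = list(rng.choice(symbols, size=n_with_probes, replace=False))
    records, specs, counter = [], {}, 0
    for gene in with_probes:
        m = int(rng.integers(1, 13))
        n = int(rng.integers(1, 13))
        specs[gene] = (m, n)
        for _ in range(m):
            records.append((f"cg{counter:06d}", [gene], ["TSS200"]))
            counter += 1
        for _ in range(n):
            records.append((f"cg{counter:06d}", [gene], ["Body"]))
            counter += 1
    ann = ProbeAnnotation(records)
    beta = BetaMatrix(
        tuple(ann.probe_ids), ("s1",), np.full((len(ann.probe_ids), 1), 0.5)
    )
    got = [g.gene for g in build_gene_probe_groups(ann, beta)]
    expected = sorted(g for g, (m, n) in specs.items() if m >= 5 and n >= 5)
    mismatches = len(set(got) ^ set(expected))
    return {"mismatch_count": mismatches, "n_pass": len(expected), "n": n_symbols}


def null_calibration_study(
    seed: int, n_genes: int = 1000, n_samples: int = 200
) -> dict:
    """Type-I rates of the age t-test and the cell-proportion Spearman test
    on a fully null cohort (no planted effects)."""
    cfg = CohortSimConfig(n_samples=n_samples, n_genes=n_genes, seed=seed)
    beta, ann, meta, _ = simulate_methylation_cohort(cfg)
    matrix = simpo_matrix(beta, build_gene_probe_groups(ann, beta))
    age_res = age_group_diff(matrix, meta)
    sp_res = correlate_cell_proportion(matrix, meta, "CD4T", method="spearman")
    return {
        "typeI_age_ttest": float(np.mean([r.p_value < 0.05 for r in age_res])),
        "typeI_spearman": float(np.mean([r.p_value < 0.05 for r in sp_res])),
        "n": len(age_res) + len(sp_res),
    }


def age_recovery_study(
    seed: int,
    n_seeds: int = 20,
    n_genes: int = 1000,
    n_samples: int = 200,
    n_effect: int = 30,
    slope: float = 0.002,
) -> dict:
    """Recovery of planted age-effect genes at BH q<0.05, averaged over seeds."""
    sens, fdp = [], []
    for s in _child_seeds(seed, n_seeds):
        rng = np.random.default_rng(s)
        genes = [f"G{i:04d}" for i in range(n_genes)]
        planted = rng.choice(genes, size=n_effect, replace=False)
        cfg = CohortSimConfig(
            n_samples=n_samples, n_genes=n_genes, seed=s,
            effect_genes_age={g: slope for g in planted},
        )
        beta, ann, meta, truth = simulate_methylation_cohort(cfg)
        matrix = simpo_matrix(beta, build_gene_probe_groups(ann, beta))
        res = age_group_diff(matrix, meta)
        sig = {r.gene for r in res if r.q_value < 0.05}
        truth_set = truth.planted("age")
        tp = len(sig & truth_set)
        sens.append(tp / len(truth_set))
        fdp.append((len(sig) - tp) / max(len(sig), 1))
    return {
        "sensitivity": float(np.mean(sens)),
        "fdp": float(np.mean(fdp)),
        "n": n_seeds,
    }


def survival_recovery_study(
    seed: int, n_seeds: int = 20, n: int = 300, true_log_hr: float = 0.7,
    censoring_rate: float = 0.4,
) -> dict:
    """Mean Cox log-HR estimate on exponential data with a known hazard."""
    coefs = []
    for s in _child_seeds(seed, n_seeds):
        rng = np.random.default_rng(s)
        scores = rng.normal(size=n)
        recs = simulate_survival(scores, true_log_hr=true_log_hr,
                                 censoring_rate=censoring_rate, seed=s)
        cov = pd.Series(scores, index=[r.sample_id for r in recs])
        coefs.append(cox_univariate(cov, recs).coef)
    return {"mean_coef": float(np.mean(coefs)), "true": true_log_hr, "n": n_seeds}


def logrank_null_study(seed: int, n_sims: int = 1000, n_per_group: int = 50) -> dict:
    """Log-rank rejection rate at alpha=0.05 under the null (no group effect)."""
    rejections = 0
    for s in _child_seeds(seed, n_sims):
        rng = np.random.default_rng(s)
        times = rng.exponential(10, 2 * n_per_group)
        # light censoring, independent of group
        cens = rng.exponential(40, 2 * n_per_group)
        event = (times <= cens).astype(int)
        obs = np.minimum(times, cens)
        from .datatypes import SurvivalRecord

        recs = [
            SurvivalRecord(f"p{i}", float(max(t, 1e-9)), int(e))
            for i, (t, e) in enumerate(zip(obs, event))
        ]
        labels = pd.Series(["a"] * n_per_group + ["b"] * n_per_group,
                           index=[r.sample_id for r in recs])
        _, p = logrank_test(labels, recs)
        rejections += p < 0.05
    return {"rejection_rate": rejections / n_sims, "n": n_sims}


def classifier_recovery_study(
    seed: int, n_seeds: int = 20, n: int = 150, target_auc: float = 0.85
) -> dict:
    """LOOCV AUC on a binormal single feature with closed-form population AUC,
    plus the label-shuffled null AUC."""
    d_prime = np.sqrt(2.0) * stats.norm.ppf(target_auc)
    aucs, null_aucs = [], []
    for s in _child_seeds(seed, n_seeds):
        rng = np.random.default_rng(s)
        n_pos = n // 2
        n_neg = n - n_pos
        x = np.r_[rng.normal(d_prime, 1, n_pos), rng.normal(0, 1, n_neg)]
        y = pd.Series(np.r_[np.ones(n_pos), np.zeros(n_neg)].astype(int))
        X = pd.DataFrame({"x": x})
        probs = loocv_predict(X, y, ["x"])
        aucs.append(roc_auc(probs, y)[1])
        y_shuf = pd.Series(rng.permutation(y.to_numpy()))
        probs0 = loocv_predict(X, y_shuf, ["x"])
        null_aucs.append(roc_auc(probs0, y_shuf)[1])
    return {
        "mean_auc": float(np.mean(aucs)),
        "null_mean_auc": float(np.mean(null_aucs)),
        "target": target_auc,
        "n": n_seeds,
    }


def auc_identity_study(seed: int, n_instances: int = 100) -> dict:
    """Mann-Whitney AUC vs trapezoidal ROC integration, plus the 4-sample
    worked example solved by brute-force pair counting."""
    max_diff = 0.0
    for s in _child_seeds(seed, n_instances):
        rng = np.random.default_rng(s)
        n = int(rng.integers(10, 80))
        p = pd.Series(np.round(rng.random(n), 2))
        y = pd.Series(rng.integers(0, 2, n))
        if y.nunique() < 2:
            y.iloc[0] = 1 - y.iloc[0]
        _, auc = roc_auc(p, y)
        fpr, tpr, _ = roc_curve(y, p, drop_intermediate=False)
        max_diff = max(max_diff, abs(auc - float(np.trapezoid(tpr, fpr))))
    p4 = pd.Series([0.9, 0.8, 0.4, 0.1])
    y4 = pd.Series([1, 0, 1, 0])
    _, auc4 = roc_auc(p4, y4)
    pairs = [
        (a, b)
        for a, ya in zip(p4, y4) if ya == 1
        for b, yb in zip(p4, y4) if yb == 0
    ]
    brute = float(np.mean([1.0 if a > b else 0.5 if a == b else 0.0 for a, b in pairs]))
    return {
        "max_abs_diff": max_diff,
        "four_sample_auc": float(auc4),
        "four_sample_brute_force": brute,
        "n": n_instances,
    }


def end_to_end_study(
    seed: int, n_seeds: int = 20, target_auc: float = 0.83, n_affected: int = 6
) -> dict:
    """Full amplicon pipeline (unit tests -> stepwise -> LOOCV -> Youden) on
    the early-stage case/control design (53 stage-I/II cases, 50 controls),
    with effects planted for a known population AUC."""
    shifts = unit_shifts_for_auc(target_auc, n_affected)
    case_shift = np.zeros(15)
    case_shift[:n_affected] = shifts
    aucs, ors, sens, spec = [], [], [], []
    consistent = True
    for s in _child_seeds(seed, n_seeds):
        units, _ = simulate_epityper(
            n_case=100, n_control=50, case_shift=case_shift, seed=s
        )
        report = CRCModel(units).fit(contrast="early")
        aucs.append(report.auc)
        ors.append(report.odds_ratio)
        sens.append(report.sensitivity)
        spec.append(report.specificity)
        c = report.confusion
        # direct arithmetic on the thresholded confusion table
        ok = (
            np.isclose(report.sensitivity, c["tp"] / (c["tp"] + c["fn"]))
            and np.isclose(report.specificity, c["tn"] / (c["tn"] + c["fp"]))
            and np.isclose(
                report.odds_ratio, odds_ratio(c["tp"], c["fp"], c["tn"], c["fn"])
            )
        )
        consistent = consistent and bool(ok)
    return {
        "mean_auc": float(np.mean(aucs)),
        "mean_odds_ratio": float(np.mean(ors)),
        "mean_sensitivity": float(np.mean(sens)),
        "mean_specificity": float(np.mean(spec)),
        "target_auc": target_auc,
        "confusion_consistent": consistent,
        "n": n_seeds,
    }
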