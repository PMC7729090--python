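"""Synthetic cohorts with the statistical structure the pipeline assumes.

Three generators cover the pipeline's inputs end to end:

* a whole-blood methylation-array cohort (probe betas + annotation + sample
  metadata) with optional age-linear and cell-proportion-linked shifts in the
  promoter-vs-other-regions contrast of chosen genes;
* exponential survival times whose hazard depends log-linearly on a supplied
  per-sample score, with independent exponential censoring;
* an EpiTyper-style amplicon table of CpG-unit fractions with case/control
  shifts, sex-specific effect modulation, pTNM stages and missingness.

Every planted effect is recorded in a :class:`TruthTable`; recovery tests
read the truth table, never re-derive truth from the data. A single seed
fans out to per-stage child streams via ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

import dataclasses
import logging
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import norm

from .datatypes import (
    BetaMatrix,
    ProbeAnnotation,
    SampleMetadata,
    SimpoError,
    SurvivalRecord,
    UnitMethylation,
)

logger = logging.getLogger(__name__)

#: Whole-blood leukocyte composition used as Dirichlet means (granulocytes
#: dominate; the seventh, unnamed component absorbs the remainder so the six
#: reported proportions sum to at most 1).
BLOOD_COMPOSITION = {
    "CD8T": 0.08,
    "CD4T": 0.15,
    "monocyte": 0.08,
    "granulocyte": 0.55,
    "NK": 0.05,
    "B": 0.05,
}


@dataclasses.dataclass(frozen=True)
class TruthTable:
    """Ground truth of every planted effect, serialised alongside the data."""

    genes: pd.DataFrame | None = None
    units: pd.DataFrame | None = None
    samples: pd.DataFrame | None = None

    def planted(self, effect_type: str) -> set[str]:
        if self.genes is None:
            return set()
        sub = self.genes[self.genes["effect_type"] == effect_type]
        return set(sub["gene"])


@dataclasses.dataclass(frozen=True)
class CohortSimConfig:
    """Study conditions for the methylation-array cohort generator.

    Defaults echo the aging-cohort design the pipeline targets: whole blood,
    ages uniform on 19-101 years, six-cell Dirichlet composition, ~5-15
    probes per region per gene, logit-normal probe noise.
    """

    n_samples: int = 656
    n_genes: int = 1000
    probes_per_region: tuple[int, int] = (5, 15)
    age_distribution: tuple[float, float] = (19.0, 101.0)
    #: gene -> beta-shift per year applied to promoter probes (age-centred)
    effect_genes_age: Mapping[str, float] = dataclasses.field(default_factory=dict)
    #: gene -> target correlation between score and the effect cell type
    effect_genes_cell: Mapping[str, float] = dataclasses.field(default_factory=dict)
    effect_cell_type: str = "CD4T"
    #: magnitude (beta scale) of the cell-linked promoter shift
    cell_effect_scale: float = 0.08
    #: Dirichlet concentration mass; larger = tighter proportions
    cell_concentration: float = 80.0
    #: logit-scale probe noise standard deviation
    noise_sd: float = 0.35
    noise_model: str = "logit-normal"
    seed: int = 0


def _gene_names(n: int) -> list[str]:
    return [f"G{i:04d}" for i in range(n)]


def simulate_methylation_cohort(
    config: CohortSimConfig,
) -> tuple[BetaMatrix, ProbeAnnotation, SampleMetadata, TruthTable]:
    """Draw one cohort under ``config``; fully determined by ``config.seed``."""
    genes = _gene_names(config.n_genes)
    universe = set(genes)
    for name, eff in (("age", config.effect_genes_age), ("cell", config.effect_genes_cell)):
        extra = set(eff) - universe
        if extra:
            raise SimpoError(f"{name}-effect genes outside the gene universe: {sorted(extra)[:5]}")
    overlap = set(config.effect_genes_age) & set(config.effect_genes_cell)
    if overlap:
        raise SimpoError(f"genes with both effect types not supported: {sorted(overlap)[:5]}")

    ss = np.random.SeedSequence(config.seed)
    rng_struct, rng_meta, rng_noise = (np.random.default_rng(s) for s in ss.spawn(3))

    # sample metadata: ages uniform, proportions Dirichlet (7th = remainder)
    ages = rng_meta.uniform(*config.age_distribution, size=config.n_samples)
    comp = np.array(list(BLOOD_COMPOSITION.values()) + [1 - sum(BLOOD_COMPOSITION.values())])
    props = rng_meta.dirichlet(comp * config.cell_concentration, size=config.n_samples)
    sample_ids = [f"S{i:04d}" for i in range(config.n_samples)]
    meta = pd.DataFrame({"age": ages}, index=pd.Index(sample_ids, name="sample_id"))
    for j, cell in enumerate(BLOOD_COMPOSITION):
        meta[cell] = props[:, j]
    meta["sex"] = np.where(rng_meta.random(config.n_samples) < 0.5, "female", "male")

    prop_eff = meta[config.effect_cell_type].to_numpy()
    z_prop = (prop_eff - prop_eff.mean()) / prop_eff.std()
    age_centred = ages - ages.mean()

    lo, hi = config.probes_per_region
    probe_rows = []
    annotation_records = []
    truth_rows = []
    probe_counter = 0
    clipped = total = 0

    for gene in genes:
        m = int(rng_struct.integers(lo, hi + 1))
        n = int(rng_struct.integers(lo, hi + 1))
        # promoters hypomethylated, gene bodies methylated, on the logit scale
        mu_prom = rng_struct.normal(-1.6, 0.4)
        mu_other = rng_struct.normal(0.9, 0.4)
        probe_mu = np.concatenate(
            [mu_prom + rng_struct.normal(0, 0.5, m), mu_other + rng_struct.normal(0, 0.5, n)]
        )
        regions = ["TSS200"] * m + ["Body"] * n

        # per-sample beta-scale shift applied to promoter probes only
        shift = np.zeros(config.n_samples)
        if gene in config.effect_genes_age:
            slope = config.effect_genes_age[gene]
            shift = slope * age_centred
            truth_rows.append((gene, "age", slope, "promoter"))
        elif gene in config.effect_genes_cell:
            rho = config.effect_genes_cell[gene]
            latent = _latent_rho(rho, probe_mu, m, n, config)
            eps = rng_struct.normal(0, 1, config.n_samples)
            shift = config.cell_effect_scale * (latent * z_prop + np.sqrt(1 - latent**2) * eps)
            truth_rows.append((gene, "cell", rho, "promoter"))
        else:
            truth_rows.append((gene, "none", 0.0, ""))

        n_probes = m + n
        if config.noise_model == "logit-normal":
            z = probe_mu[:, None] + rng_noise.normal(0, config.noise_sd, (n_probes, config.n_samples))
            betas = expit(z)
        elif config.noise_model == "gaussian":
            betas = expit(probe_mu)[:, None] + rng_noise.normal(
                0, config.noise_sd * 0.2, (n_probes, config.n_samples)
            )
        else:
            raise SimpoError(f"unknown noise model: {config.noise_model!r}")
        betas[:m] += shift[None, :]
        pre = betas
        betas = np.clip(pre, 0.0, 1.0)
        clipped += int(np.sum(pre != betas))
        total += pre.size

        ids = [f"cg{probe_counter + k:08d}" for k in range(n_probes)]
        probe_counter += n_probes
        for pid, region in zip(ids, regions):
            annotation_records.append((pid, [gene], [region]))
        probe_rows.append((ids, betas))

    if total and clipped / total > 0.01:
        logger.warning("simulate_methylation_cohort: %.2f%% of values clipped", 100 * clipped / total)

    all_ids = [pid for ids, _ in probe_rows for pid in ids]
    values = np.vstack([b for _, b in probe_rows])
    beta = BetaMatrix(tuple(all_ids), tuple(sample_ids), values)
    annotation = ProbeAnnotation(annotation_records)
    truth = TruthTable(
        genes=pd.DataFrame(truth_rows, columns=["gene", "effect_type", "magnitude", "region"])
    )
    return beta, annotation, SampleMetadata(meta), truth


def _latent_rho(
    rho: float, probe_mu: np.ndarray, m: int, n: int, config: CohortSimConfig
) -> float:
    """Latent shift correlation needed so corr(score, proportion) hits ``rho``.

    The per-sample t-score carries noise the planted shift does not control:
    the pooled-SD estimate fluctuates against the large baseline
    promoter-vs-other mean difference, and the group means carry probe noise.
    Both channels are known to the generator, so it deflates them out by the
    delta method and plants a correspondingly larger latent correlation.
    """
    means = expit(probe_mu)
    dvar = (means * (1 - means) * config.noise_sd) ** 2  # per-value noise variance
    s1 = means[:m].var(ddof=1) + dvar[:m].mean()
    s2 = means[m:].var(ddof=1) + dvar[m:].mean()
    sw2 = ((m - 1) * s1 + (n - 1) * s2) / (m + n - 2)
    c = np.sqrt(sw2 * (1.0 / m + 1.0 / n))
    t0 = (means[:m].mean() - means[m:].mean()) / c
    sd_sw = abs(t0) / np.sqrt(2 * (m + n - 2))
    sd_mean = np.sqrt(dvar[:m].mean() / m + dvar[m:].mean() / n) / c
    sd_shift = config.cell_effect_scale / c
    atten = sd_shift / np.sqrt(sd_shift**2 + sd_sw**2 + sd_mean**2)
    latent = rho / atten
    if abs(latent) > 0.995:
        logger.warning(
            "target correlation %.2f not attainable at cell_effect_scale=%.3f; clamped",
            rho, config.cell_effect_scale,
        )
        latent = np.clip(latent, -0.995, 0.995)
    return float(latent)


def simulate_survival(
    scores: Sequence[float],
    true_log_hr: float,
    censoring_rate: float = 0.4,
    seed: int = 0,
    baseline_scale_days: float = 1000.0,
    sample_ids: Sequence[str] | None = None,
) -> list[SurvivalRecord]:
    """Exponential survival with hazard proportional to exp(log-HR x z-score).

    ``true_log_hr`` is per standard deviation of ``scores``. Censoring is an
    independent exponential clock whose rate is tuned so the expected
    censored fraction approximates ``censoring_rate``.
    """
    s = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(s)):
        raise SimpoError("scores must be finite for survival simulation")
    if not 0 <= censoring_rate < 1:
        raise SimpoError("censoring_rate must lie in [0, 1)")
    z = (s - s.mean()) / s.std() if s.std() > 0 else np.zeros_like(s)
    rng = np.random.default_rng(seed)
    lam = np.exp(true_log_hr * z) / baseline_scale_days
    times = rng.exponential(1.0 / lam)
    if censoring_rate == 0:
        event = np.ones_like(times, dtype=int)
        obs = times
    else:
        # solve E_i[lam_c/(lam_c+lam_i)] = rate for the censoring hazard
        # (a mean-hazard approximation overshoots under hazard heterogeneity)
        from scipy.optimize import brentq

        def excess(lam_c: float) -> float:
            return float(np.mean(lam_c / (lam_c + lam))) - censoring_rate

        lam_c = brentq(excess, 1e-12 * lam.mean(), 1e12 * lam.mean())
        cens = rng.exponential(1.0 / lam_c, size=times.shape)
        event = (times <= cens).astype(int)
        obs = np.minimum(times, cens)
    ids = list(sample_ids) if sample_ids is not None else [f"P{i:04d}" for i in range(len(s))]
    return [
        SurvivalRecord(sid, float(max(t, 1e-9)), int(e))
        for sid, t, e in zip(ids, obs, event)
    ]


def unit_shifts_for_auc(
    target_auc: float, n_affected: int, unit_sd: float = 0.08
) -> np.ndarray:
    """Per-unit case shifts giving a Bayes-optimal population AUC.

    For independent equal-variance Gaussian units, k equal shifts delta give
    a combined discriminability d' = sqrt(k) |delta| / sd and a population
    AUC of Phi(d'/sqrt(2)). Shifts are negative (methylation decreases in
    cancer, as observed in blood amplicon data).
    """
    if not 0.5 < target_auc < 1:
        raise SimpoError("target AUC must lie in (0.5, 1)")
    d_prime = np.sqrt(2.0) * norm.ppf(target_auc)
    delta = d_prime * unit_sd / np.sqrt(n_affected)
    return -np.full(n_affected, delta)


def simulate_epityper(
    n_case: int = 100,
    n_control: int = 50,
    n_units: int = 15,
    case_shift: Sequence[float] | None = None,
    sex_modulation: Sequence[float] | None = None,
    missing_rate: float = 0.0,
    seed: int = 0,
    unit_sd: float = 0.08,
    early_fraction: float = 0.53,
    case_male_fraction: float = 0.67,
    control_male_fraction: float = 0.36,
) -> tuple[UnitMethylation, TruthTable]:
    """Draw an amplicon-style case/control unit-methylation table.

    ``case_shift`` (length ``n_units``) is added to case means; for male
    samples each unit's shift is additionally multiplied by
    ``sex_modulation`` (1 = same effect in both sexes, 0 = female-only).
    Cases receive pTNM stages I/II vs III at ``early_fraction``; missingness
    is completely at random. Sex frequencies default to the clinical design
    (cases two-thirds male, controls one-third).
    """
    if n_units <= 0:
        raise SimpoError("n_units must be positive")
    shift = np.zeros(n_units) if case_shift is None else np.asarray(case_shift, float)
    mod = np.ones(n_units) if sex_modulation is None else np.asarray(sex_modulation, float)
    if shift.shape != (n_units,) or mod.shape != (n_units,):
        raise SimpoError("case_shift and sex_modulation must have length n_units")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n = n_case + n_control
    outcome = np.concatenate([np.zeros(n_case), np.ones(n_control)])  # CRC=0, normal=1
    sex = np.concatenate(
        [
            (rng.random(n_case) < case_male_fraction).astype(float),
            (rng.random(n_control) < control_male_fraction).astype(float),
        ]
    )
    n_early = int(round(early_fraction * n_case))
    stages = np.array(
        ["I"] * (n_early // 2) + ["II"] * (n_early - n_early // 2) + ["III"] * (n_case - n_early)
    )
    rng.shuffle(stages)
    stage = pd.Series([*stages, *[None] * n_control])

    control_means = rng.uniform(0.35, 0.75, size=n_units)
    eff = np.where(sex[:, None] == 1, shift[None, :] * mod[None, :], shift[None, :])
    means = control_means[None, :] + np.where(outcome[:, None] == 0, eff, 0.0)
    values = np.clip(means + rng.normal(0, unit_sd, size=(n, n_units)), 0.0, 1.0)
    if missing_rate > 0:
        mask = rng.random((n, n_units)) < missing_rate
        values = np.where(mask, np.nan, values)

    ids = [f"A{i:04d}" for i in range(n)]
    unit_ids = [f"CpG_{i + 1}" for i in range(n_units)]
    frame = pd.DataFrame(values, index=pd.Index(ids, name="sample_id"), columns=unit_ids)
    units = UnitMethylation(
        frame,
        pd.Series(sex, index=frame.index),
        pd.Series(outcome, index=frame.index),
        stage.set_axis(frame.index),
    )
    truth = TruthTable(
        units=pd.DataFrame(
            {
                "unit": unit_ids,
                "case_shift": shift,
                "sex_modulation": mod,
                "control_mean": control_means,
            }
        )
    )
    return units, truth
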