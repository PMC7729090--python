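import numpy as np
import pytest

from simpo import (
    BetaMatrix,
    CohortSimConfig,
    ProbeAnnotation,
    build_gene_probe_groups,
    simpo_matrix,
    simulate_methylation_cohort,
)


@pytest.fixture(scope="session")
def small_cohort():
    """A 40-gene, 80-sample cohort with one planted age and one cell effect."""
    config = CohortSimConfig(
        n_samples=80,
        n_genes=40,
        seed=7,
        effect_genes_age={"G0003": 0.002},
        effect_genes_cell={"G0005": 0.5},
    )
    beta, annotation, meta, truth = simulate_methylation_cohort(config)
    return beta, annotation, meta, truth


@pytest.fixture(scope="session")
def small_scores(small_cohort):
    beta, annotation, meta, _ = small_cohort
    groups = build_gene_probe_groups(annotation, beta)
    return simpo_matrix(beta, groups), meta


@pytest.fixture()
def tiny_beta():
    probes = ("cg01", "cg02", "cg03", "cg04")
    samples = ("s1", "s2")
    values = np.array([[0.1, 0.2], [0.3, np.nan], [0.5, 0.6], [0.7, 0.8]])
    return BetaMatrix(probes, samples, values)


@pytest.fixture()
def tiny_annotation():
    return ProbeAnnotation(
        [
            ("cg01", ["GENE1"], ["TSS200"]),
            ("cg02", ["GENE1", "GENE2"], ["Body", "TSS1500"]),
            ("cg03", ["GENE1"], ["Body"]),
            ("cg04", [], []),
        ]
    )
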