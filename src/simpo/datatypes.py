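"""Domain containers for the promoter-vs-other-regions methylation pipeline.

The central measurement is a beta-value matrix (CpG probes x samples, fractions
in [0, 1]); probes are mapped to genes and to Illumina 450K ``UCSC_RefGene_Group``
region categories, and each gene's probes are partitioned into a promoter group
and an "other regions" (gene body / 3'UTR) group before scoring.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd

#: Closed vocabulary of Illumina 450K UCSC_RefGene_Group region categories.
REGION_VOCAB = frozenset({"TSS1500", "TSS200", "5UTR", "1stExon", "Body", "3UTR"})

#: Region categories treated as "promoter" by default; the remainder
#: ({Body, 3UTR}) are the "other regions" the score contrasts against.
DEFAULT_PROMOTER_TAGS = frozenset({"TSS1500", "TSS200", "5UTR", "1stExon"})

#: The six immune-cell types whose whole-blood proportions the pipeline uses.
CELL_TYPES = ("CD8T", "CD4T", "monocyte", "granulocyte", "NK", "B")

#: Composite covariate: summed CD8+ T and CD4+ T proportions.
T_CELL_SUM = "CD8T+CD4T"


class SimpoError(Exception):
    """Base error for invalid inputs to the pipeline."""


def _normalize_region_tag(tag: str) -> str:
    """Map manifest spellings (5'UTR, 3'UTR) onto the canonical vocabulary."""
    t = tag.strip().replace("'", "")
    if t not in REGION_VOCAB:
        raise SimpoError(f"unknown region tag: {tag!r}")
    return t


class ProbeAnnotation:
    """Probe -> (gene, region-category) mapping.

    Stored internally as a long-format table with one row per
    (probe, gene, region) assignment; probes with no gene assignment are
    retained with zero rows in the long table but listed in ``probe_ids``.
    """

    def __init__(self, records: Iterable[tuple[str, Sequence[str], Sequence[str]]]):
        probe_ids: list[str] = []
        seen: set[str] = set()
        rows: list[tuple[str, str, str]] = []
        for probe_id, genes, regions in records:
            probe_id = str(probe_id).strip()
            if probe_id in seen:
                raise SimpoError(f"duplicate probe_id: {probe_id!r}")
            seen.add(probe_id)
            probe_ids.append(probe_id)
            if len(genes) != len(regions):
                raise SimpoError(
                    f"probe {probe_id!r}: gene_symbols and region_groups lengths "
                    f"differ ({len(genes)} vs {len(regions)})"
                )
            for gene, region in zip(genes, regions):
                gene = str(gene).strip()
                if not gene:
                    continue
                rows.append((probe_id, gene, _normalize_region_tag(region)))
        self.probe_ids: list[str] = probe_ids
        self.table = pd.DataFrame(rows, columns=["probe_id", "gene", "region"])

    def __len__(self) -> int:
        return len(self.probe_ids)

    def genes(self) -> list[str]:
        """Sorted unique gene symbols carrying at least one probe."""
        return sorted(self.table["gene"].unique())

    def assignments(self, probe_id: str) -> list[tuple[str, str]]:
        sub = self.table[self.table["probe_id"] == probe_id]
        return list(zip(sub["gene"], sub["region"]))


@dataclasses.dataclass(frozen=True)
class BetaMatrix:
    """Beta values (methylated fraction per probe per sample), NaN = missing.

    ``values`` is probes x samples, row-aligned with ``probe_ids`` and
    column-aligned with ``sample_ids``.
    """

    probe_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise SimpoError(
                f"beta matrix shape {vals.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        if len(set(self.probe_ids)) != len(self.probe_ids):
            raise SimpoError("duplicate probe ids in beta matrix")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise SimpoError("duplicate sample ids in beta matrix")
        finite = vals[~np.isnan(vals)]
        if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
            bad = np.argwhere((vals < 0) | (vals > 1))
            i, j = bad[0]
            raise SimpoError(
                f"beta value {vals[i, j]!r} outside [0,1] at probe "
                f"{self.probe_ids[i]!r}, sample {self.sample_ids[j]!r}"
            )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "BetaMatrix":
        return cls(
            tuple(str(p) for p in frame.index),
            tuple(str(s) for s in frame.columns),
            frame.to_numpy(dtype=float),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.probe_ids), columns=list(self.sample_ids)
        )

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


@dataclasses.dataclass(frozen=True)
class GeneProbeGroups:
    """One gene's probes split into promoter vs other-region groups."""

    gene: str
    promoter_probes: tuple[str, ...]
    other_probes: tuple[str, ...]

    def __post_init__(self) -> None:
        overlap = set(self.promoter_probes) & set(self.other_probes)
        if overlap:
            raise SimpoError(
                f"gene {self.gene!r}: probes in both groups: {sorted(overlap)}"
            )

    @property
    def m(self) -> int:
        return len(self.promoter_probes)

    @property
    def n(self) -> int:
        return len(self.other_probes)


def build_gene_probe_groups(
    annotation: ProbeAnnotation,
    beta: BetaMatrix,
    promoter_tags: frozenset[str] | set[str] = DEFAULT_PROMOTER_TAGS,
    min_probes: int = 5,
) -> list[GeneProbeGroups]:
    """Partition each gene's measured probes and apply the >= ``min_probes`` rule.

    A probe contributes to every gene it is annotated to, under its region tag
    for that gene. A gene is retained only when it has at least ``min_probes``
    promoter probes *and* at least ``min_probes`` other-region probes among the
    probes present in ``beta``. Output is sorted by gene symbol.
    """
    unknown = set(promoter_tags) - REGION_VOCAB
    if unknown:
        raise SimpoError(f"promoter tags outside region vocabulary: {sorted(unknown)}")
    measured = set(beta.probe_ids)
    tab = annotation.table
    tab = tab[tab["probe_id"].isin(measured)]
    if tab.empty:
        raise SimpoError("no usable probes: annotation and beta matrix do not overlap")
    groups: list[GeneProbeGroups] = []
    is_promoter = tab["region"].isin(promoter_tags)
    for gene, sub in tab.assign(_prom=is_promoter).groupby("gene", sort=True):
        prom = tuple(sorted(set(sub.loc[sub["_prom"], "probe_id"])))
        # a probe promoter-annotated for this gene never doubles as "other"
        other = tuple(sorted(set(sub.loc[~sub["_prom"], "probe_id"]) - set(prom)))
        if len(prom) >= min_probes and len(other) >= min_probes:
            groups.append(GeneProbeGroups(str(gene), prom, other))
    return groups


class SampleMetadata:
    """Per-sample clinical and compositional annotations.

    Backed by a DataFrame indexed by sample_id with optional columns
    ``age`` (years), ``sex`` ({male, female}), the six cell-proportion columns,
    ``group_label`` ({case, control}), ``ptnm_stage`` ({I, II, III, IV}),
    ``survival_time`` (days) and ``survival_event`` ({0, 1}).
    """

    OPTIONAL_COLUMNS = (
        ("age", float),
        ("sex", object),
        ("group_label", object),
        ("ptnm_stage", object),
        ("survival_time", float),
        ("survival_event", float),
    ) + tuple((c, float) for c in CELL_TYPES)

    def __init__(self, frame: pd.DataFrame):
        frame = frame.copy()
        if frame.index.duplicated().any():
            dup = frame.index[frame.index.duplicated()][0]
            raise SimpoError(f"duplicate sample_id: {dup!r}")
        for col, dtype in self.OPTIONAL_COLUMNS:
            if col not in frame.columns:
                frame[col] = np.nan
            elif dtype is float:
                frame[col] = pd.to_numeric(frame[col], errors="raise")
        for col in CELL_TYPES:
            vals = frame[col].dropna()
            if ((vals < 0) | (vals > 1)).any():
                bad = vals[(vals < 0) | (vals > 1)].index[0]
                raise SimpoError(
                    f"cell proportion {col} outside [0,1] for sample {bad!r}"
                )
        age = frame["age"].dropna()
        if (age < 0).any():
            raise SimpoError("negative age in metadata")
        has_time = frame["survival_time"].notna()
        if (has_time & frame["survival_event"].isna()).any():
            raise SimpoError("survival_time present without survival_event")
        sex = frame["sex"].dropna()
        bad_sex = set(sex.unique()) - {"male", "female"}
        if bad_sex:
            raise SimpoError(f"unknown sex values: {sorted(bad_sex)}")
        self.frame = frame

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.frame.index]

    def ages(self, sample_ids: Sequence[str]) -> pd.Series:
        return self.frame.loc[list(sample_ids), "age"]

    def cell_proportion(self, cell_type: str, sample_ids: Sequence[str]) -> pd.Series:
        """Proportion vector for one cell type, or the CD8T+CD4T composite."""
        sub = self.frame.loc[list(sample_ids)]
        if cell_type == T_CELL_SUM:
            return sub["CD8T"] + sub["CD4T"]
        if cell_type not in CELL_TYPES:
            raise SimpoError(f"unknown cell type: {cell_type!r}")
        return sub[cell_type]


@dataclasses.dataclass(frozen=True)
class GeneSet:
    """A named set of gene symbols (e.g. the curated E3 ubiquitin ligases)."""

    name: str
    symbols: frozenset[str]

    def __post_init__(self) -> None:
        if not self.symbols:
            raise SimpoError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.symbols)


@dataclasses.dataclass(frozen=True)
class SimpoMatrix:
    """Per-gene, per-sample promoter-vs-other t-scores.

    ``scores`` is genes x samples (NaN where a score could not be computed).
    ``m`` / ``n`` / ``df`` are the manifest-level probe counts and degrees of
    freedom per gene; ``df_used`` holds the per-(gene, sample) degrees of
    freedom actually realised after dropping missing probes in that sample.
    """

    genes: tuple[str, ...]
    sample_ids: tuple[str, ...]
    scores: np.ndarray
    m: np.ndarray
    n: np.ndarray
    df_used: np.ndarray

    @property
    def df(self) -> np.ndarray:
        return self.m + self.n - 2

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.scores, index=list(self.genes), columns=list(self.sample_ids)
        )

    def sidecar_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene": list(self.genes), "m": self.m, "n": self.n, "df": self.df}
        ).set_index("gene")

    def gene_scores(self, gene: str) -> pd.Series:
        idx = self.genes.index(gene)
        return pd.Series(self.scores[idx], index=list(self.sample_ids), name=gene)


@dataclasses.dataclass(frozen=True)
class SurvivalRecord:
    """One sample's follow-up: time in days, event=1 / censored=0."""

    sample_id: str
    time: float
    event: int

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise SimpoError(f"non-positive survival time for {self.sample_id!r}")
        if self.event not in (0, 1):
            raise SimpoError(f"survival event must be 0/1, got {self.event!r}")


def survival_frame(records: Sequence[SurvivalRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "time": [r.time for r in records],
            "event": [r.event for r in records],
        },
        index=[r.sample_id for r in records],
    )


class UnitMethylation:
    """EpiTyper-style CpG-unit methylation fractions with clinical covariates.

    ``values`` is samples x units (NaN = not effectively detected);
    ``outcome_code`` follows the clinical coding CRC=0 / normal=1 and
    ``sex_code`` male=1 / female=0. ``stage`` is the optional pTNM stage of
    case samples ({I, II, III}).
    """

    def __init__(
        self,
        values: pd.DataFrame,
        sex_code: pd.Series,
        outcome_code: pd.Series,
        stage: pd.Series | None = None,
    ):
        if values.index.duplicated().any():
            raise SimpoError("duplicate sample ids in unit methylation table")
        if values.columns.duplicated().any():
            raise SimpoError("duplicate unit ids in unit methylation table")
        arr = values.to_numpy(dtype=float)
        bad = np.argwhere((arr < 0) | (arr > 1))
        if bad.size:
            i, j = bad[0]
            raise SimpoError(
                f"unit methylation {arr[i, j]!r} outside [0,1] at sample "
                f"{values.index[i]!r}, unit {values.columns[j]!r}"
            )
        for name, series in (("sex_code", sex_code), ("outcome_code", outcome_code)):
            vals = set(series.dropna().unique())
            if not vals <= {0, 1}:
                raise SimpoError(f"{name} must be binary 0/1, got {sorted(vals)}")
        self.values = values.astype(float)
        self.sex_code = sex_code.reindex(values.index).astype(float).rename("sex")
        self.outcome_code = (
            outcome_code.reindex(values.index).astype(float).rename("outcome")
        )
        if stage is None:
            stage = pd.Series(index=values.index, dtype=object)
        self.stage = stage.reindex(values.index).rename("stage")

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.values.index]

    @property
    def unit_ids(self) -> list[str]:
        return [str(u) for u in self.values.columns]

    def completeness(self) -> pd.Series:
        """Fraction of samples effectively detected, per unit."""
        return self.values.notna().mean(axis=0)

    def complete_cases(self) -> "UnitMethylation":
        """Samples with effective values in every unit (the model-input set)."""
        keep = self.values.notna().all(axis=1)
        return UnitMethylation(
            self.values.loc[keep],
            self.sex_code.loc[keep],
            self.outcome_code.loc[keep],
            self.stage.loc[keep],
        )
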