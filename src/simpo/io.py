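"""Readers and writers for the tabular formats the pipeline travels in.

All files are UTF-8 text: TSV beta matrices (probes x samples, "NA" missing),
CSV sample metadata, probe annotation in either a simple TSV dialect or the
relevant columns of an Illumina-manifest-style CSV, plain-text gene sets, and
EpiTyper-style CSV unit-methylation tables.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    BetaMatrix,
    GeneSet,
    ProbeAnnotation,
    SampleMetadata,
    SimpoError,
    SimpoMatrix,
    UnitMethylation,
)

_MISSING = {"", "NA", "NaN", "nan"}


def read_probe_annotation(path: str | Path, dialect: str = "simple-tsv") -> ProbeAnnotation:
    """Read a probe -> gene/region annotation table.

    ``simple-tsv``: header columns probe_id, gene_symbols, region_groups with
    semicolon-joined multi-assignments. ``illumina-manifest-subset``: CSV with
    IlmnID, UCSC_RefGene_Name, UCSC_RefGene_Group columns (semicolon-joined).
    """
    path = Path(path)
    if dialect == "simple-tsv":
        sep, cols = "\t", ("probe_id", "gene_symbols", "region_groups")
    elif dialect == "illumina-manifest-subset":
        sep, cols = ",", ("IlmnID", "UCSC_RefGene_Name", "UCSC_RefGene_Group")
    else:
        raise SimpoError(f"unknown annotation dialect: {dialect!r}")

    records = []
    with path.open(encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter=sep)
        header = next(reader, None)
        if header is None or not set(cols) <= set(h.strip() for h in header):
            raise SimpoError(
                f"{path}: expected header columns {cols} for dialect {dialect!r}"
            )
        idx = {h.strip(): i for i, h in enumerate(header)}
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            try:
                probe = row[idx[cols[0]]].strip()
                genes_f = row[idx[cols[1]]].strip()
                regions_f = row[idx[cols[2]]].strip()
            except IndexError:
                raise SimpoError(f"{path}: malformed row at line {lineno}") from None
            genes = [g for g in genes_f.split(";") if g.strip()] if genes_f else []
            regions = [r for r in regions_f.split(";") if r.strip()] if regions_f else []
            if len(genes) != len(regions):
                raise SimpoError(
                    f"{path}: line {lineno}: {len(genes)} gene symbols but "
                    f"{len(regions)} region groups"
                )
            records.append((probe, genes, regions))
    return ProbeAnnotation(records)


def write_probe_annotation(annotation: ProbeAnnotation, path: str | Path) -> None:
    """Write the simple-tsv dialect (semicolon-joined multi-assignments)."""
    by_probe: dict[str, tuple[list[str], list[str]]] = {
        p: ([], []) for p in annotation.probe_ids
    }
    for _, row in annotation.table.iterrows():
        by_probe[row["probe_id"]][0].append(row["gene"])
        by_probe[row["probe_id"]][1].append(row["region"])
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("probe_id\tgene_symbols\tregion_groups\n")
        for probe in annotation.probe_ids:
            genes, regions = by_probe[probe]
            fh.write(f"{probe}\t{';'.join(genes)}\t{';'.join(regions)}\n")


def read_beta_matrix(path: str | Path) -> BetaMatrix:
    """Read a probes-x-samples TSV of beta values; "NA" denotes missing."""
    path = Path(path)
    frame = pd.read_csv(
        path, sep="\t", index_col=0, na_values=sorted(_MISSING), keep_default_na=False
    )
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    vals = frame.to_numpy(dtype=float)
    bad = np.argwhere((vals < 0) | (vals > 1))
    if bad.size:
        i, j = bad[0]
        raise SimpoError(
            f"{path}: beta value {vals[i, j]} outside [0,1] at probe "
            f"{frame.index[i]!r}, sample {frame.columns[j]!r}"
        )
    return BetaMatrix.from_frame(frame)


def write_beta_matrix(beta: BetaMatrix, path: str | Path) -> None:
    frame = beta.to_frame()
    frame.index.name = "probe_id"
    frame.to_csv(path, sep="\t", na_rep="NA")


def read_sample_metadata(path: str | Path) -> SampleMetadata:
    """Read per-sample metadata CSV; absent/empty optional columns stay unset."""
    frame = pd.read_csv(
        Path(path), na_values=sorted(_MISSING), keep_default_na=False, dtype={0: str}
    )
    if "sample_id" not in frame.columns:
        raise SimpoError(f"{path}: missing sample_id column")
    frame = frame.set_index("sample_id")
    return SampleMetadata(frame)


def write_sample_metadata(meta: SampleMetadata, path: str | Path) -> None:
    frame = meta.frame.copy()
    frame.index.name = "sample_id"
    frame.to_csv(path)


def read_gene_set(path: str | Path, name: str | None = None) -> GeneSet:
    """Read a plain-text gene set, one symbol per line, '#' comments allowed."""
    path = Path(path)
    symbols = set()
    for line in path.read_text(encoding="utf-8").splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            symbols.add(line)
    if not symbols:
        raise SimpoError(f"{path}: gene set file contains no symbols")
    return GeneSet(name or path.stem, frozenset(symbols))


def write_gene_set(gene_set: GeneSet, path: str | Path) -> None:
    Path(path).write_text(
        "".join(f"{s}\n" for s in sorted(gene_set.symbols)), encoding="utf-8"
    )


def write_simpo_matrix(matrix: SimpoMatrix, path: str | Path) -> None:
    """Write genes-x-samples scores TSV plus a `.genes.tsv` sidecar of m/n/df."""
    path = Path(path)
    frame = matrix.to_frame()
    frame.index.name = "gene"
    frame.to_csv(path, sep="\t", na_rep="NA")
    sidecar = path.with_suffix(path.suffix + ".genes.tsv")
    matrix.sidecar_frame().to_csv(sidecar, sep="\t")


def read_simpo_scores(path: str | Path) -> pd.DataFrame:
    """Read a genes-x-samples score TSV (sidecar not required)."""
    frame = pd.read_csv(
        Path(path), sep="\t", index_col=0, na_values=sorted(_MISSING),
        keep_default_na=False,
    )
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    return frame


def read_epityper_units(path: str | Path) -> UnitMethylation:
    """Read an EpiTyper-style CSV: rows samples, unit columns plus sex/outcome/stage.

    Expected columns: ``sample_id``, ``sex`` (male/female or 1/0), ``outcome``
    (case/control or 0/1 in the clinical coding CRC=0, normal=1), optional
    ``stage``, and one column per CpG unit (e.g. CpG_3.4). Empty cells are
    missing ("not effectively detected") and preserved as NaN.
    """
    path = Path(path)
    frame = pd.read_csv(path, na_values=sorted(_MISSING), keep_default_na=False)
    if "sample_id" not in frame.columns:
        raise SimpoError(f"{path}: missing sample_id column")
    frame = frame.set_index("sample_id")

    sex_raw = frame.pop("sex") if "sex" in frame.columns else None
    if sex_raw is None:
        raise SimpoError(f"{path}: missing sex column")
    sex = sex_raw.map(lambda v: {"male": 1, "female": 0, "1": 1, "0": 0}.get(str(v).strip(), v))
    out_raw = frame.pop("outcome") if "outcome" in frame.columns else None
    if out_raw is None:
        raise SimpoError(f"{path}: missing outcome column")
    outcome = out_raw.map(
        lambda v: {"case": 0, "crc": 0, "control": 1, "normal": 1, "0": 0, "1": 1}.get(
            str(v).strip().lower(), v
        )
    )
    stage = frame.pop("stage") if "stage" in frame.columns else None

    units = frame.apply(pd.to_numeric, errors="raise")
    arr = units.to_numpy(dtype=float)
    bad = np.argwhere((arr < 0) | (arr > 1))
    if bad.size:
        i, j = bad[0]
        raise SimpoError(
            f"{path}: unit value {arr[i, j]} outside [0,1] at sample "
            f"{units.index[i]!r}, unit {units.columns[j]!r}"
        )
    return UnitMethylation(units, pd.to_numeric(sex), pd.to_numeric(outcome), stage)


def write_epityper_units(units: UnitMethylation, path: str | Path) -> None:
    frame = units.values.copy()
    frame.insert(0, "sex", units.sex_code.astype("Int64"))
    frame.insert(1, "outcome", units.outcome_code.astype("Int64"))
    frame.insert(2, "stage", units.stage)
    frame.index.name = "sample_id"
    frame.to_csv(path)
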