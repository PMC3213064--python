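"""Readers and writers for the panel's plain-text formats.

Formats
-------
Genotype TSV
    Header ``line_id<TAB>m1<TAB>m2...``; one row per line; cells in
    {0, 0.5, 1} (allele-frequency dialect) or {0, 1, 2} (diploid count
    dialect, halved on input); missing cells hold the missing token
    (default ``NA``).
Map TSV
    Three columns ``marker_id<TAB>linkage_group<TAB>cM``.
Labels TSV
    Two columns ``line_id<TAB>label``.
STRUCTURE export
    Whitespace-delimited, two rows per individual, integer alleles 1/2,
    missing ``-9`` — the input format of the external structure-inference
    program (running its MCMC is out of scope here).
VCF (optional)
    Biallelic SNP records via cyvcf2; GT heterozygote -> 0.5, half-calls
    and missing -> NaN.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .panel import GenotypePanel, GeneticMap, GroupLabels

__all__ = [
    "read_genotype_table",
    "write_genotype_table",
    "read_genetic_map",
    "write_genetic_map",
    "read_labels",
    "write_labels",
    "write_structure_export",
    "read_structure_export",
    "read_vcf",
]


def read_genotype_table(path, missing_token: str = "NA") -> GenotypePanel:
    """Read a genotype TSV, auto-detecting the dosage dialect.

    If any cell equals 2 the table is interpreted as diploid allele counts
    {0,1,2} and rescaled by 1/2; otherwise cells must already be in
    {0, 0.5, 1}.  The detected dialect is recorded on the returned panel as
    ``panel.dialect``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, index_col=0)
    if df.index.name is None and df.columns.size == 0:
        raise ValueError(f"{path}: empty or malformed genotype table")
    values = np.empty(df.shape, dtype=float)
    raw = df.to_numpy()
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            cell = raw[i, j]
            if cell is None or (isinstance(cell, float) and np.isnan(cell)) or cell == missing_token:
                values[i, j] = np.nan
                continue
            try:
                v = float(cell)
            except ValueError:
                raise ValueError(
                    f"{path}: malformed cell at line {df.index[i]!r}, "
                    f"marker {df.columns[j]!r}: {cell!r}"
                ) from None
            values[i, j] = v

    observed = values[~np.isnan(values)]
    if np.isin(observed, (2.0,)).any():
        dialect = "count"
        bad = ~np.isin(observed, (0.0, 1.0, 2.0))
        if bad.any():
            _raise_cell_error(path, df, values, (0.0, 1.0, 2.0))
        values = values / 2.0
    else:
        dialect = "frequency"
        bad = ~np.isin(observed, (0.0, 0.5, 1.0))
        if bad.any():
            _raise_cell_error(path, df, values, (0.0, 0.5, 1.0))

    panel = GenotypePanel(
        line_ids=list(df.index.astype(str)),
        marker_ids=list(df.columns.astype(str)),
        dosage=values,
    )
    panel.dialect = dialect
    return panel


def _raise_cell_error(path, df, values, allowed):
    with np.errstate(invalid="ignore"):
        mask = ~np.isnan(values) & ~np.isin(values, allowed)
    i, j = map(int, np.argwhere(mask)[0])
    raise ValueError(
        f"{path}: invalid dosage {values[i, j]!r} at line {df.index[i]!r}, "
        f"marker {df.columns[j]!r} (allowed: {allowed})"
    )


def write_genotype_table(panel: GenotypePanel, path, missing_token: str = "NA") -> None:
    """Write the frequency-dialect genotype TSV (round-trips bit-exactly)."""

    def fmt(v: float) -> str:
        if np.isnan(v):
            return missing_token
        return "0.5" if v == 0.5 else str(int(v))

    with open(path, "w") as fh:
        fh.write("line_id\t" + "\t".join(panel.marker_ids) + "\n")
        for i, lid in enumerate(panel.line_ids):
            fh.write(lid + "\t" + "\t".join(fmt(v) for v in panel.dosage[i]) + "\n")


def read_genetic_map(path) -> GeneticMap:
    df = pd.read_csv(path, sep="\t", dtype=str)
    expected = ["marker_id", "linkage_group", "cM"]
    if list(df.columns) != expected:
        if df.shape[1] != 3:
            raise ValueError(f"{path}: expected 3 columns {expected}, got {list(df.columns)}")
        df.columns = expected
    try:
        df["cM"] = df["cM"].astype(float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric cM position: {exc}") from None
    return GeneticMap(df)


def write_genetic_map(genetic_map: GeneticMap, path) -> None:
    genetic_map.table.to_csv(path, sep="\t", index=False)


def read_labels(path) -> GroupLabels:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] != 2:
        raise ValueError(f"{path}: expected 2 columns (line_id, label)")
    return GroupLabels(line_ids=df.iloc[:, 0].tolist(), labels=df.iloc[:, 1].tolist())


def write_labels(labels: GroupLabels, path) -> None:
    pd.DataFrame({"line_id": labels.line_ids, "label": labels.labels}).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# STRUCTURE interchange

def write_structure_export(panel: GenotypePanel, path) -> None:
    """Write the two-row-per-individual integer-allele format.

    Dosage 0 -> alleles 1/1, 1 -> 2/2, 0.5 -> 1/2, missing -> -9/-9.
    """
    codes = {0.0: ("1", "1"), 0.5: ("1", "2"), 1.0: ("2", "2")}
    with open(path, "w") as fh:
        for i, lid in enumerate(panel.line_ids):
            row = panel.dosage[i]
            first, second = [], []
            for v in row:
                a, b = ("-9", "-9") if np.isnan(v) else codes[v]
                first.append(a)
                second.append(b)
            fh.write(lid + " " + " ".join(first) + "\n")
            fh.write(lid + " " + " ".join(second) + "\n")


def read_structure_export(path, marker_ids=None) -> GenotypePanel:
    """Decode a STRUCTURE export back to a panel (round-trip check)."""
    line_ids: list = []
    rows: list = []
    with open(path) as fh:
        lines = [ln.split() for ln in fh if ln.strip()]
    if len(lines) % 2:
        raise ValueError(f"{path}: odd number of rows in two-row format")
    for k in range(0, len(lines), 2):
        top, bot = lines[k], lines[k + 1]
        if top[0] != bot[0]:
            raise ValueError(f"{path}: row pair mismatch at {top[0]!r}/{bot[0]!r}")
        line_ids.append(top[0])
        alleles = np.array([top[1:], bot[1:]], dtype=float)
        with np.errstate(invalid="ignore"):
            dosage = (alleles - 1.0).mean(axis=0)
        dosage[(alleles == -9).any(axis=0)] = np.nan
        rows.append(dosage)
    dosage = np.vstack(rows)
    if marker_ids is None:
        marker_ids = [f"m{j + 1}" for j in range(dosage.shape[1])]
    return GenotypePanel(line_ids=line_ids, marker_ids=list(marker_ids), dosage=dosage)


# ---------------------------------------------------------------------------
# optional VCF ingestion

def read_vcf(path) -> GenotypePanel:
    """Read biallelic SNP records from a VCF (requires cyvcf2).

    The GT field is converted to within-individual reference-allele
    frequency of the ALT allele complement: 0/0 -> 0, 0/1 -> 0.5, 1/1 -> 1
    (dosage counts ALT alleles).  Half-calls and missing genotypes -> NaN.
    Multi-allelic and non-SNP records are skipped.
    """
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("VCF ingestion requires the optional cyvcf2 dependency") from exc

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    marker_ids: list = []
    cols: list = []
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            continue
        gts = rec.genotypes  # [a, b, phased]
        col = np.empty(len(samples))
        for i, g in enumerate(gts):
            a, b = g[0], g[1]
            if a < 0 or b < 0:  # missing or half-call
                col[i] = np.nan
            else:
                col[i] = (a + b) / 2.0
        marker_ids.append(rec.ID or f"{rec.CHROM}:{rec.POS}")
        cols.append(col)
    if not cols:
        raise ValueError(f"{path}: no biallelic SNP records found")
    return GenotypePanel(
        line_ids=samples, marker_ids=marker_ids, dosage=np.column_stack(cols)
    )
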