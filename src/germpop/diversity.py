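"""Per-locus and genome-wide diversity and distance statistics.

Allele frequencies, gene diversity D = 1 - p^2 - q^2, polymorphic
information content PIC = 1 - p^2 - q^2 - 2 p^2 q^2, modified Rogers
distance (MRD) between lines and between groups, and bootstrap standard
errors over genotypes.

Missing data are handled by pairwise/available-case deletion: frequencies
average the non-missing dosages, and MRD between two lines is computed over
the loci non-missing in both.  On complete data, MRD between two lines
equals the Euclidean distance of their dosage rows divided by sqrt(m) — the
identity behind the PCA/PCoA duality used in the structure module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import GenotypePanel, GroupLabels

__all__ = [
    "DistanceMatrix",
    "allele_frequencies",
    "gene_diversity",
    "pic",
    "mrd_pairwise",
    "mrd_between_groups_per_locus",
    "bootstrap_se",
]


@dataclass
class DistanceMatrix:
    """Symmetric lines x lines distance matrix with shared-locus counts."""

    line_ids: list
    values: np.ndarray
    n_shared: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.line_ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match line count")
        finite = self.values[~np.isnan(self.values)]
        if finite.size and (finite.min() < -1e-12):
            raise ValueError("negative distances")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("distance matrix must be symmetric")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.line_ids, columns=self.line_ids)

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries (row-major), as used for summaries."""
        iu = np.triu_indices(len(self.line_ids), k=1)
        return self.values[iu]


def _line_indices(panel: GenotypePanel, lines) -> np.ndarray:
    if lines is None:
        return np.arange(panel.n_lines)
    lines = list(lines)
    if len(lines) == 0:
        raise ValueError("empty line subset")
    if all(isinstance(l, (int, np.integer)) for l in lines):
        return np.asarray(lines, dtype=int)
    pos = {lid: i for i, lid in enumerate(panel.line_ids)}
    try:
        return np.array([pos[str(l)] for l in lines], dtype=int)
    except KeyError as exc:
        raise KeyError(f"unknown line id {exc.args[0]!r}") from None


def allele_frequencies(panel: GenotypePanel, lines=None) -> np.ndarray:
    """Per-marker mean of non-missing dosages over a line subset.

    Markers with no data in the subset are NaN (undefined).
    """
    idx = _line_indices(panel, lines)
    sub = panel.dosage[idx]
    return _freq(sub)


def _freq(rows: np.ndarray) -> np.ndarray:
    """Column means over non-missing entries; NaN where no data."""
    cnt = np.sum(~np.isnan(rows), axis=0)
    s = np.nansum(rows, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(cnt > 0, s / np.maximum(cnt, 1), np.nan)


def gene_diversity(freq) -> np.ndarray:
    """Expected heterozygosity D = 1 - p^2 - (1-p)^2 = 2p(1-p)."""
    p = np.asarray(freq, dtype=float)
    return 1.0 - p**2 - (1.0 - p) ** 2


def pic(freq) -> np.ndarray:
    """Biallelic polymorphic information content 1 - p^2 - q^2 - 2 p^2 q^2."""
    p = np.asarray(freq, dtype=float)
    q = 1.0 - p
    return 1.0 - p**2 - q**2 - 2.0 * p**2 * q**2


def mrd_pairwise(panel: GenotypePanel) -> DistanceMatrix:
    """Modified Rogers distance between every pair of lines.

    MRD(x, y) = sqrt( (1/2m) sum_loci sum_alleles (p_a - q_a)^2 ) over the m
    loci non-missing in both lines; for biallelic dosage vectors this is
    sqrt( (1/m) sum (d_x - d_y)^2 ).  Pairs sharing no loci are NaN.
    """
    if panel.n_lines < 2:
        raise ValueError("need at least two lines")
    M = (~panel.missing_mask).astype(float)
    Z = np.where(panel.missing_mask, 0.0, panel.dosage)
    Z2 = Z * Z
    shared = M @ M.T
    s1 = Z2 @ M.T
    cross = Z @ Z.T
    with np.errstate(invalid="ignore", divide="ignore"):
        sq = (s1 + s1.T - 2.0 * cross) / shared
    sq[shared == 0] = np.nan
    np.fill_diagonal(sq, 0.0)
    values = np.sqrt(np.clip(sq, 0.0, None))
    return DistanceMatrix(line_ids=list(panel.line_ids), values=values, n_shared=shared)


def _two_groups(labels: GroupLabels):
    groups = labels.groups()
    if len(groups) != 2:
        raise ValueError(f"expected exactly two groups, found {groups}")
    return groups


def mrd_between_groups_per_locus(panel: GenotypePanel, labels: GroupLabels) -> pd.Series:
    """Single-locus MRD between two groups' allele-frequency vectors.

    sqrt( (1/2) ((p_A - p_B)^2 + (q_A - q_B)^2) ) = |p_A - p_B|.
    Markers where either group has no data are NaN.
    """
    ga, gb = _two_groups(labels)
    lab = np.asarray(labels.labels)
    order = {lid: i for i, lid in enumerate(panel.line_ids)}
    idx = np.array([order[lid] for lid in labels.line_ids])
    pa = allele_frequencies(panel, lines=idx[lab == ga])
    pb = allele_frequencies(panel, lines=idx[lab == gb])
    val = np.sqrt(0.5 * ((pa - pb) ** 2 + ((1 - pa) - (1 - pb)) ** 2))
    return pd.Series(val, index=panel.marker_ids, name=f"mrd_{ga}_{gb}")


_STATISTICS = ("gene_diversity", "pic", "mrd_between_groups")


def bootstrap_se(
    panel: GenotypePanel,
    labels: GroupLabels,
    statistic: str,
    B: int = 1000,
    seed=0,
) -> pd.DataFrame:
    """Bootstrap SEs of a per-marker statistic, resampling genotypes.

    Lines are resampled with replacement *within* each group, B times; the
    SE is the standard deviation (ddof=1) of the statistic across
    replicates.  ``statistic`` is one of ``gene_diversity`` / ``pic``
    (computed per group, columns ``<group>_se``) or ``mrd_between_groups``
    (one ``se`` column).
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    if statistic not in _STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}; choose from {_STATISTICS}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    lab = np.asarray(labels.labels)
    order = {lid: i for i, lid in enumerate(panel.line_ids)}
    idx = np.array([order[lid] for lid in labels.line_ids])
    groups = labels.groups()
    group_rows = {g: idx[lab == g] for g in groups}

    per_group_reps: dict = {g: [] for g in groups}
    for _ in range(B):
        freqs = {}
        for g, rows in group_rows.items():
            res = rng.choice(rows, size=rows.size, replace=True)
            freqs[g] = _freq(panel.dosage[res])
        if statistic == "gene_diversity":
            for g in groups:
                per_group_reps[g].append(gene_diversity(freqs[g]))
        elif statistic == "pic":
            for g in groups:
                per_group_reps[g].append(pic(freqs[g]))
        else:
            ga, gb = _two_groups(labels)
            pa, pb = freqs[ga], freqs[gb]
            per_group_reps[ga].append(
                np.sqrt(0.5 * ((pa - pb) ** 2 + ((1 - pa) - (1 - pb)) ** 2))
            )

    out = pd.DataFrame(index=pd.Index(panel.marker_ids, name="marker_id"))
    if statistic == "mrd_between_groups":
        ga, _ = _two_groups(labels)
        out["se"] = np.std(np.vstack(per_group_reps[ga]), axis=0, ddof=1)
    else:
        for g in groups:
            out[f"{g}_se"] = np.std(np.vstack(per_group_reps[g]), axis=0, ddof=1)
    return out
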