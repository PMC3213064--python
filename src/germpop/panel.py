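"""Core data model: genotype panels, genetic maps and group labels.

The canonical genotype encoding is the within-individual reference-allele
frequency: 0, 0.5 or 1 for a biallelic marker in a diploid individual, with
NaN for missing calls.  Fully inbred lines only ever show 0 or 1, so a line's
dosage vector doubles as a haplotype — every downstream statistic (allele
frequencies, PCA input, modified Rogers distance, r^2) is defined directly on
this matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypePanel",
    "GeneticMap",
    "GroupLabels",
    "ValidationReport",
    "validate_panel",
    "UNASSIGNED",
]

#: sentinel used by GroupLabels for lines that no rule could assign
UNASSIGNED = "unassigned"

_VALID_DOSAGES = (0.0, 0.5, 1.0)


def _check_unique(ids, what: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dups = seen[seen.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what}: {dups[:5]}")


@dataclass
class GenotypePanel:
    """Lines x markers matrix of within-individual allele frequencies.

    Parameters
    ----------
    line_ids : list of str
        Unique identifiers, one per row of ``dosage``.
    marker_ids : list of str
        Unique identifiers, one per column of ``dosage``.
    dosage : ndarray of float, shape (n_lines, n_markers)
        Entries in {0, 0.5, 1}; missing values are ``nan``.
    type_label : list of str, optional
        Per-line germplasm type (e.g. ``"yield"`` / ``"sugar"``).
    """

    line_ids: list
    marker_ids: list
    dosage: np.ndarray
    type_label: list | None = None

    def __post_init__(self) -> None:
        self.line_ids = [str(x) for x in self.line_ids]
        self.marker_ids = [str(x) for x in self.marker_ids]
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.line_ids), len(self.marker_ids)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.line_ids)} lines x {len(self.marker_ids)} markers"
            )
        _check_unique(self.line_ids, "line ids")
        _check_unique(self.marker_ids, "marker ids")
        finite = self.dosage[~np.isnan(self.dosage)]
        bad = ~np.isin(finite, _VALID_DOSAGES)
        if bad.any():
            raise ValueError(
                f"invalid dosage values (must be 0, 0.5 or 1): {np.unique(finite[bad])[:5]}"
            )
        if self.type_label is not None:
            self.type_label = [str(x) for x in self.type_label]
            if len(self.type_label) != len(self.line_ids):
                raise ValueError("type_label length does not match line count")

    # -- shapes ----------------------------------------------------------
    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean matrix, True where the call is missing."""
        return np.isnan(self.dosage)

    def line_missing_fraction(self) -> np.ndarray:
        return self.missing_mask.mean(axis=1)

    def marker_missing_fraction(self) -> np.ndarray:
        return self.missing_mask.mean(axis=0)

    # -- subsetting ------------------------------------------------------
    def subset_markers(self, marker_ids) -> "GenotypePanel":
        idx = [self.marker_ids.index(m) for m in marker_ids]
        return GenotypePanel(
            line_ids=list(self.line_ids),
            marker_ids=list(marker_ids),
            dosage=self.dosage[:, idx].copy(),
            type_label=list(self.type_label) if self.type_label is not None else None,
        )

    def subset_lines(self, line_ids) -> "GenotypePanel":
        idx = [self.line_ids.index(l) for l in line_ids]
        return GenotypePanel(
            line_ids=list(line_ids),
            marker_ids=list(self.marker_ids),
            dosage=self.dosage[idx, :].copy(),
            type_label=[self.type_label[i] for i in idx] if self.type_label is not None else None,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosage, index=self.line_ids, columns=self.marker_ids)


@dataclass
class GeneticMap:
    """Marker positions: marker -> (linkage group, cM).

    Positions are centimorgans within a linkage group, >= 0.  The canonical
    genome order — linkage groups lexicographically, positions ascending,
    ties broken by marker id — is the deterministic tie-break order used
    throughout the package.
    """

    table: pd.DataFrame  # columns: marker_id, linkage_group, cM

    def __post_init__(self) -> None:
        t = pd.DataFrame(self.table, copy=True)
        expected = ["marker_id", "linkage_group", "cM"]
        if list(t.columns) != expected:
            t = t[expected]
        t["marker_id"] = t["marker_id"].astype(str)
        t["linkage_group"] = t["linkage_group"].astype(str)
        t["cM"] = pd.to_numeric(t["cM"], errors="raise").astype(float)
        if not np.isfinite(t["cM"]).all():
            raise ValueError("non-finite cM position in map")
        if (t["cM"] < 0).any():
            raise ValueError("negative cM position in map")
        _check_unique(t["marker_id"], "map marker ids")
        self.table = t.reset_index(drop=True)

    @classmethod
    def from_arrays(cls, marker_ids, linkage_groups, positions) -> "GeneticMap":
        return cls(
            pd.DataFrame(
                {
                    "marker_id": list(marker_ids),
                    "linkage_group": list(linkage_groups),
                    "cM": list(positions),
                }
            )
        )

    @property
    def marker_ids(self) -> list:
        return self.table["marker_id"].tolist()

    @property
    def n_markers(self) -> int:
        return len(self.table)

    @property
    def linkage_groups(self) -> list:
        return sorted(self.table["linkage_group"].unique())

    def canonical_order(self) -> list:
        """Marker ids in canonical genome order."""
        t = self.table.sort_values(
            ["linkage_group", "cM", "marker_id"], kind="mergesort"
        )
        return t["marker_id"].tolist()

    def group_of(self) -> pd.Series:
        return self.table.set_index("marker_id")["linkage_group"]

    def position_of(self) -> pd.Series:
        return self.table.set_index("marker_id")["cM"]

    def markers_in_group(self, group: str) -> pd.DataFrame:
        t = self.table[self.table["linkage_group"] == str(group)]
        return t.sort_values(["cM", "marker_id"], kind="mergesort").reset_index(drop=True)


@dataclass
class GroupLabels:
    """One subgroup label per line; ``UNASSIGNED`` marks lines no rule placed."""

    line_ids: list
    labels: list

    def __post_init__(self) -> None:
        self.line_ids = [str(x) for x in self.line_ids]
        self.labels = [str(x) for x in self.labels]
        if len(self.line_ids) != len(self.labels):
            raise ValueError("labels length does not match line count")
        _check_unique(self.line_ids, "line ids")

    @property
    def assigned_mask(self) -> np.ndarray:
        return np.array([l != UNASSIGNED for l in self.labels])

    @property
    def assigned_fraction(self) -> float:
        return float(self.assigned_mask.mean())

    def as_series(self) -> pd.Series:
        return pd.Series(self.labels, index=self.line_ids, name="label")

    def groups(self) -> list:
        return sorted({l for l in self.labels if l != UNASSIGNED})


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_panel`; report-only, never raises."""

    passed: bool
    lines_over_missing: list = field(default_factory=list)
    markers_over_missing: list = field(default_factory=list)
    unmapped_markers: list = field(default_factory=list)
    monomorphic_markers: list = field(default_factory=list)
    max_missing: float = 0.20

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        status = "PASS" if self.passed else "FAIL"
        return (
            f"panel validation: {status}\n"
            f"  lines over {self.max_missing:.0%} missing: {len(self.lines_over_missing)}\n"
            f"  markers over {self.max_missing:.0%} missing: {len(self.markers_over_missing)}\n"
            f"  unmapped markers: {len(self.unmapped_markers)}\n"
            f"  monomorphic markers: {len(self.monomorphic_markers)}"
        )


def validate_panel(
    panel: GenotypePanel,
    genetic_map: GeneticMap | None = None,
    max_missing: float = 0.20,
) -> ValidationReport:
    """Check a panel against the missing-data ceiling and its map.

    Lists lines/markers whose missing fraction exceeds ``max_missing``,
    markers absent from the map, and monomorphic markers.  Pure: inputs are
    never mutated.  Monomorphic markers do not fail validation (they are
    excluded per-statistic downstream); missingness violations do.
    """
    lm = panel.line_missing_fraction()
    mm = panel.marker_missing_fraction()
    lines_over = [panel.line_ids[i] for i in np.nonzero(lm > max_missing)[0]]
    markers_over = [panel.marker_ids[j] for j in np.nonzero(mm > max_missing)[0]]

    unmapped: list = []
    if genetic_map is not None:
        mapped = set(genetic_map.marker_ids)
        unmapped = [m for m in panel.marker_ids if m not in mapped]

    mono: list = []
    for j, m in enumerate(panel.marker_ids):
        col = panel.dosage[:, j]
        col = col[~np.isnan(col)]
        if col.size == 0 or np.all(col == col[0]):
            mono.append(m)

    passed = not lines_over and not markers_over and not unmapped
    return ValidationReport(
        passed=passed,
        lines_over_missing=lines_over,
        markers_over_missing=markers_over,
        unmapped_markers=unmapped,
        monomorphic_markers=mono,
        max_missing=max_missing,
    )
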