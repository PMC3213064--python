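"""Linkage disequilibrium: pairwise r^2, significance thresholds, the
Hill-Weir expected-r^2 decay model and effective-population-size fits.

r^2 is the squared Pearson correlation of per-line allele frequencies at
two loci (inbred lines double as haplotypes, so no phasing is needed),
computed over pairwise-complete lines.  Marker pairs on the same linkage
group are "linked" and carry a cM distance; the 95% empirical quantile of
r^2 among unlinked pairs serves as the significance threshold for linked
pairs.

The decay model is the Hill-Weir drift-equilibrium expectation with sample
size n and C = 4 Ne r:

    E(r^2) = [ (10+C) / ((2+C)(11+C)) ]
             * [ 1 + (3+C)(12+12C+C^2) / (n (2+C)(11+C)) ]

which falls from ~0.45 + O(1/n) at C=0 to the finite-sample floor 1/n as
C -> infinity.  Ne is the single free parameter of a least-squares fit of
observed linked r^2 against this curve, with the cM -> recombination-rate
map either linear (r = d/100 capped at 0.5, the default) or Haldane
(r = (1 - exp(-2d/100))/2).  The LD decay distance is the map distance at
which the fitted curve crosses the unlinked threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .panel import GenotypePanel, GeneticMap

__all__ = [
    "LDTable",
    "DecayFit",
    "LDDecayModel",
    "pairwise_r2_table",
    "unlinked_r2_quantile",
    "expected_r2_hill_weir",
    "fit_effective_population_size",
    "ld_decay_distance",
    "binned_mean_r2",
    "window_mean_r2",
    "ld_summary",
    "ne_per_linkage_group",
]

NE_BOUNDS = (0.1, 1e6)


@dataclass
class LDTable:
    """Long-format marker-pair records of r^2, linkage status and distance."""

    pairs: pd.DataFrame  # marker_a, marker_b, r2, linked, distance_cm, n_used
    n_dropped: int = 0  # pairs excluded (monomorphic or < min shared lines)

    def __post_init__(self) -> None:
        required = {"marker_a", "marker_b", "r2", "linked", "distance_cm", "n_used"}
        if not required.issubset(self.pairs.columns):
            raise ValueError(f"LD table needs columns {sorted(required)}")
        r2 = self.pairs["r2"].to_numpy()
        if ((r2 < -1e-9) | (r2 > 1 + 1e-9)).any():
            raise ValueError("r2 outside [0, 1]")

    @property
    def linked(self) -> pd.DataFrame:
        return self.pairs[self.pairs["linked"]]

    @property
    def unlinked(self) -> pd.DataFrame:
        return self.pairs[~self.pairs["linked"]]


def pairwise_r2_table(
    panel: GenotypePanel,
    genetic_map: GeneticMap,
    lines=None,
    min_lines: int = 3,
) -> LDTable:
    """r^2 for every marker pair, over pairwise-complete lines.

    Pairs with fewer than ``min_lines`` shared informative lines, or where
    either marker is monomorphic on the shared lines, are dropped (their
    count is reported on the table).  Distance is |cM difference| for
    same-group pairs; cross-group pairs are unlinked.
    """
    from .diversity import _line_indices

    idx = _line_indices(panel, lines)
    X = panel.dosage[idx]
    M = (~np.isnan(X)).astype(float)
    Z = np.where(np.isnan(X), 0.0, X)

    n = M.T @ M
    sx = Z.T @ M
    sxx = (Z * Z).T @ M
    sxy = Z.T @ Z
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * sxy - sx * sx.T
        varx = n * sxx - sx**2
        r2 = cov**2 / (varx * varx.T)

    group = genetic_map.group_of().reindex(panel.marker_ids).to_numpy()
    pos = genetic_map.position_of().reindex(panel.marker_ids).to_numpy(dtype=float)
    if pd.isna(group).any():
        missing = [m for m, g in zip(panel.marker_ids, group) if pd.isna(g)]
        raise ValueError(f"markers absent from map: {missing[:5]}")

    ia, ib = np.triu_indices(panel.n_markers, k=1)
    valid = (n[ia, ib] >= min_lines) & (varx[ia, ib] > 1e-12) & (varx.T[ia, ib] > 1e-12)
    n_dropped = int((~valid).sum())
    ia, ib = ia[valid], ib[valid]
    linked = group[ia] == group[ib]
    dist = np.where(linked, np.abs(pos[ia] - pos[ib]), np.nan)
    marker_ids = np.asarray(panel.marker_ids)
    pairs = pd.DataFrame(
        {
            "marker_a": marker_ids[ia],
            "marker_b": marker_ids[ib],
            "r2": np.clip(r2[ia, ib], 0.0, 1.0),
            "linked": linked,
            "distance_cm": dist,
            "n_used": n[ia, ib].astype(int),
        }
    )
    return LDTable(pairs=pairs, n_dropped=n_dropped)


def unlinked_r2_quantile(table: LDTable, q: float = 0.95) -> float:
    """Empirical q-quantile of r^2 among unlinked pairs (linear interpolation)."""
    vals = table.unlinked["r2"].to_numpy()
    if vals.size == 0:
        raise ValueError("no unlinked pairs in the LD table")
    if vals.size < 20:
        warnings.warn(f"only {vals.size} unlinked pairs; quantile is unstable")
    return float(np.quantile(vals, q, method="linear"))


def expected_r2_hill_weir(C, n: int):
    """Hill-Weir drift-equilibrium expectation of r^2 at C = 4 Ne r."""
    if n < 2:
        raise ValueError("sample size n must be >= 2")
    C = np.asarray(C, dtype=float)
    if (C < 0).any():
        raise ValueError("C must be >= 0")
    first = (10.0 + C) / ((2.0 + C) * (11.0 + C))
    second = 1.0 + ((3.0 + C) * (12.0 + 12.0 * C + C**2)) / (n * (2.0 + C) * (11.0 + C))
    out = first * second
    return float(out) if out.ndim == 0 else out


def _recomb_fraction(d_cm, map_function: str):
    d = np.asarray(d_cm, dtype=float)
    if map_function == "linear":
        return np.minimum(d / 100.0, 0.5)
    if map_function == "haldane":
        return 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
    raise ValueError("map_function must be 'linear' or 'haldane'")


@dataclass
class DecayFit:
    """Fitted Hill-Weir decay curve: the Results object of LDDecayModel."""

    ne: float
    n: int
    sse: float
    n_pairs: int
    map_function: str = "linear"
    threshold: float | None = None
    decay_distance_cm: float | None = None
    decay_flag: str = "ok"  # "ok" | "above_intercept" | "never_decays" | "unset"
    at_bound: bool = False

    def expected(self, d_cm):
        """Fitted E(r^2) at map distance d (cM)."""
        r = _recomb_fraction(d_cm, self.map_function)
        return expected_r2_hill_weir(4.0 * self.ne * r, self.n)

    def summary(self) -> str:
        lines = [
            "Hill-Weir LD decay fit",
            "----------------------",
            f"effective population size Ne : {self.ne:.1f}" + (" (at bound)" if self.at_bound else ""),
            f"sample size n                : {self.n}",
            f"linked pairs fitted          : {self.n_pairs}",
            f"map function                 : {self.map_function}",
            f"residual sum of squares      : {self.sse:.4f}",
        ]
        if self.threshold is not None:
            lines.append(f"unlinked r2 threshold (Q95)  : {self.threshold:.4f}")
        if self.decay_flag == "ok" and self.decay_distance_cm is not None:
            lines.append(f"LD decay distance            : {self.decay_distance_cm:.2f} cM")
        elif self.decay_flag != "unset":
            lines.append(f"LD decay distance            : {self.decay_flag}")
        return "\n".join(lines)


class LDDecayModel:
    """Least-squares Hill-Weir decay model with Ne as the free parameter.

    Parameters
    ----------
    distances_cm, r2 : array-like
        Linked marker-pair map distances and observed r^2 values.
    n : int
        Sample size entering the finite-sample term of the expectation.
    map_function : {"linear", "haldane"}
        cM -> recombination fraction conversion.
    """

    def __init__(self, distances_cm, r2, n: int, map_function: str = "linear"):
        self.d = np.asarray(distances_cm, dtype=float)
        self.r2 = np.asarray(r2, dtype=float)
        if self.d.shape != self.r2.shape:
            raise ValueError("distances and r2 must have equal length")
        keep = np.isfinite(self.d) & np.isfinite(self.r2) & (self.d > 0)
        self.d, self.r2 = self.d[keep], self.r2[keep]
        if self.d.size == 0:
            raise ValueError("no linked pairs with positive distance")
        if n < 2:
            raise ValueError("sample size n must be >= 2")
        self.n = int(n)
        self.map_function = map_function
        self._r = _recomb_fraction(self.d, map_function)

    def sse(self, ne: float) -> float:
        pred = expected_r2_hill_weir(4.0 * ne * self._r, self.n)
        return float(((self.r2 - pred) ** 2).sum())

    def fit(self, bounds=NE_BOUNDS) -> DecayFit:
        lo, hi = np.log(bounds[0]), np.log(bounds[1])
        res = minimize_scalar(
            lambda x: self.sse(np.exp(x)),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-10},
        )
        ne = float(np.exp(res.x))
        at_bound = (ne / bounds[0] < 1.01) or (bounds[1] / ne < 1.01)
        if at_bound:
            warnings.warn(f"fitted Ne={ne:.3g} sits at the search bound {bounds}")
        return DecayFit(
            ne=ne,
            n=self.n,
            sse=float(res.fun),
            n_pairs=int(self.d.size),
            map_function=self.map_function,
            at_bound=at_bound,
            decay_flag="unset",
        )


def fit_effective_population_size(
    table: LDTable,
    n: int,
    map_function: str = "linear",
    threshold: float | None = None,
    min_pairs: int = 10,
) -> DecayFit:
    """Fit Ne from the linked pairs of an LD table.

    If ``threshold`` (the unlinked r^2 quantile) is given, the LD decay
    distance is solved from the fitted curve and stored on the result.
    """
    linked = table.linked
    if len(linked) < min_pairs:
        raise ValueError(f"need >= {min_pairs} linked pairs, have {len(linked)}")
    fit = LDDecayModel(
        linked["distance_cm"].to_numpy(), linked["r2"].to_numpy(), n, map_function
    ).fit()
    if threshold is not None:
        fit.threshold = float(threshold)
        fit.decay_distance_cm, fit.decay_flag = _solve_decay(fit)
    return fit


def _solve_decay(fit: DecayFit, d_max: float = 1e4, tol: float = 1e-6):
    thr = fit.threshold
    intercept = fit.expected(0.0)
    floor = 1.0 / fit.n
    if thr >= intercept:
        return 0.0, "above_intercept"
    if thr <= fit.expected(d_max) or thr <= floor:
        return None, "never_decays"
    lo, hi = 1e-6, d_max
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if fit.expected(mid) > thr:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi), "ok"


def ld_decay_distance(fit: DecayFit) -> float | None:
    """Map distance (cM) where the fitted curve reaches the threshold.

    Returns 0 when the threshold exceeds the curve's intercept and ``None``
    (flag ``never_decays``) when it lies at or below the 1/n floor.
    """
    if fit.threshold is None:
        raise ValueError("fit has no threshold set")
    d, flag = _solve_decay(fit)
    fit.decay_distance_cm, fit.decay_flag = d, flag
    return d


def binned_mean_r2(table: LDTable, bin_width: float = 5.0) -> pd.DataFrame:
    """Mean r^2 of linked pairs in half-open distance bins [k w, (k+1) w)."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    linked = table.linked
    d = linked["distance_cm"].to_numpy()
    r2 = linked["r2"].to_numpy()
    if d.size == 0:
        return pd.DataFrame(columns=["bin_start", "bin_end", "mean_r2", "n_pairs", "empty"])
    n_bins = int(np.floor(d.max() / bin_width)) + 1
    which = np.floor(d / bin_width).astype(int)
    rows = []
    for b in range(n_bins):
        sel = which == b
        rows.append(
            {
                "bin_start": b * bin_width,
                "bin_end": (b + 1) * bin_width,
                "mean_r2": float(r2[sel].mean()) if sel.any() else np.nan,
                "n_pairs": int(sel.sum()),
                "empty": not sel.any(),
            }
        )
    return pd.DataFrame(rows)


def window_mean_r2(
    table: LDTable, genetic_map: GeneticMap, window: float = 5.0
) -> pd.DataFrame:
    """Mean r^2 per genome window; a pair counts only if both markers fall
    inside the same window.  Windows tile each linkage group from 0 cM."""
    if window <= 0:
        raise ValueError("window must be positive")
    pos = genetic_map.position_of()
    group = genetic_map.group_of()
    linked = table.linked
    pa = pos.reindex(linked["marker_a"]).to_numpy(dtype=float)
    pb = pos.reindex(linked["marker_b"]).to_numpy(dtype=float)
    ga = group.reindex(linked["marker_a"]).to_numpy()
    wa = np.floor(pa / window).astype(int)
    wb = np.floor(pb / window).astype(int)
    inside = wa == wb
    r2 = linked["r2"].to_numpy()

    rows = []
    for g in genetic_map.linkage_groups:
        gpos = genetic_map.markers_in_group(g)["cM"]
        if gpos.empty:
            continue
        n_windows = int(np.floor(gpos.max() / window)) + 1
        for w in range(n_windows):
            sel = inside & (ga == g) & (wa == w)
            rows.append(
                {
                    "linkage_group": g,
                    "window_start": w * window,
                    "window_end": (w + 1) * window,
                    "mean_r2": float(r2[sel].mean()) if sel.any() else np.nan,
                    "n_pairs": int(sel.sum()),
                    "empty": not sel.any(),
                }
            )
    return pd.DataFrame(rows)


def ld_summary(table: LDTable, fit: DecayFit | None = None) -> dict:
    """Germplasm-set LD summary: mean r^2 and exceedance percentages for
    linked and unlinked pairs (the shape of the study's Table 1)."""
    if len(table.pairs) == 0:
        raise ValueError("empty LD table")
    linked = table.linked["r2"].to_numpy()
    unlinked = table.unlinked["r2"].to_numpy()
    thr = fit.threshold if fit is not None else None
    out = {
        "n_linked_pairs": int(linked.size),
        "n_unlinked_pairs": int(unlinked.size),
        "mean_r2_linked": float(linked.mean()) if linked.size else None,
        "mean_r2_unlinked": float(unlinked.mean()) if unlinked.size else None,
        "threshold_q95": thr,
        "pct_linked_above_threshold": (
            float((linked > thr).mean() * 100.0) if (thr is not None and linked.size) else None
        ),
        "pct_linked_above_0.8": float((linked > 0.8).mean() * 100.0) if linked.size else None,
        "pct_unlinked_above_0.8": float((unlinked > 0.8).mean() * 100.0) if unlinked.size else None,
    }
    if fit is not None:
        out["ne"] = fit.ne
        out["n"] = fit.n
        out["decay_distance_cm"] = fit.decay_distance_cm
        out["decay_flag"] = fit.decay_flag
    return out


def ne_per_linkage_group(
    table: LDTable,
    genetic_map: GeneticMap,
    n: int,
    map_function: str = "linear",
    threshold: float | None = None,
    min_pairs: int = 10,
) -> pd.DataFrame:
    """Hill-Weir Ne fitted separately within each linkage group.

    The significance threshold is inherited from the global unlinked
    quantile.  Groups with fewer than ``min_pairs`` informative linked
    pairs are flagged and carry no estimate.
    """
    group = genetic_map.group_of()
    linked = table.linked
    ga = group.reindex(linked["marker_a"]).to_numpy()
    rows = []
    for g in genetic_map.linkage_groups:
        sub = linked[ga == g]
        if len(sub) < min_pairs:
            rows.append({"linkage_group": g, "ne": np.nan, "n_pairs": len(sub),
                         "decay_distance_cm": np.nan, "flag": "too_few_pairs"})
            continue
        fit = LDDecayModel(
            sub["distance_cm"].to_numpy(), sub["r2"].to_numpy(), n, map_function
        ).fit()
        decay = np.nan
        flag = "ok" if not fit.at_bound else "at_bound"
        if threshold is not None:
            fit.threshold = float(threshold)
            d, dflag = _solve_decay(fit)
            decay = d if d is not None else np.nan
            if dflag != "ok":
                flag = dflag if flag == "ok" else flag
        rows.append({"linkage_group": g, "ne": fit.ne, "n_pairs": len(sub),
                     "decay_distance_cm": decay, "flag": flag})
    return pd.DataFrame(rows)
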