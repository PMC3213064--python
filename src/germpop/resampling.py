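"""Marker-number experiments: how many SNPs are needed to recover the
full-panel population structure and distance estimates.

Subsets of markers are drawn at random, stratified along the genetic map,
or deterministically as the top-ranked markers by PIC or by between-group
per-locus MRD.  For each subset the panel is re-ordinated (PCA),
re-clustered (Gaussian mixture with K fixed to the full-panel subgroup
count) and scored against the full-panel assignment; the coefficient of
variation of pairwise MRD across repetitions measures the precision of
distance estimation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diversity import allele_frequencies, mrd_between_groups_per_locus, mrd_pairwise, pic
from .panel import GenotypePanel, GeneticMap, GroupLabels
from .structure import assignment_correspondence, gmm_cluster, pca_components, threshold_assign

__all__ = [
    "DEFAULT_SIZE_GRID",
    "subset_random",
    "subset_stratified",
    "subset_top_ranked",
    "resampling_experiment",
    "ResamplingCurve",
]

#: the study's subset-size ladder: 9 to 252 in steps of 9 (28 sizes)
DEFAULT_SIZE_GRID = tuple(range(9, 253, 9))

STOCHASTIC_STRATEGIES = ("random", "stratified")
DETERMINISTIC_STRATEGIES = ("top_pic", "top_mrd")


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def subset_random(genetic_map: GeneticMap, size: int, seed) -> list:
    """Uniform sample of ``size`` markers without replacement."""
    markers = genetic_map.canonical_order()
    if size > len(markers):
        raise ValueError(f"size {size} exceeds marker count {len(markers)}")
    rng = _rng(seed)
    idx = rng.choice(len(markers), size=size, replace=False)
    return [markers[i] for i in sorted(idx)]


def _largest_remainder(counts: np.ndarray, total: int) -> np.ndarray:
    """Apportion ``total`` over groups proportionally to ``counts``."""
    quota = counts / counts.sum() * total
    alloc = np.floor(quota).astype(int)
    short = total - alloc.sum()
    # ties on the fractional part resolved by group order
    order = np.argsort(-(quota - alloc), kind="stable")
    alloc[order[:short]] += 1
    return alloc


def subset_stratified(genetic_map: GeneticMap, size: int, seed) -> list:
    """Markers spread evenly along the genome.

    Group allocations follow largest-remainder apportionment by marker
    count; within a group the position-ordered markers are split into
    ``allocation`` consecutive blocks of (nearly) equal count and one
    marker is drawn uniformly from each block.  Every marker keeps the
    same inclusion probability as under random sampling, but nearby
    (locally correlated) markers cannot be drawn together, which is what
    lowers the sampling variance of map-wide statistics.
    """
    markers = genetic_map.canonical_order()
    if size > len(markers):
        raise ValueError(f"size {size} exceeds marker count {len(markers)}")
    rng = _rng(seed)
    groups = genetic_map.linkage_groups
    counts = np.array([len(genetic_map.markers_in_group(g)) for g in groups])
    alloc = _largest_remainder(counts, size)

    chosen: list = []
    for g, k in zip(groups, alloc):
        if k == 0:
            continue
        ids = genetic_map.markers_in_group(g)["marker_id"].to_numpy()
        edges = np.round(np.linspace(0, len(ids), int(k) + 1)).astype(int)
        for j in range(int(k)):
            block = ids[edges[j]:edges[j + 1]]
            chosen.append(block[rng.integers(len(block))])
    order = {m: i for i, m in enumerate(markers)}
    return sorted(chosen, key=order.get)


def subset_top_ranked(
    panel: GenotypePanel,
    genetic_map: GeneticMap,
    size: int,
    criterion: str = "pic",
    labels: GroupLabels | None = None,
) -> list:
    """Deterministic top-``size`` markers by PIC or between-group MRD.

    Ties at the cutoff are broken by canonical genome order.
    """
    markers = genetic_map.canonical_order()
    if size > len(markers):
        raise ValueError(f"size {size} exceeds marker count {len(markers)}")
    if criterion == "pic":
        values = pd.Series(pic(allele_frequencies(panel)), index=panel.marker_ids)
    elif criterion == "mrd_between_groups":
        if labels is None:
            raise ValueError("criterion 'mrd_between_groups' requires group labels")
        values = mrd_between_groups_per_locus(panel, labels)
    else:
        raise ValueError("criterion must be 'pic' or 'mrd_between_groups'")
    values = values.reindex(markers).fillna(-np.inf)
    ranked = sorted(range(len(markers)), key=lambda i: (-values.iloc[i], i))
    keep = sorted(ranked[:size])
    return [markers[i] for i in keep]


@dataclass
class ResamplingCurve:
    """Long-format per-repetition records plus the summarised curves."""

    records: pd.DataFrame  # strategy, size, rep, correspondence
    summary: pd.DataFrame  # strategy, size, mean/se correspondence, mean CV of MRD


def _child_seed(master: int, strategy: str, size: int, rep: int) -> np.random.Generator:
    name = sum(ord(c) for c in strategy)
    ss = np.random.SeedSequence(entropy=int(master), spawn_key=(name, int(size), int(rep)))
    return np.random.default_rng(ss)


def _select(strategy, panel, genetic_map, size, rng, type_labels):
    if strategy == "random":
        return subset_random(genetic_map, size, rng)
    if strategy == "stratified":
        return subset_stratified(genetic_map, size, rng)
    if strategy == "top_pic":
        return subset_top_ranked(panel, genetic_map, size, "pic")
    if strategy == "top_mrd":
        return subset_top_ranked(panel, genetic_map, size, "mrd_between_groups", type_labels)
    raise ValueError(f"unknown strategy {strategy!r}")


def resampling_experiment(
    panel: GenotypePanel,
    genetic_map: GeneticMap,
    reference_labels: GroupLabels,
    sizes=DEFAULT_SIZE_GRID,
    reps: int = 100,
    strategies=STOCHASTIC_STRATEGIES + DETERMINISTIC_STRATEGIES,
    seed: int = 0,
    n_pca_components: int = 10,
    compute_correspondence: bool = True,
    compute_cv: bool = True,
    type_labels: GroupLabels | None = None,
) -> ResamplingCurve:
    """Run the marker-number experiment.

    For each strategy and subset size: select markers, run PCA on the
    subset, cluster on up to ``n_pca_components`` components with K fixed
    to the reference subgroup count, and score the assignment against
    ``reference_labels``; across repetitions, the per-line-pair CV of MRD
    is averaged into a precision curve.  Deterministic top-ranked
    strategies run once per size.  Child seeds derive from
    ``(seed, strategy, size, rep)``, so any single cell reproduces in
    isolation.  The ``top_mrd`` ranking needs two-group germplasm-type
    labels (``type_labels``; falls back to ``reference_labels`` when that
    carries exactly two groups, otherwise the strategy is skipped with a
    warning).
    """
    if reps < 2:
        raise ValueError("need reps >= 2 to compute a CV")
    ref_k = len(reference_labels.groups())
    if ref_k < 1:
        raise ValueError("reference labels contain no assigned group")
    sizes = list(sizes)
    if type_labels is None and ref_k == 2:
        type_labels = reference_labels
    strategies = list(strategies)
    if "top_mrd" in strategies and (
        type_labels is None or len(type_labels.groups()) != 2
    ):
        warnings.warn("top_mrd strategy skipped: no two-group type labels available")
        strategies = [s for s in strategies if s != "top_mrd"]

    records = []
    summary_rows = []
    for strategy in strategies:
        strat_reps = reps if strategy in STOCHASTIC_STRATEGIES else 1
        for size in sizes:
            corr_vals = []
            mrd_stack = []
            for rep in range(strat_reps):
                rng = _child_seed(seed, strategy, size, rep)
                subset = _select(strategy, panel, genetic_map, size, rng, type_labels)
                sub_panel = panel.subset_markers(subset)
                if compute_correspondence:
                    k = min(n_pca_components, size, sub_panel.n_lines - 1)
                    ord_res = pca_components(sub_panel, n_components=k)
                    _, members, _ = gmm_cluster(
                        ord_res.coordinates,
                        K_range=[ref_k],
                        seed=int(rng.integers(2**31)),
                        line_ids=sub_panel.line_ids,
                        restarts=2,
                    )
                    assigned = threshold_assign(members, rule="max")
                    corr = assignment_correspondence(assigned, reference_labels)
                    corr_vals.append(corr)
                    records.append(
                        {"strategy": strategy, "size": size, "rep": rep, "correspondence": corr}
                    )
                if compute_cv and strategy in STOCHASTIC_STRATEGIES:
                    mrd_stack.append(mrd_pairwise(sub_panel).condensed())
            row = {"strategy": strategy, "size": size}
            if corr_vals:
                row["mean_correspondence"] = float(np.mean(corr_vals))
                row["se_correspondence"] = (
                    float(np.std(corr_vals, ddof=1) / np.sqrt(len(corr_vals)))
                    if len(corr_vals) > 1
                    else 0.0
                )
            if mrd_stack:
                row["mean_cv_mrd"] = _mean_cv(np.vstack(mrd_stack))
            summary_rows.append(row)
    return ResamplingCurve(
        records=pd.DataFrame(records), summary=pd.DataFrame(summary_rows)
    )


def _mean_cv(stack: np.ndarray) -> float:
    """Mean over line pairs of (sd across reps) / (mean across reps)."""
    mean = np.nanmean(stack, axis=0)
    sd = np.nanstd(stack, axis=0, ddof=1)
    ok = np.isfinite(mean) & (mean > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = sd[ok] / mean[ok]
    return float(cv.mean()) if ok.any() else np.nan
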