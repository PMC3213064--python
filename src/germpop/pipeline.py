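"""End-to-end pipeline: simulate (optional) -> validate -> diversity ->
structure -> resample -> LD, with one master seed and a reproducibility
manifest.

Each stage writes plain-text TSV/JSON outputs into its own subdirectory of
the run directory and never touches another stage's outputs; the manifest
records parameters, seeds and file checksums so any stage can be re-run in
isolation and a rerun with the same config is bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as gio
from .diversity import (
    allele_frequencies,
    bootstrap_se,
    gene_diversity,
    mrd_between_groups_per_locus,
    mrd_pairwise,
    pic,
)
from .ld import (
    binned_mean_r2,
    fit_effective_population_size,
    ld_summary,
    ne_per_linkage_group,
    pairwise_r2_table,
    unlinked_r2_quantile,
    window_mean_r2,
)
from .panel import validate_panel
from .resampling import DEFAULT_SIZE_GRID, resampling_experiment
from .simulate import ScenarioConfig, generate_panel
from .structure import (
    assignment_correspondence,
    evanno_delta_k,
    gmm_cluster,
    likelihood_table,
    pca_components,
    pcoa_from_distance,
    threshold_assign,
)

__all__ = ["PipelineConfig", "run_pipeline"]


def _stage_seed(master: int, stage: str) -> int:
    """Counter-free named child seed: stable under adding stages."""
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    """Inputs, stage toggles and per-stage parameters.

    Defaults follow the emulated study: 10 PCA components for clustering,
    K examined 1..15, eps=0.8, q=0.95, subset grid 9..252 by 9 with 100
    repetitions, 1000 bootstrap replicates.
    """

    output_dir: str = "germpop_run"
    # either a scenario...
    scenario: ScenarioConfig | None = None
    # ...or real inputs
    genotype_path: str | None = None
    map_path: str | None = None
    labels_path: str | None = None

    stages: tuple = ("simulate", "validate", "diversity", "structure", "resample", "ld")
    seed: int = 0
    max_missing: float = 0.20
    n_pca_components: int = 10
    k_max: int = 15
    eps: float = 0.8
    q: float = 0.95
    sizes: tuple = DEFAULT_SIZE_GRID
    reps: int = 100
    bootstrap_B: int = 1000
    map_function: str = "linear"
    bin_width: float = 5.0
    window: float = 5.0


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the configured stages; returns the run directory.

    A stage failure aborts the run with a stage-named error; outputs of
    completed stages are retained alongside a ``FAILED`` marker.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": _config_dict(config),
        "stages": {},
    }
    state: dict = {}
    try:
        for stage in config.stages:
            t0 = time.time()
            runner = _STAGES.get(stage)
            if runner is None:
                raise ValueError(f"unknown stage {stage!r}")
            stage_dir = out / stage
            stage_dir.mkdir(exist_ok=True)
            runner(config, state, stage_dir)
            manifest["stages"][stage] = {
                "seconds": round(time.time() - t0, 3),
                "seed": _stage_seed(config.seed, stage),
                "outputs": {
                    p.name: _checksum(p) for p in sorted(stage_dir.iterdir()) if p.is_file()
                },
            }
    except Exception as exc:
        (out / "FAILED").write_text(f"stage {stage!r} failed: {exc}\n")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return out


def _config_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    return d


def _load_inputs(config: PipelineConfig, state: dict) -> None:
    if "panel" in state:
        return
    if config.genotype_path is None or config.map_path is None:
        raise FileNotFoundError(
            "no simulated panel in this run and no genotype/map paths configured"
        )
    for p in (config.genotype_path, config.map_path):
        if not Path(p).exists():
            raise FileNotFoundError(f"input file not found: {p}")
    state["panel"] = gio.read_genotype_table(config.genotype_path)
    state["map"] = gio.read_genetic_map(config.map_path)
    if config.labels_path:
        if not Path(config.labels_path).exists():
            raise FileNotFoundError(f"labels file not found: {config.labels_path}")
        state["labels"] = gio.read_labels(config.labels_path)
    elif state["panel"].type_label is not None:
        from .panel import GroupLabels

        state["labels"] = GroupLabels(state["panel"].line_ids, state["panel"].type_label)


def _stage_simulate(config, state, stage_dir: Path) -> None:
    scenario = config.scenario
    if scenario is None:
        if config.genotype_path is not None:
            _load_inputs(config, state)
            return
        scenario = ScenarioConfig(seed=_stage_seed(config.seed, "simulate"))
    panel, genetic_map, truth = generate_panel(scenario)
    state["panel"], state["map"], state["labels"] = panel, genetic_map, truth
    gio.write_genotype_table(panel, stage_dir / "genotypes.tsv")
    gio.write_genetic_map(genetic_map, stage_dir / "map.tsv")
    gio.write_labels(truth, stage_dir / "labels.tsv")
    gio.write_structure_export(panel, stage_dir / "structure_input.txt")


def _stage_validate(config, state, stage_dir: Path) -> None:
    _load_inputs(config, state)
    report = validate_panel(state["panel"], state["map"], config.max_missing)
    (stage_dir / "validation.json").write_text(
        json.dumps(dataclasses.asdict(report), indent=2) + "\n"
    )
    if not report.passed:
        raise ValueError("panel failed validation; see validate/validation.json")


def _stage_diversity(config, state, stage_dir: Path) -> None:
    _load_inputs(config, state)
    panel, labels = state["panel"], state.get("labels")
    freq = allele_frequencies(panel)
    tab = pd.DataFrame(
        {
            "marker_id": panel.marker_ids,
            "freq": freq,
            "gene_diversity": gene_diversity(freq),
            "pic": pic(freq),
        }
    )
    if labels is not None and len(labels.groups()) == 2:
        order = {lid: i for i, lid in enumerate(panel.line_ids)}
        lab = np.asarray(labels.labels)
        idx = np.array([order[lid] for lid in labels.line_ids])
        seed = _stage_seed(config.seed, "diversity")
        for g in labels.groups():
            fg = allele_frequencies(panel, lines=idx[lab == g])
            tab[f"gene_diversity_{g}"] = gene_diversity(fg)
        dse = bootstrap_se(panel, labels, "gene_diversity", B=config.bootstrap_B, seed=seed)
        for c in dse.columns:
            tab[f"gene_diversity_{c}"] = dse[c].to_numpy()
        tab["mrd_between"] = mrd_between_groups_per_locus(panel, labels).to_numpy()
        mse = bootstrap_se(panel, labels, "mrd_between_groups", B=config.bootstrap_B, seed=seed + 1)
        tab["mrd_between_se"] = mse["se"].to_numpy()
    order_idx = state["map"].canonical_order()
    tab = tab.set_index("marker_id").reindex(order_idx)
    tab.to_csv(stage_dir / "per_marker.tsv", sep="\t")
    D = mrd_pairwise(panel)
    state["mrd"] = D
    pd.DataFrame(
        {"statistic": ["mean_mrd"], "value": [float(np.nanmean(D.condensed()))]}
    ).to_csv(stage_dir / "summary.tsv", sep="\t", index=False)


def _stage_structure(config, state, stage_dir: Path) -> None:
    _load_inputs(config, state)
    panel = state["panel"]
    seed = _stage_seed(config.seed, "structure")
    pca = pca_components(panel, n_components=min(config.n_pca_components, panel.n_markers))
    D = state.get("mrd") or mrd_pairwise(panel)
    pcoa = pcoa_from_distance(D, n_components=config.n_pca_components)
    coords = pd.DataFrame(pca.coordinates, index=panel.line_ids)
    coords.to_csv(stage_dir / "pca_coordinates.tsv", sep="\t")
    pd.DataFrame(
        {
            "component": np.arange(1, len(pca.variance_explained) + 1),
            "pca_variance": pca.variance_explained,
        }
    ).to_csv(stage_dir / "variance.tsv", sep="\t", index=False)

    best_k, members, bic = gmm_cluster(
        pca.coordinates, K_range=range(1, config.k_max + 1), seed=seed,
        line_ids=panel.line_ids,
    )
    members.to_frame().to_csv(stage_dir / "membership.tsv", sep="\t")
    bic.to_csv(stage_dir / "bic.tsv", sep="\t")
    assigned = threshold_assign(members, rule="max")
    gio.write_labels(assigned, stage_dir / "assigned.tsv")
    state["assigned"] = assigned
    state["best_k"] = best_k

    lt = likelihood_table(pca.coordinates, K_range=range(1, 6), replicates=5, seed=seed)
    lt.to_tsv(stage_dir / "likelihoods.tsv")
    dk = evanno_delta_k(lt)
    dk.to_csv(stage_dir / "delta_k.tsv", sep="\t")

    summary = {
        "best_k_bic": best_k,
        "delta_k_best": int(dk.idxmax()) if dk.notna().any() else None,
        "pc1_variance_pct": float(pca.variance_explained[0] * 100),
        "pc2_variance_pct": float(pca.variance_explained[1] * 100),
        "pco1_variance_pct": float(pcoa.variance_explained[0] * 100),
        "pco2_variance_pct": float(pcoa.variance_explained[1] * 100),
    }
    if state.get("labels") is not None:
        summary["correspondence_with_labels"] = assignment_correspondence(
            assigned, state["labels"]
        )
    (stage_dir / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")


def _stage_resample(config, state, stage_dir: Path) -> None:
    _load_inputs(config, state)
    if "assigned" not in state:
        raise RuntimeError("resample stage requires the structure stage")
    sizes = [s for s in config.sizes if s <= state["panel"].n_markers]
    curve = resampling_experiment(
        state["panel"],
        state["map"],
        state["assigned"],
        sizes=sizes,
        reps=config.reps,
        seed=_stage_seed(config.seed, "resample"),
        n_pca_components=config.n_pca_components,
        type_labels=state.get("labels"),
    )
    curve.records.to_csv(stage_dir / "records.tsv", sep="\t", index=False)
    curve.summary.to_csv(stage_dir / "curve.tsv", sep="\t", index=False)


def _stage_ld(config, state, stage_dir: Path) -> None:
    _load_inputs(config, state)
    panel, genetic_map = state["panel"], state["map"]
    labels = state.get("labels")
    sets = {"all": None}
    if labels is not None and len(labels.groups()) == 2:
        lab = labels.as_series()
        for g in labels.groups():
            sets[g] = [lid for lid in panel.line_ids if lab.get(lid) == g]
    summaries = []
    for name, lines in sets.items():
        table = pairwise_r2_table(panel, genetic_map, lines=lines)
        n = len(lines) if lines is not None else panel.n_lines
        thr = unlinked_r2_quantile(table, config.q)
        fit = fit_effective_population_size(
            table, n=n, map_function=config.map_function, threshold=thr
        )
        summaries.append({"set": name, **ld_summary(table, fit)})
        if name == "all":
            table.pairs.to_csv(stage_dir / "pairs.tsv", sep="\t", index=False)
            binned_mean_r2(table, config.bin_width).to_csv(
                stage_dir / "binned.tsv", sep="\t", index=False
            )
            window_mean_r2(table, genetic_map, config.window).to_csv(
                stage_dir / "windowed.tsv", sep="\t", index=False
            )
        ne_per_linkage_group(
            table, genetic_map, n=n, map_function=config.map_function, threshold=thr
        ).to_csv(stage_dir / f"ne_per_group_{name}.tsv", sep="\t", index=False)
    pd.DataFrame(summaries).to_csv(stage_dir / "summary.tsv", sep="\t", index=False)


_STAGES = {
    "simulate": _stage_simulate,
    "validate": _stage_validate,
    "diversity": _stage_diversity,
    "structure": _stage_structure,
    "resample": _stage_resample,
    "ld": _stage_ld,
}
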