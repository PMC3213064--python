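"""Synthetic germplasm panels with known structure, drift and map-based LD.

The generator emulates the study design the analysis modules assume: two
diverged subpopulations of inbred lines (defaults: 264 "yield" and 238
"sugar" lines) genotyped at 328 SNPs on nine linkage groups, with the yield
pool carrying a much smaller effective population size than the sugar pool
(defaults 21 vs 73), and up to 20% missing calls.

Mechanism
---------
1.  Ancestral allele frequencies are drawn Uniform(0.05, 0.95) per marker.
2.  Each subpopulation's founder frequencies diverge under the
    Balding–Nichols model: Beta(p(1-F)/F, (1-p)(1-F)/F), whose mean is the
    ancestral frequency and whose variance is F p (1-p).
3.  Each subpopulation evolves as a forward Wright–Fisher population of Ne
    monoecious diploids for a fixed number of generations, with Haldane
    (no-interference) recombination on the genetic map and no mutation —
    so map-structured LD and drift arise mechanistically and the LD-based
    Ne estimate has a ground truth.
4.  Inbred lines are derived as doubled haploids: one recombinant gamete
    per line, doubled, giving exact homozygosity in a single step.
5.  Missing calls are injected completely at random (MCAR), kept under the
    20% per-line / per-marker ceiling.

Meiosis is implemented as a Markov switch process along each linkage group:
the parental-haplotype source switches between adjacent markers with the
Haldane recombination fraction of their cM interval, which is exactly the
marker-restricted law of Poisson crossovers on the map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .panel import GenotypePanel, GeneticMap, GroupLabels

__all__ = [
    "ScenarioConfig",
    "HaplotypePool",
    "build_genetic_map",
    "draw_subpop_frequencies",
    "simulate_wf_subpop",
    "derive_inbred_lines",
    "inject_missing",
    "generate_panel",
]

#: marker counts per linkage group in the emulated panel design
DEFAULT_MARKER_COUNTS = (26, 33, 41, 35, 40, 42, 39, 32, 40)


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class ScenarioConfig:
    """Study-design parameters for :func:`generate_panel`."""

    n_lines: tuple = (264, 238)
    subpop_names: tuple = ("yield", "sugar")
    marker_counts: tuple = DEFAULT_MARKER_COUNTS
    group_length_cm: float = 100.0
    fst: float = 0.15
    ne: tuple = (21, 73)
    generations: int = 100
    missing_rate: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.n_lines) != len(self.ne) or len(self.n_lines) != len(self.subpop_names):
            raise ValueError("n_lines, ne and subpop_names must have equal length")
        if any(n <= 0 for n in self.n_lines):
            raise ValueError("n_lines entries must be positive")
        if any(n < 2 for n in self.ne):
            raise ValueError("ne entries must be >= 2")
        if any(c <= 0 for c in self.marker_counts):
            raise ValueError("marker_counts entries must be positive")
        if not 0 < self.fst < 1:
            raise ValueError("fst must lie in (0, 1)")
        if not 0 <= self.missing_rate <= 0.2:
            raise ValueError("missing_rate must lie in [0, 0.2]")
        if self.generations < 0:
            raise ValueError("generations must be >= 0")
        if self.group_length_cm <= 0:
            raise ValueError("group_length_cm must be positive")


@dataclass
class HaplotypePool:
    """2N binary haplotypes over the markers of a genetic map."""

    haplotypes: np.ndarray  # (2N, m) of {0, 1}
    genetic_map: GeneticMap

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if self.haplotypes.shape[1] != self.genetic_map.n_markers:
            raise ValueError("haplotype column count does not match map size")
        if not np.isin(self.haplotypes, (0, 1)).all():
            raise ValueError("haplotype alleles must be 0/1")

    @property
    def frequencies(self) -> np.ndarray:
        return self.haplotypes.mean(axis=0)


def build_genetic_map(
    marker_counts=DEFAULT_MARKER_COUNTS,
    group_length_cm: float = 100.0,
    seed=0,
) -> GeneticMap:
    """Linkage groups A, B, ... with uniform-random marker positions.

    Positions are drawn Uniform(0, group length) and sorted within each
    group; marker ids encode group and rank (``A01``, ``A02``, ...).
    """
    rng = _rng(seed)
    names = [chr(ord("A") + i) for i in range(len(marker_counts))]
    ids, groups, positions = [], [], []
    for name, count in zip(names, marker_counts):
        pos = np.sort(rng.uniform(0.0, group_length_cm, size=count))
        width = len(str(count))
        for k, p in enumerate(pos):
            ids.append(f"{name}{k + 1:0{width}d}")
            groups.append(name)
            positions.append(float(p))
    return GeneticMap.from_arrays(ids, groups, positions)


def draw_subpop_frequencies(ancestral_p, fst: float, seed) -> np.ndarray:
    """Balding–Nichols divergence of subpopulation allele frequencies.

    Each frequency is Beta(p(1-F)/F, (1-p)(1-F)/F): mean p, variance
    F p (1-p), concentrating near 0/1 as F -> 1.
    """
    rng = _rng(seed)
    p = np.asarray(ancestral_p, dtype=float)
    if not 0 < fst < 1:
        raise ValueError("fst must lie in (0, 1)")
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("ancestral frequencies must lie strictly in (0, 1)")
    scale = (1.0 - fst) / fst
    return rng.beta(p * scale, (1.0 - p) * scale)


def _switch_probabilities(genetic_map: GeneticMap) -> np.ndarray:
    """Per-marker haplotype-source switch probabilities for one meiosis.

    First marker of each linkage group (and of the genome): 0.5
    (independent starting phase); within a group the Haldane fraction
    r = (1 - exp(-2 d / 100)) / 2 of the adjacent cM interval d.
    """
    order = genetic_map.canonical_order()
    group = genetic_map.group_of()[order].to_numpy()
    pos = genetic_map.position_of()[order].to_numpy(dtype=float)
    p = np.empty(len(order))
    p[0] = 0.5
    d = np.diff(pos)
    same = group[1:] == group[:-1]
    p[1:] = np.where(same, 0.5 * (1.0 - np.exp(-2.0 * np.abs(d) / 100.0)), 0.5)
    return p


def _meiosis(haps_a: np.ndarray, haps_b: np.ndarray, switch_p: np.ndarray,
             rng: np.random.Generator) -> np.ndarray:
    """Vectorised gametes: rows of haps_a/haps_b recombined per switch_p."""
    switches = rng.random(haps_a.shape) < switch_p
    source = np.cumsum(switches, axis=1, dtype=np.int64) % 2
    return np.where(source == 0, haps_a, haps_b).astype(np.int8)


def simulate_wf_subpop(
    founder_freqs,
    genetic_map: GeneticMap,
    ne: int,
    generations: int,
    seed,
) -> HaplotypePool:
    """Forward Wright–Fisher simulation of one subpopulation.

    Founder haplotypes are drawn marker-independently from
    ``founder_freqs`` (in canonical marker order); each of ``generations``
    rounds replaces the population with Ne offspring of randomly mated
    (monoecious, selfing allowed) parents.  No mutation: monomorphic loci
    stay monomorphic.  ``generations=0`` returns the founder pool.
    """
    rng = _rng(seed)
    if genetic_map.n_markers == 0:
        raise ValueError("empty genetic map")
    if ne < 2:
        raise ValueError("ne must be >= 2")
    freqs = np.asarray(founder_freqs, dtype=float)
    if freqs.shape != (genetic_map.n_markers,):
        raise ValueError("founder_freqs length does not match map size")

    haps = (rng.random((2 * ne, genetic_map.n_markers)) < freqs).astype(np.int8)
    switch_p = _switch_probabilities(genetic_map)
    for _ in range(generations):
        parents = rng.integers(ne, size=2 * ne)
        haps = _meiosis(haps[2 * parents], haps[2 * parents + 1], switch_p, rng)
    return HaplotypePool(haplotypes=haps, genetic_map=genetic_map)


def derive_inbred_lines(
    pool: HaplotypePool,
    n_lines: int,
    seed,
    line_prefix: str = "L",
) -> GenotypePanel:
    """Doubled-haploid lines: one recombinant gamete per line, doubled.

    Each line samples a random individual from the pool and one gamete from
    it; the gamete doubled gives a fully homozygous line, so dosages are
    exactly 0 or 1.  Marker ids follow the map's canonical order.
    """
    if n_lines < 1:
        raise ValueError("n_lines must be >= 1")
    rng = _rng(seed)
    ne = pool.haplotypes.shape[0] // 2
    parents = rng.integers(ne, size=n_lines)
    switch_p = _switch_probabilities(pool.genetic_map)
    gametes = _meiosis(
        pool.haplotypes[2 * parents], pool.haplotypes[2 * parents + 1], switch_p, rng
    )
    width = len(str(n_lines))
    return GenotypePanel(
        line_ids=[f"{line_prefix}{i + 1:0{width}d}" for i in range(n_lines)],
        marker_ids=pool.genetic_map.canonical_order(),
        dosage=gametes.astype(float),
    )


def inject_missing(panel: GenotypePanel, rate: float, seed,
                   ceiling: float = 0.20, max_tries: int = 100) -> GenotypePanel:
    """Set cells missing completely at random at the given rate.

    The whole mask is redrawn if any line or marker would exceed the
    ``ceiling`` missing fraction, so generated panels always satisfy the
    panel-validation ceiling.
    """
    if not 0 <= rate <= 0.2:
        raise ValueError("missing rate must lie in [0, 0.2]")
    if rate == 0:
        return GenotypePanel(
            line_ids=list(panel.line_ids),
            marker_ids=list(panel.marker_ids),
            dosage=panel.dosage.copy(),
            type_label=list(panel.type_label) if panel.type_label is not None else None,
        )
    rng = _rng(seed)
    for _ in range(max_tries):
        mask = rng.random(panel.dosage.shape) < rate
        if mask.mean(axis=1).max() <= ceiling and mask.mean(axis=0).max() <= ceiling:
            dosage = panel.dosage.copy()
            dosage[mask] = np.nan
            return GenotypePanel(
                line_ids=list(panel.line_ids),
                marker_ids=list(panel.marker_ids),
                dosage=dosage,
                type_label=list(panel.type_label) if panel.type_label is not None else None,
            )
    raise RuntimeError(
        f"could not draw a missingness mask under the {ceiling:.0%} ceiling "
        f"in {max_tries} tries"
    )


def generate_panel(config: ScenarioConfig):
    """Generate a full synthetic scenario.

    Returns ``(panel, genetic_map, truth)`` where ``truth`` holds the true
    subpopulation label of every line.  Deterministic given
    ``config.seed``; all internal random streams are spawned from one seed
    sequence so each stage is reproducible in isolation.
    """
    ss = np.random.SeedSequence(config.seed)
    keys = ("map", "ancestral", "diverge", "sim", "derive", "missing")
    streams = dict(zip(keys, ss.spawn(len(keys))))

    genetic_map = build_genetic_map(
        config.marker_counts, config.group_length_cm, np.random.default_rng(streams["map"])
    )
    m = genetic_map.n_markers
    ancestral = np.random.default_rng(streams["ancestral"]).uniform(0.05, 0.95, size=m)

    diverge_rng = np.random.default_rng(streams["diverge"])
    sim_children = streams["sim"].spawn(len(config.n_lines))
    derive_children = streams["derive"].spawn(len(config.n_lines))

    panels = []
    for k, (n, ne, name) in enumerate(zip(config.n_lines, config.ne, config.subpop_names)):
        founder = draw_subpop_frequencies(ancestral, config.fst, diverge_rng)
        pool = simulate_wf_subpop(
            founder, genetic_map, ne, config.generations,
            np.random.default_rng(sim_children[k]),
        )
        sub = derive_inbred_lines(
            pool, n, np.random.default_rng(derive_children[k]),
            line_prefix=name[:1].upper(),
        )
        sub.type_label = [name] * n
        panels.append(sub)

    dosage = np.vstack([p.dosage for p in panels])
    line_ids = sum((p.line_ids for p in panels), [])
    type_label = sum((p.type_label for p in panels), [])
    panel = GenotypePanel(
        line_ids=line_ids,
        marker_ids=genetic_map.canonical_order(),
        dosage=dosage,
        type_label=type_label,
    )
    panel = inject_missing(
        panel, config.missing_rate, np.random.default_rng(streams["missing"])
    )
    truth = GroupLabels(line_ids=line_ids, labels=type_label)
    return panel, genetic_map, truth
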