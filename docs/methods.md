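# Methods

This note records the models, conventions and design choices behind
`germpop`, in the order the pipeline runs them.

## Data model

The canonical genotype encoding is the within-individual allele frequency
at a biallelic SNP: 0, ½ or 1, with NaN for missing calls.  For inbred
lines the heterozygous value never occurs, so a line's dosage vector is
simultaneously a haplotype; all downstream statistics (frequencies, PCA
input, MRD, r²) are defined directly on this matrix.  Diploid allele
counts {0,1,2} are accepted on input and halved; the dialect is
auto-detected from the observed values.  Panels are validated against a
20 % missingness ceiling per line and per marker.  Missing-data policy is
per-statistic and always available-case: frequencies average the
non-missing dosages, MRD and r² use pairwise-complete entries, and
ordination mean-imputes per marker (recorded on the result object).  The
canonical marker order — linkage groups lexicographic, positions
ascending, marker id as tie-break — is the deterministic tie-break order
everywhere.

## Synthetic panels

The generator emulates the study design the analysis assumes: two
subpopulations of inbred lines (defaults 264 + 238) at 328 SNPs on nine
linkage groups with per-group counts (26, 33, 41, 35, 40, 42, 39, 32, 40),
divergent effective population sizes (defaults 21 and 73) and MCAR
missingness (default rate 0.10, always under the 0.20 ceiling).

1. *Map*: each linkage group is 100 cM (no published lengths exist for
   the emulated panel; 100 cM per group is a conventional beet-genome
   scale) with uniform-random marker positions.
2. *Divergence*: ancestral frequencies are Uniform(0.05, 0.95); each
   subpopulation's founder frequencies follow the Balding–Nichols model,
   Beta(p(1−F)/F, (1−p)(1−F)/F) with F = Fst (default 0.15): mean p,
   variance F·p(1−p).
3. *Drift and LD*: each subpopulation runs as a forward Wright–Fisher
   population of Ne monoecious diploids for 100 generations (random
   mating, selfing allowed, no mutation/selection/migration).  Meiosis is
   a Markov switch process along each group: the parental-haplotype
   source switches between adjacent markers with the Haldane
   recombination fraction r = (1 − e^(−2d/100))/2 of their cM interval,
   which is exactly the marker-restricted law of Poisson (no-interference)
   crossovers and is fully vectorisable.  A forward simulation (rather
   than a coalescent) was chosen so the LD the Hill–Weir fit estimates
   has a mechanistic ground truth.
4. *Lines*: doubled haploids — one recombinant gamete per line, doubled —
   giving exact homozygosity in one step, matching the inbred data model.

All stages draw from named child streams of one seed sequence, so
identical configurations are bit-identical and each stage is reproducible
in isolation.

What the generator does **not** emulate: spatially autocorrelated marker
informativeness (regional selection signatures), ascertainment bias in
SNP discovery, admixed or intermediate lines, pedigree structure beyond
one Wright–Fisher pool, and genotyping error.  Consequences observed in
testing: PC1 separations and between-type divergences are far stronger
than in typical real elite panels (a century of drift at Ne ≈ 21 fixes
most loci), lines sampled from one small pool carry half-sib family
substructure that BIC-selected mixture models legitimately detect as
extra components, and position-stratified marker sampling gains less than
it would on a genome with regionally correlated diversity.  Passing tests
therefore certify the estimators and their internal consistency, not that
real panels will show effects of these magnitudes.

## Diversity statistics

Gene diversity D = 1 − p² − q² and PIC = 1 − p² − q² − 2p²q² use plain
within-group frequencies (no small-sample correction); genome-wide
averages weight markers equally.  MRD between lines is
√(Σ(dₓ − dᵧ)²/m) over the m loci non-missing in both — on complete data
this equals Euclidean distance over √m, the identity behind the PCA/PCoA
duality.  Between-group per-locus MRD reduces to |p_A − p_B|.  Bootstrap
SEs resample genotypes (lines) with replacement within each group,
B = 1000 by default, SE = sd (ddof 1) across replicates.

## Ordination and eigenvalue significance

PCA mean-imputes, column-centres and decomposes by SVD; variance
fractions are eigenvalue shares of the total, so they sum to one over all
components.  The Tracy–Widom test requires the p(1−p)-normalised variant
("patterson" scaling, monomorphic markers dropped).  Successive
eigenvalues are standardised with the effective-marker moment estimator
m̂ = (L+1)a²/((L−1)b − a²) (a = Σλ, b = Σλ² over the L remaining
eigenvalues) and compared to tabulated Tracy–Widom (GOE) points
(0.4501 / 0.9793 / 2.0234 / 3.2724 at the 10/5/1/0.1 % levels); testing
stops at the first non-significant eigenvalue.  On 200 unstructured
panels the leading-eigenvalue rejection rate at the 5 % level is close to
nominal (the acceptance suite checks 2–9 %).

PCoA double-centres −D²/2; negative eigenvalues (non-Euclidean input) are
excluded from the variance denominator and reported.  Laplacian
eigenfunctions use one-sided thresholding (ρ ≥ eps, default 0.8) of the
individual-by-individual correlation of centred dosage rows, the
unnormalised Laplacian L = Degree − W, and eigenvectors computed on the
orthogonal complement of the constant vector (so disconnected components
yield exact block contrasts).  "Variance explained" for lapvectors is the
projection R² of the centred genotype matrix on each vector — one of
several possible conventions, chosen because it is comparable with the
PCA fractions.

## Mixture clustering, ΔK and assignment

`gmm_cluster` runs EM over four covariance families (spherical, shared
full, diagonal, full — the scikit-learn family set closest to the MCLUST
ladder) for each K, selecting by BIC = 2 logL − ν log N.  Restarts
combine one deterministic farthest-point seeding (order-independent, so
results are invariant to permuting input lines) with seeded k-means++
starts; tolerance 1e-8, 500 iterations, covariance floor 1e-6 of the
total variance.  Candidate fits with a component supported by fewer than
d+1 effective points are rejected: such spike components sit on the
covariance floor and inflate the likelihood, which otherwise makes BIC
prefer K = 2 on a substantial fraction of genuinely unstructured
datasets.  Components are re-ordered by their means so labels are stable.

Replicate likelihood tables (the input to Evanno's
ΔK = |L(K+1) − 2L(K) + L(K−1)| / sd(L(K))) are produced by refitting each
replicate on a bootstrap resample of the lines and evaluating the full
data under the refitted model.  Deterministic EM would give bit-identical
replicates at a well-supported K — a zero in exactly the denominator that
should be small — whereas bootstrap refits give the parameter-uncertainty
spread that replicate MCMC runs of an external structure program exhibit.
ΔK is undefined at the endpoints and wherever the replicate spread is
exactly zero.

Threshold assignment takes the argmax (ties unassigned), optionally
requiring the winning probability to reach t ∈ (0.5, 1].  Correspondence
between two labelings maximises the matched fraction over one-to-one
label matchings (Hungarian algorithm; injective for unequal label
counts); unassigned lines are excluded pairwise by default or counted as
mismatches on request.

## Marker resampling

Subset sizes default to 9…252 by 9.  Stratified subsets apportion the
size over linkage groups by largest remainder on marker counts, then
split each group's position-ordered markers into equal-count blocks and
draw one per block — every marker keeps the random-sampling inclusion
probability while locally correlated neighbours cannot be drawn together.
Top-PIC and top-between-group-MRD subsets are deterministic with
canonical-order tie-breaks.  Each repetition re-runs PCA on the subset
and re-clusters with K fixed to the full-panel subgroup count (the
experiment compares assignments, not K estimates), scoring against the
full-panel reference; the CV of MRD is computed per line pair across
repetitions and averaged over pairs.  Child seeds derive from
(seed, strategy, size, rep), so any cell reproduces in isolation.

The property-test scenario for the correspondence curve uses the default
design with 20 (not 100) generations of drift: under the full default
drift the two pools are separable from ~30 SNPs and the curve sits at
exactly 1.0 over half the size grid, where a rank correlation degenerates
into tie-handling noise; with milder drift the curve spans its range and
the monotone rise is measurable.  Problem sizes in the test suite (grid
to 126, 30 repetitions, 10 experiment replicates) are the package's
standing choices for property checks.

## LD and effective population size

r² is the squared Pearson correlation of per-line dosages over
pairwise-complete lines (inbreds are haplotypes; no phasing), pairs with
fewer than 3 informative lines or a monomorphic member dropped with a
count.  The significance threshold is the empirical 95 % quantile
(linear-interpolation convention, bit-reproducible) of r² among
different-linkage-group pairs.  The Hill–Weir drift-equilibrium
expectation with C = 4·Ne·r and sample size n decreases from
≈ 0.45 + O(1/n) at C = 0 to the 1/n sampling floor; Ne is fitted by
unweighted least squares over all linked pairs (not distance-binned
means) via bounded 1-D minimisation on log Ne (bounds 0.1–10⁶, tolerance
1e-10; bound-touching fits are flagged).  cM → r conversion defaults to
linear r = d/100 capped at 0.5, with Haldane available — the two differ
by <10 % inside the informative 0–10 cM range.  The decay distance solves
E(r²) = threshold by bisection to 1e-6 cM; thresholds above the intercept
give 0, thresholds at or below 1/n are flagged as never decaying.
Binned profiles use half-open [kw, (k+1)w) bins; genome windows anchor at
0 cM per group and count a pair only when both markers fall in the same
window.  Per-linkage-group fits inherit the global unlinked threshold and
require 10 linked pairs.

On combined two-population panels the unlinked background is inflated by
structure LD (markers on different chromosomes correlate through
subpopulation membership); under the generator's strong default
divergence this dominates the combined-set threshold and Ne — an honest
property of the statistic, visible in the acceptance output, and the
reason per-type analyses are the interpretable ones there.

## Pipeline

`run_pipeline` wires simulate → validate → diversity → structure →
resample → ld with per-stage output directories, named child seeds
derived by hashing (master seed, stage name) — adding stages never
perturbs existing streams — and a manifest of parameters, seeds and
checksums; reruns are bit-identical and single stages can be reproduced
in isolation.  The acceptance script runs the same computations on one
default-design panel with reduced resampling repetitions (grid to 126,
10 repetitions), the package's standing choice for a single-panel report.

## Known limitations

Biallelic SNPs only; no phasing, physical coordinates, D′ or
haplotype-block statistics; no admixture-model MCMC (the export format
for the external program is provided and its likelihood tables can be
post-processed); the Tracy–Widom table covers the four tabulated levels
only; mixture clustering rejects components smaller than d+1 points, so
genuinely tiny subgroups are invisible to it; and the generator's
idealisations listed above bound what synthetic-panel results say about
real germplasm.
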