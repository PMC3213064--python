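"""Population-structure analysis: ordination, eigenvalue significance,
model-based clustering and assignment scoring.

Three ordinations are offered: PCA on the (mean-imputed, column-centered)
dosage matrix; principal coordinate analysis (PCoA) on a modified Rogers
distance matrix; and Laplacian eigenfunctions ("lapvectors") of a
thresholded individual-by-individual correlation graph.  On complete data
PCA and PCoA-from-MRD are dual: PCoA coordinates equal PCA scores divided
by sqrt(m), so both report near-identical variance fractions.

Cluster membership comes from Gaussian-mixture EM over several covariance
families with BIC model selection (the MCLUST approach), and the number of
subgroups can also be judged from replicate log-likelihood tables via the
Evanno delta-K second-difference statistic.  The significance of leading
PCA eigenvalues is tested against the Tracy-Widom law using the
effective-marker moment estimator (eigenanalysis).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.exceptions import ConvergenceWarning
from sklearn.mixture import GaussianMixture

from .diversity import DistanceMatrix
from .panel import GenotypePanel, GroupLabels, UNASSIGNED

__all__ = [
    "OrdinationResult",
    "MembershipMatrix",
    "LikelihoodTable",
    "pca_components",
    "tw_significant_components",
    "pcoa_from_distance",
    "laplacian_components",
    "gmm_cluster",
    "likelihood_table",
    "evanno_delta_k",
    "threshold_assign",
    "assignment_correspondence",
    "TRACY_WIDOM_CRITICAL",
]

# Upper critical values of the Tracy-Widom (GOE) law, as tabulated in the
# eigenanalysis literature.
TRACY_WIDOM_CRITICAL = {0.10: 0.4501, 0.05: 0.9793, 0.01: 2.0234, 0.001: 3.2724}


@dataclass
class OrdinationResult:
    method: str  # "PCA" | "PCoA" | "LAP"
    line_ids: list
    coordinates: np.ndarray  # lines x components
    eigenvalues: np.ndarray  # all (positive) eigenvalues, descending for PCA/PCoA
    variance_explained: np.ndarray  # per returned component, fraction of total
    scale: str | None = None  # PCA normalisation used ("patterson" or None)
    negative_eigenvalues: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def n_components(self) -> int:
        return self.coordinates.shape[1]


@dataclass
class MembershipMatrix:
    """Posterior subgroup membership probabilities, one row per line."""

    line_ids: list
    probabilities: np.ndarray  # lines x K

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if self.probabilities.ndim != 2 or self.probabilities.shape[0] != len(self.line_ids):
            raise ValueError("probabilities shape does not match line count")
        if self.probabilities.shape[1] < 1:
            raise ValueError("need K >= 1")
        sums = self.probabilities.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-8):
            raise ValueError("membership rows must sum to 1")

    @property
    def K(self) -> int:
        return self.probabilities.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.probabilities,
            index=self.line_ids,
            columns=[f"G{k + 1}" for k in range(self.K)],
        )


# ---------------------------------------------------------------------------
# ordination

def _imputed_centered(panel: GenotypePanel, scale: str | None = None):
    """Mean-impute missing dosages per marker, column-center, optionally
    divide columns by sqrt(p(1-p)) (the eigenanalysis normalisation).
    Monomorphic markers are dropped under Patterson scaling."""
    X = panel.dosage.copy()
    mask = np.isnan(X)
    from .diversity import _freq

    mu = _freq(panel.dosage)
    mu = np.where(np.isnan(mu), 0.0, mu)
    X[mask] = np.broadcast_to(mu, X.shape)[mask]
    Xc = X - X.mean(axis=0)
    if scale == "patterson":
        p = X.mean(axis=0)
        sd = np.sqrt(p * (1.0 - p))
        keep = sd > 1e-12
        Xc = Xc[:, keep] / sd[keep]
    elif scale is not None:
        raise ValueError(f"unknown scale {scale!r}")
    return Xc


def pca_components(
    panel: GenotypePanel, n_components: int | None = None, scale: str | None = None
) -> OrdinationResult:
    """PCA of the genotype matrix (mean-imputed, column-centered).

    Coordinates are the component scores; ``variance_explained`` is each
    eigenvalue over the total variance, so it sums to 1 over all
    components.  ``scale="patterson"`` applies the sqrt(p(1-p)) column
    normalisation required by the Tracy-Widom eigenvalue test.
    """
    if panel.n_lines < 2 or panel.n_markers < 2:
        raise ValueError("need at least two lines and two markers")
    limit = min(panel.n_lines, panel.n_markers)
    if n_components is not None and n_components > limit:
        raise ValueError(f"n_components {n_components} exceeds min(lines, markers) = {limit}")
    Xc = _imputed_centered(panel, scale)
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    eig = s**2 / (panel.n_lines - 1)
    total = eig.sum()
    k = n_components if n_components is not None else min(panel.n_lines - 1, Xc.shape[1])
    k = min(k, len(s))
    scores = U[:, :k] * s[:k]
    with np.errstate(invalid="ignore", divide="ignore"):
        ve = eig[:k] / total if total > 0 else np.zeros(k)
    return OrdinationResult(
        method="PCA",
        line_ids=list(panel.line_ids),
        coordinates=scores,
        eigenvalues=eig,
        variance_explained=ve,
        scale=scale,
    )


def tw_significant_components(
    pca: OrdinationResult, n_lines: int, n_markers: int, alpha: float = 0.05
) -> int:
    """Count of PCA eigenvalues significant under the Tracy-Widom law.

    Successive leading eigenvalues of a Patterson-normalised PCA are
    standardised with the effective-marker moment estimator
    m_hat = (L+1) a^2 / ((L-1) b - a^2)  (a = sum of the remaining
    eigenvalues, b = sum of their squares, L their number) and compared against the
    tabulated TW critical value; testing stops at the first
    non-significant eigenvalue.
    """
    if n_lines < 3 or n_markers < 3:
        raise ValueError("need at least three lines and three markers")
    if alpha == 0:
        return 0
    if alpha not in TRACY_WIDOM_CRITICAL:
        raise ValueError(
            f"alpha must be one of {sorted(TRACY_WIDOM_CRITICAL)} (tabulated TW points)"
        )
    if pca.scale != "patterson":
        raise ValueError("Tracy-Widom test requires PCA computed with scale='patterson'")
    crit = TRACY_WIDOM_CRITICAL[alpha]
    lam = np.asarray(pca.eigenvalues, dtype=float)
    lam = lam[lam > 1e-12 * max(lam.max(), 1.0)]
    count = 0
    for j in range(len(lam) - 2):
        rem = lam[j:]
        L = len(rem)
        a, b = rem.sum(), (rem**2).sum()
        denom = (L - 1) * b - a**2
        if denom <= 0:
            break
        m_hat = (L + 1) * a**2 / denom
        if m_hat <= 1:
            break
        ell = L * rem[0] / a
        sm, sn = np.sqrt(m_hat - 1.0), np.sqrt(L)
        mu = (sm + sn) ** 2 / m_hat
        sigma = (sm + sn) / m_hat * (1.0 / sm + 1.0 / sn) ** (1.0 / 3.0)
        x = (ell - mu) / sigma
        if x > crit:
            count += 1
        else:
            break
    return count


def pcoa_from_distance(D: DistanceMatrix, n_components: int | None = None) -> OrdinationResult:
    """Principal coordinate analysis (classical MDS) of a distance matrix.

    Double-centers -D^2/2 and eigendecomposes; coordinates are eigenvectors
    scaled by sqrt(eigenvalue).  Negative eigenvalues (non-Euclidean input)
    are excluded from the variance-explained denominator and reported on
    the result.
    """
    V = np.asarray(D.values, dtype=float)
    if np.isnan(V).any():
        raise ValueError("distance matrix contains undefined entries")
    if not np.allclose(V, V.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    n = V.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (V**2) @ J
    eigval, eigvec = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = 1e-9 * max(abs(eigval).max(), 1.0)
    pos = eigval > tol
    neg = eigval[eigval < -tol]
    lam = eigval[pos]
    vec = eigvec[:, pos]
    k = n_components if n_components is not None else len(lam)
    k = min(k, len(lam))
    coords = vec[:, :k] * np.sqrt(lam[:k])
    total = lam.sum()
    ve = lam[:k] / total if total > 0 else np.zeros(k)
    if total == 0:  # degenerate: all points coincide
        coords = np.zeros((n, max(k, 1)))
        ve = np.zeros(max(k, 1))
        lam = np.zeros(max(k, 1))
    return OrdinationResult(
        method="PCoA",
        line_ids=list(D.line_ids),
        coordinates=coords,
        eigenvalues=lam,
        variance_explained=ve,
        negative_eigenvalues=neg,
    )


def laplacian_components(
    panel: GenotypePanel, eps: float = 0.8, n_components: int | None = None
) -> OrdinationResult:
    """Laplacian eigenfunctions of the thresholded correlation graph.

    Edge weights are the individual-by-individual Pearson correlations of
    centered dosage rows, kept when rho >= eps (one-sided), else zero; the
    unnormalised graph Laplacian L = Degree - W is eigendecomposed on the
    orthogonal complement of the constant vector, and the "lapvectors" for
    the smallest eigenvalues are returned.  Variance explained is the
    fraction of total (centered) dosage variance captured by projecting the
    genotype matrix onto each lapvector.
    """
    if not 0 < eps <= 1:
        raise ValueError("eps must lie in (0, 1]")
    Xc = _imputed_centered(panel)
    n = panel.n_lines
    rho = np.corrcoef(Xc)
    W = np.where(rho >= eps, rho, 0.0)
    np.fill_diagonal(W, 0.0)
    if not (W > 0).any():
        raise ValueError(f"no correlations reach eps={eps}; lower the threshold")
    L = np.diag(W.sum(axis=1)) - W

    # orthonormal basis of the complement of the constant vector
    A = np.eye(n)
    A[:, 0] = 1.0
    Q, _ = np.linalg.qr(A)
    Q1 = Q[:, 1:]
    eigval, eigvec = np.linalg.eigh(Q1.T @ L @ Q1)
    lapvecs = Q1 @ eigvec  # ascending eigenvalues, constant vector excluded

    k = n_components if n_components is not None else min(n - 1, panel.n_markers)
    k = min(k, lapvecs.shape[1])
    V = lapvecs[:, :k]
    total = (Xc**2).sum()
    ve = ((Xc.T @ V) ** 2).sum(axis=0) / total if total > 0 else np.zeros(k)
    return OrdinationResult(
        method="LAP",
        line_ids=list(panel.line_ids),
        coordinates=V,
        eigenvalues=np.clip(eigval, 0.0, None),
        variance_explained=ve,
    )


# ---------------------------------------------------------------------------
# Gaussian-mixture clustering

#: covariance families examined, nearest sklearn equivalents of the
#: MCLUST family ladder (spherical, shared full, diagonal, full)
DEFAULT_COVARIANCES = ("spherical", "tied", "diag", "full")


def _coords_and_ids(coordinates, line_ids):
    if isinstance(coordinates, OrdinationResult):
        return np.asarray(coordinates.coordinates, float), list(coordinates.line_ids)
    X = np.atleast_2d(np.asarray(coordinates, dtype=float))
    if line_ids is None:
        line_ids = [str(i) for i in range(X.shape[0])]
    return X, list(line_ids)


def _farthest_point_means(X: np.ndarray, k: int) -> np.ndarray:
    """Deterministic, order-independent seeding: start from the point
    closest to the centroid, then repeatedly add the point farthest from
    the chosen set (ties broken by coordinates, not input order)."""
    centroid = X.mean(axis=0)
    d0 = ((X - centroid) ** 2).sum(axis=1)
    chosen = [_argmin_stable(d0, X)]
    while len(chosen) < k:
        dmin = np.min(
            ((X[:, None, :] - X[chosen][None, :, :]) ** 2).sum(axis=2), axis=1
        )
        chosen.append(_argmin_stable(-dmin, X))
    return X[chosen]


def _argmin_stable(values: np.ndarray, X: np.ndarray) -> int:
    idx = np.nonzero(values == values.min())[0]
    if len(idx) == 1:
        return int(idx[0])
    return int(min(idx, key=lambda i: tuple(X[i])))  # order-independent tie-break


def _fit_gmm(X, k, cov, seed, restarts, reg):
    """Best-of-restarts EM fit: one deterministic farthest-point start plus
    seeded k-means++ restarts; returns the fit with the highest logL."""
    best = None
    candidates = []
    if k <= X.shape[0]:
        means = _farthest_point_means(X, k)
        candidates.append(
            GaussianMixture(
                n_components=k, covariance_type=cov, means_init=means,
                n_init=1, max_iter=500, tol=1e-8, reg_covar=reg,
                random_state=seed,
            )
        )
    if restarts > 1:
        candidates.append(
            GaussianMixture(
                n_components=k, covariance_type=cov, init_params="k-means++",
                n_init=restarts - 1, max_iter=500, tol=1e-8, reg_covar=reg,
                random_state=seed,
            )
        )
    for gm in candidates:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                gm.fit(X)
        except Exception:
            continue
        # reject degenerate solutions: a component supported by fewer than
        # d+1 points collapses onto the covariance floor and inflates logL
        n_eff = gm.weights_ * X.shape[0]
        if k > 1 and (n_eff < X.shape[1] + 1).any():
            continue
        ll = gm.score(X) * X.shape[0]
        if best is None or ll > best[0]:
            best = (ll, gm)
    return best


def gmm_cluster(
    coordinates,
    K_range=range(1, 16),
    seed=0,
    line_ids=None,
    covariance_types=DEFAULT_COVARIANCES,
    restarts: int = 10,
):
    """Gaussian-mixture clustering with BIC model selection.

    EM is run for every K in ``K_range`` and every covariance family;
    the model maximising BIC = 2 logL - nu log N is returned as
    ``(best_K, MembershipMatrix, per_K_bic)``.  Components are re-ordered
    by their means so labels are stable across input permutations.
    """
    X, ids = _coords_and_ids(coordinates, line_ids)
    K_range = list(K_range)
    if not K_range or min(K_range) < 1:
        raise ValueError("K_range must contain integers >= 1")
    if X.shape[0] <= max(K_range):
        raise ValueError("need more lines than the largest K")
    reg = max(1e-6 * float(np.var(X)), 1e-12)
    seed = int(seed) if not isinstance(seed, np.random.Generator) else int(
        seed.integers(2**31)
    )

    rows = []
    fits = {}
    for K in K_range:
        best_for_k = None
        for cov in covariance_types:
            res = _fit_gmm(X, K, cov, seed, restarts, reg)
            if res is None:
                continue
            ll, gm = res
            bic = 2.0 * ll - gm._n_parameters() * np.log(X.shape[0])
            if best_for_k is None or bic > best_for_k[0]:
                best_for_k = (bic, cov, gm)
        if best_for_k is None:
            warnings.warn(f"EM failed for all covariance families at K={K}; skipped")
            continue
        bic, cov, gm = best_for_k
        rows.append({"K": K, "covariance": cov, "bic": bic})
        fits[K] = gm
    if not fits:
        raise RuntimeError("EM failed for every K in K_range")

    bic_table = pd.DataFrame(rows).set_index("K")
    best_k = int(bic_table["bic"].idxmax())
    gm = fits[best_k]
    probs = gm.predict_proba(X)
    order = np.lexsort(gm.means_.T[::-1])  # stable component order by mean
    probs = probs[:, order]
    probs = probs / probs.sum(axis=1, keepdims=True)
    return best_k, MembershipMatrix(line_ids=ids, probabilities=probs), bic_table


# ---------------------------------------------------------------------------
# likelihood tables and delta-K

@dataclass
class LikelihoodTable:
    """Replicate log-likelihoods per candidate subgroup count K."""

    table: pd.DataFrame  # columns: K, replicate, logL

    def __post_init__(self) -> None:
        t = pd.DataFrame(self.table)
        if not {"K", "replicate", "logL"}.issubset(t.columns):
            raise ValueError("likelihood table needs columns K, replicate, logL")
        t = t[["K", "replicate", "logL"]].copy()
        t["K"] = t["K"].astype(int)
        t["logL"] = t["logL"].astype(float)
        self.table = t.reset_index(drop=True)

    @classmethod
    def from_tsv(cls, path) -> "LikelihoodTable":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def mean_by_k(self) -> pd.Series:
        return self.table.groupby("K")["logL"].mean()

    def sd_by_k(self) -> pd.Series:
        return self.table.groupby("K")["logL"].std(ddof=1)


def likelihood_table(
    coordinates,
    K_range=range(1, 6),
    replicates: int = 5,
    seed=0,
    covariance_type: str = "full",
) -> LikelihoodTable:
    """Replicate per-K log-likelihoods (stand-in for external MCMC runs).

    Deterministic EM collapses the replicate spread to zero at a
    well-supported K, which would leave the delta-K ratio undefined; each
    replicate therefore refits the mixture on a bootstrap resample of the
    lines (independently seeded k-means++ start) and reports the
    log-likelihood of the full data under the refitted model, so the
    replicate spread reflects parameter uncertainty the way replicate MCMC
    runs do.
    """
    X, _ = _coords_and_ids(coordinates, None)
    n = X.shape[0]
    ss = np.random.SeedSequence(seed if not isinstance(seed, np.random.Generator)
                                else int(seed.integers(2**31)))
    rng = np.random.default_rng(ss)
    reg = max(1e-6 * float(np.var(X)), 1e-12)
    rows = []
    for K in K_range:
        for rep in range(replicates):
            idx = rng.integers(n, size=n)
            gm = GaussianMixture(
                n_components=K, covariance_type=covariance_type,
                init_params="k-means++", n_init=1, max_iter=500, tol=1e-8,
                reg_covar=reg, random_state=int(rng.integers(2**31)),
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                gm.fit(X[idx])
            rows.append({"K": K, "replicate": rep, "logL": gm.score(X) * n})
    return LikelihoodTable(pd.DataFrame(rows))


def evanno_delta_k(table: LikelihoodTable) -> pd.Series:
    """Evanno's delta-K: |L(K+1) - 2 L(K) + L(K-1)| / sd(L(K)).

    Means and standard deviations are over replicates; endpoints are
    undefined (NaN), as are interior K with zero replicate spread.
    """
    means = table.mean_by_k().sort_index()
    sds = table.sd_by_k().sort_index()
    ks = means.index.to_numpy()
    if len(ks) < 3 or not np.all(np.diff(ks) == 1):
        raise ValueError("delta-K needs at least three consecutive K values")
    counts = table.table.groupby("K")["logL"].count()
    if (counts.loc[ks[1:-1]] < 2).any():
        raise ValueError("delta-K needs >= 2 replicates at interior K")
    out = pd.Series(np.nan, index=means.index, name="delta_K")
    for k in ks[1:-1]:
        sd = sds.loc[k]
        if not np.isfinite(sd) or sd == 0:
            warnings.warn(f"zero replicate spread at K={k}; delta-K undefined there")
            continue
        out.loc[k] = abs(means.loc[k + 1] - 2 * means.loc[k] + means.loc[k - 1]) / sd
    return out


# ---------------------------------------------------------------------------
# assignment

def threshold_assign(members: MembershipMatrix, rule="max") -> GroupLabels:
    """Assign lines to subgroups from membership probabilities.

    ``rule="max"`` takes the argmax (ties -> unassigned); a float rule t in
    (0.5, 1] additionally requires the winning probability to reach t.
    """
    if rule != "max":
        t = float(rule)
        if not 0.5 < t <= 1.0:
            raise ValueError("threshold must lie in (0.5, 1]")
    P = members.probabilities
    labels = []
    for row in P:
        top = row.max()
        winners = np.nonzero(row == top)[0]
        if len(winners) != 1:
            labels.append(UNASSIGNED)
            continue
        if rule != "max" and top < float(rule):
            labels.append(UNASSIGNED)
            continue
        labels.append(f"G{winners[0] + 1}")
    return GroupLabels(line_ids=list(members.line_ids), labels=labels)


def assignment_correspondence(
    a: GroupLabels, b: GroupLabels, unassigned: str = "exclude"
) -> float:
    """Best-bijection agreement between two labelings, in [0, 1].

    Maximises the matched fraction over one-to-one label matchings
    (injective when label counts differ) via the Hungarian algorithm, so
    the score is invariant to relabeling either argument.  Unassigned
    lines are excluded pairwise (``unassigned="exclude"``) or counted as
    mismatches (``unassigned="mismatch"``).
    """
    if set(a.line_ids) != set(b.line_ids):
        raise ValueError("labelings cover different line sets")
    sa = a.as_series()
    sb = b.as_series().reindex(sa.index)
    both = (sa != UNASSIGNED) & (sb != UNASSIGNED)
    if unassigned == "exclude":
        denom = int(both.sum())
    elif unassigned == "mismatch":
        denom = len(sa)
    else:
        raise ValueError("unassigned must be 'exclude' or 'mismatch'")
    if int(both.sum()) == 0:
        raise ValueError("no commonly assigned lines")
    ct = pd.crosstab(sa[both], sb[both])
    ri, ci = linear_sum_assignment(ct.to_numpy(), maximize=True)
    matched = int(ct.to_numpy()[ri, ci].sum())
    return matched / denom
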