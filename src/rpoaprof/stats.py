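"""Cohort statistics for species-level composition profiles.

Rank tests (Mann-Whitney U with an exact small-sample branch; Kruskal-Wallis
with Bonferroni-adjusted pairwise comparisons), Bray-Curtis dissimilarity,
principal coordinates analysis, PAM clustering with silhouette-based choice
of k, envfit-style vector fitting, PERMANOVA, and multivariable linear
diet/nutrient associations with Benjamini-Hochberg FDR control and the
q < 0.1 / 0.25 / 0.3 confidence tiers.

Every permutation procedure takes an explicit seed and permutation count and
is reproducible bit-exact; permutation p-values use the add-one estimator
p = (1 + #{permuted statistic >= observed}) / (n_perm + 1).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.spatial.distance as ssd
import scipy.stats as sps
import statsmodels.formula.api as smf
from sklearn.metrics import silhouette_score
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "Ordination",
    "VectorFit",
    "AssociationResult",
    "ClusterSolution",
    "mann_whitney_u",
    "kruskal_wallis",
    "pairwise_bonferroni",
    "bray_curtis",
    "pcoa",
    "pam_with_silhouette",
    "envfit_vectors",
    "permanova",
    "bh_fdr",
    "fit_associations",
    "confidence_tier",
]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    group_labels: tuple = ()
    n_per_group: tuple = ()
    adjusted_p: float | None = None


@dataclass(frozen=True)
class Ordination:
    """PCoA embedding: axes ordered by non-increasing eigenvalue; coordinates
    exist only for positive eigenvalues; percent variance is taken over the
    positive eigenvalues (negative ones are reported, not corrected)."""

    coordinates: np.ndarray  # samples x positive axes
    eigenvalues: np.ndarray  # all eigenvalues, descending
    pct_variance: np.ndarray  # per positive axis, sums to <= 100


@dataclass(frozen=True)
class VectorFit:
    variable: str
    direction: tuple[float, float]
    r2: float
    p_value: float


@dataclass(frozen=True)
class ClusterSolution:
    k: int
    medoids: np.ndarray
    assignments: np.ndarray
    avg_silhouette: float
    #: average silhouette width for every k scanned
    silhouette_by_k: dict[int, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Rank tests


def _u_counts(n1: int, n2: int) -> np.ndarray:
    """Null distribution counts of the Mann-Whitney U statistic.

    c[u] = number of the C(n1+n2, n1) group assignments with U == u, via the
    standard recurrence c(n1, n2, u) = c(n1-1, n2, u-n2) + c(n1, n2-1, u)
    (the Gaussian binomial coefficient's q-expansion).
    """
    prev_row = None
    for i in range(n1 + 1):
        row: list[np.ndarray] = []
        for j in range(n2 + 1):
            c = np.zeros(i * j + 1, dtype=float)
            if i == 0 or j == 0:
                c[0] = 1.0
            else:
                c[: i * (j - 1) + 1] += row[j - 1]
                c[j:] += prev_row[j][: i * j - j + 1]
            row.append(c)
        prev_row = row
    return prev_row[n2]


def _exact_u_cdf(u_obs: int, n1: int, n2: int) -> float:
    """P(U <= u_obs) under the exact no-ties null."""
    counts = _u_counts(n1, n2)
    total = comb(n1 + n2, n1)
    return float(counts[: u_obs + 1].sum() / total)


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float], exact_limit: int = 16
) -> TestResult:
    """Two-sided Mann-Whitney U test.

    Uses exact enumeration of the U null distribution when the pooled sample
    size is at most ``exact_limit`` and there are no ties; otherwise the
    normal approximation with tie and continuity corrections (scipy).
    The reported statistic is U for the first sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < n1 + n2
    ranks = sps.rankdata(pooled)
    u1 = float(np.sum(ranks[:n1]) - n1 * (n1 + 1) / 2)
    if n1 + n2 <= exact_limit and not has_ties:
        lo = _exact_u_cdf(int(round(u1)), n1, n2)
        hi = 1.0 - (_exact_u_cdf(int(round(u1)) - 1, n1, n2) if u1 >= 1 else 0.0)
        p = min(1.0, 2.0 * min(lo, hi))
        method = "mann-whitney-exact"
    else:
        p = float(
            sps.mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic", use_continuity=True
            ).pvalue
        )
        method = "mann-whitney-asymptotic"
    return TestResult(
        statistic=u1, p_value=p, method=method, n_per_group=(n1, n2)
    )


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Kruskal-Wallis H test (tie-corrected, chi-square on k-1 df).

    With fewer than three groups the comparison is routed to the
    Mann-Whitney U test.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(g.size == 0 for g in groups):
        raise ValueError("every group must be non-empty")
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if len(groups) == 2:
        return mann_whitney_u(groups[0], groups[1])
    if all(np.array_equal(g, groups[0]) for g in groups[1:]) and np.all(
        groups[0] == groups[0][0]
    ):
        # all observations identical: H = 0, p = 1 (scipy raises on this)
        return TestResult(0.0, 1.0, "kruskal-wallis",
                          n_per_group=tuple(len(g) for g in groups))
    h, p = sps.kruskal(*groups)
    return TestResult(
        statistic=float(h),
        p_value=float(p),
        method="kruskal-wallis",
        n_per_group=tuple(len(g) for g in groups),
    )


def pairwise_bonferroni(
    groups: Sequence[Sequence[float]], labels: Sequence[str] | None = None
) -> list[TestResult]:
    """All pairwise Mann-Whitney comparisons with Bonferroni adjustment
    over the C(k,2) comparisons (adjusted p = min(1, p * m))."""
    k = len(groups)
    if labels is None:
        labels = [f"group{i + 1}" for i in range(k)]
    m = comb(k, 2)
    out = []
    for i, j in itertools.combinations(range(k), 2):
        base = mann_whitney_u(groups[i], groups[j])
        out.append(
            TestResult(
                statistic=base.statistic,
                p_value=base.p_value,
                method=base.method,
                group_labels=(labels[i], labels[j]),
                n_per_group=base.n_per_group,
                adjusted_p=min(1.0, base.p_value * m),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Bray-Curtis / PCoA


def bray_curtis(abundances: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Bray-Curtis dissimilarity matrix d(x,y) = sum|x-y| / sum(x+y).

    Rows are samples.  A pair of all-zero vectors has distance 0 (with a
    warning); values lie in [0, 1] for non-negative data.
    """
    a = np.asarray(abundances, dtype=float)
    if np.any(a < 0):
        raise ValueError("abundances must be non-negative")
    with np.errstate(invalid="ignore"):
        d = ssd.squareform(ssd.pdist(a, metric="braycurtis"))
    if np.any(np.isnan(d)):
        warnings.warn("all-zero sample pair(s): distance defined as 0")
        d = np.nan_to_num(d, nan=0.0)
    return d


def pcoa(dist: np.ndarray) -> Ordination:
    """Principal coordinates analysis (Gower double-centering).

    Coordinates are eigenvectors scaled by the square root of the positive
    eigenvalues; negative eigenvalues are reported unchanged.  Axis signs
    follow a deterministic convention: the largest-magnitude loading on each
    axis is positive.
    """
    d = np.asarray(dist, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    n = d.shape[0]
    a = -0.5 * d**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = j @ a @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > np.max(np.abs(evals)) * 1e-12 if evals.size else evals > 0
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    # deterministic sign convention
    for k in range(coords.shape[1]):
        i = np.argmax(np.abs(coords[:, k]))
        if coords[i, k] < 0:
            coords[:, k] = -coords[:, k]
    pct = 100.0 * evals[pos] / evals[pos].sum() if pos.any() else np.array([])
    return Ordination(coordinates=coords, eigenvalues=evals, pct_variance=pct)


# ---------------------------------------------------------------------------
# PAM + silhouette


def _pam_build(d: np.ndarray, k: int) -> list[int]:
    n = d.shape[0]
    medoids = [int(np.argmin(d.sum(axis=1)))]
    while len(medoids) < k:
        nearest = d[:, medoids].min(axis=1)
        best_gain, best_c = -np.inf, -1
        for c in range(n):
            if c in medoids:
                continue
            gain = np.maximum(nearest - d[:, c], 0.0).sum()
            if gain > best_gain + 1e-12:
                best_gain, best_c = gain, c
        medoids.append(best_c)
    return medoids


def _pam_swap(d: np.ndarray, medoids: list[int]) -> list[int]:
    n = d.shape[0]
    medoids = list(medoids)
    while True:
        cost = d[:, medoids].min(axis=1).sum()
        best = (0.0, None)
        for mi, m in enumerate(medoids):
            for h in range(n):
                if h in medoids:
                    continue
                trial = medoids.copy()
                trial[mi] = h
                delta = d[:, trial].min(axis=1).sum() - cost
                if delta < best[0] - 1e-12:
                    best = (delta, (mi, h))
        if best[1] is None:
            return medoids
        mi, h = best[1]
        medoids[mi] = h


def pam_with_silhouette(
    dist: np.ndarray, k_range: Sequence[int] = range(2, 9)
) -> ClusterSolution:
    """Classic PAM (BUILD + steepest-descent SWAP) for each k, returning the
    solution with the highest average silhouette width (ties -> smaller k).

    Fully deterministic: BUILD is greedy, SWAP applies the best improving
    swap, ties broken by lowest index.  Raises on degenerate input (fewer
    than three points, or all points identical).
    """
    d = np.asarray(dist, dtype=float)
    n = d.shape[0]
    if n < 3:
        raise ValueError("need at least three samples to cluster")
    if np.allclose(d, 0):
        raise ValueError("all points identical: silhouette undefined")
    best: ClusterSolution | None = None
    sil_by_k: dict[int, float] = {}
    for k in sorted(set(k_range)):
        if not 2 <= k <= n - 1:
            raise ValueError(f"k={k} outside [2, n-1]")
        medoids = _pam_swap(d, _pam_build(d, k))
        assign = np.argmin(d[:, medoids], axis=1)
        if len(np.unique(assign)) < 2:
            continue
        sil = float(silhouette_score(d, assign, metric="precomputed"))
        sil_by_k[k] = sil
        if best is None or sil > best.avg_silhouette + 1e-12:
            best = ClusterSolution(
                k=k,
                medoids=np.asarray(medoids),
                assignments=assign,
                avg_silhouette=sil,
            )
    if best is None:
        raise ValueError("no valid clustering found in k_range")
    return ClusterSolution(
        best.k, best.medoids, best.assignments, best.avg_silhouette, sil_by_k
    )


# ---------------------------------------------------------------------------
# envfit / PERMANOVA


def envfit_vectors(
    ordination: Ordination,
    variables: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
) -> list[VectorFit]:
    """Fit external variables as vectors onto the first two ordination axes.

    R^2 is the fraction of a (centred) variable's variance explained by
    least-squares regression on the two axes; significance comes from
    permuting the variable's values (seeded).  Constant variables get
    R^2 = 0, p = 1.
    """
    if n_perm < 99:
        raise ValueError("use at least 99 permutations")
    x = ordination.coordinates[:, :2]
    n = x.shape[0]
    xc = x - x.mean(axis=0)
    q, _ = np.linalg.qr(xc)
    rng = np.random.default_rng(seed)
    out = []
    for name in variables.columns:
        v = variables[name].to_numpy(dtype=float)
        vc = v - v.mean()
        ss = float(vc @ vc)
        if ss < 1e-30:
            out.append(VectorFit(name, (0.0, 0.0), 0.0, 1.0))
            continue
        proj = q.T @ vc
        r2 = float(proj @ proj) / ss
        beta, *_ = np.linalg.lstsq(xc, vc, rcond=None)
        norm = np.linalg.norm(beta)
        direction = tuple(beta / norm) if norm > 0 else (0.0, 0.0)
        perms = np.stack([rng.permutation(n) for _ in range(n_perm)])
        vperm = vc[perms]  # (n_perm, n), already centred
        proj_p = vperm @ q  # (n_perm, 2)
        r2_p = np.einsum("ij,ij->i", proj_p, proj_p) / ss
        p = (1 + int(np.sum(r2_p >= r2 - 1e-12))) / (n_perm + 1)
        out.append(VectorFit(name, direction, r2, p))
    return out


def _pseudo_f(d2: np.ndarray, groups: np.ndarray) -> float:
    """Anderson's PERMANOVA pseudo-F from squared distances and labels."""
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    labels = np.unique(groups)
    for g in labels:
        idx = np.flatnonzero(groups == g)
        if idx.size > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(idx.size, 1)].sum() / idx.size
    a = labels.size
    ss_among = ss_total - ss_within
    return (ss_among / (a - 1)) / (ss_within / (n - a))


def permanova(
    dist: np.ndarray,
    grouping: Sequence,
    n_perm: int = 999,
    seed: int = 0,
) -> TestResult:
    """Permutational multivariate ANOVA on a distance matrix.

    Pseudo-F follows the total/within sum-of-squared-distances partition;
    the p-value permutes group labels with a seeded generator.
    """
    d = np.asarray(dist, dtype=float)
    groups = np.asarray(grouping)
    labels, counts = np.unique(groups, return_counts=True)
    if labels.size < 2:
        raise ValueError("need at least two groups")
    if np.any(counts < 2):
        raise ValueError("every group needs at least two members")
    if n_perm < 99:
        raise ValueError("use at least 99 permutations")
    d2 = d**2
    f_obs = _pseudo_f(d2, groups)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        f_p = _pseudo_f(d2, rng.permutation(groups))
        if f_p >= f_obs - 1e-12:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return TestResult(
        statistic=f_obs,
        p_value=p,
        method="permanova",
        group_labels=tuple(labels.tolist()),
        n_per_group=tuple(int(c) for c in counts),
    )


# ---------------------------------------------------------------------------
# Associations (multivariable linear model, BH FDR)


def bh_fdr(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    return multipletests(np.asarray(pvals, dtype=float), method="fdr_bh")[1]


def confidence_tier(q: float) -> str:
    """Confidence tier by FDR q-value: <0.1 high, <0.25 moderate,
    <0.3 exploratory, otherwise ns."""
    if q < 0.1:
        return "high"
    if q < 0.25:
        return "moderate"
    if q < 0.3:
        return "exploratory"
    return "ns"


@dataclass(frozen=True)
class AssociationResult:
    feature: str
    exposure: str
    coef: float
    p_value: float
    q_value: float
    tier: str


def fit_associations(
    profiles: pd.DataFrame,
    cohort: pd.DataFrame,
    exposures: Sequence[str],
    covariates: Sequence[str] = ("BMI", "age", "sex"),
    features: Sequence[str] | None = None,
    min_median: float = 0.01,
    min_prevalence: float = 0.10,
    detection_relab: float = 0.005,
) -> list[AssociationResult]:
    """Multivariable linear associations between label abundances and
    exposures, adjusted for covariates, with BH FDR across all tests.

    Features default to the non-minor labels (median >= ``min_median`` and
    prevalence >= ``min_prevalence`` at the detection threshold).  Each
    feature is total-sum-scaled relative abundance with a half-minimum
    pseudocount and log2 transform; one OLS fit per feature x exposure with
    the exposure plus all covariates; the exposure coefficient's t-test p is
    BH-adjusted across every test, then mapped to confidence tiers.
    Exposures collinear with the covariates are dropped with a warning.
    """
    common = profiles.index.intersection(cohort.index)
    if len(common) == 0:
        raise ValueError("no overlapping samples between profiles and cohort")
    prof = profiles.loc[common]
    meta = cohort.loc[common]

    if features is None:
        median = prof.median()
        prevalence = (prof >= detection_relab).mean()
        features = [
            c for c in prof.columns
            if median[c] >= min_median and prevalence[c] >= min_prevalence
        ]
    if not features:
        raise ValueError("no non-minor features to test")

    rows: list[tuple[str, str, float, float]] = []
    for exposure in exposures:
        design = meta[[exposure, *covariates]].copy()
        # collinearity guard: exposure must have residual variance given covariates
        num_cov = [
            c for c in covariates if np.issubdtype(design[c].dtype, np.number)
        ]
        expo = design[exposure].to_numpy(dtype=float)
        if num_cov:
            cm = np.column_stack(
                [np.ones(len(design))]
                + [design[c].to_numpy(dtype=float) for c in num_cov]
            )
            beta, *_ = np.linalg.lstsq(cm, expo, rcond=None)
            resid = expo - cm @ beta
        else:
            resid = expo - expo.mean()
        if float(resid @ resid) < 1e-10 * max(1.0, float(expo @ expo)):
            warnings.warn(f"exposure {exposure!r} collinear with covariates; dropped")
            continue
        for feat in features:
            y = prof[feat].to_numpy(dtype=float)
            nonzero = y[y > 0]
            pseudo = nonzero.min() / 2 if nonzero.size else 1e-6
            data = design.copy()
            data["__y"] = np.log2(y + pseudo)
            data = data.rename(columns={exposure: "__x"})
            formula = "__y ~ __x + " + " + ".join(
                f"C({c})" if not np.issubdtype(meta[c].dtype, np.number) else c
                for c in covariates
            ) if covariates else "__y ~ __x"
            fit = smf.ols(formula, data=data).fit()
            rows.append(
                (feat, exposure, float(fit.params["__x"]), float(fit.pvalues["__x"]))
            )
    if not rows:
        return []
    qvals = bh_fdr([r[3] for r in rows])
    return [
        AssociationResult(f, e, c, p, float(q), confidence_tier(float(q)))
        for (f, e, c, p), q in zip(rows, qvals)
    ]
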