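"""Chemodiversity and multivariate dispersion/composition statistics.

Hill-number (q=1) effective diversity, Manhattan/Jaccard distance
matrices, principal-coordinate dispersion around group centers with its
homogeneity ANOVA, and PERMANOVA with exact enumeration for small
designs - the distance machinery is implemented from first principles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform


# ---------------------------------------------------------------------------
# Diversity
# ---------------------------------------------------------------------------

def shannon_effective(abundances) -> float:
    """Hill number of order 1: exp of Shannon entropy, zeros dropped."""
    a = np.asarray(abundances, dtype=float)
    if np.any(a < 0):
        raise ValueError("abundances must be non-negative")
    a = a[a > 0]
    if a.size == 0:
        raise ValueError("all-zero abundance vector has undefined diversity")
    p = a / a.sum()
    return float(np.exp(-(p * np.log(p)).sum()))


LEVELS = ("individual-month", "plot", "subsite", "site")


@dataclass
class DiversityTable:
    level: str
    per_sample: pd.Series           # sample id -> effective number
    groups: pd.DataFrame            # group id -> mean, n, se
    anova_F: float | None
    anova_df: tuple | None
    anova_p: float | None
    skipped: str | None = None


def diversity_by_level(table_abundance: pd.DataFrame, metadata: pd.DataFrame,
                       level: str) -> DiversityTable:
    """Per-sample effective numbers aggregated to a spatial level.

    Diversity is computed per individual-per-month row, then averaged per
    group at the requested level; a one-way ANOVA tests group differences.
    """
    if level not in LEVELS:
        raise ValueError(f"level must be one of {LEVELS}")
    per_sample = table_abundance.apply(
        lambda row: shannon_effective(row.to_numpy()), axis=1)
    meta = metadata.loc[per_sample.index]
    if level == "individual-month":
        group_of = meta["individual"]
    else:
        group_of = meta[level]
    grouped = per_sample.groupby(group_of)
    groups = pd.DataFrame({
        "mean": grouped.mean(),
        "n": grouped.size(),
        "se": grouped.std(ddof=1) / np.sqrt(grouped.size()),
    })
    if groups.shape[0] < 2:
        return DiversityTable(level, per_sample, groups, None, None, None,
                              skipped="single group at this level")
    samples = [v.to_numpy() for _, v in grouped]
    with np.errstate(invalid="ignore", divide="ignore"):
        F, p = stats.f_oneway(*samples)
    if np.isnan(F):  # zero variance everywhere
        F, p = 0.0, 1.0
    df = (groups.shape[0] - 1, len(per_sample) - groups.shape[0])
    return DiversityTable(level, per_sample, groups, float(F), df, float(p))


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    ids: list
    values: np.ndarray
    metric: str
    flagged_empty: list = field(default_factory=list)

    def __post_init__(self) -> None:
        v = self.values
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(v < 0):
            raise ValueError("distances must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def manhattan_distances(table: pd.DataFrame) -> DistanceMatrix:
    """d(i, j) = sum_f |x_if - x_jf| over samples (rows)."""
    if table.isna().to_numpy().any():
        raise ValueError("missing values not allowed")
    d = squareform(pdist(table.to_numpy(dtype=float), metric="cityblock"))
    return DistanceMatrix(ids=list(table.index), values=d, metric="manhattan")


def jaccard_distances(counts: pd.DataFrame) -> DistanceMatrix:
    """Presence/absence Jaccard distance 1 - |A&B| / |A|B|.

    A pair of empty communities gets distance 0 and both rows are flagged.
    """
    X = (counts.to_numpy(dtype=float) > 0)
    n = X.shape[0]
    d = np.zeros((n, n))
    empty = ~X.any(axis=1)
    for i in range(n):
        for j in range(i + 1, n):
            union = np.logical_or(X[i], X[j]).sum()
            if union == 0:
                dij = 0.0
            else:
                inter = np.logical_and(X[i], X[j]).sum()
                dij = 1.0 - inter / union
            d[i, j] = d[j, i] = dij
    return DistanceMatrix(ids=list(counts.index), values=d, metric="jaccard",
                          flagged_empty=list(np.asarray(counts.index)[empty]))


# ---------------------------------------------------------------------------
# Dispersion (betadisper)
# ---------------------------------------------------------------------------

@dataclass
class DispersionResult:
    groups: pd.Series               # sample id -> group label
    distances: pd.Series            # sample id -> distance to own group center
    group_means: pd.Series
    F: float | None
    df: tuple | None
    p: float | None
    center: str = "centroid"
    flagged_singletons: list = field(default_factory=list)


def _pcoa(dist: DistanceMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Principal-coordinate embedding keeping negative-eigenvalue axes.

    Returns (real coordinates, imaginary-axis coordinates): Gower
    double-centering of -D^2/2 followed by an eigendecomposition;
    axes with negative eigenvalues are embedded with |lambda|.
    """
    D = dist.values
    n = D.shape[0]
    A = -0.5 * D ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    G = J @ A @ J
    G = (G + G.T) / 2
    evals, evecs = np.linalg.eigh(G)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(1e-10, 1e-8 * np.abs(evals).max()) if evals.size else 0.0
    pos = evals > tol
    neg = evals < -tol
    real = evecs[:, pos] * np.sqrt(evals[pos])
    imag = evecs[:, neg] * np.sqrt(-evals[neg])
    return real, imag


def dispersion(dist: DistanceMatrix, groups, center: str = "centroid") -> DispersionResult:
    """Distance of each sample to its group center in PCoA space.

    Squared real-axis distance minus squared imaginary-axis distance,
    floored at zero before the square root (Anderson's correction), then
    a one-way ANOVA across groups on the per-sample distances.
    """
    groups = pd.Series(groups, index=dist.ids) if not isinstance(groups, pd.Series) \
        else groups.loc[dist.ids]
    real, imag = _pcoa(dist)
    dists = np.zeros(len(dist.ids))
    singletons = []
    for g in groups.unique():
        mask = (groups == g).to_numpy()
        if mask.sum() == 1:
            singletons.append(g)
            dists[mask] = 0.0
            continue
        if center == "centroid":
            c_real = real[mask].mean(axis=0)
            c_imag = imag[mask].mean(axis=0) if imag.size else np.zeros(0)
        elif center == "median":
            c_real = _spatial_median(real[mask])
            c_imag = _spatial_median(imag[mask]) if imag.size else np.zeros(0)
        else:
            raise ValueError("center must be 'centroid' or 'median'")
        d2_real = ((real[mask] - c_real) ** 2).sum(axis=1)
        d2_imag = ((imag[mask] - c_imag) ** 2).sum(axis=1) if imag.size else 0.0
        dists[mask] = np.sqrt(np.maximum(d2_real - d2_imag, 0.0))
    distances = pd.Series(dists, index=dist.ids)
    group_means = distances.groupby(groups).mean()
    n_groups = groups.nunique()
    if n_groups < 2:
        return DispersionResult(groups, distances, group_means, None, None, None,
                                center=center, flagged_singletons=singletons)
    samples = [distances[groups == g].to_numpy() for g in groups.unique()]
    with np.errstate(invalid="ignore", divide="ignore"):
        F, p = stats.f_oneway(*samples)
    if np.isnan(F):  # zero variance everywhere
        F, p = 0.0, 1.0
    df = (n_groups - 1, len(distances) - n_groups)
    return DispersionResult(groups, distances, group_means, float(F), df, float(p),
                            center=center, flagged_singletons=singletons)


def _spatial_median(X: np.ndarray, n_iter: int = 200, tol: float = 1e-10) -> np.ndarray:
    """Weiszfeld iteration for the geometric median."""
    c = X.mean(axis=0)
    for _ in range(n_iter):
        d = np.linalg.norm(X - c, axis=1)
        d = np.where(d < 1e-12, 1e-12, d)
        w = 1.0 / d
        c_new = (X * w[:, None]).sum(axis=0) / w.sum()
        if np.linalg.norm(c_new - c) < tol:
            return c_new
        c = c_new
    return c


def dispersion_gate(dispersion_p: float, alpha: float = 0.05) -> bool:
    """True when composition testing may proceed (dispersion homogeneous).

    Non-strict at the boundary: p == alpha proceeds.
    """
    return dispersion_p >= alpha


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

@dataclass
class PermanovaResult:
    pseudo_F: float
    R2: float
    p: float
    n_permutations: int
    seed: int | None
    complete_enumeration: bool


def _pseudo_F_terms(D2: np.ndarray, labels: np.ndarray, uniq: np.ndarray) -> tuple:
    # D2 is symmetric with zero diagonal: sum of upper triangle = sum/2
    n = D2.shape[0]
    ss_total = D2.sum() / (2 * n)
    ss_within = 0.0
    for g in uniq:
        idx = np.where(labels == g)[0]
        ss_within += D2[np.ix_(idx, idx)].sum() / (2 * len(idx))
    ss_between = ss_total - ss_within
    return ss_total, ss_within, ss_between


def permanova(dist: DistanceMatrix, groups, n_perm: int = 9999,
              seed: int | None = 0, enumeration_limit: int = 10 ** 5) -> PermanovaResult:
    """Anderson's pseudo-F with a label-permutation p-value.

    Complete enumeration of distinct relabelings is used automatically
    when their count is at most ``enumeration_limit``; otherwise
    ``n_perm`` seeded random permutations with the (1 + B>=obs)/(1 + B)
    estimator.
    """
    groups = pd.Series(groups, index=dist.ids) if not isinstance(groups, pd.Series) \
        else groups.loc[dist.ids]
    labels, uniq = groups.to_numpy(), groups.unique()
    g = len(uniq)
    if g < 2:
        raise ValueError("PERMANOVA requires at least 2 groups")
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    n = len(labels)
    D2 = dist.values ** 2

    def f_of(lbl: np.ndarray) -> float:
        _, ssw, ssb = _pseudo_F_terms(D2, lbl, uniq)
        denom = ssw / (n - g)
        if denom <= 0:
            return 0.0 if ssb <= 1e-12 else np.inf
        return (ssb / (g - 1)) / denom

    ss_total, ss_within, ss_between = _pseudo_F_terms(D2, labels, uniq)
    F_obs = f_of(labels)
    R2 = ss_between / ss_total if ss_total > 0 else 0.0

    counts = groups.value_counts()
    n_distinct = math.factorial(n)
    for c in counts:
        n_distinct //= math.factorial(c)

    if n_distinct <= enumeration_limit:
        from sympy.utilities.iterables import multiset_permutations
        ge = 0
        total = 0
        for perm in multiset_permutations(list(labels)):
            total += 1
            if f_of(np.asarray(perm)) >= F_obs - 1e-12:
                ge += 1
        p = ge / total
        return PermanovaResult(pseudo_F=F_obs, R2=float(R2), p=float(p),
                               n_permutations=total, seed=None,
                               complete_enumeration=True)
    rng = np.random.default_rng(seed)
    ge = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        if f_of(perm) >= F_obs - 1e-12:
            ge += 1
    p = (1 + ge) / (1 + n_perm)
    return PermanovaResult(pseudo_F=F_obs, R2=float(R2), p=float(p),
                           n_permutations=n_perm, seed=seed,
                           complete_enumeration=False)


# ---------------------------------------------------------------------------
# Gradient model and parasitoid success
# ---------------------------------------------------------------------------

def fit_gradient_model(response, predictors: pd.DataFrame):
    """OLS with intercept plus pairwise Pearson correlations for reporting.

    Returns (results dict, correlation DataFrame). Perfectly collinear
    predictor pairs raise with the offending pair named.
    """
    import statsmodels.api as sm

    y = np.asarray(response, dtype=float)
    X = predictors.astype(float)
    if len(y) <= X.shape[1] + 1:
        raise ValueError("need n > number of predictors + 1")
    cols = list(X.columns)
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            r = np.corrcoef(X[cols[i]], X[cols[j]])[0, 1]
            if abs(r) > 1 - 1e-10:
                raise ValueError(f"collinear predictors: {cols[i]} and {cols[j]}")
    fit = sm.OLS(y, sm.add_constant(X)).fit()
    corr = pd.concat([X, pd.Series(y, index=X.index, name="response")], axis=1).corr()
    results = {
        "coefficients": dict(fit.params),
        "p_values": dict(fit.pvalues),
        "r_squared": float(fit.rsquared),
        "f_pvalue": float(fit.f_pvalue),
        "n": int(fit.nobs),
    }
    return results, corr


def parasitoid_success(outcomes: pd.DataFrame) -> pd.Series:
    """Per-plot fraction parasitoid / (adult + parasitoid); died excluded.

    Plots where nothing survived rearing get NaN.
    """
    bad = set(outcomes["outcome"]) - {"adult", "parasitoid", "died"}
    if bad:
        raise ValueError(f"unknown rearing outcomes: {sorted(bad)}")
    surv = outcomes[outcomes["outcome"].isin(["adult", "parasitoid"])]
    denom = surv.groupby("plot").size()
    num = surv[surv["outcome"] == "parasitoid"].groupby("plot").size()
    frac = num.reindex(denom.index, fill_value=0) / denom
    all_plots = outcomes["plot"].unique()
    return frac.reindex(all_plots)
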