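"""Unsigned weighted correlation networks over features.

Soft-threshold power selection by scale-free fit, topological overlap,
average-linkage module detection with a static tree cut, first-PC module
eigenvalues with kME hub scores, and eigenvalue-correlation merging.
The whole stage is deterministic: no random initialization anywhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

# conventional size-ordered module palette; grey = unassigned
MODULE_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "midnightblue",
    "lightcyan", "grey60", "lightgreen", "lightyellow", "royalblue",
]
GREY = "grey"


@dataclass
class NetworkConfig:
    candidate_powers: tuple = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 12, 14, 16, 18, 20)
    power: int = 8
    min_module_size: int = 5
    merge_height: float = 0.25
    cut_height: float | None = None   # None => largest-gap automatic cut
    cut_quantile: float | None = None

    def __post_init__(self) -> None:
        if self.power < 1:
            raise ValueError("power must be >= 1")
        if not 0 < self.merge_height < 1:
            raise ValueError("merge height must lie in (0, 1)")
        if self.min_module_size < 2:
            raise ValueError("min module size must be >= 2")


def _correlation(X: pd.DataFrame) -> tuple[np.ndarray, list]:
    """|cor| over mean-centered columns; constant columns are excluded."""
    sd = X.std(axis=0, ddof=1)
    dropped = list(sd.index[sd <= 0])
    if dropped:
        warnings.warn(f"excluding {len(dropped)} constant feature(s) from the network")
        X = X.loc[:, sd > 0]
    cor = np.corrcoef(X.to_numpy(dtype=float), rowvar=False)
    return cor, [c for c in X.columns], dropped


def adjacency(X: pd.DataFrame, power: int) -> pd.DataFrame:
    cor, cols, _ = _correlation(X)
    a = np.abs(cor) ** power
    np.fill_diagonal(a, 0.0)
    return pd.DataFrame(a, index=cols, columns=cols)


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Signed R^2 of log10 p(k) ~ log10 k over connectivity bins.

    Returns (fit index, slope); index = -sign(slope) * R^2 so a
    power-law-like declining degree distribution scores positively.
    """
    k = np.asarray(k, dtype=float)
    k = k[k > 0]
    if k.size < 2:
        return 0.0, 0.0
    edges = np.linspace(k.min(), k.max() * (1 + 1e-9), n_bins + 1)
    which = np.digitize(k, edges) - 1
    xs, ys = [], []
    for b in range(n_bins):
        mask = which == b
        if mask.sum() == 0:
            continue
        xs.append(np.log10(k[mask].mean()))
        ys.append(np.log10(mask.mean()))
    if len(xs) < 3:
        return 0.0, 0.0
    xs, ys = np.asarray(xs), np.asarray(ys)
    slope, intercept = np.polyfit(xs, ys, 1)
    pred = slope * xs + intercept
    ss_res = ((ys - pred) ** 2).sum()
    ss_tot = ((ys - ys.mean()) ** 2).sum()
    r2 = 1 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return float(-np.sign(slope) * r2), float(slope)


def pick_soft_power(X: pd.DataFrame, candidate_powers=None) -> tuple[int, pd.DataFrame]:
    """Power maximizing the scale-free topology index (ties -> smallest)."""
    if candidate_powers is None:
        candidate_powers = NetworkConfig().candidate_powers
    if X.shape[1] < 3:
        raise ValueError("need at least 3 features")
    Xc = X - X.mean(axis=0)
    cor, cols, _ = _correlation(Xc)
    acor = np.abs(cor)
    np.fill_diagonal(acor, 0.0)
    rows = []
    for beta in candidate_powers:
        a = acor ** beta
        k = a.sum(axis=0)
        fit, slope = scale_free_fit(k)
        rows.append({"power": beta, "fit_index": fit, "slope": slope,
                     "mean_k": float(k.mean())})
    table = pd.DataFrame(rows)
    best = table.sort_values(["fit_index", "power"],
                             ascending=[False, True]).iloc[0]
    return int(best["power"]), table


def tom_from_correlation(X: pd.DataFrame, power: int) -> pd.DataFrame:
    """Topological overlap of the unsigned adjacency a = |cor|^power.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij),
    unit diagonal, symmetric, entries in [0, 1].
    """
    a_df = adjacency(X, power)
    a = a_df.to_numpy()
    k = a.sum(axis=0)
    shared = a @ a
    kmin = np.minimum.outer(k, k)
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = (shared + a) / (kmin + 1.0 - a)
    tom = np.nan_to_num(tom, nan=0.0)
    np.fill_diagonal(tom, 1.0)
    tom = (tom + tom.T) / 2
    return pd.DataFrame(np.clip(tom, 0.0, 1.0),
                        index=a_df.index, columns=a_df.columns)


@dataclass
class ModuleSet:
    labels: pd.Series                   # feature id -> color ("grey" = unassigned)
    eigenvalues: pd.DataFrame           # samples x modules, unit variance columns
    explained: pd.Series                # module -> first-PC variance fraction
    kme: pd.Series                      # feature id -> cor(feature, own eigenvalue)
    merge_history: list = field(default_factory=list)

    @property
    def module_names(self) -> list:
        return [c for c in self.eigenvalues.columns]

    def members(self, module: str) -> list:
        return list(self.labels.index[self.labels == module])

    def sizes(self) -> pd.Series:
        return self.labels.value_counts()


def detect_modules(tom: pd.DataFrame, min_size: int = 5,
                   cut_height: float | None = None,
                   cut_quantile: float | None = None) -> pd.Series:
    """Average-linkage clustering of 1 - TOM with a static tree cut.

    The default cut height is placed in the middle of the largest gap in
    the upper half of the sorted merge heights: merges that join distinct
    modules (and attach noise features) sit on a plateau near the maximum
    dissimilarity, well separated from within-module merges. A fixed
    ``cut_height`` or a merge-height ``cut_quantile`` may be given
    instead. Clusters below ``min_size`` become grey; surviving clusters
    get color names in decreasing size order (largest = turquoise).
    """
    dissim = 1.0 - tom.to_numpy()
    np.fill_diagonal(dissim, 0.0)
    condensed = squareform(dissim, checks=False)
    linkage = average(condensed)
    heights = linkage[:, 2]
    if cut_height is not None:
        cut = float(cut_height)
    elif cut_quantile is not None:
        cut = float(np.quantile(heights, cut_quantile))
    else:
        hs = np.sort(heights)
        top = hs[hs >= np.median(hs)]
        if len(top) < 2:
            cut = float(hs[-1]) if len(hs) else 1.0
        else:
            gaps = np.diff(top)
            i = int(np.argmax(gaps))
            cut = float((top[i] + top[i + 1]) / 2)
    raw = fcluster(linkage, t=cut, criterion="distance")
    labels = pd.Series(raw, index=tom.index)
    sizes = labels.value_counts()
    keep = sizes[sizes >= min_size]
    if keep.empty:
        warnings.warn("no module reached the minimum size; all features grey")
    color_of = {}
    for rank, cl in enumerate(keep.sort_values(ascending=False).index):
        color_of[cl] = MODULE_COLORS[rank] if rank < len(MODULE_COLORS) \
            else f"module{rank + 1}"
    return labels.map(lambda c: color_of.get(c, GREY))


def module_eigenvalues(X: pd.DataFrame, labels: pd.Series) -> ModuleSet:
    """First principal component per module over z-scored member features.

    Scores are scaled to unit variance and sign-oriented so each
    eigenvalue correlates non-negatively with the module's mean
    standardized profile. kME is each feature's correlation with its own
    module eigenvalue; grey features get NaN.
    """
    eig_cols = {}
    explained = {}
    kme = pd.Series(np.nan, index=labels.index)
    modules = [m for m in labels.unique() if m != GREY]
    # deterministic column order: by size desc then name
    modules.sort(key=lambda m: (-(labels == m).sum(), m))
    for mod in modules:
        members = list(labels.index[labels == mod])
        sub = X[members].to_numpy(dtype=float)
        sd = sub.std(axis=0, ddof=1)
        ok = sd > 0
        if ok.sum() < len(members):
            warnings.warn(f"dropping {len(members) - ok.sum()} zero-variance "
                          f"feature(s) from module {mod}")
        if ok.sum() < 2:
            continue
        members = [m for m, o in zip(members, ok) if o]
        sub = sub[:, ok]
        Z = (sub - sub.mean(axis=0)) / sub.std(axis=0, ddof=1)
        U, s, Vt = np.linalg.svd(Z, full_matrices=False)
        scores = U[:, 0] * s[0]
        scores = scores / scores.std(ddof=1)
        mean_profile = Z.mean(axis=1)
        if np.corrcoef(scores, mean_profile)[0, 1] < 0:
            scores = -scores
        eig_cols[mod] = scores
        explained[mod] = float(s[0] ** 2 / (s ** 2).sum())
        for j, f in enumerate(members):
            kme[f] = float(np.corrcoef(Z[:, j], scores)[0, 1])
    eigenvalues = pd.DataFrame(eig_cols, index=X.index)
    return ModuleSet(labels=labels.copy(), eigenvalues=eigenvalues,
                     explained=pd.Series(explained), kme=kme)


def merge_close_modules(X: pd.DataFrame, modules: ModuleSet,
                        merge_height: float = 0.25) -> ModuleSet:
    """Merge module pairs whose eigenvalues correlate above 1 - merge_height.

    Iterates (closest pair first, recomputing eigenvalues after each
    merge) until all pairwise eigenvalue dissimilarities are >= the merge
    height. Grey never merges. The merged pair keeps the larger module's
    color.
    """
    labels = modules.labels.copy()
    history = list(modules.merge_history)
    max_iter = max(len(modules.module_names), 1)
    current = modules
    for _ in range(max_iter):
        names = current.module_names
        if len(names) < 2:
            break
        E = current.eigenvalues[names]
        cor = E.corr().to_numpy()
        dissim = 1.0 - cor
        np.fill_diagonal(dissim, np.inf)
        i, j = np.unravel_index(np.argmin(dissim), dissim.shape)
        if dissim[i, j] >= merge_height:
            break
        a, b = names[i], names[j]
        big, small = (a, b) if (labels == a).sum() >= (labels == b).sum() else (b, a)
        labels[labels == small] = big
        history.append({"kept": big, "absorbed": small,
                        "dissimilarity": float(dissim[i, j])})
        current = module_eigenvalues(X, labels)
    current.merge_history = history
    return current


def hub_features(modules: ModuleSet, top_n: int | None = None) -> dict:
    """Per-module features ranked by |kME| descending, ties by feature id."""
    out = {}
    for mod in modules.module_names:
        members = modules.members(mod)
        ranked = sorted(members,
                        key=lambda f: (-abs(modules.kme.get(f, 0.0)), f))
        out[mod] = ranked[:top_n] if top_n else ranked
    return out


def module_dispersion(table_abundance: pd.DataFrame, modules: ModuleSet,
                      metadata: pd.DataFrame, grouping: str = "plot",
                      include_grey: bool = False) -> pd.DataFrame:
    """Plot-level dispersion ANOVA per module, ranked by F (descending).

    Restricts the feature table to each module's members, builds Manhattan
    distances, and runs the dispersion homogeneity ANOVA.
    """
    from .diversity import dispersion, manhattan_distances

    rows = []
    names = list(modules.module_names)
    if include_grey and (modules.labels == GREY).any():
        names.append(GREY)
    for mod in names:
        members = [f for f in modules.members(mod) if f in table_abundance.columns]
        if len(members) < 2:
            warnings.warn(f"module {mod} has < 2 features; skipped")
            continue
        dist = manhattan_distances(table_abundance[members])
        groups = metadata.loc[table_abundance.index, grouping]
        res = dispersion(dist, groups)
        rows.append({"module": mod, "n_features": len(members),
                     "F": res.F, "df1": res.df[0] if res.df else None,
                     "df2": res.df[1] if res.df else None, "p": res.p})
    out = pd.DataFrame(rows)
    if not out.empty:
        out = out.sort_values("F", ascending=False).reset_index(drop=True)
    return out
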