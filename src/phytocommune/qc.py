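"""Feature-table quality control.

Pipeline: pseudospectrum grouping (co-elution + cross-sample correlation,
single linkage) -> ammonium-adduct removal within groups -> representative
selection (max mean abundance) -> per-feature batch-effect ANOVA filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

# m/z spacing between [M+NH4]+ and [M+H]+ ions of the same molecule
NH4_H_SPACING = 17.026549


@dataclass
class PseudospectrumGrouping:
    groups: dict                 # feature id -> group id
    representatives: dict        # group id -> representative feature id
    singletons_constant: list = field(default_factory=list)  # undefined correlation

    def members(self, group_id) -> list:
        return [f for f, g in self.groups.items() if g == group_id]

    @property
    def n_groups(self) -> int:
        return len(set(self.groups.values()))


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def group_pseudospectra(table, rt_window: float = 5.0,
                        corr_min: float = 0.7) -> PseudospectrumGrouping:
    """Single-linkage grouping of co-eluting, cross-sample-correlated features.

    Two features share a group iff connected by a chain of pairs each with
    |delta rt| <= rt_window and Pearson r >= corr_min. Constant-abundance
    features have undefined correlation and stay singletons.
    """
    if table.n_samples < 2:
        raise ValueError("grouping requires at least 2 samples")
    if not 0 < corr_min < 1:
        raise ValueError("corr_min must lie in (0, 1)")
    feats = table.features
    X = table.abundance.to_numpy(dtype=float)
    sd = X.std(axis=0)
    constant = sd <= 0
    # standardized columns make pairwise Pearson r a dot product / n
    Z = np.zeros_like(X)
    ok = ~constant
    Z[:, ok] = (X[:, ok] - X[:, ok].mean(axis=0)) / sd[ok]
    n = X.shape[0]

    order = np.argsort(feats["rt_s"].to_numpy())
    rts = feats["rt_s"].to_numpy()[order]
    ids = np.asarray(feats.index)[order]
    const_sorted = constant[order]

    uf = _UnionFind(list(feats.index))
    j0 = 0
    for i in range(len(ids)):
        while rts[i] - rts[j0] > rt_window:
            j0 += 1
        if const_sorted[i]:
            continue
        for j in range(j0, i):
            if const_sorted[j]:
                continue
            zi = Z[:, order[i]]
            zj = Z[:, order[j]]
            r = float(zi @ zj) / n
            if r >= corr_min:
                uf.union(ids[i], ids[j])

    roots = {}
    groups = {}
    next_gid = 0
    for fid in feats.index:  # deterministic group numbering by table order
        root = uf.find(fid)
        if root not in roots:
            roots[root] = f"G{next_gid:04d}"
            next_gid += 1
        groups[fid] = roots[root]

    mean_ab = table.abundance.mean(axis=0)
    representatives = {}
    for gid in sorted(set(groups.values())):
        members = [f for f in feats.index if groups[f] == gid]
        representatives[gid] = max(members, key=lambda f: (mean_ab[f], f))
    return PseudospectrumGrouping(
        groups=groups,
        representatives=representatives,
        singletons_constant=[f for f, c in zip(feats.index, constant) if c],
    )


def select_representatives(grouping: PseudospectrumGrouping, table):
    """Keep one feature per pseudospectrum group, ordered by retention time."""
    missing = [f for f in table.features.index if f not in grouping.groups]
    if missing:
        raise ValueError(f"grouping does not cover features: {missing[:5]}")
    present = set(table.features.index)
    keep = []
    for gid in sorted(set(grouping.groups[f] for f in present)):
        members = [f for f in present if grouping.groups[f] == gid]
        rep = grouping.representatives.get(gid)
        if rep not in members:  # original representative already removed upstream
            mean_ab = table.abundance[members].mean(axis=0)
            rep = max(members, key=lambda f: (mean_ab[f], f))
        keep.append(rep)
    keep.sort(key=lambda f: (table.features.at[f, "rt_s"], f))
    return table.subset(keep)


def remove_ammonium_adducts(grouping: PseudospectrumGrouping, table,
                            mass_tol: float = 0.005):
    """Drop within-group features sitting one NH4+/H+ spacing above a partner.

    Returns (filtered table, removal log of {feature, partner, delta_mz}).
    """
    if mass_tol <= 0:
        raise ValueError("mass_tol must be positive")
    present = set(table.features.index)
    mz = table.features["mz"]
    removed = []
    by_group: dict = {}
    for f in table.features.index:
        by_group.setdefault(grouping.groups.get(f), []).append(f)
    for gid, members in by_group.items():
        if gid is None or len(members) < 2:
            continue
        for f in members:
            for g in members:
                if f == g:
                    continue
                delta = mz[f] - mz[g]
                if abs(delta - NH4_H_SPACING) <= mass_tol:
                    removed.append({"feature": f, "partner": g,
                                    "delta_mz": float(delta)})
                    break
    removed_ids = {r["feature"] for r in removed}
    keep = [f for f in table.features.index if f not in removed_ids]
    assert set(keep) <= present
    return table.subset(keep), removed


def filter_batch_effects(table, metadata: pd.DataFrame, alpha: float = 0.10):
    """Remove features whose abundance differs across extraction batches.

    One-way ANOVA per feature grouped by batch; p < alpha => removed.
    Zero-variance features get p = 1 (no evidence) and are retained.
    Returns (filtered table, log DataFrame of removed ids and p-values).
    """
    batches = metadata.loc[table.abundance.index, "batch"]
    counts = batches.value_counts()
    if len(counts) < 2:
        raise ValueError("batch filter requires >= 2 batches")
    small = counts[counts < 2]
    if not small.empty:
        raise ValueError(f"batch(es) with < 2 samples: {list(small.index)}")
    groups_idx = [np.where((batches == b).to_numpy())[0] for b in counts.index]
    X = table.abundance.to_numpy(dtype=float)
    pvals = np.ones(X.shape[1])
    for j in range(X.shape[1]):
        col = X[:, j]
        if col.std() <= 0:
            continue  # p = 1 by decision
        samples = [col[idx] for idx in groups_idx]
        with np.errstate(invalid="ignore", divide="ignore"):
            _, p = stats.f_oneway(*samples)
        pvals[j] = 1.0 if np.isnan(p) else float(p)
    feats = np.asarray(table.features.index)
    removed_mask = pvals < alpha
    log = pd.DataFrame({"feature_id": feats[removed_mask],
                        "p_value": pvals[removed_mask]})
    return table.subset(list(feats[~removed_mask])), log


def run_qc(table, metadata: pd.DataFrame, rt_window: float = 5.0,
           corr_min: float = 0.7, mass_tol: float = 0.005,
           alpha: float = 0.10) -> tuple:
    """Full QC chain. Adduct removal precedes representative selection so a
    representative can never itself be an ammonium adduct; internal-standard
    channels bypass every filter. Returns (table, stage log dict)."""
    standards = table.features.index[table.features["is_standard"]].tolist()
    work = table.drop(standards) if standards else table
    grouping = group_pseudospectra(work, rt_window=rt_window, corr_min=corr_min)
    deadducted, adduct_log = remove_ammonium_adducts(grouping, work, mass_tol=mass_tol)
    reps = select_representatives(grouping, deadducted)
    if standards:
        std_tab = table.subset(standards)
        reps = _concat_tables(reps, std_tab)
    filtered, batch_log = filter_batch_effects(reps, metadata, alpha=alpha)
    # re-attach standards if the batch filter clipped one (they are controls)
    lost_std = [s for s in standards if s not in filtered.features.index]
    if lost_std:
        filtered = _concat_tables(filtered, table.subset(lost_std))
    log = {
        "n_input": table.n_features,
        "n_groups": grouping.n_groups,
        "constant_singletons": grouping.singletons_constant,
        "adducts_removed": adduct_log,
        "n_after_representatives": reps.n_features,
        "batch_removed": batch_log.to_dict(orient="list"),
        "n_output": filtered.n_features,
        "params": {"rt_window": rt_window, "corr_min": corr_min,
                   "mass_tol": mass_tol, "batch_alpha": alpha},
    }
    return filtered, log


def _concat_tables(a, b):
    from .feature_table import FeatureTable
    feats = pd.concat([a.features, b.features])
    ab = pd.concat([a.abundance, b.abundance], axis=1)
    return FeatureTable(features=feats, abundance=ab)
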