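"""Compound-class annotation and internal-standard normalization.

Representative features are partitioned by the nitrogen rule (even
nominal protonated m/z => presumed nitrogenous), clustered by Gaussian
mixtures over standardized (rt, m/z, RMD) with BIC model selection, and
each cluster is labeled by the first class-window rule its means satisfy.
Class-matched internal standards then normalize abundances before
division by dry extracted mass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from .feature_table import FeatureTable, nominal_mass


def relative_mass_defect(mz) -> np.ndarray | float:
    """Relative mass defect in ppm: fractional mass over measured ion m/z.

    Computed against the integer mass below the ion (floor) so the defect
    is always non-negative, including lipid-like ions whose fractional
    mass exceeds 0.5.
    """
    mz_arr = np.asarray(mz, dtype=float)
    if np.any(mz_arr <= 0):
        raise ValueError("m/z must be positive")
    rmd = (mz_arr - np.floor(mz_arr)) / mz_arr * 1e6
    return float(rmd) if np.isscalar(mz) else rmd


def partition_by_nitrogen_rule(features: pd.DataFrame,
                               ambiguity_band: float = 0.3) -> tuple:
    """Split features into (nitrogenous, non-nitrogenous) index sets.

    Even nominal protonated m/z implies an odd-nitrogen neutral molecule.
    Fractional masses within ``ambiguity_band`` of the half-integer
    boundary are still assigned but reported in the returned log.
    """
    mz = features["mz"].to_numpy(dtype=float)
    nominal = nominal_mass(mz)
    even = nominal % 2 == 0
    # distance of the fractional mass from the nominal integer, in [0, 0.5]
    ambiguous = np.abs(mz - nominal) > (0.5 - ambiguity_band)
    log = {
        "n_nitrogenous": int(even.sum()),
        "n_non_nitrogenous": int((~even).sum()),
        "parity_ambiguous": list(np.asarray(features.index)[ambiguous]),
    }
    nitro = features.index[even]
    non_nitro = features.index[~even]
    return nitro, non_nitro, log


# ---------------------------------------------------------------------------
# Gaussian-mixture clustering with BIC selection
# ---------------------------------------------------------------------------

@dataclass
class ClusterModel:
    partition: str                    # "nitrogenous" | "non_nitrogenous"
    labels: pd.Series                 # feature id -> cluster id (int)
    means: pd.DataFrame               # cluster x (rt_s, mz, rmd_ppm), original units
    k: int
    covariance_type: str
    bic_trace: pd.DataFrame           # k, covariance_type, bic (NaN if failed)

    @property
    def cluster_ids(self) -> list:
        return sorted(self.means.index)


COVARIANCE_STRUCTURES = ("spherical", "diag", "tied", "full")


def cluster_features(features: pd.DataFrame, partition: str = "all",
                     k_range=range(1, 13),
                     covariance_structures=COVARIANCE_STRUCTURES,
                     seed: int = 0) -> ClusterModel:
    """EM-fitted Gaussian mixtures over standardized (rt, m/z, RMD).

    The (k, covariance structure) pair minimizing BIC wins; fixed seeded
    initializations keep the fit deterministic. Candidates that fail to
    converge are skipped and recorded with NaN BIC.
    """
    cols = ["rt_s", "mz", "rmd_ppm"]
    X = features[cols].to_numpy(dtype=float)
    k_range = [k for k in k_range if k <= len(X)]
    if not k_range:
        raise ValueError("subset smaller than every candidate k")
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - X.mean(axis=0)) / sd

    best = None
    trace = []
    for cov in covariance_structures:
        for k in k_range:
            gm = GaussianMixture(n_components=k, covariance_type=cov,
                                 n_init=3, random_state=seed, reg_covar=1e-6,
                                 max_iter=500)
            try:
                gm.fit(Z)
                if not gm.converged_:
                    raise ValueError("EM did not converge")
                bic = gm.bic(Z)
            except Exception:  # noqa: BLE001 - candidate skipped, logged
                trace.append({"k": k, "covariance_type": cov, "bic": np.nan})
                continue
            trace.append({"k": k, "covariance_type": cov, "bic": bic})
            if best is None or bic < best[0]:
                best = (bic, k, cov, gm)
    if best is None:
        raise RuntimeError("all mixture candidates failed to converge")
    _, k, cov, gm = best
    raw_labels = gm.predict(Z)
    # renumber clusters by size (largest first) for stable reporting
    sizes = pd.Series(raw_labels).value_counts()
    remap = {old: new for new, old in enumerate(sizes.index)}
    labels = pd.Series([remap[l] for l in raw_labels], index=features.index)
    means = features.groupby(labels)[cols].mean()
    means.index.name = "cluster"
    return ClusterModel(partition=partition, labels=labels, means=means,
                        k=k, covariance_type=cov,
                        bic_trace=pd.DataFrame(trace))


# ---------------------------------------------------------------------------
# Class-window rules
# ---------------------------------------------------------------------------

@dataclass
class ClassRule:
    """First-match classification window; ``None`` bounds are open."""

    class_label: str
    nitrogenous: bool | None = None
    rt_window: tuple | None = None
    mz_window: tuple | None = None
    rmd_window: tuple | None = None

    def matches(self, nitro: bool, rt: float, mz: float, rmd: float) -> bool:
        if self.nitrogenous is not None and nitro != self.nitrogenous:
            return False
        for window, value in ((self.rt_window, rt), (self.mz_window, mz),
                              (self.rmd_window, rmd)):
            if window is not None and not (window[0] <= value <= window[1]):
                return False
        return True


def default_class_rules() -> list:
    """Window rules in fixed precedence order.

    Lipid-class windows: RMD 600-800 ppm, m/z 400-900 Da, rt 750-1050 s;
    flavonoid RMD 200-400 ppm with glycosides eluting at 350-450 s and
    aglycones at 600-800 s; peptides are the nitrogenous catch-all.
    """
    return [
        ClassRule("phospholipid", nitrogenous=True, rt_window=(750, 1050),
                  mz_window=(400, 900), rmd_window=(600, 800)),
        ClassRule("peptide", nitrogenous=True),
        ClassRule("flavonoid_glycoside", nitrogenous=False, rt_window=(350, 450),
                  rmd_window=(200, 400)),
        ClassRule("flavonoid_aglycone", nitrogenous=False, rt_window=(600, 800),
                  rmd_window=(200, 400)),
        ClassRule("lipid", nitrogenous=False, rt_window=(750, 1050),
                  mz_window=(400, 900), rmd_window=(600, 800)),
        ClassRule("other", nitrogenous=False, rt_window=(0, 300),
                  rmd_window=(400, 600)),
    ]


@dataclass
class ClassAssignment:
    table: pd.DataFrame   # feature id -> nitrogenous, cluster, class_label, standard_id
    rule_log: list = field(default_factory=list)

    def class_of(self, feature_id) -> str:
        return self.table.at[feature_id, "class_label"]

    def features_of_class(self, label: str) -> list:
        return list(self.table.index[self.table["class_label"] == label])


def assign_classes(cluster_models: list, rules: list | None = None) -> ClassAssignment:
    """Label every cluster by the first rule its means satisfy.

    ``cluster_models`` holds the per-partition ClusterModels (nitrogenous
    and non-nitrogenous). Unmatched clusters fall through to "unknown";
    members inherit their cluster's label.
    """
    if rules is None:
        rules = default_class_rules()
    if not rules:
        raise ValueError("empty rule table")
    rows = []
    rule_log = []
    for model in cluster_models:
        nitro = model.partition == "nitrogenous"
        for cid in model.cluster_ids:
            mean = model.means.loc[cid]
            label = "unknown"
            matched = []
            for rule in rules:
                if rule.matches(nitro, mean["rt_s"], mean["mz"], mean["rmd_ppm"]):
                    matched.append(rule.class_label)
            if matched:
                label = matched[0]
            if len(matched) > 1:
                rule_log.append({"partition": model.partition, "cluster": int(cid),
                                 "matches": matched, "chosen": label})
            for fid in model.labels.index[model.labels == cid]:
                rows.append({"feature_id": fid, "nitrogenous": nitro,
                             "cluster": f"{model.partition[:1]}{cid}",
                             "class_label": label, "standard_id": ""})
    table = pd.DataFrame(rows).set_index("feature_id")
    return ClassAssignment(table=table, rule_log=rule_log)


def annotate_features(features: pd.DataFrame, k_range=range(1, 13),
                      rules: list | None = None, seed: int = 0,
                      ) -> tuple[ClassAssignment, list, dict]:
    """Nitrogen partition -> per-partition GMM -> class windows.

    ``features`` must carry rt_s and mz; RMD is derived. Returns the
    assignment, the fitted ClusterModels and the parity log.
    """
    feats = features.copy()
    feats["rmd_ppm"] = relative_mass_defect(feats["mz"].to_numpy())
    nitro_idx, non_idx, parity_log = partition_by_nitrogen_rule(feats)
    models = []
    for name, idx in (("nitrogenous", nitro_idx), ("non_nitrogenous", non_idx)):
        if len(idx) == 0:
            continue
        usable_k = [k for k in k_range if k <= len(idx)]
        models.append(cluster_features(feats.loc[idx], partition=name,
                                       k_range=usable_k, seed=seed))
    assignment = assign_classes(models, rules=rules)
    return assignment, models, parity_log


# ---------------------------------------------------------------------------
# Internal standards and normalization
# ---------------------------------------------------------------------------

@dataclass
class InternalStandard:
    standard_id: str
    name: str
    class_served: str
    expected_mz: float
    concentration_uM: float

    def __post_init__(self) -> None:
        if self.concentration_uM <= 0:
            raise ValueError("standard concentration must be positive")


def default_standards() -> list:
    return [
        InternalStandard("IS_naringenin", "naringenin", "flavonoid_aglycone",
                         273.0757, 100.0),
        InternalStandard("IS_naringin", "naringin", "flavonoid_glycoside",
                         581.1865, 101.0),
        InternalStandard("IS_cck_fragment", "cholecystokinin fragment 30-33 amide",
                         "peptide", 597.2490, 52.0),
    ]


def locate_standards(table: FeatureTable, standards: list,
                     mz_tol: float = 0.01) -> dict:
    """Map standard_id -> feature id, by explicit flag first, else m/z match."""
    feats = table.features
    located = {}
    for std in standards:
        flagged = feats.index[(feats["is_standard"])
                              & (feats["standard_class"] == std.class_served)]
        if len(flagged):
            located[std.standard_id] = flagged[0]
            continue
        delta = (feats["mz"] - std.expected_mz).abs()
        hits = delta[delta <= mz_tol]
        if len(hits):
            located[std.standard_id] = hits.idxmin()
    return located


def normalize_abundances(table: FeatureTable, assignment: ClassAssignment,
                         standards: list, metadata: pd.DataFrame,
                         mz_tol: float = 0.01) -> FeatureTable:
    """Divide class-matched features by their standard's area, then divide
    everything by per-sample dry mass (g). Classes without a located
    standard are mass-normalized only.
    """
    located = locate_standards(table, standards, mz_tol=mz_tol)
    mass = metadata.loc[table.abundance.index, "dry_mass_g"]
    if not (mass > 0).all():
        bad = list(mass.index[~(mass > 0)])
        raise ValueError(f"non-positive dry mass for samples: {bad[:5]}")
    ab = table.abundance.copy()
    class_to_std = {s.class_served: s.standard_id for s in standards}
    std_ids = set(located.values())
    for cls, sid in class_to_std.items():
        if sid not in located:
            continue
        std_feature = located[sid]
        area = table.abundance[std_feature]
        if (area <= 0).any() or area.isna().any():
            bad = list(area.index[(area <= 0) | area.isna()])
            raise ValueError(
                f"standard {sid} has zero/missing area in samples: {bad[:5]}")
        members = [f for f in assignment.features_of_class(cls)
                   if f in ab.columns and f not in std_ids]
        if members:
            ab[members] = ab[members].div(area, axis=0)
    ab = ab.div(mass, axis=0)
    out = FeatureTable(features=table.features.copy(), abundance=ab)
    return out
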