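"""Synthetic LC-MS feature tables, sample hierarchies and insect communities.

Everything downstream of raw-data processing is testable against planted
ground truth: compound classes with characteristic (rt, m/z, RMD)
distributions, block-structured covariance modules, internal-standard
channels, batch offsets, and herbivore/parasitoid communities generated
from planted standardized path coefficients.

All generators are deterministic for a fixed seed (``numpy``
``default_rng``); per-stage seeds are derived from a single root seed by
fixed offsets so stages can be regenerated in isolation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .feature_table import FeatureTable

# fixed seed offsets per stage
_SEED_HIERARCHY = 11
_SEED_TRUTH = 23
_SEED_TABLE = 37
_SEED_COMMUNITY = 53

CLASS_LABELS = (
    "peptide", "flavonoid_glycoside", "flavonoid_aglycone",
    "lipid", "phospholipid", "other", "unknown",
)


class ConfigurationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Sampling hierarchy
# ---------------------------------------------------------------------------

@dataclass
class HierarchyConfig:
    """Spatiotemporal sampling design: sites > subsites > plots > plants.

    Defaults mirror a 2-site x 3-subsite x 3-plot design sampled over 3
    months along a 1600-2600 m elevational gradient.
    """

    n_sites: int = 2
    subsites_per_site: int = 3
    plots_per_subsite: int = 3
    individuals_mean: float = 3.0
    individuals_dispersion: float = 0.0   # 0 => exactly round(mean) per plot
    months: int = 3
    elevation_range: tuple = (1600.0, 2600.0)
    batches: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_sites", "subsites_per_site", "plots_per_subsite",
                     "months", "batches"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if self.individuals_mean < 1:
            raise ConfigurationError("individuals_mean must be >= 1")
        lo, hi = self.elevation_range
        if not lo < hi:
            raise ConfigurationError("elevation range must satisfy min < max")

    @property
    def n_plots(self) -> int:
        return self.n_sites * self.subsites_per_site * self.plots_per_subsite


def make_hierarchy(config: HierarchyConfig) -> pd.DataFrame:
    """One metadata row per (individual, month).

    Elevation is the subsite band midpoint jittered by +/-50 m per plot;
    dry extracted mass is drawn near 0.020 g; extraction batches are
    assigned in contiguous blocks over the sample sequence.
    """
    rng = np.random.default_rng(config.seed + _SEED_HIERARCHY)
    lo, hi = config.elevation_range
    band = (hi - lo) / config.subsites_per_site
    rows = []
    for s in range(config.n_sites):
        site = f"site{s + 1}"
        for b in range(config.subsites_per_site):
            subsite = f"{site}_sub{b + 1}"
            mid = lo + (b + 0.5) * band
            for pl in range(config.plots_per_subsite):
                plot = f"{subsite}_p{pl + 1}"
                elev = mid + rng.uniform(-50.0, 50.0)
                if config.individuals_dispersion > 0:
                    n_ind = 1 + rng.poisson(max(config.individuals_mean - 1, 0))
                else:
                    n_ind = int(round(config.individuals_mean))
                for ind in range(n_ind):
                    individual = f"{plot}_i{ind + 1}"
                    for m in range(1, config.months + 1):
                        rows.append({
                            "sample_id": f"{individual}_m{m}",
                            "site": site, "subsite": subsite, "plot": plot,
                            "individual": individual, "month": m,
                            "elevation_m": elev,
                        })
    meta = pd.DataFrame(rows).set_index("sample_id")
    n = len(meta)
    meta["dry_mass_g"] = np.clip(rng.normal(0.020, 0.002, size=n), 0.005, None)
    blocks = np.array_split(np.arange(n), config.batches)
    batch = np.empty(n, dtype=object)
    for k, idxs in enumerate(blocks):
        batch[idxs] = f"batch{k + 1}"
    meta["batch"] = batch
    return meta


# ---------------------------------------------------------------------------
# Compound-class profiles and planted truth
# ---------------------------------------------------------------------------

@dataclass
class ClassProfile:
    """Generative (rt, m/z, RMD) windows for one compound class.

    ``shape`` controls the within-window draw: "uniform" over the window,
    or "normal" centered on the window midpoint with sd = width/6
    (clipped to the window) so classes form genuine Gaussian components.
    """

    class_label: str
    n_features: int
    rt_range: tuple          # seconds
    mz_range: tuple          # Da
    rmd_range: tuple         # ppm
    nitrogen_prob: float = 0.0
    shape: str = "uniform"

    def __post_init__(self) -> None:
        if self.n_features < 0:
            raise ConfigurationError("n_features must be >= 0")
        if self.rt_range[0] <= 0:
            raise ConfigurationError("retention times must be positive")
        if self.mz_range[0] <= 50:
            raise ConfigurationError("m/z must exceed 50 Da")
        if not (0 <= self.rmd_range[0] <= self.rmd_range[1] < 1e6):
            raise ConfigurationError("RMD range must lie in [0, 1e6) ppm")
        if self.shape not in ("uniform", "normal"):
            raise ConfigurationError("shape must be 'uniform' or 'normal'")

    def draw(self, rng: np.random.Generator, rng_range: tuple) -> float:
        lo, hi = rng_range
        if self.shape == "uniform":
            return float(rng.uniform(lo, hi))
        mid, sd = (lo + hi) / 2.0, (hi - lo) / 6.0
        return float(np.clip(rng.normal(mid, sd), lo, hi))


def default_class_profiles() -> list:
    """Feature counts per class follow the study design: peptides 40,
    flavonoid glycosides 35, phospholipids 33, lipids 31, flavonoid
    aglycones 11, minor classes 7, unidentified 18 (175 total).
    """
    return [
        ClassProfile("peptide", 40, (200, 700), (300, 800), (300, 590), 1.0),
        ClassProfile("flavonoid_glycoside", 35, (355, 445), (400, 800), (210, 390), 0.0),
        ClassProfile("phospholipid", 33, (760, 1040), (410, 890), (610, 790), 1.0),
        ClassProfile("lipid", 31, (760, 1040), (410, 890), (610, 790), 0.0),
        ClassProfile("flavonoid_aglycone", 11, (605, 795), (250, 450), (210, 390), 0.0),
        ClassProfile("other", 7, (60, 250), (110, 300), (420, 580), 0.0),
        ClassProfile("unknown", 18, (860, 1050), (120, 390), (340, 560), 0.0),
    ]


def _draw_mz(rng: np.random.Generator, mz_range: tuple, rmd_range: tuple,
             nitrogenous: bool, profile: "ClassProfile | None" = None) -> float:
    """Draw an ion m/z whose nominal (half-up) mass parity obeys the
    nitrogen rule for protonated adducts: nitrogenous => even nominal m/z.

    The fractional defect f (relative to floor) satisfies
    RMD = f / mz * 1e6; for defects >= 0.5 the rounded nominal mass is
    floor + 1, which the integer basis accounts for.
    """
    parity = 0 if nitrogenous else 1
    if profile is not None:
        r = profile.draw(rng, rmd_range) * 1e-6
    else:
        r = rng.uniform(*rmd_range) * 1e-6
    lo = int(np.ceil(mz_range[0]))
    hi = int(np.floor(mz_range[1]))
    candidates = np.arange(lo, hi + 1)
    candidates = candidates[candidates % 2 == parity]
    if candidates.size == 0:
        raise ConfigurationError(f"no nominal mass of parity {parity} in {mz_range}")
    if profile is not None and profile.shape == "normal":
        target = profile.draw(rng, mz_range)
        R = int(candidates[np.argmin(np.abs(candidates - target))])
    else:
        R = int(rng.choice(candidates))
    f = r * R / (1.0 - r)
    if f < 0.5:
        return R + f
    f = r * (R - 1) / (1.0 - r)
    if f >= 0.5:
        return (R - 1) + f
    return (R - 1) + 0.5  # boundary sliver: defect pinned at exactly .5


def default_path_coefficients() -> dict:
    """Planted standardized effects linking elevation, plants, chemistry
    modules and the insect community (generative counterpart of the
    study's pruned chemistry path model)."""
    return {
        "elevation->leaves": 0.22,
        "elevation->mod_flavonoid_glycoside": -0.27,
        "leaves->herb_abundance": 0.16,
        "mod_peptide->herb_abundance": 0.60,
        "mod_flavonoid_glycoside->herb_abundance": -0.40,
        "elevation->herb_diversity": -0.30,
        "mod_flavonoid_glycoside->herb_diversity": -0.35,
        "elevation->parasitoid": 0.46,
        "leaves->parasitoid": 0.37,
        "mod_flavonoid_glycoside->parasitoid": -0.33,
        "mod_lipid->herb_abundance": 0.0,
        "mod_lipid->herb_diversity": 0.0,
        "mod_lipid->parasitoid": 0.0,
    }


@dataclass
class SyntheticTruth:
    """Ground truth for one synthetic dataset.

    ``features`` holds per-feature class, parity flag, (rt, mz, RMD) and
    planted module; ``loadings`` the feature loading on its module factor
    (0 outside the block, so the loading matrix is block-disjoint).
    """

    features: pd.DataFrame
    loadings: pd.Series
    module_classes: dict
    path_coefficients: dict
    batch_offsets: pd.DataFrame
    noise_sd: float
    seed: int

    def to_json(self, path) -> None:
        payload = {
            "features": self.features.reset_index().to_dict(orient="list"),
            "loadings": {k: float(v) for k, v in self.loadings.items()},
            "module_classes": self.module_classes,
            "path_coefficients": self.path_coefficients,
            "batch_offsets": {
                "index": list(self.batch_offsets.index),
                "columns": list(self.batch_offsets.columns),
                "values": self.batch_offsets.to_numpy().tolist(),
            },
            "noise_sd": self.noise_sd,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            payload = json.load(fh)
        features = pd.DataFrame(payload["features"]).set_index("feature_id")
        bo = payload["batch_offsets"]
        return cls(
            features=features,
            loadings=pd.Series(payload["loadings"]),
            module_classes=payload["module_classes"],
            path_coefficients=payload["path_coefficients"],
            batch_offsets=pd.DataFrame(bo["values"], index=bo["index"],
                                       columns=bo["columns"]),
            noise_sd=payload["noise_sd"],
            seed=payload["seed"],
        )


def make_feature_truth(class_profiles: list | None = None,
                       n_modules: int = 3,
                       seed: int = 0,
                       module_classes: list | None = None,
                       min_module_size: int = 5,
                       batch_effect_frac: float = 0.10,
                       batch_effect_sd: float = 1.5,
                       n_batches: int = 4,
                       noise_sd: float = 0.7,
                       path_coefficients: dict | None = None) -> SyntheticTruth:
    """Plant per-feature (rt, m/z, RMD), classes and covariance modules.

    Each module is a loading block inside one compound class (by default
    the peptide, flavonoid-glycoside and lipid classes, matching the
    study's dominant modules). Nitrogenous features get even nominal
    protonated m/z, non-nitrogenous odd.
    """
    if class_profiles is None:
        class_profiles = default_class_profiles()
    if not class_profiles:
        raise ConfigurationError("class profile list is empty")
    total = sum(p.n_features for p in class_profiles)
    if total < n_modules * min_module_size:
        raise ConfigurationError(
            f"{total} features cannot host {n_modules} modules of >= {min_module_size}")
    rng = np.random.default_rng(seed + _SEED_TRUTH)

    rows = []
    fid = 0
    for prof in class_profiles:
        for _ in range(prof.n_features):
            fid += 1
            nitro = bool(rng.random() < prof.nitrogen_prob)
            mz = _draw_mz(rng, prof.mz_range, prof.rmd_range, nitro, profile=prof)
            rmd = (mz - np.floor(mz)) / mz * 1e6
            rows.append({
                "feature_id": f"F{fid:04d}",
                "class_label": prof.class_label,
                "nitrogenous": nitro,
                "rt_s": prof.draw(rng, prof.rt_range),
                "mz": float(mz),
                "rmd_ppm": float(rmd),
            })
    features = pd.DataFrame(rows).set_index("feature_id")

    if module_classes is None:
        preferred = ["peptide", "flavonoid_glycoside", "lipid", "phospholipid",
                     "flavonoid_aglycone", "other", "unknown"]
        present = [p.class_label for p in class_profiles if p.n_features >= min_module_size]
        module_classes = [c for c in preferred if c in present][:n_modules]
        if len(module_classes) < n_modules:
            module_classes = present[:n_modules]
    if len(module_classes) != n_modules:
        raise ConfigurationError("module_classes length must equal n_modules")

    features["module"] = ""
    loadings = pd.Series(0.0, index=features.index)
    mod_map = {}
    for k, cls in enumerate(module_classes):
        mod = f"mod_{cls}"
        mod_map[mod] = cls
        members = features.index[features["class_label"] == cls]
        if len(members) < min_module_size:
            raise ConfigurationError(f"class {cls} too small to host a module")
        features.loc[members, "module"] = mod
        loadings.loc[members] = rng.uniform(0.7, 1.0, size=len(members))

    batch_ids = [f"batch{i + 1}" for i in range(n_batches)]
    offsets = pd.DataFrame(0.0, index=features.index, columns=batch_ids)
    n_affected = int(round(batch_effect_frac * len(features)))
    affected = rng.choice(features.index, size=n_affected, replace=False)
    for f in affected:
        offsets.loc[f] = rng.normal(0.0, batch_effect_sd, size=n_batches)

    return SyntheticTruth(
        features=features,
        loadings=loadings,
        module_classes=mod_map,
        path_coefficients=dict(path_coefficients or default_path_coefficients()),
        batch_offsets=offsets,
        noise_sd=noise_sd,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Abundance matrix
# ---------------------------------------------------------------------------

# internal standard channels: (id, class served, [M+H]+ m/z, nominal rt s, uM)
INTERNAL_STANDARDS = [
    ("IS_naringenin", "flavonoid_aglycone", 273.0757, 650.0, 100.0),
    ("IS_naringin", "flavonoid_glycoside", 581.1865, 400.0, 101.0),
    ("IS_cck_fragment", "peptide", 597.2490, 300.0, 52.0),
]


def make_feature_table(truth: SyntheticTruth, metadata: pd.DataFrame,
                       add_standards: bool = True,
                       factor_table: pd.DataFrame | None = None,
                       ) -> tuple[FeatureTable, pd.DataFrame]:
    """Realize log-normal abundances from the planted truth.

    log abundance = baseline + loading * module factor + batch offset +
    Gaussian noise; module factors are standard normal per sample except
    where a planted ``elevation->mod_*`` coefficient ties them to the
    elevation gradient. Returns the table and the latent factor matrix
    (samples x modules).
    """
    rng = np.random.default_rng(truth.seed + _SEED_TABLE)
    samples = list(metadata.index)
    n = len(samples)
    modules = list(truth.module_classes)

    elev = metadata["elevation_m"].to_numpy(dtype=float)
    z_elev = (elev - elev.mean()) / (elev.std() or 1.0)
    if factor_table is None:
        factors = {}
        for mod in modules:
            c = float(truth.path_coefficients.get(f"elevation->{mod}", 0.0))
            eps = rng.standard_normal(n)
            factors[mod] = c * z_elev + np.sqrt(max(1 - c * c, 0.0)) * eps
        factor_table = pd.DataFrame(factors, index=samples)
    else:
        if list(factor_table.index) != samples:
            raise ValueError("factor table index does not match metadata samples")

    feats = truth.features
    base = rng.uniform(8.0, 12.0, size=len(feats))
    batch_of = metadata["batch"]
    log_ab = np.empty((n, len(feats)))
    batch_mat = truth.batch_offsets.loc[feats.index, batch_of].to_numpy().T  # n x f
    for j, fid in enumerate(feats.index):
        mod = feats.at[fid, "module"]
        signal = truth.loadings[fid] * factor_table[mod].to_numpy() if mod else 0.0
        log_ab[:, j] = base[j] + signal
    log_ab += batch_mat
    log_ab += rng.normal(0.0, truth.noise_sd, size=log_ab.shape)
    abundance = pd.DataFrame(np.exp(log_ab), index=samples, columns=feats.index)

    meta_cols = feats[["rt_s", "mz"]].copy()
    meta_cols["is_standard"] = False
    meta_cols["standard_class"] = ""
    if add_standards:
        for sid, cls, mz, rt, _conc in INTERNAL_STANDARDS:
            meta_cols.loc[sid] = {"rt_s": rt, "mz": mz, "is_standard": True,
                                  "standard_class": cls}
            abundance[sid] = np.exp(10.0 + rng.normal(0.0, 0.01, size=n))
    table = FeatureTable(features=meta_cols, abundance=abundance)
    return table, factor_table


# ---------------------------------------------------------------------------
# Herbivore community
# ---------------------------------------------------------------------------

@dataclass
class HerbivoreTable:
    """Plot x collection morphotype counts plus per-larva rearing outcomes."""

    counts: pd.DataFrame    # rows plot-month; columns plot, month, m01..mK
    outcomes: pd.DataFrame  # larva_id, plot, month, morphotype, outcome
    plots: pd.DataFrame     # plot-level covariates incl. leaves_per_plant

    def morphotype_columns(self) -> list:
        return [c for c in self.counts.columns if c.startswith("m") and c[1:].isdigit()]

    def write(self, directory) -> None:
        from pathlib import Path
        d = Path(directory)
        self.counts.to_csv(d / "herbivore_counts.csv", index=False)
        self.outcomes.to_csv(d / "rearing_outcomes.csv", index=False)
        self.plots.to_csv(d / "plot_covariates.csv")


_COMMUNITY_TARGETS = ("herb_abundance", "herb_diversity", "parasitoid", "leaves")


def make_community(truth: SyntheticTruth, metadata: pd.DataFrame,
                   module_signals: pd.DataFrame,
                   n_morphotypes: int = 19,
                   mean_count: float = 30.0,
                   death_rate: float = 0.15,
                   base_parasitoid_rate: float = 0.30) -> HerbivoreTable:
    """Generate herbivore counts and rearing outcomes from planted paths.

    Per plot, expected log total abundance is linear in the planted
    predictors (z-scored elevation, log leaves per plant, plot-mean
    module signals); morphotype identities follow a plot-specific
    multinomial whose Dirichlet concentration responds to the planted
    diversity effects; each larva's outcome is died / adult / parasitoid
    with a logit-linear parasitoid probability.
    """
    rng = np.random.default_rng(truth.seed + _SEED_COMMUNITY)
    coeffs = truth.path_coefficients
    known_sources = {"elevation", "leaves"} | set(module_signals.columns)
    for key in coeffs:
        src, dst = key.split("->")
        if dst in _COMMUNITY_TARGETS and src not in known_sources:
            raise ConfigurationError(f"coefficient {key} references unknown variable {src!r}")
        if dst.startswith("mod_"):
            continue
        if dst not in _COMMUNITY_TARGETS:
            raise ConfigurationError(f"coefficient {key} references unknown target {dst!r}")

    plot_meta = metadata.groupby("plot").agg(
        site=("site", "first"), subsite=("subsite", "first"),
        elevation_m=("elevation_m", "first"))
    plots = list(plot_meta.index)
    months = sorted(metadata["month"].unique())
    n_plots = len(plots)

    def zscore(v: np.ndarray) -> np.ndarray:
        sd = v.std()
        return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)

    z = {"elevation": zscore(plot_meta["elevation_m"].to_numpy(dtype=float))}
    # leaves per plant: lognormal, elevation-driven by the planted path
    c_lv = float(coeffs.get("elevation->leaves", 0.0))
    lv_z = c_lv * z["elevation"] + np.sqrt(max(1 - c_lv ** 2, 0.0)) * rng.standard_normal(n_plots)
    leaves = np.exp(7.0 + 0.5 * lv_z)
    z["leaves"] = zscore(np.log(leaves))

    sig_plot = module_signals.join(metadata["plot"]).groupby("plot").mean()
    sig_plot = sig_plot.loc[plots]
    for col in module_signals.columns:
        z[col] = zscore(sig_plot[col].to_numpy(dtype=float))

    def linpred(target: str) -> np.ndarray:
        eta = np.zeros(n_plots)
        for key, c in coeffs.items():
            src, dst = key.split("->")
            if dst == target and src in z:
                eta += c * z[src]
        return eta

    eta_abund = np.log(mean_count) + linpred("herb_abundance")
    eta_div = 1.2 + linpred("herb_diversity")
    logit_base = np.log(base_parasitoid_rate / (1 - base_parasitoid_rate))
    eta_par = logit_base + linpred("parasitoid")

    base_p = 1.0 / np.arange(1, n_morphotypes + 1)
    base_p /= base_p.sum()
    morph_cols = [f"m{i + 1:02d}" for i in range(n_morphotypes)]

    count_rows, outcome_rows = [], []
    larva = 0
    for i, plot in enumerate(plots):
        theta = np.exp(eta_div[i])
        probs = rng.dirichlet(theta * n_morphotypes * base_p)
        p_par = 1.0 / (1.0 + np.exp(-eta_par[i]))
        for m in months:
            lam = np.exp(eta_abund[i]) / len(months)
            total = rng.poisson(lam)
            counts = rng.multinomial(total, probs)
            row = {"plot": plot, "month": m}
            row.update(dict(zip(morph_cols, counts.astype(int))))
            count_rows.append(row)
            for k, cnt in enumerate(counts):
                for _ in range(int(cnt)):
                    larva += 1
                    u = rng.random()
                    if u < death_rate:
                        outcome = "died"
                    else:
                        outcome = "parasitoid" if rng.random() < p_par else "adult"
                    outcome_rows.append({"larva_id": f"L{larva:05d}", "plot": plot,
                                         "month": m, "morphotype": morph_cols[k],
                                         "outcome": outcome})

    counts_df = pd.DataFrame(count_rows)
    outcomes_df = pd.DataFrame(outcome_rows,
                               columns=["larva_id", "plot", "month", "morphotype", "outcome"])
    plot_df = plot_meta.copy()
    plot_df["leaves_per_plant"] = leaves
    return HerbivoreTable(counts=counts_df, outcomes=outcomes_df, plots=plot_df)


# ---------------------------------------------------------------------------
# One-call dataset
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    metadata: pd.DataFrame
    truth: SyntheticTruth
    table: FeatureTable
    factors: pd.DataFrame
    community: HerbivoreTable

    def write(self, directory) -> None:
        from pathlib import Path
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.metadata.to_csv(d / "metadata.csv")
        self.table.to_csv(d / "feature_table.csv")
        self.factors.to_csv(d / "latent_factors.csv")
        self.truth.to_json(d / "truth.json")
        self.community.write(d)


def make_module_benchmark(n_per_block: int = 50, n_blocks: int = 3,
                          n_noise: int = 27, n_samples: int = 300,
                          noise_sd: float = 0.6, seed: int = 0) -> tuple:
    """Planted-block covariance benchmark for module detection.

    Returns (X samples x features, planted labels, latent factors):
    ``n_blocks`` rank-1 blocks of ``n_per_block`` features with loadings
    U(0.7, 1.0) on independent standard-normal factors, plus pure-noise
    features labeled "noise".
    """
    rng = np.random.default_rng(seed)
    factors = rng.standard_normal((n_samples, n_blocks))
    cols, labels = {}, {}
    loadings = {}
    for b in range(n_blocks):
        for j in range(n_per_block):
            name = f"B{b + 1}F{j + 1:03d}"
            l = rng.uniform(0.7, 1.0)
            cols[name] = l * factors[:, b] + noise_sd * rng.standard_normal(n_samples)
            labels[name] = f"block{b + 1}"
            loadings[name] = l
    for j in range(n_noise):
        name = f"N{j + 1:03d}"
        cols[name] = rng.standard_normal(n_samples)
        labels[name] = "noise"
        loadings[name] = 0.0
    X = pd.DataFrame(cols)
    truth = pd.Series(labels)
    factors_df = pd.DataFrame(factors,
                              columns=[f"block{b + 1}" for b in range(n_blocks)])
    return X, truth, factors_df, pd.Series(loadings)


def make_dataset(config: HierarchyConfig | None = None,
                 class_profiles: list | None = None,
                 n_modules: int = 3,
                 seed: int = 0,
                 **truth_kwargs) -> SyntheticDataset:
    """Hierarchy -> truth -> feature table -> community, all from one seed."""
    if config is None:
        config = HierarchyConfig(seed=seed)
    metadata = make_hierarchy(config)
    truth = make_feature_truth(class_profiles, n_modules=n_modules, seed=seed,
                               n_batches=config.batches, **truth_kwargs)
    table, factors = make_feature_table(truth, metadata)
    community = make_community(truth, metadata, factors)
    return SyntheticDataset(metadata=metadata, truth=truth, table=table,
                            factors=factors, community=community)
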