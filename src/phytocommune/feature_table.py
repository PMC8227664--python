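"""Aligned LC-MS feature table container and CSV round-trip."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

FEATURE_META_COLS = ["rt_s", "mz", "is_standard", "standard_class"]


@dataclass
class FeatureTable:
    """Features x samples abundance matrix with per-feature rt/mz metadata.

    Attributes
    ----------
    features : pd.DataFrame
        Indexed by feature id; columns ``rt_s`` (retention time, seconds),
        ``mz`` (positive-mode ion m/z, Da) and optionally ``is_standard`` /
        ``standard_class`` for internal-standard channels.
    abundance : pd.DataFrame
        Samples x features, non-negative reals. Columns follow
        ``features.index`` exactly.
    """

    features: pd.DataFrame
    abundance: pd.DataFrame

    def __post_init__(self) -> None:
        if "is_standard" not in self.features.columns:
            self.features = self.features.assign(is_standard=False)
        if "standard_class" not in self.features.columns:
            self.features = self.features.assign(standard_class="")
        self.features["standard_class"] = self.features["standard_class"].fillna("")
        self.validate()

    def validate(self) -> None:
        feats = self.features
        if feats.index.duplicated().any():
            dup = feats.index[feats.index.duplicated()].tolist()
            raise ValueError(f"duplicate feature ids: {dup[:5]}")
        if not (feats["rt_s"] > 0).all():
            raise ValueError("all retention times must be > 0 s")
        if not (feats["mz"] > 50).all():
            raise ValueError("all m/z values must exceed 50 Da")
        if list(self.abundance.columns) != list(feats.index):
            raise ValueError("abundance columns do not match feature index")
        if (self.abundance.to_numpy() < 0).any():
            raise ValueError("abundances must be non-negative")

    # -- convenience -------------------------------------------------------
    @property
    def feature_ids(self) -> list:
        return list(self.features.index)

    @property
    def sample_ids(self) -> list:
        return list(self.abundance.index)

    @property
    def n_features(self) -> int:
        return self.features.shape[0]

    @property
    def n_samples(self) -> int:
        return self.abundance.shape[0]

    def subset(self, feature_ids) -> "FeatureTable":
        """Return a new table restricted to ``feature_ids`` (order kept)."""
        feature_ids = list(feature_ids)
        return FeatureTable(
            features=self.features.loc[feature_ids].copy(),
            abundance=self.abundance.loc[:, feature_ids].copy(),
        )

    def drop(self, feature_ids) -> "FeatureTable":
        keep = [f for f in self.features.index if f not in set(feature_ids)]
        return self.subset(keep)

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.features.copy(), self.abundance.copy())

    # -- IO ----------------------------------------------------------------
    def to_csv(self, path) -> None:
        """Write rows=features: id, rt_s, mz, standard flags, sample columns."""
        out = self.features.copy()
        out.index.name = "feature_id"
        mat = self.abundance.T  # features x samples
        out = pd.concat([out, mat], axis=1)
        out.to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "FeatureTable":
        raw = pd.read_csv(path, index_col="feature_id")
        meta_cols = [c for c in FEATURE_META_COLS if c in raw.columns]
        features = raw[meta_cols].copy()
        if "is_standard" in features.columns:
            features["is_standard"] = features["is_standard"].astype(bool)
        sample_cols = [c for c in raw.columns if c not in meta_cols]
        abundance = raw[sample_cols].T
        abundance = abundance.astype(float)
        abundance.index.name = "sample_id"
        return cls(features=features, abundance=abundance)


def nominal_mass(mz) -> np.ndarray:
    """Nominal (integer) mass via half-up rounding.

    Half-up avoids the bankers-rounding parity artifacts of ``round`` at
    exact .5 fractional masses.
    """
    return np.floor(np.asarray(mz, dtype=float) + 0.5).astype(int)
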