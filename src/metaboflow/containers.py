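"""In-memory containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

PLATFORMS = ("lc_polar", "lc_lipid", "gc")


@dataclass
class FeatureTable:
    """Per-platform feature × injection intensity matrix with metadata.

    ``features``: indexed by feature_id with columns rt_min, mz, annotation,
    annotation_score, metabolite_class, carbons (NaN/None where absent).
    ``matrix``: features × injections, NaN marks a missing (undetected) cell.
    ``sample_meta``: indexed by injection sample_id with columns sample_type
    (bio / QC_blank / QC_mix / QC_NIST / QC_bio), group, hospital, sex, age,
    batch, injection_index, subject_id, concentration.
    """

    platform: str
    features: pd.DataFrame
    matrix: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.matrix.index.equals(self.features.index):
            raise ValueError("matrix rows must match feature metadata index")
        if not self.matrix.columns.equals(self.sample_meta.index):
            raise ValueError("matrix columns must match sample metadata index")
        if (self.features["rt_min"] < 0).any():
            raise ValueError("rt_min must be >= 0")
        vals = self.matrix.to_numpy(dtype=float)
        if np.any(vals[np.isfinite(vals)] < 0):
            raise ValueError("intensities must be positive where present")

    # -- convenience views -------------------------------------------------
    @property
    def n_features(self) -> int:
        return len(self.features)

    def columns_of_type(self, *types: str) -> pd.Index:
        mask = self.sample_meta["sample_type"].isin(types)
        return self.sample_meta.index[mask]

    @property
    def bio_columns(self) -> pd.Index:
        return self.columns_of_type("bio")

    def coverage(self) -> pd.Series:
        """Fraction of biological injections with a detected value, per feature."""
        bio = self.matrix[self.bio_columns]
        if bio.shape[1] == 0:
            raise ValueError("table has no biological injections")
        return bio.notna().mean(axis=1)

    def is_annotated(self) -> pd.Series:
        ann = self.features["annotation"]
        return ann.notna() & (ann.astype(str) != "")

    def subset_features(self, keep: pd.Index) -> "FeatureTable":
        return replace(
            self, features=self.features.loc[keep], matrix=self.matrix.loc[keep]
        )

    def subset_columns(self, keep: pd.Index) -> "FeatureTable":
        return replace(
            self, matrix=self.matrix[keep], sample_meta=self.sample_meta.loc[keep]
        )

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            platform=self.platform,
            features=self.features.copy(),
            matrix=self.matrix.copy(),
            sample_meta=self.sample_meta.copy(),
        )


@dataclass
class CurationResult:
    """Outcome of cross-platform merge and deduplication."""

    merged: FeatureTable
    kept: pd.DataFrame  # feature_id, platform, annotation, rule
    dropped: pd.DataFrame  # annotation, platform, rule
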