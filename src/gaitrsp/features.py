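"""Waveform feature reduction by principal component analysis.

Each sensor's cohort matrix (n subjects × 300 waveform points) is
column-standardized and decomposed into n−1 principal components, which
together retain 100% of the variance of a mean-centered rank-deficient
matrix.  PC scores, named ``B1..`` (back), ``T1..`` (thigh), ``S1..``
(shank), ``F1..`` (foot), are combined with the four baseline KOOS
subscales into the candidate feature table for classification.

Component signs are fixed deterministically (the largest-magnitude element
of every loading column is made positive) so selected-feature reports are
reproducible across runs and row permutations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .preprocessing import PLACEMENTS
from .synthetic_data import KOOS_SUBSCALES

SENSOR_PREFIX = {"back": "B", "thigh": "T", "shank": "S", "foot": "F"}


@dataclass
class PcaModel:
    """Standardization constants + loadings for one sensor's waveforms."""

    placement: str
    column_means: np.ndarray  # (300,)
    column_scales: np.ndarray  # (300,)
    loadings: np.ndarray  # 300 x (n-1), orthonormal columns
    explained_variance_ratio: np.ndarray  # (n-1,), non-increasing, sums to 1

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def feature_names(self) -> list:
        pre = SENSOR_PREFIX[self.placement]
        return [f"{pre}{k + 1}" for k in range(self.n_components)]


def _standardize(matrix: np.ndarray, means: np.ndarray, scales: np.ndarray) -> np.ndarray:
    return (matrix - means) / scales


def fit_pca(matrix, placement: str = "back", scale: bool = True) -> PcaModel:
    """Fit an n−1-component PCA to an n×300 waveform matrix.

    ``scale=True`` z-scores each column (constant columns get scale 1);
    ``scale=False`` mean-centers only.
    """
    X = np.asarray(matrix, dtype=float)
    n = X.shape[0]
    if n < 3:
        raise ValueError(f"PCA needs at least 3 subjects, got {n}")
    means = X.mean(axis=0)
    if scale:
        scales = X.std(axis=0, ddof=1)
        scales[scales == 0] = 1.0
    else:
        scales = np.ones(X.shape[1])
    Z = _standardize(X, means, scales)
    pca = PCA(n_components=n - 1, svd_solver="full")
    pca.fit(Z)
    loadings = pca.components_.T  # (300, n-1)
    # deterministic sign: largest-|.| element of each column positive
    flip = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(n - 1)])
    flip[flip == 0] = 1.0
    loadings = loadings * flip
    ev = pca.explained_variance_
    return PcaModel(
        placement=placement,
        column_means=means,
        column_scales=scales,
        loadings=loadings,
        explained_variance_ratio=ev / ev.sum(),
    )


def transform(model: PcaModel, matrix) -> np.ndarray:
    """Project waveforms onto the model's components: standardize·loadings."""
    X = np.atleast_2d(np.asarray(matrix, dtype=float))
    if X.shape[1] != model.column_means.shape[0]:
        raise ValueError(
            f"expected {model.column_means.shape[0]} waveform columns, got {X.shape[1]}"
        )
    return _standardize(X, model.column_means, model.column_scales) @ model.loadings


@dataclass
class FeatureTable:
    """Subjects × candidate features, with responder labels attached."""

    features: pd.DataFrame  # index subject_id, columns ordered deterministically
    labels: pd.Series  # index subject_id, values Non/Low/High
    pca_models: dict  # placement -> PcaModel (for the sensors included)

    def __post_init__(self):
        if self.features.isna().any().any():
            raise ValueError("feature table contains missing values")
        if len(set(self.features.columns)) != self.features.shape[1]:
            raise ValueError("feature names must be unique")
        if not self.features.index.equals(self.labels.index):
            raise ValueError("feature and label subject ids differ")

    @property
    def n_subjects(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def subset(self, columns) -> "FeatureTable":
        return FeatureTable(self.features[list(columns)], self.labels, self.pca_models)


def build_feature_table(
    waveforms: dict,
    koos_baseline: pd.DataFrame,
    labels: pd.Series,
    sensors=PLACEMENTS,
    scale: bool = True,
    pca_models: dict | None = None,
) -> FeatureTable:
    """Assemble the candidate feature table for a set of sensors.

    ``waveforms`` maps placement -> n×300 DataFrame (indexed by subject).
    Column order is deterministic: sensors in body order (back, thigh,
    shank, foot), PCs ascending within each, then the four KOOS baselines.
    Pre-fitted ``pca_models`` may be supplied (e.g. one cohort-level fit
    shared across sensor subsets); otherwise models are fit here.
    """
    sensors = [s for s in PLACEMENTS if s in set(sensors)]
    index = labels.index
    blocks, models = [], {}
    for s in sensors:
        wf = waveforms[s]
        missing = index.difference(wf.index)
        extra = wf.index.difference(index)
        if len(missing) or len(extra):
            raise ValueError(
                f"{s} waveforms subject mismatch: missing {sorted(missing)}, "
                f"unexpected {sorted(extra)}"
            )
        wf = wf.loc[index]
        model = (pca_models or {}).get(s) or fit_pca(wf.to_numpy(), placement=s, scale=scale)
        models[s] = model
        scores = transform(model, wf.to_numpy())
        blocks.append(pd.DataFrame(scores, index=index, columns=model.feature_names()))
    missing = index.difference(koos_baseline.index)
    if len(missing):
        raise ValueError(f"KOOS baseline missing subjects: {sorted(missing)}")
    koos = koos_baseline.loc[index, list(KOOS_SUBSCALES)]
    koos = koos.rename(columns={s: f"koos_{s}" for s in KOOS_SUBSCALES})
    blocks.append(koos)
    return FeatureTable(pd.concat(blocks, axis=1), labels, models)
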