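"""Voxelwise encoding models ("brain scores").

The brain score of a feature space X for subject s and voxel v is the
cross-validated Pearson correlation

    R(s, v) = corr(W . X, Y(s, v))

where W is a ridge regression fitted on training folds.  The pipeline per
outer training fold is (1) feature standardisation, (2) PCA to 20
components, (3) ridge regression whose penalty is chosen per voxel by
nested leave-one-out cross-validation over ten values log-spaced between
1e-1 and 1e8.  The outer scheme uses five *contiguous* folds of the time
series, which respects the temporal autocorrelation of BOLD: shuffled
folds would leak information between train and test scans.

Standardiser and PCA are fitted on the training rows of each outer fold
only, never on test rows.  Targets are centred on the training fold and
the ridge is fitted without an intercept, which keeps the efficient
leave-one-out identity exact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.linear_model import RidgeCV
from sklearn.preprocessing import StandardScaler

from .errors import InvalidInputError, InvalidParameterError, InvalidSplitError, ShapeError
from .stimuli import DesignMatrix

__all__ = [
    "BoldRun",
    "EncodingConfig",
    "EncodingModel",
    "ScoreMap",
    "contiguous_folds",
    "fit_ridge_cv",
    "brain_score",
]


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class BoldRun:
    """One subject's BOLD time series: ``T scans x V voxels`` at a given TR."""

    values: np.ndarray
    tr: float
    subject_id: str = "sub-00"
    story_ids: Optional[List] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise InvalidInputError("BOLD values must be a 2-D (scans x voxels) array")
        if not np.all(np.isfinite(self.values)):
            raise InvalidInputError("BOLD values must be finite")

    @property
    def n_scans(self) -> int:
        return self.values.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[1]


def _default_lambda_grid() -> np.ndarray:
    return np.logspace(-1, 8, 10)


@dataclass
class EncodingConfig:
    """Hyper-parameters of the encoding pipeline.

    Defaults follow the standard naturalistic-fMRI recipe: 5 contiguous
    outer folds, 20 principal components per feature block, ten ridge
    penalties log-spaced between 1e-1 and 1e8 selected per voxel by
    leave-one-out, and a 6-delay FIR expansion.
    """

    n_folds: int = 5
    n_components: int = 20
    lambda_grid: np.ndarray = field(default_factory=_default_lambda_grid)
    n_fir_delays: int = 6
    standardize: bool = True

    def __post_init__(self) -> None:
        self.lambda_grid = np.asarray(self.lambda_grid, dtype=float)
        if self.lambda_grid.ndim != 1 or len(self.lambda_grid) == 0:
            raise InvalidParameterError("lambda_grid must be a non-empty 1-D array")
        if np.any(self.lambda_grid <= 0):
            raise InvalidParameterError("lambda_grid must be strictly positive")
        if np.any(np.diff(self.lambda_grid) <= 0):
            raise InvalidParameterError("lambda_grid must be sorted ascending")
        if self.n_folds < 2:
            raise InvalidParameterError("n_folds must be >= 2")
        if self.n_components < 1:
            raise InvalidParameterError("n_components must be >= 1")


@dataclass
class EncodingModel:
    """A fitted ridge map: per-voxel penalty and weights."""

    weights: np.ndarray               # features x voxels
    chosen_lambda: np.ndarray         # per voxel
    loo_errors: Optional[np.ndarray] = None  # samples x voxels x lambdas


@dataclass
class ScoreMap:
    """Per-(subject, voxel) scalar scores, ``S x V``."""

    values: np.ndarray
    subjects: List[str]
    metadata: str = ""

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] != len(self.subjects):
            raise ShapeError("one row of scores per subject expected")

    @property
    def n_voxels(self) -> int:
        return self.values.shape[1]

    def group_mean(self) -> np.ndarray:
        return self.values.mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s, subj in enumerate(self.subjects):
            for v in range(self.n_voxels):
                rows.append((subj, v, self.values[s, v]))
        return pd.DataFrame(rows, columns=["subject", "voxel", "score"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Cross-validation plumbing
# ---------------------------------------------------------------------------

def contiguous_folds(T: int, k: int = 5) -> List[np.ndarray]:
    """Split ``0..T-1`` into ``k`` contiguous blocks with sizes differing by <= 1.

    The remainder goes to the leading blocks, e.g. T=11, k=5 gives sizes
    (3, 2, 2, 2, 2).
    """
    if k < 1:
        raise InvalidParameterError("k must be >= 1")
    if T < k:
        raise InvalidSplitError(f"cannot split {T} samples into {k} contiguous folds")
    return list(np.array_split(np.arange(T), k))


def fit_ridge_cv(
    design: np.ndarray,
    targets: np.ndarray,
    lambda_grid: Sequence[float] = None,
    store_loo: bool = False,
) -> EncodingModel:
    """Ridge regression with per-target leave-one-out penalty selection.

    For every target column the penalty minimising the exact leave-one-out
    squared error over the training rows is selected, then the weights are
    refitted on all rows at that penalty.  The caller is expected to have
    standardised/reduced the design and centred the targets (no intercept
    is fitted, which is what makes the efficient LOO identity exact).
    """
    design = np.asarray(design, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if targets.ndim == 1:
        targets = targets[:, None]
    if design.shape[0] != targets.shape[0]:
        raise ShapeError(
            f"design has {design.shape[0]} rows, targets have {targets.shape[0]}"
        )
    if lambda_grid is None:
        lambda_grid = _default_lambda_grid()
    ridge = RidgeCV(
        alphas=np.asarray(lambda_grid, dtype=float),
        fit_intercept=False,
        alpha_per_target=True,
        store_cv_results=store_loo,
    )
    ridge.fit(design, targets)
    coef = np.atleast_2d(ridge.coef_)
    chosen = np.atleast_1d(np.asarray(ridge.alpha_, dtype=float))
    if chosen.size == 1 and targets.shape[1] > 1:
        chosen = np.full(targets.shape[1], chosen[0])
    loo = getattr(ridge, "cv_results_", None) if store_loo else None
    if loo is not None and loo.ndim == 2:  # single target
        loo = loo[:, None, :]
    return EncodingModel(weights=coef.T, chosen_lambda=chosen, loo_errors=loo)


def _pearson_columns(pred: np.ndarray, actual: np.ndarray) -> np.ndarray:
    """Column-wise Pearson r; constant predictions give 0, constant targets NaN."""
    pred = pred - pred.mean(axis=0)
    actual = actual - actual.mean(axis=0)
    sp = np.sqrt((pred ** 2).sum(axis=0))
    sa = np.sqrt((actual ** 2).sum(axis=0))
    r = np.zeros(pred.shape[1])
    const_target = sa == 0
    const_pred = (sp == 0) & ~const_target
    ok = ~const_target & ~const_pred
    r[ok] = (pred[:, ok] * actual[:, ok]).sum(axis=0) / (sp[ok] * sa[ok])
    if const_pred.any():
        warnings.warn(
            f"{int(const_pred.sum())} voxel(s) had a constant prediction on a "
            "test fold; their fold correlation is defined as 0",
            RuntimeWarning,
            stacklevel=3,
        )
    if const_target.any():
        warnings.warn(
            f"{int(const_target.sum())} zero-variance voxel(s) on a test fold; "
            "their score is NaN",
            RuntimeWarning,
            stacklevel=3,
        )
        r[const_target] = np.nan
    return r


def _project_fold_block(
    block: np.ndarray,
    train: np.ndarray,
    test: np.ndarray,
    config: EncodingConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Standardise + PCA one feature block, fitted on the training rows only."""
    Xtr, Xte = block[train], block[test]
    if config.standardize:
        scaler = StandardScaler().fit(Xtr)
        Xtr = scaler.transform(Xtr)
        Xte = scaler.transform(Xte)
    n_comp = min(config.n_components, Xtr.shape[1], Xtr.shape[0])
    if n_comp < config.n_components:
        warnings.warn(
            f"PCA components clipped from {config.n_components} to {n_comp} "
            "(fewer features or samples than components)",
            RuntimeWarning,
            stacklevel=3,
        )
    pca = PCA(n_components=n_comp, random_state=0)
    Ztr = pca.fit_transform(Xtr)
    Zte = pca.transform(Xte)
    return Ztr, Zte


def fold_feature_projections(
    blocks: Sequence[np.ndarray],
    folds: Sequence[np.ndarray],
    config: EncodingConfig,
) -> List[tuple[np.ndarray, np.ndarray]]:
    """Per-fold projected features, blocks projected independently then stacked.

    Each block gets its own standardiser and PCA (fitted on the training
    rows of the fold); the reduced blocks are concatenated.  Computing this
    once per fold lets many subjects share the same projections.
    """
    T = blocks[0].shape[0]
    all_idx = np.arange(T)
    out = []
    for test in folds:
        train = np.setdiff1d(all_idx, test)
        parts = [_project_fold_block(np.asarray(b, float), train, test, config) for b in blocks]
        Ztr = np.hstack([p[0] for p in parts])
        Zte = np.hstack([p[1] for p in parts])
        out.append((Ztr, Zte))
    return out


def cv_fold_correlations(
    projections: Sequence[tuple[np.ndarray, np.ndarray]],
    folds: Sequence[np.ndarray],
    Y: np.ndarray,
    config: EncodingConfig,
) -> np.ndarray:
    """Per-fold per-voxel correlations for pre-projected features.

    Returns an ``n_folds x V`` array; the brain score is its column mean.
    """
    T = Y.shape[0]
    all_idx = np.arange(T)
    rows = []
    for (Ztr, Zte), test in zip(projections, folds):
        train = np.setdiff1d(all_idx, test)
        Ytr, Yte = Y[train], Y[test]
        mean = Ytr.mean(axis=0)
        model = fit_ridge_cv(Ztr, Ytr - mean, config.lambda_grid)
        pred = Zte @ model.weights + mean
        rows.append(_pearson_columns(pred, Yte))
    return np.vstack(rows)


def score_feature_blocks(
    blocks: Sequence[np.ndarray],
    runs: Sequence[BoldRun],
    config: EncodingConfig,
    projections=None,
    folds=None,
) -> ScoreMap:
    """Brain scores for a list of feature blocks shared by several subjects."""
    T = blocks[0].shape[0]
    for run in runs:
        if run.n_scans != T:
            raise ShapeError(
                f"features have {T} scans but run {run.subject_id} has {run.n_scans}"
            )
    if folds is None:
        folds = contiguous_folds(T, config.n_folds)
    if projections is None:
        projections = fold_feature_projections(blocks, folds, config)
    values = np.vstack(
        [cv_fold_correlations(projections, folds, run.values, config).mean(axis=0)
         for run in runs]
    )
    return ScoreMap(values=values, subjects=[r.subject_id for r in runs])


def brain_score(
    features: Union[DesignMatrix, np.ndarray],
    bold: Union[BoldRun, Sequence[BoldRun]],
    config: EncodingConfig = None,
) -> ScoreMap:
    """Cross-validated encoding score of a feature space, per subject and voxel.

    ``features`` is a (typically FIR-expanded) ``T x F`` design; ``bold``
    one run or a list of runs sharing the scan grid.  Returns an ``S x V``
    :class:`ScoreMap` of fold-averaged Pearson correlations.
    """
    if config is None:
        config = EncodingConfig()
    X = features.values if isinstance(features, DesignMatrix) else np.asarray(features, float)
    runs = [bold] if isinstance(bold, BoldRun) else list(bold)
    return score_feature_blocks([X], runs, config)
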