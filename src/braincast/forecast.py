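"""Forecast windows, forecast scores and distance/depth maps.

A forecast window at distance d with width w concatenates the activations
of w consecutive words, the last one d words after the current word:

    Xtilde(d)_n = X[n+d-w+1] (+) ... (+) X[n+d]

The forecast score F(d) is the gain in brain score from appending the
window to the present-word activations:

    F(d) = R(X (+) Xtilde(d)) - R(X)

with the PCA of the encoding pipeline fitted on X and Xtilde *separately*
before concatenation (so both blocks contribute the same number of
components), and identical folds for both terms.  The forecast distance
d* is the argmax of F(d) over an integer grid (negative d = past-only
windows), and the forecast depth k* is the argmax over model layers of
F at a fixed reference distance.  Because the argmax of a flat curve is
meaningless, distance/depth maps carry a significance mask based on the
across-subject contrast F(reference) - F(baseline).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .encoding import (
    BoldRun,
    EncodingConfig,
    ScoreMap,
    contiguous_folds,
    fold_feature_projections,
    score_feature_blocks,
)
from .errors import (
    InvalidCurveError,
    InvalidInputError,
    InvalidParameterError,
    ShapeError,
)
from .group_stats import GroupResult, group_significance
from .stimuli import Stimulus, fir_expand, pool_words_to_scans

__all__ = [
    "ForecastConfig",
    "ForecastWindow",
    "ForecastCurve",
    "DistanceMap",
    "DepthMap",
    "build_forecast_window",
    "forecast_score",
    "forecast_curves",
    "forecast_distance_map",
    "forecast_depth_curves",
    "forecast_depth_map",
]


@dataclass
class ForecastConfig:
    """Grid and window parameters of the forecast analysis."""

    width: int = 7
    distance_grid: np.ndarray = field(default_factory=lambda: np.arange(-10, 31))
    depth_grid: np.ndarray = field(default_factory=lambda: np.arange(0, 13))
    reference_distance: int = 8
    baseline_distance: int = 0

    def __post_init__(self) -> None:
        self.distance_grid = np.asarray(self.distance_grid, dtype=int)
        self.depth_grid = np.asarray(self.depth_grid, dtype=int)
        if self.width < 1:
            raise InvalidParameterError("window width must be >= 1")
        for d in (self.reference_distance, self.baseline_distance):
            if d not in self.distance_grid:
                raise InvalidParameterError(
                    f"distance {d} not in the distance grid"
                )


@dataclass
class ForecastWindow:
    """Concatenated activations of ``width`` words ending ``distance`` ahead."""

    values: np.ndarray            # M x (width * U)
    distance: int
    width: int
    source_layer: Optional[int] = None


@dataclass
class ForecastCurve:
    """Forecast scores over the distance grid: ``S subjects x V voxels x D``."""

    values: np.ndarray
    distance_grid: np.ndarray
    subjects: List[str]
    baseline: Optional[ScoreMap] = None  # R(X), same folds

    def score_at(self, d: int) -> np.ndarray:
        idx = np.nonzero(self.distance_grid == d)[0]
        if len(idx) == 0:
            raise InvalidCurveError(f"distance {d} not in curve grid")
        return self.values[:, :, idx[0]]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s, subj in enumerate(self.subjects):
            for v in range(self.values.shape[1]):
                for j, d in enumerate(self.distance_grid):
                    rows.append((subj, v, int(d), self.values[s, v, j]))
        return pd.DataFrame(rows, columns=["subject", "voxel", "d", "F"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class DistanceMap:
    """Per-(subject, voxel) optimal forecast distance with a group mask."""

    dstar: np.ndarray             # S x V
    mask: np.ndarray              # V, True where the F(ref)-F(base) contrast survives FDR
    subjects: List[str]
    group_result: Optional[GroupResult] = None

    def group_mean(self) -> np.ndarray:
        """Mean d* across subjects; NaN where the voxel is masked out."""
        mean = self.dstar.mean(axis=0).astype(float)
        mean[~self.mask] = np.nan
        return mean

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s, subj in enumerate(self.subjects):
            for v in range(self.dstar.shape[1]):
                rows.append((subj, v, int(self.dstar[s, v]), bool(~self.mask[v])))
        return pd.DataFrame(rows, columns=["subject", "voxel", "dstar", "masked"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class DepthMap:
    """Per-(subject, voxel) optimal forecast depth with a group mask."""

    kstar: np.ndarray             # S x V
    mask: np.ndarray              # V
    subjects: List[str]
    group_result: Optional[GroupResult] = None

    def group_mean(self) -> np.ndarray:
        mean = self.kstar.mean(axis=0).astype(float)
        mean[~self.mask] = np.nan
        return mean

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s, subj in enumerate(self.subjects):
            for v in range(self.kstar.shape[1]):
                rows.append((subj, v, int(self.kstar[s, v]), bool(~self.mask[v])))
        return pd.DataFrame(rows, columns=["subject", "voxel", "kstar", "masked"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Window construction
# ---------------------------------------------------------------------------

def build_forecast_window(
    X: np.ndarray,
    stimulus: Stimulus,
    d: int,
    w: int = 7,
    source_layer: Optional[int] = None,
) -> ForecastWindow:
    """Concatenate the activations of words ``n+d-w+1 .. n+d`` for each word n.

    Positions outside the current story (before its first word or after its
    last) are zero-filled; windows never mix words across stories.  ``d``
    may be negative, in which case the window holds only past words.
    """
    if w < 1:
        raise InvalidParameterError("window width must be >= 1")
    X = np.asarray(X, dtype=float)
    M, U = X.shape
    if M != stimulus.n_words:
        raise ShapeError(f"X has {M} rows but stimulus has {stimulus.n_words} words")
    story = stimulus.story_index()
    n = np.arange(M)
    blocks = []
    for j in range(w):
        offset = d - w + 1 + j
        src = n + offset
        valid = (src >= 0) & (src < M)
        src_clipped = np.clip(src, 0, M - 1)
        valid &= story[src_clipped] == story
        block = np.zeros((M, U))
        block[valid] = X[src_clipped[valid]]
        blocks.append(block)
    return ForecastWindow(
        values=np.hstack(blocks), distance=int(d), width=int(w),
        source_layer=source_layer,
    )


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def _word_block_to_design(
    values: np.ndarray, stimulus: Stimulus, tr: float, n_scans: int, n_delays: int
) -> np.ndarray:
    pooled = pool_words_to_scans(values, stimulus, tr, n_scans)
    return fir_expand(pooled, n_delays).values


def _check_runs(runs: Sequence[BoldRun]) -> None:
    if len(runs) == 0:
        raise InvalidInputError("at least one BOLD run is required")
    T = runs[0].n_scans
    if any(r.n_scans != T for r in runs):
        raise ShapeError("all BOLD runs must share the scan count")


def forecast_score(
    X: np.ndarray,
    window: ForecastWindow,
    stimulus: Stimulus,
    bold: Sequence[BoldRun] | BoldRun,
    config: EncodingConfig = None,
    baseline: Optional[ScoreMap] = None,
) -> ScoreMap:
    """Gain in brain score from appending one forecast window to X.

    X and the window are pooled to the scan grid and FIR-expanded in the
    same way; each block is reduced by its own standardiser + PCA before
    concatenation, and both terms of the difference use identical folds.
    ``baseline`` (the plain brain score of X) can be passed to avoid
    recomputing it across distances.
    """
    if config is None:
        config = EncodingConfig()
    runs = [bold] if isinstance(bold, BoldRun) else list(bold)
    _check_runs(runs)
    if window.values.shape[0] != np.asarray(X).shape[0]:
        raise ShapeError("X and window must cover the same words")
    T = runs[0].n_scans
    tr = runs[0].tr
    design_x = _word_block_to_design(X, stimulus, tr, T, config.n_fir_delays)
    design_w = _word_block_to_design(window.values, stimulus, tr, T, config.n_fir_delays)
    if baseline is None:
        baseline = score_feature_blocks([design_x], runs, config)
    enhanced = score_feature_blocks([design_x, design_w], runs, config)
    return ScoreMap(
        values=enhanced.values - baseline.values,
        subjects=enhanced.subjects,
        metadata=f"forecast score, d={window.distance}, w={window.width}",
    )


def forecast_curves(
    X: np.ndarray,
    stimulus: Stimulus,
    bold: Sequence[BoldRun],
    enc_config: EncodingConfig = None,
    fc_config: ForecastConfig = None,
    window_source: Optional[np.ndarray] = None,
) -> ForecastCurve:
    """Forecast scores over the whole distance grid, sharing folds and baseline.

    ``window_source`` defaults to ``X`` itself; passing a different matrix
    supports component windows (e.g. syntactic or semantic activations).
    The per-fold projection of the X block is computed once and reused for
    every distance, which is what makes the full grid tractable.
    """
    if enc_config is None:
        enc_config = EncodingConfig()
    if fc_config is None:
        fc_config = ForecastConfig()
    runs = list(bold)
    _check_runs(runs)
    source = X if window_source is None else window_source
    T, tr = runs[0].n_scans, runs[0].tr
    folds = contiguous_folds(T, enc_config.n_folds)
    design_x = _word_block_to_design(X, stimulus, tr, T, enc_config.n_fir_delays)
    proj_x = fold_feature_projections([design_x], folds, enc_config)
    baseline = score_feature_blocks(
        [design_x], runs, enc_config, projections=proj_x, folds=folds
    )
    S, V = baseline.values.shape
    grid = fc_config.distance_grid
    values = np.empty((S, V, len(grid)))
    for j, d in enumerate(grid):
        window = build_forecast_window(source, stimulus, int(d), fc_config.width)
        design_w = _word_block_to_design(
            window.values, stimulus, tr, T, enc_config.n_fir_delays
        )
        proj_w = fold_feature_projections([design_w], folds, enc_config)
        proj = [
            (np.hstack([zx_tr, zw_tr]), np.hstack([zx_te, zw_te]))
            for (zx_tr, zx_te), (zw_tr, zw_te) in zip(proj_x, proj_w)
        ]
        enhanced = score_feature_blocks(
            [design_x, design_w], runs, enc_config, projections=proj, folds=folds
        )
        values[:, :, j] = enhanced.values - baseline.values
    return ForecastCurve(
        values=values,
        distance_grid=grid.copy(),
        subjects=baseline.subjects,
        baseline=baseline,
    )


# ---------------------------------------------------------------------------
# Argmax maps
# ---------------------------------------------------------------------------

def forecast_distance_map(
    curves: ForecastCurve,
    config: ForecastConfig = None,
    group_p_threshold: float = 0.01,
) -> DistanceMap:
    """Per-voxel optimal forecast distance d*, with a flatness mask.

    d* is the argmax of F(d) over the grid (ties broken toward the smallest
    distance).  Voxels whose across-subject contrast F(reference) -
    F(baseline) does not survive FDR at ``group_p_threshold`` are masked:
    the argmax of a flat curve carries no information.
    """
    if config is None:
        config = ForecastConfig()
    if not np.array_equal(np.sort(curves.distance_grid), np.sort(config.distance_grid)):
        raise InvalidCurveError(
            "curves do not cover the configured distance grid"
        )
    order = np.argsort(curves.distance_grid, kind="stable")
    grid = curves.distance_grid[order]
    vals = curves.values[:, :, order]
    dstar = grid[np.argmax(vals, axis=2)]
    contrast = curves.score_at(config.reference_distance) - curves.score_at(
        config.baseline_distance
    )
    group = group_significance(contrast, threshold=group_p_threshold)
    return DistanceMap(
        dstar=dstar, mask=group.mask, subjects=curves.subjects, group_result=group
    )


def forecast_depth_curves(
    activations: Mapping[int, np.ndarray],
    stimulus: Stimulus,
    bold: Sequence[BoldRun],
    enc_config: EncodingConfig = None,
    fc_config: ForecastConfig = None,
    distance: Optional[int] = None,
) -> Dict[int, ScoreMap]:
    """F(reference distance) per layer: k -> ScoreMap of forecast scores.

    For each layer k, both the present-word features and the window are
    taken from layer k (the score measures how well that level of
    representation forecasts, not a cross-layer transfer).
    """
    if enc_config is None:
        enc_config = EncodingConfig()
    if fc_config is None:
        fc_config = ForecastConfig()
    if distance is None:
        distance = fc_config.reference_distance
    runs = list(bold)
    _check_runs(runs)
    T, tr = runs[0].n_scans, runs[0].tr
    folds = contiguous_folds(T, enc_config.n_folds)
    out: Dict[int, ScoreMap] = {}
    for k in fc_config.depth_grid:
        k = int(k)
        if k not in activations:
            raise InvalidInputError(f"layer {k} missing from activations")
        Xk = np.asarray(activations[k], dtype=float)
        design_x = _word_block_to_design(Xk, stimulus, tr, T, enc_config.n_fir_delays)
        proj_x = fold_feature_projections([design_x], folds, enc_config)
        baseline = score_feature_blocks(
            [design_x], runs, enc_config, projections=proj_x, folds=folds
        )
        window = build_forecast_window(Xk, stimulus, distance, fc_config.width, k)
        design_w = _word_block_to_design(
            window.values, stimulus, tr, T, enc_config.n_fir_delays
        )
        proj_w = fold_feature_projections([design_w], folds, enc_config)
        proj = [
            (np.hstack([a, c]), np.hstack([b, d]))
            for (a, b), (c, d) in zip(proj_x, proj_w)
        ]
        enhanced = score_feature_blocks(
            [design_x, design_w], runs, enc_config, projections=proj, folds=folds
        )
        out[k] = ScoreMap(
            values=enhanced.values - baseline.values,
            subjects=enhanced.subjects,
            metadata=f"forecast score, layer {k}, d={distance}",
        )
    return out


def forecast_depth_map(
    layer_scores: Mapping[int, ScoreMap],
    config: ForecastConfig = None,
    mask: Optional[np.ndarray] = None,
    group_p_threshold: float = 0.01,
) -> DepthMap:
    """Per-voxel optimal forecast depth k* (ties toward the shallowest layer).

    ``layer_scores`` maps each layer of the depth grid to its forecast
    scores at the reference distance.  The significance mask follows the
    distance-map convention; if the distance analysis' mask is available it
    can be passed in, otherwise voxels where the best layer's forecast
    score is not significantly non-zero across subjects are masked.
    """
    if config is None:
        config = ForecastConfig()
    missing = [int(k) for k in config.depth_grid if int(k) not in layer_scores]
    if missing:
        raise InvalidInputError(f"layers {missing} missing from layer scores")
    ks = [int(k) for k in np.sort(config.depth_grid)]
    stack = np.stack([layer_scores[k].values for k in ks], axis=2)  # S x V x K
    kstar = np.asarray(ks)[np.argmax(stack, axis=2)]
    subjects = layer_scores[ks[0]].subjects
    group = None
    if mask is None:
        best = stack.max(axis=2)
        group = group_significance(best, threshold=group_p_threshold)
        mask = group.mask
    return DepthMap(kstar=kstar, mask=np.asarray(mask, bool), subjects=subjects,
                    group_result=group)
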