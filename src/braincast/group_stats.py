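"""Group-level inference and ROI summaries.

Per-voxel metrics (brain scores, forecast scores, their differences) are
computed per individual; group inference asks whether the metric differs
from zero across individuals.  One-sample and paired contrasts use the
two-sided Wilcoxon signed-rank test; independent groups use the Wilcoxon
rank-sum test.  P values are corrected across voxels with the
Benjamini-Hochberg false discovery rate and an effect is called
significant when the corrected p falls below the threshold (0.01 by
default).  95% confidence intervals of the across-subject mean use the t
distribution.

The module also provides an anatomical-parcellation splitter (regions
larger than a vertex budget are recursively bisected along their principal
spatial axis) and ROI summaries over random subject subdivisions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from statsmodels.stats.multitest import multipletests

from .errors import InvalidInputError, InvalidParameterError, ShapeError

__all__ = [
    "GroupResult",
    "Parcellation",
    "group_significance",
    "compare_groups",
    "split_parcellation",
    "roi_summary",
]


@dataclass
class GroupResult:
    """Per-voxel (or per-region) group statistics."""

    statistic: np.ndarray
    p_value: np.ndarray
    fdr_q: np.ndarray
    mask: np.ndarray
    ci_low: Optional[np.ndarray] = None
    ci_high: Optional[np.ndarray] = None
    threshold: float = 0.01


@dataclass
class Parcellation:
    """Voxel-to-region labels, with optional geometry.

    ``coords`` (V x ndim) enables principal-axis splitting; ``adjacency``
    is an (E, 2) array of neighbouring voxel index pairs used for
    contiguity checks and as a splitting fallback.
    """

    labels: np.ndarray
    names: Optional[Dict] = None
    coords: Optional[np.ndarray] = None
    adjacency: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=float)
            if self.coords.shape[0] != len(self.labels):
                raise ShapeError("coords must have one row per voxel")
        if self.adjacency is not None:
            self.adjacency = np.asarray(self.adjacency, dtype=np.intp)

    @property
    def n_voxels(self) -> int:
        return len(self.labels)

    def region_sizes(self) -> Dict:
        uniq, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(uniq.tolist(), counts.tolist()))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"voxel": np.arange(self.n_voxels), "region": self.labels})

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "Parcellation":
        df = pd.read_csv(path, sep="\t")
        return cls(labels=df["region"].to_numpy())


def _t_confidence_interval(values: np.ndarray, level: float = 0.95):
    n = values.shape[0]
    mean = values.mean(axis=0)
    sem = values.std(axis=0, ddof=1) / np.sqrt(n)
    half = stats.t.ppf(0.5 + level / 2, df=n - 1) * sem
    return mean - half, mean + half


def _signed_rank_p(diffs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided Wilcoxon signed-rank per column; all-zero columns give p=1."""
    diffs = np.atleast_2d(diffs)
    n_col = diffs.shape[1]
    statistic = np.empty(n_col)
    p_value = np.empty(n_col)
    all_zero = np.all(diffs == 0, axis=0)
    if all_zero.any():
        warnings.warn(
            f"{int(all_zero.sum())} column(s) have all-zero differences; "
            "their p value is 1 by convention",
            RuntimeWarning,
            stacklevel=3,
        )
    for j in range(n_col):
        if all_zero[j]:
            statistic[j], p_value[j] = 0.0, 1.0
            continue
        res = stats.wilcoxon(diffs[:, j], alternative="two-sided")
        statistic[j], p_value[j] = res.statistic, res.pvalue
    return statistic, p_value


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p values (q values)."""
    return multipletests(np.asarray(p_values, float), method="fdr_bh")[1]


def group_significance(
    score_maps: np.ndarray,
    null_value: float = 0.0,
    threshold: float = 0.01,
    ci_level: float = 0.95,
) -> GroupResult:
    """Across-subject test of per-voxel values against a null value.

    ``score_maps`` is an ``S subjects x V voxels`` array.  Each voxel gets a
    two-sided Wilcoxon signed-rank test of (value - null_value) across
    subjects; p values are BH-FDR corrected across voxels and the mask
    keeps voxels with corrected p below ``threshold``.
    """
    values = np.atleast_2d(np.asarray(score_maps, dtype=float))
    if values.shape[0] < 6:
        raise InvalidInputError(
            f"group tests need >= 6 subjects, got {values.shape[0]}"
        )
    diffs = values - null_value
    statistic, p_value = _signed_rank_p(diffs)
    q = benjamini_hochberg(p_value)
    lo, hi = _t_confidence_interval(values, ci_level)
    return GroupResult(
        statistic=statistic,
        p_value=p_value,
        fdr_q=q,
        mask=q < threshold,
        ci_low=lo,
        ci_high=hi,
        threshold=threshold,
    )


def compare_groups(
    values_a: np.ndarray,
    values_b: np.ndarray,
    paired: bool = False,
    threshold: float = 0.01,
) -> GroupResult:
    """Two-group comparison, per column when the inputs are 2-D.

    Paired comparisons use the signed-rank test on differences (and
    require equal lengths); independent comparisons use the rank-sum test.
    When several columns (voxels/regions) are tested, p values are BH-FDR
    corrected across columns.
    """
    a = np.atleast_2d(np.asarray(values_a, dtype=float))
    b = np.atleast_2d(np.asarray(values_b, dtype=float))
    if np.asarray(values_a).ndim == 1:
        a, b = a.T, b.T
    if a.shape[1] != b.shape[1]:
        raise ShapeError("both groups must have the same number of columns")
    if paired:
        if a.shape[0] != b.shape[0]:
            raise ShapeError("paired comparison requires equal group sizes")
        statistic, p_value = _signed_rank_p(a - b)
        lo, hi = _t_confidence_interval(a - b)
    else:
        res = stats.ranksums(a, b, axis=0)
        statistic = np.atleast_1d(res.statistic)
        p_value = np.atleast_1d(res.pvalue)
        lo = hi = None
    q = benjamini_hochberg(p_value)
    return GroupResult(
        statistic=statistic, p_value=p_value, fdr_q=q, mask=q < threshold,
        ci_low=lo, ci_high=hi, threshold=threshold,
    )


# ---------------------------------------------------------------------------
# Parcellation splitting
# ---------------------------------------------------------------------------

def _principal_axis_order(idx: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Indices ordered along the first principal axis of their coordinates."""
    pts = coords[idx]
    centred = pts - pts.mean(axis=0)
    # first right-singular vector = principal spatial axis
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    proj = centred @ vt[0]
    return idx[np.argsort(proj, kind="stable")]


def _fiedler_order(idx: np.ndarray, adjacency: np.ndarray) -> np.ndarray:
    """Indices ordered by the Fiedler vector of the subgraph Laplacian."""
    pos = {v: i for i, v in enumerate(idx)}
    n = len(idx)
    deg = np.zeros(n)
    lap = np.zeros((n, n))
    for u, v in adjacency:
        if u in pos and v in pos:
            i, j = pos[u], pos[v]
            lap[i, j] -= 1
            lap[j, i] -= 1
            deg[i] += 1
            deg[j] += 1
    lap[np.diag_indices(n)] = deg
    _, vecs = np.linalg.eigh(lap)
    fiedler = vecs[:, 1] if n > 1 else np.zeros(n)
    return idx[np.argsort(fiedler, kind="stable")]


def _components(idx: np.ndarray, adjacency: Optional[np.ndarray]) -> List[np.ndarray]:
    if adjacency is None:
        return [idx]
    pos = {v: i for i, v in enumerate(idx)}
    edges = [(pos[u], pos[v]) for u, v in adjacency if u in pos and v in pos]
    n = len(idx)
    if not edges:
        return [idx[[i]] for i in range(n)] if n > 1 else [idx]
    rows, cols = zip(*edges)
    graph = coo_matrix((np.ones(len(edges)), (rows, cols)), shape=(n, n))
    n_comp, labels = connected_components(graph, directed=False)
    return [idx[labels == c] for c in range(n_comp)]


def split_parcellation(parcellation: Parcellation, max_vertices: int = 500) -> Parcellation:
    """Split oversized regions until every region has at most ``max_vertices``.

    An oversized region of n vertices is cut into ceil(n / max_vertices)
    equal slabs along its principal spatial axis (without coordinates,
    along the Fiedler vector of the adjacency subgraph, a balanced graph
    partition).  Disconnected regions are split within their connected
    components first, with a warning.  Vertex count and membership are
    conserved; sub-regions are named ``<region>/0``, ``<region>/1``, ...
    """
    if max_vertices < 1:
        raise InvalidParameterError("max_vertices must be >= 1")
    if parcellation.coords is None and parcellation.adjacency is None:
        raise InvalidInputError(
            "splitting needs voxel coordinates or an adjacency list"
        )
    labels = parcellation.labels.astype(object).copy()

    def bisect(idx: np.ndarray) -> List[np.ndarray]:
        if len(idx) <= max_vertices:
            return [idx]
        if parcellation.coords is not None:
            ordered = _principal_axis_order(idx, parcellation.coords)
        else:
            ordered = _fiedler_order(idx, parcellation.adjacency)
        n_parts = int(np.ceil(len(idx) / max_vertices))
        parts = np.array_split(ordered, n_parts)
        out: List[np.ndarray] = []
        for part in parts:  # equal slabs are already <= max_vertices
            out.extend(bisect(part))
        return out

    for region in np.unique(parcellation.labels):
        idx = np.nonzero(parcellation.labels == region)[0]
        if len(idx) <= max_vertices:
            continue
        comps = _components(idx, parcellation.adjacency)
        if len(comps) > 1:
            warnings.warn(
                f"region {region!r} is disconnected; splitting within its "
                f"{len(comps)} components",
                RuntimeWarning,
                stacklevel=2,
            )
        parts: List[np.ndarray] = []
        for comp in comps:
            parts.extend(bisect(comp))
        if len(parts) == 1:
            continue
        for p, part in enumerate(parts):
            labels[part] = f"{region}/{p}"
    return Parcellation(
        labels=labels,
        names=parcellation.names,
        coords=parcellation.coords,
        adjacency=parcellation.adjacency,
    )


# ---------------------------------------------------------------------------
# ROI summaries
# ---------------------------------------------------------------------------

def roi_summary(
    score_map: np.ndarray,
    parcellation: Parcellation,
    rois: Sequence,
    n_subdivisions: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean score per ROI, per subject and per random subject subdivision.

    Returns a tidy table with one row per (roi, subject) carrying the
    subject-level ROI mean, and one row per (roi, subdivision) carrying the
    mean over a random disjoint subject group.  The ``n_subdivisions``
    groups partition the subjects (seeded permutation), mirroring the
    boxplot-over-random-subdivisions convention of group reports.
    """
    values = np.atleast_2d(np.asarray(score_map, dtype=float))
    S = values.shape[0]
    if values.shape[1] != parcellation.n_voxels:
        raise ShapeError("score map and parcellation disagree on voxel count")
    missing = [r for r in rois if r not in parcellation.labels]
    if missing:
        raise InvalidInputError(f"ROIs {missing} absent from the parcellation")
    rng = np.random.default_rng(seed)
    groups = np.array_split(rng.permutation(S), n_subdivisions)
    rows = []
    for roi in rois:
        sel = parcellation.labels == roi
        if not sel.any():
            warnings.warn(f"ROI {roi!r} is empty; its mean is NaN", RuntimeWarning)
            roi_means = np.full(S, np.nan)
        else:
            roi_means = values[:, sel].mean(axis=1)
        for s in range(S):
            rows.append((roi, "subject", s, roi_means[s]))
        for g, members in enumerate(groups):
            mean = roi_means[members].mean() if len(members) else np.nan
            rows.append((roi, "subdivision", g, mean))
    return pd.DataFrame(rows, columns=["roi", "unit", "index", "mean_score"])
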