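"""Noise-ceiling estimation by cross-subject prediction.

The explainable signal of a voxel is bounded by how well it can be
predicted from *other brains* hearing the same stories.  For each subject
the predictor is the average BOLD of all other subjects, passed through
the same standardise + PCA + ridge + contiguous-5-fold scheme as the
encoding models; no FIR expansion is applied because the hemodynamic
delay is assumed comparable across individuals.  The resulting per-voxel
correlation is one possible upper bound on the brain score attainable at
the dataset's noise level.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .encoding import BoldRun, EncodingConfig, ScoreMap, score_feature_blocks
from .errors import InvalidInputError, ShapeError

__all__ = ["noise_ceiling"]


def noise_ceiling(
    runs: Sequence[BoldRun],
    config: EncodingConfig = None,
) -> ScoreMap:
    """Per-subject, per-voxel noise ceiling from the average of other subjects.

    ``runs`` must be aligned to the same stories (equal scan counts).
    Returns an ``S x V`` :class:`ScoreMap` of cross-validated correlations
    between each subject's BOLD and its ridge prediction from the mean of
    the other subjects' BOLD.
    """
    if config is None:
        config = EncodingConfig()
    runs = list(runs)
    if len(runs) < 2:
        raise InvalidInputError("the noise ceiling needs at least 2 subjects")
    T = runs[0].n_scans
    V = runs[0].n_voxels
    for run in runs:
        if run.n_scans != T or run.n_voxels != V:
            raise ShapeError("all runs must share the scan and voxel counts")
    stack = np.stack([r.values for r in runs])          # S x T x V
    total = stack.sum(axis=0)
    values = []
    for s, run in enumerate(runs):
        others_mean = (total - stack[s]) / (len(runs) - 1)
        score = score_feature_blocks([others_mean], [run], config)
        values.append(score.values[0])
    return ScoreMap(
        values=np.vstack(values),
        subjects=[r.subject_id for r in runs],
        metadata="noise ceiling (mean of other subjects, no FIR)",
    )
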