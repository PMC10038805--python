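"""File adapters: events TSV and an HDF5 container for activations/BOLD.

Layout of the HDF5 container:

    /activations/<story>/<layer>   M_story x U float arrays
    /bold/<subject>                T x V float arrays

with root attributes ``tr``, ``dim`` and ``seed``.  Stimuli travel as
BIDS-style events TSV (columns ``story_id, word, onset, offset``); score
maps, curves and argmax maps as plain TSV via their ``to_tsv`` methods.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import h5py
import numpy as np
import pandas as pd

from .encoding import BoldRun
from .errors import InvalidInputError
from .stimuli import LayeredActivations, Stimulus

__all__ = [
    "write_dataset",
    "read_activations",
    "read_bold",
    "write_score_tsv",
    "read_score_tsv",
]


def write_dataset(
    path,
    stimulus: Stimulus,
    activations: Optional[LayeredActivations] = None,
    runs: Optional[Sequence[BoldRun]] = None,
    tr: Optional[float] = None,
    seed: Optional[int] = None,
) -> None:
    """Write activations and/or BOLD runs to one HDF5 container."""
    story = stimulus.story_index()
    with h5py.File(path, "w") as f:
        if activations is not None:
            grp = f.create_group("activations")
            for sid in stimulus.story_ids:
                sub = grp.create_group(str(sid))
                sel = story == stimulus.story_ids.index(sid)
                for k in activations.layer_indices:
                    sub.create_dataset(str(k), data=activations[k][sel])
            f.attrs["dim"] = activations.n_units
            f.attrs["model_name"] = activations.model_name
        if runs:
            grp = f.create_group("bold")
            for run in runs:
                grp.create_dataset(str(run.subject_id), data=run.values)
            f.attrs["tr"] = runs[0].tr
        if tr is not None:
            f.attrs["tr"] = tr
        if seed is not None:
            f.attrs["seed"] = seed


def read_activations(path, stimulus: Stimulus) -> LayeredActivations:
    """Re-assemble per-story activation groups into word order."""
    story = stimulus.story_index()
    with h5py.File(path, "r") as f:
        if "activations" not in f:
            raise InvalidInputError(f"{path} holds no /activations group")
        grp = f["activations"]
        layer_names = None
        per_story: Dict[str, Dict[int, np.ndarray]] = {}
        for sid in grp:
            layers = {int(k): grp[sid][k][()] for k in grp[sid]}
            per_story[sid] = layers
            layer_names = sorted(layers)
        model_name = f.attrs.get("model_name", "unknown")
    M = stimulus.n_words
    out = {}
    for k in layer_names:
        dim = next(iter(per_story.values()))[k].shape[1]
        arr = np.zeros((M, dim))
        for i, sid in enumerate(stimulus.story_ids):
            arr[story == i] = per_story[str(sid)][k]
        out[k] = arr
    return LayeredActivations(out, model_name=str(model_name))


def read_bold(path) -> List[BoldRun]:
    with h5py.File(path, "r") as f:
        if "bold" not in f:
            raise InvalidInputError(f"{path} holds no /bold group")
        tr = float(f.attrs["tr"])
        return [
            BoldRun(values=f["bold"][sid][()], tr=tr, subject_id=str(sid))
            for sid in f["bold"]
        ]


def write_score_tsv(path, frame: pd.DataFrame) -> None:
    frame.to_csv(path, sep="\t", index=False)


def read_score_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
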