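"""Stimuli, language-model activations and alignment to the scan grid.

This module holds the word-level side of the encoding pipeline:

* :class:`Stimulus` — a word-timed transcript (story, word, onset, offset);
* :func:`clean_transcript` — punctuation normalisation applied before
  tokenisation;
* :func:`extract_activations` — run a causal language-model adapter over a
  stimulus and collect one hidden-state vector per word and layer;
* :func:`pool_words_to_scans` — sum word vectors into TR bins;
* :func:`fir_expand` — finite-impulse-response lag expansion of the scan
  matrix, which models the slow hemodynamic response without committing to
  a canonical HRF shape.

Conventions: scans and words are 0-indexed; TR bins are half-open
``[t*tr, (t+1)*tr)`` and words are assigned to bins by their *onset*.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Protocol, Sequence

import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    CoverageError,
    InvalidInputError,
    InvalidParameterError,
    ShapeError,
)

__all__ = [
    "Stimulus",
    "LayeredActivations",
    "ScanMatrix",
    "DesignMatrix",
    "clean_transcript",
    "LanguageModelAdapter",
    "FakeCausalLM",
    "OneHotLM",
    "extract_activations",
    "pool_words_to_scans",
    "fir_expand",
]


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class Stimulus:
    """A word-timed transcript covering one or more stories.

    ``words`` is a DataFrame with columns ``story_id, word, onset, offset``
    (onsets/offsets in seconds on a single continuous timeline).  Onsets are
    non-decreasing within each story and offsets never precede onsets.
    """

    words: pd.DataFrame

    REQUIRED_COLUMNS = ("story_id", "word", "onset", "offset")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED_COLUMNS if c not in self.words.columns]
        if missing:
            raise InvalidInputError(f"stimulus table is missing columns {missing}")
        if len(self.words) == 0:
            raise InvalidInputError("stimulus contains no words")
        self.words = self.words.reset_index(drop=True)
        for _, grp in self.words.groupby("story_id", sort=False):
            onsets = grp["onset"].to_numpy(float)
            if np.any(np.diff(onsets) < 0):
                raise InvalidInputError("onsets must be non-decreasing within a story")
        if np.any(self.words["offset"].to_numpy(float) < self.words["onset"].to_numpy(float)):
            raise InvalidInputError("offsets must be >= onsets")

    @property
    def n_words(self) -> int:
        return len(self.words)

    # alias used throughout the encoding literature: M words
    M = n_words

    @property
    def story_ids(self) -> List:
        seen: List = []
        for s in self.words["story_id"]:
            if s not in seen:
                seen.append(s)
        return seen

    def story_index(self) -> np.ndarray:
        """Integer story code per word, in order of first appearance."""
        ids = self.story_ids
        lut = {s: i for i, s in enumerate(ids)}
        return np.array([lut[s] for s in self.words["story_id"]], dtype=np.intp)

    @property
    def onsets(self) -> np.ndarray:
        return self.words["onset"].to_numpy(float)

    @property
    def duration(self) -> float:
        return float(self.words["offset"].to_numpy(float).max())

    def to_tsv(self, path) -> None:
        """Write as a BIDS-style events table (tab-separated)."""
        self.words.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "Stimulus":
        return cls(pd.read_csv(path, sep="\t"))


@dataclass
class LayeredActivations:
    """Per-word activations for one or more layers of a language model.

    ``layers`` maps layer index ``k`` to an ``M x U`` array.  All layers
    share the word count ``M`` and the unit count ``U``.
    """

    layers: Dict[int, np.ndarray]
    model_name: str = "unknown"

    def __post_init__(self) -> None:
        if not self.layers:
            raise InvalidInputError("activations must contain at least one layer")
        shapes = {a.shape for a in self.layers.values()}
        if len(shapes) != 1:
            raise ShapeError(f"layers disagree on shape: {shapes}")

    def __getitem__(self, k: int) -> np.ndarray:
        if k not in self.layers:
            raise InvalidParameterError(
                f"layer {k} not available (have {sorted(self.layers)})"
            )
        return self.layers[k]

    def __contains__(self, k: int) -> bool:
        return k in self.layers

    @property
    def layer_indices(self) -> List[int]:
        return sorted(self.layers)

    @property
    def n_words(self) -> int:
        return next(iter(self.layers.values())).shape[0]

    @property
    def n_units(self) -> int:
        return next(iter(self.layers.values())).shape[1]


@dataclass
class ScanMatrix:
    """Word features summed into TR bins: ``T scans x U features``."""

    values: np.ndarray
    tr: float

    @property
    def n_scans(self) -> int:
        return self.values.shape[0]


@dataclass
class DesignMatrix:
    """FIR-expanded scan matrix: ``T x (n_delays * U)``.

    Block ``j`` of row ``t`` equals the scan-matrix row at ``t - j``
    (zero where ``t - j < 0``).  ``delays`` lists the lag times in seconds.
    """

    values: np.ndarray
    delays: Sequence[float] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Transcript cleaning
# ---------------------------------------------------------------------------

_HYPHENS = re.compile(r"[-‐-―]")
_DUP_MARKS = re.compile(r"[.?!]{2,}")


def clean_transcript(text: str) -> str:
    """Normalise punctuation before tokenisation.

    Hyphen-like characters are replaced by dots, and runs of duplicated
    terminal marks (``?.``, ``!!``, ``...``) collapse to a single dot.
    Word characters are left untouched.
    """
    text = _HYPHENS.sub(".", text)
    return _DUP_MARKS.sub(".", text)


# ---------------------------------------------------------------------------
# Language-model adapters
# ---------------------------------------------------------------------------

class LanguageModelAdapter(Protocol):
    """Minimal causal-LM interface used by :func:`extract_activations`.

    ``tokenize`` splits one word into sub-tokens; ``hidden_states`` maps a
    token context to per-layer hidden states, one row per token, causally
    (row ``i`` may depend only on tokens ``0..i``).
    """

    layer_indices: Sequence[int]

    def tokenize(self, word: str) -> List[str]: ...

    def hidden_states(
        self, tokens: Sequence[str], layers: Sequence[int]
    ) -> Mapping[int, np.ndarray]: ...


def _token_vector(token: str, dim: int, seed: int) -> np.ndarray:
    """Deterministic pseudo-random embedding of a token string."""
    digest = hashlib.blake2b(f"{seed}:{token}".encode(), digest_size=8).digest()
    rng = np.random.default_rng(int.from_bytes(digest, "little"))
    return rng.standard_normal(dim)


class FakeCausalLM:
    """Deterministic stand-in for a causal transformer (synthetic model).

    Token embeddings are seeded hashes of the token string; the hidden
    state of layer ``k`` at position ``i`` is a normalised causal moving
    average of the last ``k + 1`` token embeddings *within the provided
    context*.  Deeper layers therefore integrate longer context, emulating
    the increasing contextualisation of real transformer layers, and the
    output depends only on the tokens passed in — which makes context
    truncation by the caller observable.
    """

    def __init__(self, dim: int = 16, n_layers: int = 13, seed: int = 0,
                 split_long_words: int = 0):
        self.dim = dim
        self.layer_indices = list(range(n_layers))
        self.seed = seed
        # split words longer than this into chunks (0 disables): lets tests
        # exercise multi-sub-token words without a real tokenizer
        self.split_long_words = split_long_words

    def tokenize(self, word: str) -> List[str]:
        word = word.strip()
        if not word:
            return []
        n = self.split_long_words
        if n and len(word) > n:
            return [word[i : i + n] for i in range(0, len(word), n)]
        return [word]

    def hidden_states(self, tokens, layers):
        emb = np.stack([_token_vector(t, self.dim, self.seed) for t in tokens])
        csum = np.vstack([np.zeros(self.dim), np.cumsum(emb, axis=0)])
        out = {}
        n = len(tokens)
        idx = np.arange(n)
        for k in layers:
            width = np.minimum(k + 1, idx + 1)
            start = idx + 1 - width
            window = (csum[idx + 1] - csum[start]) / np.sqrt(width)[:, None]
            out[k] = window
        return out


class OneHotLM:
    """Identity adapter: each token maps to a fixed one-hot vector.

    Useful as an oracle: the activation of a word equals the one-hot of its
    final sub-token, independent of context.
    """

    def __init__(self, dim: int = 64, seed: int = 0):
        self.dim = dim
        self.seed = seed
        self.layer_indices = [0]

    def tokenize(self, word: str) -> List[str]:
        word = word.strip()
        return [word] if word else []

    def token_index(self, token: str) -> int:
        digest = hashlib.blake2b(f"{self.seed}:{token}".encode(), digest_size=8).digest()
        return int.from_bytes(digest, "little") % self.dim

    def hidden_states(self, tokens, layers):
        states = np.zeros((len(tokens), self.dim))
        for i, t in enumerate(tokens):
            states[i, self.token_index(t)] = 1.0
        return {k: states for k in layers}


class HuggingFaceLM:  # pragma: no cover - requires the optional 'lm' extra
    """Adapter around a HuggingFace causal LM (e.g. GPT-2).

    Only instantiated when the ``transformers`` package is installed; the
    test suite uses :class:`FakeCausalLM` instead.
    """

    def __init__(self, model_name: str = "gpt2", device: str = "cpu"):
        try:
            import torch
            from transformers import AutoModel, AutoTokenizer
        except ImportError as exc:
            raise ImportError(
                "HuggingFaceLM requires the optional 'transformers' dependency"
            ) from exc
        self._torch = torch
        self.tokenizer = AutoTokenizer.from_pretrained(model_name)
        self.model = AutoModel.from_pretrained(model_name, output_hidden_states=True)
        self.model.eval().to(device)
        self.device = device
        self.layer_indices = list(range(self.model.config.n_layer + 1))

    def tokenize(self, word: str) -> List[str]:
        return self.tokenizer.tokenize(" " + word.strip())

    def hidden_states(self, tokens, layers):
        ids = self.tokenizer.convert_tokens_to_ids(list(tokens))
        with self._torch.no_grad():
            out = self.model(self._torch.tensor([ids]).to(self.device))
        return {
            k: out.hidden_states[k][0].cpu().numpy() for k in layers
        }


# ---------------------------------------------------------------------------
# Activation extraction
# ---------------------------------------------------------------------------

def extract_activations(
    model: LanguageModelAdapter,
    stimulus: Stimulus,
    layers: Iterable[int],
    max_context: int = 1024,
) -> LayeredActivations:
    """One activation vector per word per layer.

    Each word is fed to the model together with at most ``max_context``
    previous tokens of the *same story* (context never crosses story
    boundaries).  The word's vector is the hidden state at its final
    sub-token, the standard choice for causal models.
    """
    layers = list(layers)
    unknown = [k for k in layers if k not in model.layer_indices]
    if unknown:
        raise InvalidParameterError(
            f"layers {unknown} unknown to adapter (has {list(model.layer_indices)})"
        )
    if max_context < 1:
        raise InvalidParameterError("max_context must be >= 1")

    M = stimulus.n_words
    out = {k: np.empty((M, 0)) for k in layers}
    rows: Dict[int, List[np.ndarray]] = {k: [] for k in layers}

    for _, grp in stimulus.words.groupby("story_id", sort=False):
        tokens: List[str] = []
        for word_idx, word in zip(grp.index, grp["word"]):
            sub = model.tokenize(str(word))
            if not sub:
                raise AlignmentError(
                    f"word index {word_idx} ({word!r}) produced zero tokens"
                )
            tokens.extend(sub)
            context = tokens[-max_context:]
            states = model.hidden_states(context, layers)
            for k in layers:
                rows[k].append(np.asarray(states[k][-1], dtype=float))

    for k in layers:
        out[k] = np.stack(rows[k])
    return LayeredActivations(out, model_name=type(model).__name__)


# ---------------------------------------------------------------------------
# Alignment to the scan grid
# ---------------------------------------------------------------------------

def pool_words_to_scans(
    X: np.ndarray, stimulus: Stimulus, tr: float, n_scans: int
) -> ScanMatrix:
    """Sum word features into TR bins.

    Row ``t`` of the result is the sum of the rows of ``X`` whose word onset
    falls in ``[t*tr, (t+1)*tr)``; bins with no word are zero.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != stimulus.n_words:
        raise ShapeError(
            f"X has {X.shape[0]} rows but stimulus has {stimulus.n_words} words"
        )
    if tr <= 0:
        raise InvalidParameterError("tr must be positive")
    bins = np.floor(stimulus.onsets / tr).astype(np.intp)
    if bins.max() >= n_scans:
        raise CoverageError(
            f"word onset {stimulus.onsets.max():.2f}s exceeds scan coverage "
            f"({n_scans} scans x {tr}s)"
        )
    pooled = np.zeros((n_scans, X.shape[1]))
    np.add.at(pooled, bins, X)
    return ScanMatrix(values=pooled, tr=tr)


def fir_expand(scans: ScanMatrix, n_delays: int = 6) -> DesignMatrix:
    """Finite-impulse-response expansion of the scan matrix.

    Horizontally concatenates the scan matrix shifted by ``0 .. n_delays-1``
    scans (zero-padded at the start), so a voxel's response can load on any
    lag of the stimulus features.  Six delays at TR = 1.5 s span lags
    0–7.5 s, covering the bulk of the hemodynamic response.
    """
    if n_delays < 1:
        raise InvalidParameterError("n_delays must be >= 1")
    V = scans.values
    T, U = V.shape
    blocks = []
    for j in range(n_delays):
        shifted = np.zeros_like(V)
        if j == 0:
            shifted[:] = V
        else:
            shifted[j:] = V[:-j]
        blocks.append(shifted)
    delays = [j * scans.tr for j in range(n_delays)]
    return DesignMatrix(values=np.hstack(blocks), delays=delays)
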