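"""Syntactic/semantic factorisation of activations and component forecasts.

For each word, n tag-matched alternative futures are sampled: word
sequences with the same part-of-speech and dependency tags as the true
future but randomly resampled word identities.  Averaging the model
activations over those futures keeps what is common to all of them — the
syntax — and washes out word-specific semantics:

    X_syn = mean over futures of the futures' activations
    X_sem = X - X_syn            (residuals of syntax)

Forecast windows are factorised *after* concatenation: the full window is
built first, then its syntactic and semantic components are extracted, and
the component forecast scores are

    F_syn(d) = R(X (+) Xtilde_syn(d)) - R(X)
    F_sem(d) = R(X (+) Xtilde_sem(d)) - R(X)

computed exactly like the full forecast score with the component window in
place of the full one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np

from .encoding import BoldRun, EncodingConfig, ScoreMap
from .errors import (
    InvalidParameterError,
    LexiconCoverageError,
    ShapeError,
)
from .forecast import ForecastConfig, ForecastCurve, ForecastWindow, forecast_curves, forecast_score
from .synthetic import TaggedCorpus, TaggedLexicon

__all__ = [
    "FactorizationConfig",
    "FactorizedActivations",
    "sample_matched_words",
    "sample_matched_futures",
    "factorize_activations",
    "resampled_corpus_activations",
    "factorize_corpus_activations",
    "component_forecast_scores",
    "component_forecast_curves",
]


@dataclass
class FactorizationConfig:
    """Parameters of the tag-matched resampling."""

    n_futures: int = 10
    horizon: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_futures < 2:
            raise InvalidParameterError("n_futures must be >= 2")
        if self.horizon < 1:
            raise InvalidParameterError("horizon must be >= 1")


@dataclass
class FactorizedActivations:
    """Additive split of activations into syntax and semantic residual."""

    syntactic: np.ndarray
    semantic: np.ndarray

    def __post_init__(self) -> None:
        if self.syntactic.shape != self.semantic.shape:
            raise ShapeError("syntactic and semantic components must share shape")

    @property
    def total(self) -> np.ndarray:
        return self.syntactic + self.semantic


# ---------------------------------------------------------------------------
# Tag-matched sampling
# ---------------------------------------------------------------------------

def sample_matched_words(
    tags: Sequence[Tuple[str, str]],
    lexicon: TaggedLexicon,
    n_futures: int,
    rng: np.random.Generator,
) -> List[List[str]]:
    """``n_futures`` word sequences sharing the given tag sequence.

    Each token is drawn uniformly from the lexicon bucket of its (pos,
    dep) pair; a missing bucket raises :class:`LexiconCoverageError`
    naming the pair.
    """
    for pair in tags:
        if not lexicon.bucket(tuple(pair)):
            raise LexiconCoverageError(f"tag pair {tuple(pair)} not covered by the lexicon")
    futures = []
    for _ in range(n_futures):
        futures.append(
            [str(rng.choice(lexicon.bucket(tuple(pair)))) for pair in tags]
        )
    return futures


def sample_matched_futures(
    corpus: TaggedCorpus,
    position: int,
    config: FactorizationConfig,
) -> List[List[str]]:
    """Tag-matched alternative futures for the words after ``position``.

    The true future is ``corpus`` words ``position+1 .. position+horizon``;
    every sampled future shares its tag sequence token for token.
    """
    if not 0 <= position < corpus.n_words:
        raise InvalidParameterError(f"position {position} out of range")
    stop = min(position + 1 + config.horizon, corpus.n_words)
    tags = corpus.tags[position + 1 : stop]
    rng = np.random.default_rng(config.seed)
    return sample_matched_words(tags, corpus.lexicon, config.n_futures, rng)


# ---------------------------------------------------------------------------
# Factorisation
# ---------------------------------------------------------------------------

def factorize_activations(
    X: np.ndarray,
    futures_activations: Sequence[np.ndarray],
) -> FactorizedActivations:
    """Mean-over-futures syntax component and its residual.

    ``X_syn`` is the element-wise mean of the futures' activations and
    ``X_sem = X - X_syn``, so the residual identity ``X = X_syn + X_sem``
    holds to machine precision.
    """
    X = np.asarray(X, dtype=float)
    stack = [np.asarray(f, dtype=float) for f in futures_activations]
    if len(stack) == 0:
        raise InvalidParameterError("at least one future activation set is required")
    for f in stack:
        if f.shape != X.shape:
            raise ShapeError(
                f"future activations shape {f.shape} differs from X {X.shape}"
            )
    syn = np.mean(stack, axis=0)
    return FactorizedActivations(syntactic=syn, semantic=X - syn)


def resampled_corpus_activations(
    corpus: TaggedCorpus,
    rng: np.random.Generator,
) -> np.ndarray:
    """Embeddings of one full tag-matched resampling of the corpus."""
    lex = corpus.lexicon
    rows = []
    for pair in corpus.tags:
        if not lex.bucket(pair):
            raise LexiconCoverageError(f"tag pair {pair} not covered by the lexicon")
        word = str(rng.choice(lex.bucket(pair)))
        rows.append(lex.embed(word, pair))
    return np.stack(rows)


def factorize_corpus_activations(
    corpus: TaggedCorpus,
    config: FactorizationConfig,
    layer: int = 0,
) -> FactorizedActivations:
    """Factorise a tagged corpus' activations via whole-corpus resampling."""
    rng = np.random.default_rng(config.seed)
    futures = [
        resampled_corpus_activations(corpus, rng) for _ in range(config.n_futures)
    ]
    return factorize_activations(corpus.activations[layer], futures)


def factorize_window(
    corpus: TaggedCorpus,
    distance: int,
    width: int,
    config: FactorizationConfig,
    layer: int = 0,
) -> Tuple[ForecastWindow, ForecastWindow]:
    """Syntactic and semantic components of one forecast window.

    The full window is built first from the true activations; each sampled
    future replaces every word by a tag-matched draw, its window is built
    the same way, and the mean over futures is the syntactic window.  The
    semantic window is the residual, so the two reconstruct the full
    window exactly.
    """
    from .forecast import build_forecast_window  # local to avoid confusion with the public API

    full = build_forecast_window(corpus.activations[layer], corpus.stimulus, distance, width)
    rng = np.random.default_rng(config.seed)
    future_windows = []
    for _ in range(config.n_futures):
        acts = resampled_corpus_activations(corpus, rng)
        future_windows.append(
            build_forecast_window(acts, corpus.stimulus, distance, width).values
        )
    fact = factorize_activations(full.values, future_windows)
    syn = ForecastWindow(values=fact.syntactic, distance=distance, width=width)
    sem = ForecastWindow(values=fact.semantic, distance=distance, width=width)
    return syn, sem


# ---------------------------------------------------------------------------
# Component forecast scores
# ---------------------------------------------------------------------------

def component_forecast_scores(
    X: np.ndarray,
    window_syn: ForecastWindow,
    window_sem: ForecastWindow,
    stimulus,
    bold: Sequence[BoldRun] | BoldRun,
    config: EncodingConfig = None,
    baseline: Optional[ScoreMap] = None,
) -> Tuple[ScoreMap, ScoreMap]:
    """Forecast scores of the syntactic and semantic window components."""
    f_syn = forecast_score(X, window_syn, stimulus, bold, config, baseline=baseline)
    f_sem = forecast_score(X, window_sem, stimulus, bold, config, baseline=baseline)
    return f_syn, f_sem


def component_forecast_curves(
    corpus: TaggedCorpus,
    bold: Sequence[BoldRun],
    enc_config: EncodingConfig = None,
    fc_config: ForecastConfig = None,
    fact_config: FactorizationConfig = None,
    layer: int = 0,
) -> Tuple[ForecastCurve, ForecastCurve]:
    """F_syn(d) and F_sem(d) over the full distance grid for a tagged corpus.

    Equivalent to running :func:`forecast_curves` once per component, with
    the window factorised after construction at every distance and the
    baseline R(X) shared between the two components.
    """
    if enc_config is None:
        enc_config = EncodingConfig()
    if fc_config is None:
        fc_config = ForecastConfig()
    if fact_config is None:
        fact_config = FactorizationConfig()
    X = corpus.activations[layer]
    baseline = _plain_brain_score(X, corpus.stimulus, bold, enc_config)
    per_d = {"syntactic": [], "semantic": []}
    for d in fc_config.distance_grid:
        syn, sem = factorize_window(corpus, int(d), fc_config.width, fact_config, layer)
        for name, window in (("syntactic", syn), ("semantic", sem)):
            score = forecast_score(
                X, window, corpus.stimulus, bold, enc_config, baseline=baseline
            )
            per_d[name].append(score.values)
    grid = np.asarray(fc_config.distance_grid, int)
    make = lambda name: ForecastCurve(
        values=np.stack(per_d[name], axis=2),
        distance_grid=grid.copy(),
        subjects=baseline.subjects,
        baseline=baseline,
    )
    return make("syntactic"), make("semantic")


def _plain_brain_score(X, stimulus, bold, enc_config):
    from .encoding import score_feature_blocks
    from .forecast import _word_block_to_design

    runs = [bold] if isinstance(bold, BoldRun) else list(bold)
    T, tr = runs[0].n_scans, runs[0].tr
    design = _word_block_to_design(X, stimulus, tr, T, enc_config.n_fir_delays)
    return score_feature_blocks([design], runs, enc_config)
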