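"""Synthetic stimuli, embeddings and BOLD with planted forecast structure.

Every downstream stage of the package (brain scores, forecast curves,
distance/depth maps, factorisation, noise ceiling, group stats) is tested
against data generated here, because the generator plants *known* forecast
structure that the analyses must recover.

The forward model mirrors the assumptions of the encoding analysis:

* a word stream at a realistic rate (~2.54 words/s by default);
* a layered embedding hierarchy in which layer k is a causal moving
  average of the word-wise white layer 0 over the last k+1 words
  (renormalised to unit variance) — deeper layers are more contextual,
  emulating transformer depth without shipping a language model;
* each planted voxel reads out, through a fixed random linear functional,
  the concatenated embeddings of a window of ``plant_width`` future words
  ending ``planted_distance`` words after the current word, pooled to the
  scan grid and delayed by a pure hemodynamic lag of ``hrf_lag_scans``
  scans.  A window-shaped readout (rather than a single word) gives the
  forecast-score curve a unique, recoverable peak at the planted distance.
* a fraction ``shared_signal_fraction`` of each planted voxel's signal
  variance is common to all subjects (the stimulus-driven readout); the
  rest is a smooth subject-specific process that no feature model can
  explain, plus independent white measurement noise.

All generators are pure functions of their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .encoding import BoldRun
from .errors import (
    InvalidInputError,
    InvalidLexiconError,
    InvalidParameterError,
    ShapeError,
)
from .forecast import build_forecast_window
from .stimuli import LayeredActivations, Stimulus, pool_words_to_scans

__all__ = [
    "SyntheticSpec",
    "TaggedLexicon",
    "TaggedCorpus",
    "generate_stimulus",
    "generate_layered_embeddings",
    "generate_bold",
    "make_default_lexicon",
    "generate_tagged_language",
    "DISTANCE_GRID_BOUNDS",
]

# analysis grid for planted distances (inclusive)
DISTANCE_GRID_BOUNDS = (-10, 30)


def _empty_plants() -> pd.DataFrame:
    return pd.DataFrame(
        columns=[
            "voxel_id",
            "planted_distance",
            "planted_layer",
            "planted_component",
            "signal_gain",
        ]
    )


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic multi-subject dataset.

    ``voxel_plants`` is a table with one row per planted voxel:
    ``voxel_id`` (column index), ``planted_distance`` (words; 0 = current
    word), ``planted_layer`` (embedding layer read out),
    ``planted_component`` (``full`` | ``syntactic`` | ``semantic``) and
    ``signal_gain`` (signal s.d. in units of the BOLD scale; noise has
    s.d. ``noise_sd``).  Voxels not listed are pure noise.
    """

    n_subjects: int = 8
    n_voxels: int = 200
    tr: float = 1.5
    voxel_plants: pd.DataFrame = field(default_factory=_empty_plants)
    noise_sd: float = 1.0
    shared_signal_fraction: float = 1.0
    hrf_lag_scans: int = 3
    plant_width: int = 7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_voxels < 1:
            raise InvalidParameterError("n_subjects and n_voxels must be >= 1")
        if self.tr <= 0:
            raise InvalidParameterError("tr must be positive")
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be >= 0")
        if not 0 <= self.shared_signal_fraction <= 1:
            raise InvalidParameterError("shared_signal_fraction must be in [0, 1]")
        if self.hrf_lag_scans < 0:
            raise InvalidParameterError("hrf_lag_scans must be >= 0")
        if self.plant_width < 1:
            raise InvalidParameterError("plant_width must be >= 1")
        plants = pd.DataFrame(self.voxel_plants)
        if len(plants):
            lo, hi = DISTANCE_GRID_BOUNDS
            d = plants["planted_distance"].to_numpy(int)
            if np.any((d < lo) | (d > hi)):
                raise InvalidParameterError(
                    f"planted_distance must lie within the analysis grid [{lo}, {hi}]"
                )
            if np.any(plants["planted_layer"].to_numpy(int) < 0):
                raise InvalidParameterError("planted_layer must be >= 0")
            vox = plants["voxel_id"].to_numpy(int)
            if np.any((vox < 0) | (vox >= self.n_voxels)):
                raise InvalidParameterError("voxel_id out of range")
            bad = set(plants["planted_component"]) - {"full", "syntactic", "semantic"}
            if bad:
                raise InvalidParameterError(f"unknown planted_component {bad}")
        self.voxel_plants = plants


# ---------------------------------------------------------------------------
# Stimulus
# ---------------------------------------------------------------------------

_VOCAB_SIZE = 250


def generate_stimulus(
    n_words: int,
    word_rate: float = 2.54,
    n_stories: int = 1,
    seed: int = 0,
) -> Stimulus:
    """A word-timed stream at a target rate, split into stories.

    Inter-word gaps are gamma-distributed (shape 4), rescaled per story so
    that each story of m words lasts exactly m / word_rate seconds; the
    realised mean rate therefore equals the target.  Stories follow one
    another on a single timeline with a 3 s silence in between.
    """
    if word_rate <= 0:
        raise InvalidParameterError("word_rate must be positive")
    if n_words < 1 or n_stories < 1:
        raise InvalidParameterError("n_words and n_stories must be >= 1")
    if n_stories > n_words:
        raise InvalidParameterError("cannot have more stories than words")
    rng = np.random.default_rng(seed)
    vocab = np.array([f"w{i:04d}" for i in range(_VOCAB_SIZE)])
    counts = [len(c) for c in np.array_split(np.arange(n_words), n_stories)]
    rows = []
    t0 = 0.0
    for s, m in enumerate(counts):
        gaps = rng.gamma(shape=4.0, scale=1.0, size=m)
        gaps *= (m / word_rate) / gaps.sum()
        onsets = t0 + np.concatenate([[0.0], np.cumsum(gaps[:-1])])
        offsets = np.minimum(onsets + 0.8 * gaps, t0 + m / word_rate)
        words = rng.choice(vocab, size=m)
        for w, on, off in zip(words, onsets, offsets):
            rows.append((f"story-{s:02d}", w, on, off))
        t0 += m / word_rate + 3.0
    return Stimulus(pd.DataFrame(rows, columns=["story_id", "word", "onset", "offset"]))


# ---------------------------------------------------------------------------
# Layered embeddings
# ---------------------------------------------------------------------------

def _causal_moving_average(layer0: np.ndarray, window: int) -> np.ndarray:
    """Unit-variance causal moving average over the last ``window`` rows."""
    M = layer0.shape[0]
    csum = np.vstack([np.zeros((1, layer0.shape[1])), np.cumsum(layer0, axis=0)])
    idx = np.arange(M)
    width = np.minimum(window, idx + 1)
    start = idx + 1 - width
    return (csum[idx + 1] - csum[start]) / np.sqrt(width)[:, None]


def generate_layered_embeddings(
    stimulus: Stimulus,
    n_layers: int = 13,
    dim: int = 16,
    seed: int = 0,
    layer_specificity: float = 0.8,
    depth_correlation: float = 0.7,
    context_growth: float = 0.5,
) -> LayeredActivations:
    """A 13-level hierarchy: deeper layers integrate longer context.

    Layer 0 is word-wise white Gaussian noise ``e``.  Layer k (k >= 1)
    mixes a depth-indexed latent stream

        u_k = sqrt(1 - eta) * e + sqrt(eta) * f_k

    (``eta = layer_specificity``; the layer-specific streams ``f_k``
    follow an AR(1) across depth with coefficient ``depth_correlation``)
    with its own causal moving average over the last k+1 words of the
    same story:

        layer_k ∝ sqrt(1 - c_k) * u_k + sqrt(c_k) * MA_{k+1}(u_k)

    where the context fraction ``c_k = context_growth * k / (n_layers-1)``
    grows with depth; columns are renormalised to unit variance.

    Three properties matter downstream: (1) deeper layers are more
    contextual — their lag-1 word autocorrelation grows monotonically
    with k, like real transformer depth; (2) layers are similar to their
    depth neighbours yet carry content that other layers cannot linearly
    span — without the layer-specific streams, every deep layer would be
    an exact linear function of short windows of layer 0 and planted
    depths would be unidentifiable; (3) every layer keeps a word-precise
    component — a fully smoothed deep signal would be predictable from
    lagged present-word features alone, again hiding planted depths.

    Context never crosses story boundaries.
    """
    if stimulus.n_words == 0:
        raise InvalidInputError("stimulus is empty")
    if n_layers < 1 or dim < 1:
        raise InvalidParameterError("n_layers and dim must be >= 1")
    if not 0 <= layer_specificity <= 1:
        raise InvalidParameterError("layer_specificity must be in [0, 1]")
    if not 0 <= depth_correlation < 1:
        raise InvalidParameterError("depth_correlation must be in [0, 1)")
    if not 0 <= context_growth <= 1:
        raise InvalidParameterError("context_growth must be in [0, 1]")
    rng = np.random.default_rng(seed)
    M = stimulus.n_words
    e = rng.standard_normal((M, dim))
    story = stimulus.story_index()
    eta = layer_specificity
    layers = {0: e}
    f = rng.standard_normal((M, dim))
    for k in range(1, n_layers):
        if k > 1:
            f = depth_correlation * f + np.sqrt(
                1 - depth_correlation**2
            ) * rng.standard_normal((M, dim))
        u = np.sqrt(1 - eta) * e + np.sqrt(eta) * f
        ma = np.empty_like(e)
        for s in np.unique(story):
            sel = story == s
            ma[sel] = _causal_moving_average(u[sel], k + 1)
        c_k = context_growth * k / max(n_layers - 1, 1)
        mixed = np.sqrt(1 - c_k) * u + np.sqrt(c_k) * ma
        sd = mixed.std(axis=0)
        sd[sd == 0] = 1.0
        layers[k] = (mixed - mixed.mean(axis=0)) / sd
    return LayeredActivations(layers, model_name="synthetic")


# ---------------------------------------------------------------------------
# BOLD forward model
# ---------------------------------------------------------------------------

def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else x - x.mean()


def _smooth_noise(rng: np.random.Generator, n: int, width: int = 3) -> np.ndarray:
    """Unit-variance temporally smooth nuisance series (moving-average of white noise)."""
    raw = rng.standard_normal(n + width - 1)
    kernel = np.ones(width) / np.sqrt(width)
    return np.convolve(raw, kernel, mode="valid")


def generate_bold(
    stimulus: Stimulus,
    activations: LayeredActivations,
    spec: SyntheticSpec,
    components: Optional[Dict[str, LayeredActivations]] = None,
) -> Tuple[List[BoldRun], pd.DataFrame]:
    """Multi-subject BOLD whose planted voxels read out future embeddings.

    For each planted voxel the noiseless signal is a fixed random linear
    readout of the window of ``spec.plant_width`` embeddings (layer
    ``planted_layer``) ending ``planted_distance`` words after the current
    word, pooled into TR bins by word onset, standardised, and delayed by
    ``spec.hrf_lag_scans`` scans.  Plants on the ``syntactic`` or
    ``semantic`` component read the corresponding additive component
    passed via ``components`` (from :func:`generate_tagged_language`).

    Subject s sees ``sqrt(rho) * shared + sqrt(1-rho) * private`` times the
    voxel's gain (rho = ``shared_signal_fraction``; the private part is a
    smooth stimulus-independent process), plus white noise of s.d.
    ``noise_sd``.  Returns the runs and a ground-truth table echoing the
    plants.
    """
    if activations.n_words != stimulus.n_words:
        raise ShapeError("activations do not cover the stimulus")
    plants = spec.voxel_plants
    rng = np.random.default_rng(spec.seed)
    n_scans = int(np.ceil(stimulus.duration / spec.tr)) + spec.hrf_lag_scans + 2
    rho = spec.shared_signal_fraction

    shared = np.zeros((n_scans, spec.n_voxels))
    gains = np.zeros(spec.n_voxels)
    for row in plants.itertuples(index=False):
        comp = str(row.planted_component)
        layer = int(row.planted_layer)
        if comp == "full":
            source = activations
        else:
            if not components or comp not in components:
                raise InvalidParameterError(
                    f"plant on component {comp!r} requires component activations"
                )
            source = components[comp]
        X = source[layer]
        window = build_forecast_window(
            X, stimulus, int(row.planted_distance), spec.plant_width
        )
        beta = rng.standard_normal(window.values.shape[1])
        z_words = window.values @ beta
        pooled = pool_words_to_scans(z_words, stimulus, spec.tr, n_scans).values[:, 0]
        z = _standardize(pooled)
        lagged = np.zeros(n_scans)
        if spec.hrf_lag_scans:
            lagged[spec.hrf_lag_scans:] = z[: -spec.hrf_lag_scans]
        else:
            lagged = z
        v = int(row.voxel_id)
        shared[:, v] += lagged
        gains[v] = float(row.signal_gain)

    runs = []
    for s in range(spec.n_subjects):
        private = np.zeros_like(shared)
        if rho < 1:
            for v in np.nonzero(gains)[0]:
                private[:, v] = _smooth_noise(rng, n_scans)
        signal = gains * (np.sqrt(rho) * shared + np.sqrt(1 - rho) * private)
        noise = spec.noise_sd * rng.standard_normal((n_scans, spec.n_voxels))
        runs.append(
            BoldRun(
                values=signal + noise,
                tr=spec.tr,
                subject_id=f"sub-{s:02d}",
                story_ids=stimulus.story_ids,
            )
        )
    return runs, plants.copy()


# ---------------------------------------------------------------------------
# Tagged language with additive syntax/semantics
# ---------------------------------------------------------------------------

@dataclass
class TaggedLexicon:
    """Words with (pos, dep) tags and additive syntax/semantics vectors.

    ``syntax_vectors`` maps a tag pair to a vector shared by every word
    carrying those tags; ``semantics_vectors`` maps a word to its own
    vector.  A word's embedding is the sum of the two.  Tag-matched
    resampling requires at least two words per tag pair.
    """

    entries: pd.DataFrame                      # word, pos, dep
    syntax_vectors: Dict[Tuple[str, str], np.ndarray]
    semantics_vectors: Dict[str, np.ndarray]

    def __post_init__(self) -> None:
        required = {"word", "pos", "dep"}
        if not required <= set(self.entries.columns):
            raise InvalidLexiconError(f"lexicon entries need columns {sorted(required)}")
        self._buckets: Dict[Tuple[str, str], List[str]] = {}
        for row in self.entries.itertuples(index=False):
            self._buckets.setdefault((row.pos, row.dep), []).append(row.word)

    def validate(self) -> None:
        for pair, words in self._buckets.items():
            if len(words) < 2:
                raise InvalidLexiconError(
                    f"tag pair {pair} has fewer than 2 words; "
                    "tag-matched resampling could never change the word"
                )

    @property
    def tag_pairs(self) -> List[Tuple[str, str]]:
        return sorted(self._buckets)

    def bucket(self, pair: Tuple[str, str]) -> List[str]:
        return self._buckets.get(pair, [])

    @property
    def dim(self) -> int:
        return len(next(iter(self.syntax_vectors.values())))

    def embed(self, word: str, pair: Tuple[str, str]) -> np.ndarray:
        return self.syntax_vectors[pair] + self.semantics_vectors[word]


def make_default_lexicon(
    n_pairs: int = 8,
    words_per_pair: int = 20,
    dim: int = 16,
    seed: int = 0,
    syntax_scale: float = 1.0,
    semantics_scale: float = 1.0,
) -> TaggedLexicon:
    """A seeded lexicon with ``n_pairs`` tag pairs and Gaussian vectors."""
    rng = np.random.default_rng(seed)
    rows = []
    syntax = {}
    semantics = {}
    for i in range(n_pairs):
        pair = (f"POS{i}", f"DEP{i}")
        syntax[pair] = syntax_scale * rng.standard_normal(dim)
        for j in range(words_per_pair):
            word = f"tok_{i}_{j}"
            rows.append((word, *pair))
            semantics[word] = semantics_scale * rng.standard_normal(dim)
    return TaggedLexicon(
        entries=pd.DataFrame(rows, columns=["word", "pos", "dep"]),
        syntax_vectors=syntax,
        semantics_vectors=semantics,
    )


@dataclass
class TaggedCorpus:
    """A tagged synthetic text with known additive embedding components."""

    stimulus: Stimulus
    tags: List[Tuple[str, str]]
    activations: LayeredActivations              # layer 0 = syntax + semantics
    components: Dict[str, LayeredActivations]    # 'syntactic', 'semantic'
    lexicon: TaggedLexicon

    @property
    def n_words(self) -> int:
        return self.stimulus.n_words


def generate_tagged_language(
    n_words: int,
    lexicon: TaggedLexicon,
    seed: int = 0,
    word_rate: float = 2.54,
    n_stories: int = 1,
) -> TaggedCorpus:
    """A corpus with random tags and additive syntax/semantics embeddings.

    Tag pairs are drawn i.i.d. from the lexicon (a deterministic cyclic
    grammar would make the syntax stream exactly periodic, so a planted
    syntactic forecast distance would only be identifiable modulo the
    cycle length); each word is drawn uniformly from its tag bucket.  The
    embedding of a word is ``syntax_vector(tags) + semantics_vector(word)``,
    exposed both summed (``activations``) and split (``components``) so
    recovery tests have the ground truth.
    """
    lexicon.validate()
    timing = generate_stimulus(n_words, word_rate, n_stories, seed)
    rng = np.random.default_rng(seed)
    pairs = lexicon.tag_pairs
    tags = [pairs[i] for i in rng.integers(0, len(pairs), size=n_words)]
    words = [str(rng.choice(lexicon.bucket(p))) for p in tags]
    table = timing.words.copy()
    table["word"] = words
    stimulus = Stimulus(table)
    syn = np.stack([lexicon.syntax_vectors[p] for p in tags])
    sem = np.stack([lexicon.semantics_vectors[w] for w in words])
    return TaggedCorpus(
        stimulus=stimulus,
        tags=tags,
        activations=LayeredActivations({0: syn + sem}, model_name="tagged-synthetic"),
        components={
            "syntactic": LayeredActivations({0: syn}, model_name="tagged-syntax"),
            "semantic": LayeredActivations({0: sem}, model_name="tagged-semantics"),
        },
        lexicon=lexicon,
    )
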