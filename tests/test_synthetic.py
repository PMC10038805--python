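import numpy as np
import pandas as pd
import pytest

import braincast as bc
from braincast.errors import InvalidLexiconError, InvalidParameterError
from conftest import planted_table


class TestGenerateStimulus:
    def test_realistic_rate_gives_expected_duration(self):
        stim = bc.generate_stimulus(2540, word_rate=2.54, n_stories=1, seed=0)
        # 2540 words at 2.54 words/s span ~1000 s
        assert stim.duration == pytest.approx(1000.0, rel=0.05)
        realised_rate = stim.n_words / stim.duration
        assert realised_rate == pytest.approx(2.54, rel=0.05)

    def test_single_word_stream(self):
        stim = bc.generate_stimulus(1, word_rate=5.0, seed=3)
        assert stim.n_words == 1
        assert stim.onsets[0] == 0.0

    def test_same_seed_reproduces_table(self):
        a = bc.generate_stimulus(200, 2.54, 3, seed=42)
        b = bc.generate_stimulus(200, 2.54, 3, seed=42)
        pd.testing.assert_frame_equal(a.words, b.words)

    def test_onsets_strictly_increasing_within_story(self):
        stim = bc.generate_stimulus(500, 2.54, 2, seed=1)
        for _, grp in stim.words.groupby("story_id"):
            assert np.all(np.diff(grp["onset"].to_numpy()) > 0)

    def test_non_positive_rate_rejected(self):
        with pytest.raises(InvalidParameterError):
            bc.generate_stimulus(10, word_rate=0.0)


class TestLayeredEmbeddings:
    def test_layer_zero_is_word_wise_white(self, tiny_stimulus):
        acts = bc.generate_layered_embeddings(tiny_stimulus, 3, dim=8, seed=0)
        x = acts[0]
        lag1 = np.mean(
            [np.corrcoef(x[:-1, j], x[1:, j])[0, 1] for j in range(x.shape[1])]
        )
        assert abs(lag1) < 0.1

    def test_lag1_autocorrelation_increases_with_depth(self):
        stim = bc.generate_stimulus(5000, 2.54, 1, seed=5)
        acts = bc.generate_layered_embeddings(stim, 13, dim=8, seed=6)
        ac = []
        for k in range(13):
            x = acts[k]
            ac.append(np.mean([np.corrcoef(x[:-1, j], x[1:, j])[0, 1]
                               for j in range(x.shape[1])]))
        assert np.all(np.diff(ac) > 0)

    def test_context_never_crosses_story_boundary(self):
        stim = bc.generate_stimulus(200, 2.54, 2, seed=7)
        # with full smoothing weight and no layer-specific stream, the
        # first word of a story has a length-1 context window: its deep
        # rows are proportional to its layer-0 row
        acts = bc.generate_layered_embeddings(
            stim, 5, dim=6, seed=8, layer_specificity=0.0, context_growth=1.0
        )
        story = stim.story_index()
        first_of_story2 = int(np.nonzero(story == 1)[0][0])
        a = acts[4][first_of_story2]
        b = acts[0][first_of_story2]
        # proportional up to the per-column centring/renormalisation
        corr = np.corrcoef(a, b)[0, 1]
        assert corr > 0.95

    def test_empty_dimensions_rejected(self, tiny_stimulus):
        with pytest.raises(InvalidParameterError):
            bc.generate_layered_embeddings(tiny_stimulus, 0, 4)


class TestSyntheticSpecValidation:
    def test_distance_outside_grid_rejected(self):
        plants = planted_table([(0, 31, 2, "full", 1.0)])
        with pytest.raises(InvalidParameterError, match="grid"):
            bc.SyntheticSpec(n_voxels=4, voxel_plants=plants)

    def test_bad_fraction_rejected(self):
        with pytest.raises(InvalidParameterError):
            bc.SyntheticSpec(shared_signal_fraction=1.5)

    def test_unknown_component_rejected(self):
        plants = planted_table([(0, 5, 2, "lexical", 1.0)])
        with pytest.raises(InvalidParameterError, match="component"):
            bc.SyntheticSpec(n_voxels=4, voxel_plants=plants)


class TestGenerateBold:
    def test_zero_gain_is_pure_noise(self, tiny_stimulus, tiny_activations):
        spec = bc.SyntheticSpec(n_subjects=2, n_voxels=6, noise_sd=1.0, seed=9)
        runs, truth = bc.generate_bold(tiny_stimulus, tiny_activations, spec)
        assert len(truth) == 0
        values = np.concatenate([r.values.ravel() for r in runs])
        assert abs(values.mean()) < 0.05
        assert values.std() == pytest.approx(1.0, abs=0.05)

    def test_fully_shared_noiseless_runs_identical(self, tiny_stimulus, tiny_activations):
        plants = planted_table([(0, 4, 2, "full", 3.0)])
        spec = bc.SyntheticSpec(
            n_subjects=3, n_voxels=2, voxel_plants=plants,
            noise_sd=0.0, shared_signal_fraction=1.0, seed=10,
        )
        runs, _ = bc.generate_bold(tiny_stimulus, tiny_activations, spec)
        assert np.array_equal(runs[0].values, runs[1].values)
        assert np.array_equal(runs[0].values, runs[2].values)

    def test_outputs_finite_and_truth_echoes_plants(self, small_planted_dataset):
        runs = small_planted_dataset["runs"]
        truth = small_planted_dataset["truth"]
        assert all(np.all(np.isfinite(r.values)) for r in runs)
        assert len(truth) == len(small_planted_dataset["spec"].voxel_plants)

    def test_determinism(self, tiny_stimulus, tiny_activations):
        plants = planted_table([(1, 6, 3, "full", 2.0)])
        spec = bc.SyntheticSpec(n_subjects=2, n_voxels=3, voxel_plants=plants, seed=11)
        a, _ = bc.generate_bold(tiny_stimulus, tiny_activations, spec)
        b, _ = bc.generate_bold(tiny_stimulus, tiny_activations, spec)
        assert np.array_equal(a[0].values, b[0].values)
        assert np.array_equal(a[1].values, b[1].values)

    def test_component_plant_requires_components(self, tiny_stimulus, tiny_activations):
        plants = planted_table([(0, 5, 0, "syntactic", 2.0)])
        spec = bc.SyntheticSpec(n_subjects=2, n_voxels=2, voxel_plants=plants, seed=12)
        with pytest.raises(InvalidParameterError, match="component"):
            bc.generate_bold(tiny_stimulus, tiny_activations, spec)


class TestTaggedLanguage:
    def test_same_tags_differ_only_in_semantics(self):
        lex = bc.make_default_lexicon(n_pairs=3, words_per_pair=4, dim=5, seed=1)
        corpus = bc.generate_tagged_language(60, lex, seed=2)
        tags = np.array([f"{p}|{d}" for p, d in corpus.tags])
        syn = corpus.components["syntactic"][0]
        sem = corpus.components["semantic"][0]
        pair = corpus.tags[0]
        same = np.nonzero(tags == f"{pair[0]}|{pair[1]}")[0]
        assert len(same) >= 2
        i, j = same[:2]
        assert np.array_equal(syn[i], syn[j])
        full = corpus.activations[0]
        assert np.allclose(full[i] - full[j], sem[i] - sem[j])

    def test_bucket_mean_is_syntax_plus_mean_semantics(self):
        lex = bc.make_default_lexicon(n_pairs=2, words_per_pair=5, dim=4, seed=3)
        pair = lex.tag_pairs[0]
        words = lex.bucket(pair)
        mean_embedding = np.mean([lex.embed(w, pair) for w in words], axis=0)
        expected = lex.syntax_vectors[pair] + np.mean(
            [lex.semantics_vectors[w] for w in words], axis=0
        )
        assert np.allclose(mean_embedding, expected)

    def test_same_seed_identical_corpus(self):
        lex = bc.make_default_lexicon(seed=4)
        a = bc.generate_tagged_language(80, lex, seed=5)
        b = bc.generate_tagged_language(80, lex, seed=5)
        pd.testing.assert_frame_equal(a.stimulus.words, b.stimulus.words)
        assert a.tags == b.tags

    def test_undersized_bucket_rejected(self):
        lex = bc.make_default_lexicon(n_pairs=2, words_per_pair=1, dim=4, seed=6)
        with pytest.raises(InvalidLexiconError, match="fewer than 2"):
            bc.generate_tagged_language(20, lex, seed=7)
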