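# braincast

Voxelwise encoding models and **forecast-window analyses** for
naturalistic-listening fMRI.

When people listen to stories, activity in much of the cortex can be
predicted linearly from the contextual embeddings of the words being heard.
`braincast` implements the analysis chain that asks a further question: does
a voxel's activity also reflect representations of words that have *not been
heard yet* — and if so, how far ahead, at what level of the representation
hierarchy, and is the anticipated content syntactic or semantic?

## The quantities it computes

For a stimulus of M words with activations `X` (M × U, from layer k of a
causal language model) and BOLD recordings `Y` (T scans × V voxels):

* **Brain score** — R(X) = corr(W·X, Y⁽ˢ'ᵛ⁾): the cross-validated Pearson
  correlation between a voxel's BOLD and its ridge prediction from the
  TR-pooled, FIR-lagged features. Pipeline per training fold:
  standardisation → 20-component PCA → ridge with per-voxel penalty chosen
  by nested leave-one-out over ten values in [10⁻¹, 10⁸]; five contiguous
  outer folds.
* **Forecast window** — X̃⁽ᵈ⁾ₙ = X[n+d−w+1] ⊕ … ⊕ X[n+d]: the concatenated
  embeddings of w = 7 consecutive words ending d words after word n
  (d may be negative; windows never cross story boundaries).
* **Forecast score** — F⁽ᵈ⁾ = R(X ⊕ X̃⁽ᵈ⁾) − R(X): the gain in brain score
  from appending the window, with each block PCA-reduced separately and
  identical folds for both terms.
* **Forecast distance / depth** — d\* = argmax over d ∈ [−10…30] of F⁽ᵈ⁾
  per subject and voxel; k\* = argmax over layers k ∈ [0…12] of F⁽⁸⁾(X_k).
  Voxels whose F⁽⁸⁾ − F⁽⁰⁾ contrast is not significant across subjects
  (Wilcoxon signed-rank, BH-FDR, p < 0.01) are masked: the argmax of a flat
  curve is meaningless.
* **Syntactic / semantic factorisation** — X_syn = mean activation over
  n = 10 tag-matched resampled futures (same part-of-speech and dependency
  tags, random word identities); X_sem = X − X_syn. Component forecast
  scores F_syn, F_sem use the factorised window in place of the full one.
* **Noise ceiling** — each subject's BOLD predicted from the average of the
  other subjects' BOLD through the same pipeline (no FIR): an upper bound on
  the explainable signal.
* **CPC loss arithmetic** — the InfoNCE loss at temperature τ = 0.1 with
  cosine similarity, and the contribution-balancing rule
  α′ = α·L_lm / ((1−α)·L_high + α·L_lm) that makes the high-level term
  contribute exactly the fraction α of the mixed training loss.

Every stage is exercised end-to-end against a **synthetic-data generator**
(`braincast.synthetic`) that plants known forecast structure: word streams
at ~2.54 words/s, a 13-level embedding hierarchy whose depth is both more
contextual and partially layer-specific, and multi-subject BOLD (TR 1.5 s)
whose voxels read out future embedding windows at chosen distances, depths
and components, with a controllable across-subject shared-signal fraction.

## Worked example

Plant four voxels that read a window of layer-2 embeddings ending 8 words
in the future, then recover the distance:

```python
import numpy as np, pandas as pd
import braincast as bc

plants = pd.DataFrame(
    {"voxel_id": [0, 1, 2, 3], "planted_distance": 8, "planted_layer": 2,
     "planted_component": "full", "signal_gain": 5.0}
)
stimulus = bc.generate_stimulus(n_words=2000, word_rate=2.54, n_stories=2, seed=0)
acts = bc.generate_layered_embeddings(stimulus, n_layers=5, dim=4, seed=1)
spec = bc.SyntheticSpec(n_subjects=6, n_voxels=10, voxel_plants=plants, seed=2)
runs, truth = bc.generate_bold(stimulus, acts, spec)

fc = bc.ForecastConfig(distance_grid=np.arange(-10, 21))
curves = bc.forecast_curves(acts[2], stimulus, runs, fc_config=fc)
dmap = bc.forecast_distance_map(curves, fc)

R = curves.baseline.values
print(f"group-mean brain score, planted voxels: {R[:, :4].mean():.3f}")
print(f"group-mean brain score, null voxels:    {R[:, 4:].mean():.3f}")
mean_curve = curves.values[:, :4].mean(axis=(0, 1))
peak = int(fc.distance_grid[np.argmax(mean_curve)])
print(f"forecast score peaks at d* = {peak} (F = {mean_curve.max():.3f})")
print(f"per-voxel mean d*: {dmap.dstar.mean(axis=0)[:4]}")
print(f"noise ceiling, planted voxels: {bc.noise_ceiling(runs).values[:, :4].mean():.3f}")
```

prints

```
group-mean brain score, planted voxels: 0.768
group-mean brain score, null voxels:    0.011
forecast score peaks at d* = 8 (F = 0.099)
per-voxel mean d*: [ 9.   8.   8.  10.5]
noise ceiling, planted voxels: 0.976
```

Planted voxels score far above the unplanted ones; appending the forecast
window raises their score most when the window ends exactly at the planted
distance (d\* = 8), and the per-voxel distance estimates recover the plant
to within a couple of words at this small scale. The noise ceiling (0.976)
confirms that almost all of the planted signal is shared across subjects
and hence explainable in principle.

The same analyses are available from the shell:

```bash
braincast simulate --config config.yaml --out data/
braincast embed --transcripts data/events.tsv --model fake --layers 0..12 --out acts.h5
braincast score --features acts.h5 --bold data/data.h5 --transcripts data/events.tsv --out scores.tsv
braincast forecast --features data/data.h5 --bold data/data.h5 --transcripts data/events.tsv --grid -10:30 --out forecast/
braincast ceiling --bold data/data.h5 --out ceiling.tsv
braincast objective --alpha 0.5
```

## Layout

```
src/braincast/
  synthetic.py       generators: stimuli, layered embeddings, tagged language, BOLD
  stimuli.py         transcripts, LM adapters, TR pooling, FIR expansion
  encoding.py        folds, LOO ridge, brain scores
  forecast.py        windows, forecast scores, distance/depth maps
  factorization.py   tag-matched futures, syntax/semantics split, component scores
  ceiling.py         cross-subject noise ceiling
  group_stats.py     Wilcoxon tests, BH-FDR, CIs, parcellation splitting, ROI tables
  objective.py       CPC/InfoNCE loss, mixture balancing
  io.py, cli.py      events TSV + HDF5 adapters, command line
docs/methods.md      model assumptions, parameter rationale, limitations
```
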