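# vocalmod

Analysis pipeline for individual differences in volitional social voice
modulation: rating-based performance indices, self-report reactivity
scoring, association models with influence diagnostics and robust
estimation, and voxelwise covariate inference with Monte-Carlo
cluster-extent correction — exercised end-to-end on synthetic data with
planted effects.

## What it computes

* **Performance indices** (`vocalmod.ratings`): per-speaker mean rating
  change of each trait-modulated recording over the neutral recording
  (Δ-trait), a 3×3 rating similarity matrix (RSM) of Pearson
  correlations between the likeable/hostile/intelligent scale vectors,
  and the **modulation index** — the Euclidean distance of the RSM to a
  theoretical maximal-discrimination matrix (off-diagonals −1, 0, 0)
  over the three unique off-diagonal cells (range 0 to √6 ≈ 2.45;
  lower = more specific trait expression).
* **Reactivity scoring** (`vocalmod.scales`): QCAE (31 items,
  cognitive 19–76 / affective 12–48) and SD3 (27 items, 9–45 per
  subscale) sum scores from editable YAML keymaps, plus Cronbach's α.
* **Association suite** (`vocalmod.association`): OLS of the modulation
  index on z-scored reactivity indices with age/sex covariates;
  externally studentized residual outlier tests with Bonferroni
  correction; a Shapiro–Wilk residual screen driving the exclusion
  rule; Huber M-estimator robust regression; partial Pearson
  correlations controlling age/sex with Benjamini–Hochberg FDR.
* **Voxel GLM** (`vocalmod.voxel`): per-voxel OLS of contrast volumes
  on a covariate of interest, t→z conversion, cluster-extent thresholds
  from Monte-Carlo simulation of smoothed Gaussian noise, and cluster/
  peak tables in mm coordinates (6/18/26 connectivity).
* **Synthetic data** (`vocalmod.synthetic`): the full study design —
  24 speakers, 24 listeners each rating 10 speakers with ≥10 raters per
  speaker, 5 recording conditions on 7-point scales, questionnaires
  with a planted correlation structure (Mach–psychopathy 0.60 by
  default), and smooth contrast volumes with a planted linear
  dependence on the modulation index — all driven by one seed.

## CLI

```bash
vocalmod simulate --out sim --seed 7            # synthetic study
vocalmod score   --items sim/questionnaire_items.csv \
                 --speakers sim/speakers.csv --out profiles.csv
vocalmod index   --ratings sim/ratings.csv --out idx
vocalmod regress --performance idx/performance.csv \
                 --profiles profiles.csv --out assoc
vocalmod voxelglm --volumes sim/volumes_4d.nii --covariate ed \
                 --performance idx/performance.csv --profiles profiles.csv \
                 --voxel-p 0.001 --alpha 0.05 --iters 1000 --out vox
vocalmod run     --out fullrun --seed 7         # all stages + manifest
```

`vocalmod run` writes a `manifest.json` (config snapshot, seed, output
checksums, per-stage status) sufficient to reproduce deterministic
outputs bit-identically.

## Layout

```
src/vocalmod/
  synthetic.py    simulation with planted ground truth
  ratings.py      Δ-trait, RSM, modulation index, one-sample t
  scales.py       QCAE/SD3 scoring, Cronbach alpha (data/ keymaps)
  association.py  OLS, diagnostics, robust fit, partial r, BH-FDR
  voxel.py        voxelwise GLM, MC cluster threshold, cluster tables
  io.py, cli.py   validated CSV/NIfTI I/O and the CLI
tests/            unit, property, and acceptance suites
scripts/acceptance.py
```
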