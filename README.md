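# amyseg

Multi-atlas segmentation of small lateralized brain structures in 3D scalar
volumes, with a built-in synthetic phantom generator for fully reproducible,
ground-truthed cohorts.

The pipeline:

1. **Intensity normalization** — 3-class tissue clustering, rescaling so the
   white-matter histogram mode sits at 80% of the 16-bit range, intensity
   squaring for peak separation, and a second rescale.
2. **Template construction** — iterative averaging with diffeomorphic warping
   and displacement demeaning over the training subjects; smoothed
   probabilistic label maps; automatic per-hemisphere ROI search boxes.
3. **Registration** — 6-dof rigid alignment plus a greedy diffeomorphic
   demons variant with a step-size cap and per-iteration field smoothing, run
   coarse-to-fine (default 4x subsampling / 80 iters, 2x / 80, full / 30).
   Every emitted field has a strictly positive Jacobian determinant.
4. **Label fusion** — each atlas is warped into the test ROI and votes per
   voxel with an inverse-patch-distance similarity weight; a structure is
   assigned where its weighted vote fraction reaches 0.5.
5. **Correction** — discrete AdaBoost over decision stumps (appearance,
   contextual and spatial features), trained by leave-one-out over the atlas
   set, flips systematically mislabeled voxels inside a learned working
   region.
6. **Evaluation** — Dice, Jaccard, volumes, Pearson r, and two-way
   single-measures ICC (consistency and absolute agreement).

Everything is deterministic given (inputs, config, seed).

## Test

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` holds the property-based acceptance suite
(metric oracles, registration contracts, fusion dominance, corrective
learning, warp bookkeeping, normalization, end-to-end determinism).

## CLI

```sh
# generate a seeded synthetic cohort (NIfTI images + labels + manifest)
amyseg simulate --n-train 20 --n-test 35 --shape 48 --seed 7 --out cohort/

# end-to-end run: normalize, build template, segment, correct, evaluate
amyseg run --train-dir cohort/ --test-dir cohort/ --out results/

# individual stages
amyseg normalize IN.nii.gz --mask MASK.nii.gz --out OUT.nii.gz
amyseg build-template cohort/ --iters 3 --out template/
amyseg register MOVING.nii.gz FIXED.nii.gz --schedule 4x80,2x80,1x30 --out-field FIELD.nii.gz
amyseg segment TEST.nii.gz --template template/ --out SEG.nii.gz --save-votes VOTES.nii.gz
amyseg train-corrector cohort/ template/ --rounds 100 --out-prefix model
amyseg correct SEG.nii.gz --model model_L.json --model model_R.json \
    --image TEST_TEMPLATE_SPACE.nii.gz --votes VOTES.nii.gz --out SEG_CORR.nii.gz
amyseg evaluate AUTO_DIR REF_DIR --out report.csv --out report.json
```

Pipeline tunables live in a YAML config (`--config`); unknown keys are
rejected and the effective config is serialized alongside every output
(`config.yaml`, `run_manifest.json`).

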