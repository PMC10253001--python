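# dtmt — double-teacher mean-teacher segmentation

`dtmt` is a semi-supervised pipeline for voxel-wise binary segmentation of 3D
grayscale volumes (the motivating task is left-atrium segmentation in
gadolinium-enhanced cardiac MRI) when only a small fraction of volumes carry
expert labels.  Volumes are sliced along Z and segmented by a 2D U-Net
student that learns from two teachers at once:

* **teacher 1** — an architecturally identical 2D network whose weights are an
  exponential moving average (EMA) of the student's,
  θ_T ← η·θ_T + (1−η)·θ_S with η = 0.99;
* **teacher 2** — a hybrid network that also sees a pseudo-3D stack of the
  slice and its through-plane neighbours, fusing a plane-collapsing 3D
  convolution stem with the 2D features of the centre plane.

The framework's signal on unlabeled slices is *inter-model discrepancy*.
With f_s, f_s1, f_s2 the student's final and two auxiliary probability maps
and f_t1, f_t2 the teachers' final maps:

* a confidence anchor `A = Σᵢ Sum(f_s(xᵢ)·yᵢ) / Σᵢ Sum(yᵢ)` (the batch-mean
  student probability on true target pixels of the labelled half) splits
  teacher 1's map into high- (f_t1 ≥ A) and low-confidence regions;
* the isomorphic map `D1 = High·D1h + Low·D1l` with
  `D1h = (a|f_s−f_t1| + b|f_s1−f_t1| + c|f_s2−f_t1|)·𝟙[f_t1 ≥ A]` (D1l
  analogous on the complement), and the heterogeneous map
  `D2 = a|f_s−f_t2| + b|f_s1−f_t2| + c|f_s2−f_t2|` combine into
  `D = m·D1 + n·D2`;
* D is driven toward the all-zero image by a discrepancy loss
  `l_D = MSE(D, 0)` and gates region-weighted consistency losses
  `l_Dcon = α·MSE on {D > TH} + β·MSE on {D ≤ TH}` between student and each
  teacher;
* the total objective is `l_total = X·l_sup + Y·l_D + Z·l_Dcon`, with a Dice
  supervised term on labelled slices and a warm-up ramp on the unsupervised
  terms.

The mean pixel value of D — the discrepancy rate `Dr` — is tracked per epoch
as a convergence diagnostic: as student and teachers learn from each other it
falls while test Dice rises.

The networks and their training (SGD with momentum, EMA updates) run on a
compact reverse-mode autodiff engine over numpy included in `dtmt.nn`;
gradients are verified against finite differences in the test suite.

## Worked example

A desk-scale study on bundled synthetic phantoms (bright blob plus satellite
blobs on a noisy darker background, sliced along Z like the real data; 20
volumes of 64×64×32 voxels, two held out, 10% of training volumes labelled):

```python
import dtmt

volumes = dtmt.generate_cohort(20, seed=1)
est = dtmt.DualTeacherSegmenter(base_channels=16, depth=3, input_size=64,
                                iterations=400, random_state=1)
est.fit(volumes)
print(est.evaluate().per_volume[["volume_id", "dice", "jaccard", "asd", "hd95"]])
```

prints (about four minutes on one CPU):

```
     volume_id      dice   jaccard       asd  hd95
0  phantom-001  0.959288  0.921762  0.329484   1.0
1  phantom-010  0.955079  0.914021  0.405478   1.0
```

Dice/Jaccard are overlap ratios in [0, 1]; ASD and HD95 are the average and
95th-percentile symmetric surface distances in voxels — here the predicted
boundary sits well under half a voxel from the reference on average.  The
fitted estimator exposes `history_` (per-iteration losses and diagnostics)
and `state_.dr_history` (the discrepancy rate); the epoch means of Dr for
this run decay 0.219 → 0.081 → 0.057 → 0.050 over the four unlabeled-pool
epochs.

The same pipeline is scriptable from the shell:

```
dtmt simulate --n-volumes 20 --shape 64 64 32 --seed 1 --out-dir data/
dtmt train --preset full --manifest data/manifest.csv --out-dir run/
dtmt predict --checkpoint run/checkpoint.npz --in data/phantom-000_image.nii.gz --out mask.nii.gz
dtmt evaluate --checkpoint run/checkpoint.npz --manifest data/manifest.csv --out metrics.csv
```

Four configuration presets mirror the framework's ablation grid:
`teacher1` (2D teacher only), `teacher1_po` (+ anchor-based prediction
optimisation), `teacher1_teacher2` (+ hybrid teacher), and `full`.

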