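# affectmvpc

Multivoxel pattern classification (MVPC) of dimensional affect —
decoding binarized **valence** (positive vs. negative, split at the
9-point scale midpoint `V ≥ 5.0`) and **arousal** (high vs. low,
`A ≥ 5.0`) from per-stimulus brain activation maps, for researchers
studying how affective dimensions are distributed across the brain.

The package implements the full analysis chain around a linear
soft-margin SVM decoder:

- **class-balanced rotation cross-validation** — for each held-out
  subject the majority label class (`N_max` stimuli) is rotated through
  circular windows of minority-class size `N_min`, so every test pool is
  exactly balanced and every stimulus is tested; `N_max` rotation
  accuracies average into one per-subject accuracy, summarized as
  mean ± t-based 95% CI with a one-sample t-test against chance 0.50;
- **univariate pipeline** — condition GLMs and trial-wise
  least-squares-separate (LSS) beta series, voting-rule group
  gray-matter masks, group t-maps, Monte-Carlo cluster-extent
  correction (two-sided, face-connected), ROI masks with relaxed
  thresholds and morphological dilation;
- **cluster stability** — greedy size-ordered matching of leave-one-out
  cluster maps onto group clusters by center-of-mass distance;
- **decoder interpretation** — forward encoding patterns
  `a = Cov(X)·w`, hyperplane-distance projections into (V, A) space
  with an observed vs. ideal separating line, and a Gaussian-process
  surface of joint misclassification `p_joint = p_V · p_A` (chance
  0.25) on warped probabilities `y = atanh(2p − 1)` over the grid
  V ∈ [1, 9] × A ∈ [2, 7.5];
- **synthetic data generator** — tiered stimulus sets, brain states with
  planted linear affect encodings of controllable SNR
  (`β = snr·(w_V·g(V) + w_A·g(A)) + offset + smooth noise`,
  `g(r) = (r−5)/4`), per-subject gray-matter masks, and event-related
  BOLD timeseries, so the whole pipeline is testable end to end without
  any data download.

See `docs/methods.md` for the model details, defaults, and limitations.

## Worked example

```python
from affectmvpc import AffectDecoder, MisclassificationGP, synthetic
from affectmvpc.datasets import VolumeGeometry

geom = VolumeGeometry((12, 12, 12))                      # 1728 voxels, 3 mm
stimuli = synthetic.generate_stimulus_set(n_stim=88, seed=0)
encoding = synthetic.random_encoding_spec(geom, snr=0.5, seed=1)
data = synthetic.generate_subject_betas(stimuli, 16, geom, encoding,
                                        stimuli_per_subject=44, seed=2)

valence = AffectDecoder(data, stimuli, target="valence").fit()
print(valence.summary())
```

```
AffectDecoder results (inter-subject LOOCV, target=valence)
================================================================
subjects:   16    classifier: linear SVM (C=1.0)
mean accuracy: 0.6906   95% CI [0.6641, 0.7171]
t vs 0.50: 15.329   p = 1.428e-10
mean TPR: 0.7179   mean FPR: 0.3367
```

At this SNR the planted valence pattern supports ~69% leave-one-subject-
out accuracy, significantly above the 0.50 chance level.  Joint analysis
of the two decoders locates where in affect space classification fails:

```python
arousal = AffectDecoder(data, stimuli, target="arousal").fit()
gp, joint = MisclassificationGP.from_results(valence, arousal, seed=3)
surface = gp.fit().predict_surface()
print(f"mean joint misclassification: {joint['p_joint'].mean():.4f}")
print(f"hardest region: V={surface.argmax[0]:.2f}, A={surface.argmax[1]:.2f}")
```

```
mean joint misclassification: 0.1478
hardest region: V=4.50, A=6.60
```

The mean joint error 0.148 sits well below the 0.25 chance product, and
the GP surface points at mid-valence / high-arousal stimuli as the
hardest to classify for this particular planted encoding.
`valence.encoding_map()` returns the decoder's forward encoding pattern;
on this dataset it correlates r = 0.53 with the planted valence weights
(rising above 0.9 as SNR grows).

The same pipeline runs from the shell:

```bash
affectmvpc all --seed 2 --out run1        # simulate → classify → interpret
affectmvpc simulate --out sim1 --seed 4   # synthetic dataset only
```

writing stimulus tables (CSV), beta volumes and masks (NIfTI-1), cluster
and classification tables (CSV), and a `metrics.json` report.

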