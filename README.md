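# ceusvv

Quantification of adventitial **vasa vasorum** (VV) from contrast-enhanced
ultrasound (CEUS), with a fully synthetic validation cohort.

Proliferation of the vasa vasorum — the microvessel network in the
adventitia of large arteries — marks atherosclerosis progression and can
precede intimal thickening. CEUS sees it: intravenous microbubbles raise
video-intensity wherever perfused vessels exist, so the enhancement of the
adventitia, read from a region of interest (ROI) over time, is an in-vivo
proxy for VV density. This package implements that quantification end to
end and, because no imaging data of this kind is publicly deposited,
ships a synthetic cine-loop/cohort generator with exact ground truth so
every stage is verifiable.

## The statistic

For each ROI the **time–intensity curve** (TIC) is the mean video-intensity
per frame. With background *I₀* estimated from the frames before the
microbubble destruction pulse, the **maximal video-intensity enhancement**
is

    MVE = max_t TIC(t) − I₀

and the headline quantity is the dimensionless **normalized MVE**,

    nMVE = MVE_adventitia / MVE_lumen ,

the adventitial enhancement normalized by a luminal reference ROI drawn
proximal to the lesion, which cancels acquisition gain. Synthetic
compartments follow destruction–replenishment kinetics
*I(t) = I₀ + A(1 − e^(−βt))*, so the true nMVE of a simulated vessel is an
amplitude ratio known exactly. Group analysis uses one-way ANOVA,
Dunnett-T3 pairwise comparisons (unequal variances, studentized-maximum-
modulus adjustment), and Pearson correlation of nMVE against two-observer
CD31/VEGF microvessel counts.

## Worked example

`python examples/extract_and_quantify.py` renders a noiseless 16×16 vessel
phantom (lumen amplitude 40, adventitia 16, β = 0.5/s, pulse at 2 s),
extracts TICs through polygon ROIs and quantifies them:

```
cine loop: 111 frames, destruction pulse at 2.0 s
lumen       n_pixels= 56  background=10.000  peak= 49.998 at t=22.0 s  MVE=39.9982
adventitia  n_pixels= 28  background=10.000  peak= 25.999 at t=22.0 s  MVE=15.9993
normalized MVE = 0.400000  (true amplitude ratio 16/40 = 0.4)
```

The luminal MVE equals the closed form 40(1 − e^(−10)) ≈ 39.9982 and the
normalized MVE recovers the configured amplitude ratio exactly.

`python examples/cohort_study.py` simulates the six-group graded cohort
(control; 4/8/12 weeks of high-fat diet; small plaque; near-occlusive
plaque, which contributes histology only) and runs the full report:

```
normalized MVE by group (mean +/- SD):
  group 0:  0.147 +/- 0.060  (n=10)
  group 1:  0.242 +/- 0.112  (n=10)
  group 2:  0.408 +/- 0.188  (n=10)
  group 3:  0.612 +/- 0.192  (n=10)
  group 4:  0.581 +/- 0.319  (n=10)

one-way ANOVA across groups: F = 10.93, p = 2.81e-06

Dunnett T3 vs control (normalized MVE):
  group 0 vs 1:  T3 =  2.365, adjusted p = 0.2492
  group 0 vs 2:  T3 =  4.178, adjusted p = 0.01408
  group 0 vs 3:  T3 =  7.312, adjusted p = 0.0001607
  group 0 vs 4:  T3 =  4.218, adjusted p = 0.01656

correlation of normalized MVE with histology counts:
  cd31_mean  r = 0.933  (n=50, p = 6.11e-23)
  vegf_mean  r = 0.870  (n=50, p = 2.30e-16)
```

Enhancement increases with disease stage (significant for the later
groups after the multiplicity adjustment) and tracks the microvessel
counts driven by the same latent density. See `docs/methods.md` for the
models, conventions and calibration behind these numbers — including why
the simulated correlations are stronger than real-cohort values.

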