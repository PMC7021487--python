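# mtquant

Quantification of **microtubule sliding**, **microtubule–protein
colocalization** and **dendritic-arbor morphometry** from fluorescence
microscopy, with a synthetic-data generator that provides analytic ground
truth for every stage.

The package is aimed at labs measuring motor-driven microtubule transport
in *Drosophila* S2 cells and neurons with photoconvertible tubulin
(tdEos/tdMaple): tubulin is photoconverted inside a confined zone, the cell
is imaged every minute for ~10 minutes, and the movement of the converted
signal out of the zone reports microtubule–microtubule sliding.

## The statistics it computes

**Sliding rate.** Per frame, the *motile fraction* is

```
f(t) = MT_outside_initial_zone(t) / MT_total(t)
```

counted in thresholded converted-tubulin pixels. The slope of the linear
portion of f(t), in fraction/min, is the sliding rate; rates are reported
as fold of the matched control-group mean, so the control averages exactly
1.0. The full chain is: simple-ratio bleach correction (frame sums
renormalized to frame 0), denoising, Otsu threshold fixed from frame 0,
pixel counting against the initial zone, and an objective linear-window
OLS fit (longest window from t=0 with R² ≥ 0.9, minimum 5 points).

**Colocalization.** Percent of microtubule mask area overlapped by a
second channel's mask (a binary-mask Manders-M1-style area overlap):
`100 · |MT ∧ Pav| / |MT|` with per-channel Otsu thresholds. Off-microtubule
signal (e.g. nuclear pools) cannot contribute because both numerator and
denominator are restricted to the microtubule mask.

**Arbor morphometry.** Hessian ridge ("tubeness") enhancement → Otsu →
topology-preserving skeletonization → total skeleton length (µm, by
chord-resampled branch chains) and branch-point count (skeleton pixels
with ≥3 neighbors, clustered per junction).

**Group statistics.** Mean ± SEM with t-based 95% CIs, pooled-variance
Student's t-tests, one-way ANOVA with Sidak (`1−(1−p)^m` over the m
requested pairs) or Tukey post-hoc correction, and western-blot
phospho/total ratios normalized to a control lane.

## A worked example

```sh
python examples/01_sliding_assay.py
```

```
control: measured slope 0.00209 fraction/min (R^2 0.986, frames (0, 10)), ground-truth fraction reaches 0.022 by 10 min
fast: measured slope 0.00456 fraction/min (R^2 0.996, frames (0, 10)), ground-truth fraction reaches 0.044 by 10 min
```

Two movies are simulated with identical conditions except the
translocation velocity of the motile 10% of microtubules (0.15 vs
0.30 µm/min). The measured slopes — the per-minute growth of the share of
converted tubulin outside the conversion zone — recover the 2× velocity
difference (0.00456/0.00209 ≈ 2.2). `examples/02–04` walk through
colocalization, morphometry and the statistical reporting the same way.

The same pipelines are scriptable from the shell:

```sh
mtquant simulate sliding --seed 1 --out demo/
mtquant e2e-demo --seed 1 --out demo-e2e/
mtquant slide --movies movies/ --groups groups.csv --zone auto --out rates.csv
```

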