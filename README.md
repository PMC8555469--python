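# plvnet

EEG functional-connectivity analysis for motor-imagery BCI performance
groups: phase-locking values (PLV) from complex Morlet wavelet phases,
aggregated at three network scales and compared between High and Low
performers with permutation factorial ANOVA — plus a synthetic
phase-coupled EEG generator with exact ground truth, so the whole chain is
testable without any recordings.

## The problem

A sizeable fraction of motor-imagery BCI users cannot produce brain
patterns a classifier can separate ("BCI inefficiency", accuracy below
~70%). One candidate neural marker is phase synchronization between
sensorimotor electrodes. The question this pipeline answers: do High and
Low performers differ in alpha/beta-band phase locking — at rest, during
motor imagery, and in the rest→MI change — and at which spatial scale
(whole-head, inter-hemispheric, or within the C3/C4 neighbourhoods)?

## The statistic

For electrodes *i, j*, instantaneous phases φᵢ(t, n), φⱼ(t, n) are
extracted per trial *n* by convolution with a complex Morlet wavelet
ψ(t) = (π f_b)^(−1/2) e^(j2π f_c t) e^(−t²/f_b) (alpha: f_c = 10.5,
f_b = 0.3; beta: f_c = 21.5, f_b = 0.13). The inter-trial PLV at time t is
the mean resultant length

    PLV(t) = (1/N) | Σₙ exp( j [φᵢ(t, n) − φⱼ(t, n)] ) | ,

averaged over the analysis window (rest: 0–3 s of each 8 s trial; MI:
1–4.5 s after the 3 s cue), and ΔPLV = PLV_MI − PLV_Rest. Preprocessing
before phase extraction: common average reference → 8–30 Hz zero-phase
FIR band-pass → spherical-spline surface Laplacian (spline order 4,
regularization 1e-5). Pairwise PLV is averaged into four scales: global
(all 120 pairs of 16 channels), large (25 pairs between the left hub
FC5/FC1/C3/CP5/CP1 and right hub FC6/FC2/C4/CP6/CP2), and local left /
local right (C3 resp. C4 with their 4 hub neighbours).

Subjects are median-split on online BCI accuracy (the median subject is
excluded, leaving balanced groups). Per scale, band and window, the
scale-averaged PLV enters a 2×2 factorial ANOVA (group × imagined hand,
with interaction) whose p-values come from 999 restricted permutations
(group labels permuted at the subject level; hand values swapped within
subjects), with two-sample permutation t-tests post hoc and Bonferroni
control at 0.05/6 = 0.008 across 3 activity types × 2 bands.

## Worked example

Simulate a 13-subject cohort in which the High aptitude class tightens
its right-hub coupling during motor imagery (von Mises κ = 1.0 vs 0.5),
run the full chain, and read the group tests for the MI window:

```python
import json, pandas as pd, plvnet as pv

cfg = pv.RunConfig(bands=("alpha",), n_subjects=13)
paths = pv.run_pipeline(cfg, "out/", seed=7)

m = json.loads(open(paths["manifest"]).read())
print(m["n_high"], m["n_low"], m["excluded_subjects"])   # 6 6 ['S09']

df = pd.read_csv(paths["stats"])
print(df[(df.window == "mi") & (df.effect == "group")]
      [["scale", "F", "p", "significant_at_adjusted"]])
```

which prints (seed 7):

```
      scale         F     p  significant_at_adjusted
     global  3.673274 0.164                    False
      large  1.450948 0.266                    False
 local_left  0.281336 0.572                    False
local_right 47.358456 0.003                     True
```

Exactly the pattern the method is built to localize: the group difference
shows up only at the right-hemisphere local scale, while whole-head and
inter-hemispheric averages — where the localized effect is diluted and
between-subject heterogeneity dominates — stay non-significant. In this
alpha-only run the manifest records an adjusted threshold of 0.05/3 =
0.017; the full two-band analysis uses 0.05/6, displayed as 0.008.

The same stages are exposed as a CLI
(`plvnet simulate | preprocess | connectivity | scales | stats | run`),
e.g. `plvnet run --out out/ --seed 7`.

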