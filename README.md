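# ttgsim

Rigid-body simulation of how the **screw-home mechanism** — the obligatory
external rotation of the tibia during terminal knee extension, reversed as
internal rotation in early flexion — changes the **TT-TG distance**, the
axial separation between the tibial tuberosity (TTP) and the trochlear groove
centre (TGCP) used to grade patellofemoral instability and plan tibial
tuberosity osteotomies.

TT-TG is measured by orthogonally projecting TTP and TGCP onto the posterior
condylar axis (the line through the posterior extremes of the medial and
lateral femoral condyles, FMCP–FLCP):

```
TT-TG = (TTP − TGCP) · â,   â = (FLCP − FMCP)/|FLCP − FMCP|
```

positive = lateralised tuberosity. Knee flexion is simulated as rotation of
the tibia about the **FAR** axis (femoral axial rotation: the least-squares
cylinder through both femoral condyles, a surrogate for the surgical
transepicondylar axis) and tibial internal rotation about the **TAR** axis
(tibial axial rotation: the anatomical tibial long axis through the 1/3 and
2/3 shaft midpoints, TAPP/TADP). Every pose of a flexion × rotation grid
(defaults 0–30° × 0–20°, in 10°/5° steps) is a rigid transform of the tibial
landmarks; the femur never moves.

Because no real CT cohort ships with the package, a calibrated synthetic
generator (`ttgsim.synthetic`) produces knee specimens — condylar cylinder
surface samples, the full landmark roster, left/right sides, random world
poses — with a baseline TT-TG distribution calibrated in closed form to
14.1 ± 4.0 mm, and records every generative draw as ground truth so the
whole pipeline can be verified against analytic oracles. Cohort statistics
follow the repeated-measures design: Shapiro–Wilk screening, paired Friedman
tests per flexion angle, pairwise Wilcoxon signed-rank post-hocs with
Bonferroni correction.

## Worked example

```python
import ttgsim as tg

params = tg.SyntheticKneeParams(seed=1)           # n = 56 knees
cohort = tg.sample_cohort(params)
long_df = tg.simulate_cohort(lm for lm, _ in cohort)

summary = tg.summarize(long_df)
print(summary.loc[(0.0, 0.0)].round(2))           # baseline pose
#  n            56.00
#  mean         14.28
#  sd            3.49
#  ci95_low     13.34
#  ci95_high    15.22

delta = tg.summarize_delta(tg.cohort_delta(long_df))
print(delta.loc[(10.0, 5.0), ["mean", "sd"]].round(2))
#  mean   -2.72
#  sd      0.24
```

The baseline cohort sits at its calibration target (14.28 ± 3.49 mm here);
5° of internal rotation at 10° flexion shifts TT-TG by −2.72 mm on average —
the tuberosity medialises by roughly the anterior lever arm times sin(5°) —
and the loss attenuates at deeper flexion (−1.67 mm at 30°). Pairwise
rotation comparisons within each flexion angle are all Bonferroni-significant
(p < 10⁻⁹), while isolated flexion changes nothing
(`tg.flexion_effect_tests(long_df)` → Friedman p ≈ 0.33).

The same pipeline accepts real data: a landmark CSV (`name,x,y,z` in mm, one
row per landmark) via `tg.read_landmarks`, with condylar surface points
sampled from a segmented PLY/STL bone mesh via `tg.condyle_points_from_mesh`.

A CLI wraps the same steps:

```sh
ttgsim run --n 56 --seed 1 --outdir out/   # simulate + tables + boxplot
ttgsim generate --n 10 --seed 2 --out cohort/
```

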