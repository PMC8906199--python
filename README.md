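# contourval

A toolkit for the **clinical validation of auto-contouring workflows** in
radiotherapy planning: it quantifies whether atlas-assisted contours that
an observer then edits (**AM**) are as repeatable, consistent, fast and
unbiased as contours the same observer draws manually from scratch
(**M**).

It is written for medical physicists and radiation oncology researchers
who run multi-observer delineation studies — several radiation
oncologists (ROs) contouring pelvic structures (bladder, rectum, pelvic
lymph nodes, femoral heads) on the same planning CTs, twice per method —
and need the full statistical machinery to analyze them:

- **Similarity metrics** between binary masks on anisotropic voxel grids:
  the Dice similarity coefficient
  `DSC = 2|A ∩ B| / (|A| + |B|)` and the mean distance to agreement
  (MDA), the symmetrized mean surface distance
  `MDA = (d(∂A→∂B) + d(∂B→∂A)) / 2` in mm, computed with a spacing-aware
  exact Euclidean distance transform.
- **STAPLE label fusion** (Simultaneous Truth and Performance Level
  Estimation): binary EM that fuses all raters' masks of one structure
  into a consensus reference while estimating each rater's sensitivity
  `p_j` and specificity `q_j`.  The E-step computes the posterior
  foreground probability `W_i = a_i / (a_i + b_i)` with
  `a_i = γ Π_j p_j^{D_ij}(1−p_j)^{1−D_ij}` and
  `b_i = (1−γ) Π_j (1−q_j)^{D_ij} q_j^{1−D_ij}`; the M-step re-estimates
  `p_j = Σ W_i D_ij / Σ W_i` and `q_j = Σ(1−W_i)(1−D_ij) / Σ(1−W_i)`.
- **Variability analyses**: intra-observer (session 1 vs session 2 of the
  same observer) and inter-observer (each observer vs the STAPLE
  reference) DSC/MDA index tables, compared between M and AM with
  normality-gated paired tests (Shapiro–Wilk on the differences chooses
  paired *t* vs exact Wilcoxon signed-rank), IQR ratios and
  5th/95th-percentile boxplot summaries.
- **Timing analysis**: per-ROI and whole-pelvis contouring-time savings
  `|T_M − T_AM| / T_M`, plus 16 paired *t*-tests for session consistency
  and M-vs-AM differences.
- **Blind-review bias test**: paired accept/reject decisions on
  anonymized contours feed a 2×2 contingency table and McNemar's test
  (exact binomial and continuity-corrected χ², both two-sided).
- **A synthetic study simulator** that generates complete studies —
  ground-truth organs, multi-rater/multi-session masks under either an
  i.i.d. label-flip model (STAPLE's own generative model) or a
  spatially-correlated boundary-noise model, lognormal contouring times
  and paired review decisions — so every stage of the pipeline is
  testable without patient data.

## Worked example

```python
import contourval as cv
from contourval.io_model import StudyDesign
from contourval.synthetic import SimulationConfig, simulate_decisions

design = StudyDesign(subjects=("s1", "s2"), raters=("RO1", "RO2", "RO3"))
study = cv.simulate_study(SimulationConfig(design=design, seed=7))

for method in ("M", "AM"):
    table = cv.intra_observer_indices(study, method)
    print(f"intra-observer medians ({method}):")
    print(table.groupby("structure")[["dsc", "mda_mm"]].median().round(3))

timing = cv.timing_summary(study)
pelvis = timing[timing["scope"] == "pelvis"].iloc[0]
print(f"pelvis: T_M = {pelvis['t_m_min']:.1f} min, "
      f"T_AM = {pelvis['t_am_min']:.1f} min, saving = {pelvis['pct_saving']}%")

report = cv.bias_analysis(simulate_decisions(SimulationConfig(design=design, seed=7)))
print(f"blind review: table = {report['table']}, "
      f"McNemar exact p = {report['p_exact']:.3f}")
```

prints

```
intra-observer medians (M):
                  dsc  mda_mm
PLN             0.901   1.657
bladder         0.933   0.804
femoral_head_L  0.944   0.511
femoral_head_R  0.797   1.939
rectum          0.836   1.533
intra-observer medians (AM):
                  dsc  mda_mm
PLN             0.979   0.299
bladder         0.964   0.397
femoral_head_L  0.951   0.356
femoral_head_R  0.951   0.358
rectum          0.948   0.546

pelvis: T_M = 36.7 min, T_AM = 20.6 min, saving = 44%
blind review: table = {'n_nn': 1, 'n_ny': 1, 'n_yn': 1, 'n_yy': 21}, McNemar exact p = 1.000
```

Because this simulated study uses boundary noise for AM at half the M
level, AM contours are more repeatable (higher DSC, lower MDA) for every
structure, editing roughly halves the whole-pelvis contouring time, and
the blind review shows no detectable bias — the qualitative pattern such
a validation study is designed to detect.

The same analyses are available from the shell via the `contourval` CLI
(`simulate`, `metrics`, `staple`, `intra`, `inter`, `timing`, `bias`,
`run-all`, `report`); `run-all` writes `intra_indices.csv`,
`inter_indices.csv`, `method_comparison.json`, `timing_summary.csv`,
`timing_tests.json`, `bias_report.json` and `run_report.json` into an
output directory.

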