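# timask — time-intensity curve analysis for flavor-masking chemometrics

`timask` is a Python library for **time-intensity (TI) sensory analysis**:
panels record the perceived intensity of a flavor attribute every second
while tasting, and the resulting curves are distilled into scalar
descriptors that explain which flavoring materials best *mask* an
unpleasant off-flavor (the motivating case: the beany note of soy
products). It is written for sensory scientists and flavor chemists who
have replicate TI curves and visual-analog-scale (VAS) ratings and want a
reproducible, scriptable path from raw curves to a masking-ability
classification — plus a fully seeded synthetic panel generator so every
stage can be exercised without proprietary panel data.

## The method

**TI parameters.** Each material's replicate curves are smoothed (centered
moving average), the three most *intermediate* replicates are kept (rank
distance from the per-landmark median ranks of Imax, TsPl and Tend), and
the survivors are averaged. The average curve I(t) is segmented into an
increasing phase, an optional plateau around the maximum, and a decreasing
phase, yielding 14 descriptors: onset and end of sensation (Tstart, Tend),
peak intensity (Imax), plateau bounds and duration (TsPl, TePl, DurPl),
phase durations (DurInc, DurDec), maximum phase slopes (SIMInc, SIMDec),
and trapezoidal phase areas (AreaInc, AreaPl, AreaDec) with their total
AreaTse = AreaInc + AreaPl + AreaDec.

**Masking score.** Panelists rate residual off-flavor intensity on a 0–10
VAS; a material's masking score is

    masking score = 10 − median(beany intensity),

so 10 means complete suppression. A median of 4.0 scores 6.0.

**Statistics.** Near-collinear parameters (|r| ≥ 0.98 Pearson) are pruned
to one representative per correlation group; each retained parameter is
compared between the top-10 and bottom-10 masking materials with a
two-tailed Mann–Whitney U test (exact null distribution for tie-free
samples up to n+m = 24, tie-corrected normal approximation otherwise),
α = 0.05, no multiplicity correction.

**Classification.** PCA on the retained materials × parameters matrix
(raw-scale by default — see `docs/methods.md` for why — standardized via
one config flag), then seeded k-means (k = 3, k-means++, 10 restarts) in
the PCA1–PCA2 plane. Clusters are relabeled deterministically so the
highest-masking cluster always carries the largest label.

## Worked example

```python
from timask import RunConfig, run_pipeline

res = run_pipeline(RunConfig(seed=1))          # 100 materials, 10 panelists
print(res.report.loading_table.round(3).head(3).to_string(index=False))
print(res.report.cluster_table.round(1).to_string(index=False))
```

prints (full output in `examples/05_classify_materials.py`):

```
parameter  loading_pc1  abs_loading
  AreaDec        0.985        0.985
  AreaInc        0.163        0.163
   DurDec        0.056        0.056
 cluster  n  mean_masking_score
       0 56                 4.6
       1 27                 7.5
       2 17                 9.8
```

Reading this: the first principal component of the TI-parameter matrix is
dominated by **AreaDec**, the area under the decreasing phase — its
loading is about six times that of the runner-up AreaInc — and the
materials in the high-PCA1 cluster (label 2) average a masking score of
9.8 versus 4.6 in the low cluster. The decay-phase exposure of a flavoring
material is the strongest single correlate of how well it masks the
off-flavor; the top-10 vs bottom-10 comparison (see
`examples/04_compare_groups.py`) flags the same parameter at p < 10⁻⁴.

Each script in `examples/` is a self-contained narrative: simulate a
study, extract parameters, score masking, compare groups, classify, and
run the whole pipeline with artifacts.

A thin CLI mirrors the stages:

```bash
timask simulate --config run.yaml --out study/
timask extract  --curves study/curves.csv --out study/
timask score    --vas study/vas.csv --out study/masking.csv
timask compare  --params study/params.csv --masking study/masking.csv -k 10
timask classify --params study/params.csv --masking study/masking.csv --seed 42
timask run-all  --config run.yaml --out study/
```

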