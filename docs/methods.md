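# Methods

This note documents the models, conventions and numerical choices behind
`timask`, in the order the pipeline applies them, together with what the
synthetic generator does and does not emulate.

## Curve processing

A replicate TI curve is a 1 Hz sampling of perceived intensity on a 0–100
scale, starting at t = 0. Processing per material:

1. **Smoothing** — centered moving average, default window 5 s, window
   shrinking symmetrically at the ends so the grid is preserved. The
   method is deliberately the simplest one consistent with the visual
   effect of commercial TI software; any smoother that never expands the
   curve's range would do, and the window is a config entry.
2. **Representative selection** — each replicate is summarized by three
   landmarks (Imax, TsPl, Tend); replicates are mid-ranked per landmark
   and the three with the smallest summed |rank − median rank| are kept.
   This operationalizes "intermediate measurements" as a scale-free
   outlier exclusion; ties break to the lower replicate index so the
   selection is deterministic and permutation-invariant.
3. **Averaging** — point-wise mean with zero-extension to the longest end
   time (after a sensation ends its intensity is 0 by definition). The
   default averages within each (material, panelist) first and then
   across panelists, so a panelist with more replicates does not dominate;
   a pooled mode selects representatives across all of a material's
   curves at once.

## Phase segmentation and the 14 parameters

Onset/offset and the plateau criterion are not standardized anywhere in
the TI literature (commercial packages keep them internal), so all four
tunables are explicit:

| tunable | default | meaning |
|---|---|---|
| `eps_i` | 1.0 a.u. | onset/offset intensity threshold |
| `min_dur_s` | 2 s | excursions must be sustained this long |
| `eps_pl` | 0.002 | plateau band as a fraction of Imax |
| `min_plateau_s` | 3 s | shorter near-peak intervals collapse to the peak |

Tstart is the first sample strictly above `eps_i` whose excursion lasts at
least `min_dur_s`; Tend is the symmetric last one. The plateau is the
maximal contiguous interval containing the (earliest) global argmax on
which intensity stays within `eps_pl · Imax`; if shorter than
`min_plateau_s` it collapses to the single peak time and DurPl = AreaPl
= 0. Slopes are consecutive-sample differences (SIMDec reported as a
positive magnitude); areas are trapezoidal on the detected boundaries,
and AreaTse is defined as the sum of the three phase areas so additivity
is exact by construction.

**Why the plateau band is 0.2% and the minimum 3 s.** A plateau should
mean the panel *held* the maximum, not that the curve was merely near it.
A slowly decaying release (decay constant τ) stays within a fraction ε of
its peak for τ·ln(1/(1−ε)) seconds: with ε = 5% and τ = 60 s that is
≈ 3 s of ordinary decay shoulder, and averaging onset-jittered replicates
rounds the peak further — under such a band roughly half of all simulated
continuous-release materials acquire spurious plateaus. With ε = 0.2%
(about the recording resolution of the 0–100 scale relative to a typical
peak) the slowest plausible shoulder lasts ≈ 0.1 s, far below the 3 s
minimum (itself ≈ two breathing cycles at the 40 bpm pacing used in TI
panels), so only genuinely sustained maxima qualify. Exactly flat tops of
any height are unaffected. Under the defaults no simulated material shows
a plateau, matching the empirical observation that continuous-release
flavoring materials do not plateau.

**Onset convention and its area bias.** Because phase areas integrate
from the *detected* boundaries, the sub-threshold "toe" of the ramp (the
interval before the first sample above `eps_i`) is excluded. For a linear
ramp of duration D sampled on-grid the excluded toe is exactly a fraction
(offset/D)² of the increase-phase area, with offset ≤ 1 s — negligible
for slow-release materials (< 1% at D ≥ 12 s) but up to 6% at D = 4 s.
The alternative (extending integration one sample below threshold) was
rejected because it mis-attributes area to instantaneous-onset signals; a
step curve must have AreaInc = 0. Off-grid peaks additionally alias up to
a few per cent of area between the increase and decrease phases at 1 Hz
sampling; oracle tests therefore use grid-aligned archetypes to isolate
extraction fidelity from sampling artifacts.

## Masking scores

VAS ratings are stored on the 0–10 scale (mm/10). The per-material median
pools all ratings (midpoint rule for even counts); the masking score is
10 − median, computed at full precision and rounded only for reporting.
Top-k/bottom-k ranking sorts by score with material-id tie-breaks and
includes *all* materials tied at the k boundary, so an extreme group can
exceed k members.

## Group statistics

Collinear parameters carry no independent information, so the 14 columns
are pruned before testing: identically zero plateau columns are dropped
first, then columns are grouped by |Pearson r| ≥ 0.98 (connected
components) and one representative is kept per group — by field
convention DurInc for the increase-timing group {TsPl, TePl, DurInc},
DurDec for {DurDec, Tend}, AreaDec for {AreaDec, AreaTse}; otherwise (and
always in `mode="auto"`) the highest-variance member. Every exclusion is
reported with its reason and the correlation that triggered it.

The Mann–Whitney U test returns U = min(U₁, U₂) with midrank ties. The
p-value is exact (full null distribution) for tie-free samples with
n + m ≤ 24 — which covers the 10-vs-10 design exactly — and otherwise a
normal approximation with tie and continuity corrections; the path used
is logged per comparison. At n = m = 10 the two paths agree within 0.01
absolute p. No multiplicity correction is applied across the retained
parameters; each comparison is reported with its own p.

## Classification

PCA is computed with all components (explained-variance ratios sum to 1);
component signs follow the convention that each component's
largest-magnitude loading is positive. k-means (k = 3 default) runs in the
PCA1–PCA2 score plane with k-means++ initialization, 10 restarts, and a
fixed seed; configurable to the full parameter space. Because raw k-means
labels are permutation-arbitrary, clusters are relabeled so the cluster
with the highest mean masking score receives the *largest* label (without
masking data: the highest centroid PCA1), making "the high-masking
cluster" a stable identifier across runs.

**Raw-scale vs standardized PCA.** Both are implemented;
`RunConfig.pca_on_raw=True` is the pipeline default. The choice matters:
on standardized data the type-linked timing parameters (DurInc, TsPl,
DurDec) and the areas all load comparably on PC1 (|loadings| ≈ 0.34–0.42
on synthetic studies) because standardization erases the areas' scale
advantage; on raw-scale data AreaDec — whose variance (units a.u.·s,
values in the thousands) dwarfs every other column — dominates PC1 almost
entirely (loading ≈ 0.985, PC1 carrying ~99% of variance, top-two loading
ratio ≈ 6×). The characteristic published loading pattern for this kind
of analysis — a single dominant decay-area coefficient with a ~98% first
component — is only producible on raw-scale data; a 0.985 unit-norm
loading with 98% explained variance is arithmetically impossible for
eight standardized, weakly correlated columns. The package therefore
defaults to the raw-scale analysis for classification while keeping
standardization one flag away; note that on raw scale the loading
magnitudes reflect units as much as importance, which is exactly why the
group comparison (unit-free, rank-based) is run alongside.

## Synthetic studies

Each material is a **ramp + exponential decay** archetype: intensity 0
until `t_start`, linear rise to `i_peak` over `dur_inc`, then
`i_peak·exp(−t/τ)` truncated where it falls below `cutoff` (= 1 a.u., the
onset threshold). This is the simplest family with independent control of
the increase- and decrease-phase descriptors, and every TI parameter has
a closed form (e.g. AreaInc = ½·i_peak·dur_inc, DurDec = τ·ln(i_peak/
cutoff), AreaDec = τ·(i_peak − cutoff)) — the oracles for the extraction
tests.

Type ranges (uniform draws) encode the release kinetics of the three
commercial material classes — oil-soluble/low-volatility materials
release slowly and persist, water-soluble/high-volatility essences spike
and vanish, "flavor"-type materials sit between:

| type | dur_inc (s) | τ (s) |
|---|---|---|
| oil | 12–22 | 30–60 |
| essence | 4–8 | 8–15 |
| flavor | 8–14 | 15–30 |

with shared `t_start` ∈ [4, 8] s and `i_peak` ∈ [30, 90] a.u. The default
study is 100 materials (33/33/34 by type), 10 panelists, 6 replicates per
material and panelist, one VAS rating per material and panelist.

Noise model, chosen once at what a panel study plausibly shows: a
per-panelist multiplicative intensity scale (sd 0.15 — panelists use the
scale consistently but differently), per-replicate onset jitter (sd 1 s),
per-sample Gaussian intensity noise (sd 3 a.u., added only where the
underlying sensation is non-zero — a panelist does not move the cursor at
baseline), and VAS rating noise (sd 1 point). Under these defaults the
extracted parameters recover the generating truth with r ≥ 0.98 for the
four kinetic parameters.

The masking link is `true score = clip(2 + 0.003·AreaDec, 0, 10)`; each
panelist reports `clip(10 − score + N(0, 1), 0, 10)`. Linking through
AreaDec only (not AreaInc) makes decay-phase exposure the single causal
driver, so end-to-end recovery of AreaDec by the group test and the
loading report is a well-posed check. Because AreaDec correlates with the
other type-linked parameters, several of them also reach significance in
the top-vs-bottom comparison — the generator produces a *correlated*
parameter family, as real release kinetics do, not an isolated signal.

What the generator does **not** emulate: adaptation and carry-over
between samples, panelist-specific time warping (perceived durations are
noise-free up to onset jitter), VAS anchoring effects, and any matrix
interaction between the masking agent and the food base. Passing tests
therefore certify the *statistical machinery* under a plausible data
model, not the sensory realism of any particular panel.

## Numerical and reproducibility choices

- Standardization uses the population (divisor-n) standard deviation, so
  "variance 1" holds exactly under `ddof=0`; it is idempotent and
  scale/shift invariant to 1e−12.
- All boundary times live on the sampling grid; `phase_parameters`
  rejects off-grid boundaries rather than interpolating.
- Ties at the global maximum resolve to the earliest time.
- CSV writers emit shortest exact float representations and readers parse
  with correctly-rounded round-trip precision, so canonical tables
  round-trip byte-identically.
- One global seed fans out to per-stage seeds via
  `numpy.random.SeedSequence.spawn` (order: simulation, k-means), each
  reduced below 2³¹; reruns with the same config are bit-identical.
- Test problem sizes: unit tests run on analytic curves and 10-material
  studies; the end-to-end recovery check runs 20 full default studies
  (100 materials × 60 curves each), about 2 s per study.

## Known limitations

- The onset-toe bias above means increase-phase areas of very fast
  releases (ramps ≲ 7 s) are systematically ~2–6% low relative to their
  continuous-time values; comparisons *between* materials are unaffected
  in rank terms.
- SIMDec from 1 Hz differences underestimates the instantaneous initial
  decay slope i_peak/τ by ≈ 1/(2τ) relative (6% at τ = 8 s); it is a
  per-second, not instantaneous, slope.
- Exact U p-values require tie-free data; duration parameters on a 1 s
  grid tie frequently, in which case the corrected normal approximation
  is used and logged.
- Raw-scale PCA loadings mix units with importance (see above); any
  cross-study comparison of loadings should fix a unit convention first.
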