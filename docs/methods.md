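# Methods

## The gait index

The index is a fixed linear combination of nine CatWalk gait parameters,
`p_LDA = Σ w_i p_i`, evaluated in raw parameter units (s, cm, %, cm/s);
the weights absorb scale, and no standardization is applied before
scoring.  The packaged weight vector (forepaw swing time 1; forepaw stride
length 0.0015; forepaw duty cycle 0.0005; hindpaw BOS −0.0103; RI 0.00002;
body speed 0.001; AB sequence −0.0001; forepaw max-contact-at −0.0015;
hindpaw stride length −0.0017) was derived on pooled uninjured vs thoracic
contusion SCI rat runs and is anchored so the forepaw swing-time weight is
exactly 1, oriented so uninjured animals score higher.

Refitting follows the same recipe the published vector came from:

1. per-animal means of the candidate parameters, Welch t test (no
   equal-variance assumption) between the uninjured and injured groups;
2. all parameters with unadjusted p < 0.01 enter the combination (Cohen's
   d, pooled-SD form, is reported alongside; the selected set in the
   source data all had d > 1.3);
3. on run-level data, the within-class scatter `S_w = ΣΣ (x−μ_j)(x−μ_j)ᵀ`
   and between-class scatter `S_b = Σ (μ_j−μ)(μ_j−μ)ᵀ` are formed, where μ
   is the mean over all runs.  `S_b` deliberately uses *unweighted*
   group-mean outer products — the form the index was defined with — not
   the textbook `N_j`-weighted form; for two groups of equal size the
   discriminant direction coincides, and `sb_weighting="nj_weighted"`
   switches to the textbook form;
4. the leading eigenvector of `S_w⁻¹ S_b` is taken.  Numerically the
   symmetric-definite generalized problem `S_b w = λ S_w w` is solved with
   `scipy.linalg.eigh`, which is algebraically identical and keeps the
   spectrum real and non-negative.  For two groups the direction equals
   the closed form `S_w⁻¹(μ₁−μ₂)` up to scale, which the tests verify on
   100 random instances;
5. the vector is oriented so the designated positive group (uninjured)
   scores higher, then scaled by the magnitude of its anchor component.
   When the anchor parameter itself rises with the positive group — the
   published situation — the anchor weight is +1; orientation takes
   precedence over the anchor sign when the two conventions conflict.

Near-singular `S_w` raises with its condition number; optional ridge
regularization adds `εI` with `ε = 1e-8·trace(S_w)/N_p`.

## Engine conventions

Gait-parameter definitions follow standard CatWalk usage; where the
mechanics are not published, the following conventions apply and are fixed:

* **NSSP counting / RI.** The regularity index is `100·4·NSSP/PP`.
  Patterns are counted by a greedy, non-overlapping left-to-right scan of
  the placement order (ties in initial-contact time broken by the fixed
  paw order RF, LF, RH, LH): if the next four placements match one of the
  six patterns all four are consumed, otherwise the scan advances by one.
  This makes a perfectly regular gait score exactly 100.  Proprietary
  CatWalk software may window differently; the convention here is
  documented, not claimed identical.
* **AB sequence** is the share of AB patterns among *classified* patterns
  (not among placements).
* **Base of support** uses `|y_R − y_L|`; each right-paw placement is
  paired with the most recent left placement of the same girdle.
* **Max contact at (%)** is clocked from the initial contact of the
  placement, the only reading that keeps the ratio to stand time in
  [0, 100].
* Trailing incomplete step cycles (the last placement of each paw) are
  excluded from stand/swing/cycle/stride means, so stand + swing equals
  the step cycle exactly per pair.
* **Support percentages** sample the run on the camera tick grid
  (1/frame_rate; 100 Hz default, 50 Hz for the older system) with
  half-open membership `[t_contact, t_release)`; two-paw ticks split into
  diagonal / girdle / lateral.  The support number is
  `(one + 2·diagonal + 2·girdle + 2·lateral + 3·three + 4·four)/100`.
* Units are fixed (cm, s, %, cm/s); dialect conversion lives in I/O only.

## Candidate set and registry

The exported-parameter registry maps both CatWalk header dialects onto
canonical names and realizes 22 candidate parameters after preprocessing:
seven per-girdle means (stand, swing, step cycle, stride, swing speed,
duty cycle, max-contact-at) × 2, body speed (mean over all four paws), two
BOS values, two print positions (pass-through columns, not left/right
averaged), RI, AB sequence and the support number.  Green-pixel-intensity
parameters are registered but flagged and always excluded — they are too
sensitive to walkway moisture and the experimental setting.  Missing
values propagate; nothing is imputed, and runs lacking any scoring
parameter are reported as unscoreable rather than filled.  Per-animal
means are unweighted by run count.

## Synthetic data

The footfall generator realizes a gait template (step cycle, duty factor,
stride, BOS, pattern, max-contact fraction) with four paws stepping at
quarter-cycle phase offsets and one stride of advance per cycle.
Noise-free, regular templates are exact fixed points of the engine (every
parameter recovered to 1e-9), which the tests exploit as an oracle.
Defaults describe a well-coordinated adult rat: 0.35 s cycle, duty 0.6,
13 cm stride (body speed ≈ 37 cm/s), fore/hind BOS 2.5/3.0 cm, AB
stepping.  Irregularity inserts out-of-pattern placements into swing
phases (never overlapping a paw's own stance), lowering RI.

The feature generator draws run vectors hierarchically — an animal effect
plus a run effect whose variances sum to the stated SD, split 50/50 by
default since the source cohorts report only pooled SDs — around the
published per-cohort means/SDs of the nine index parameters, which ship in
`catgait/data/cohort_statistics.csv` together with each cohort's published
index value.  RI and AB-sequence draws are clipped at their 100% ceiling,
piling probability mass at 100 the way fully coordinated cohorts behave
(uninjured groups sit at RI = 100 almost surely).  Parameters are drawn
independently by default; real gait parameters are interdependent, so
synthetic covariance structure understates reality — passing tests show
the pipeline's algebra and conventions are right, not that the index
generalizes to new biology.  Feature generators do not emulate camera
artifacts, mislabelled paws or partial crossings.

## Problem sizes and numerical checks

The test suite works at desk scale: moment checks use 1,000 generated
runs; the null calibration of the Welch test uses 10,000 replicates of
8 vs 8; the closed-form discriminant identity is checked on 100 random
9-dimensional instances (cosine ≥ 1−1e-8); the planted-selection fixture
uses 12 animals × 4 runs per group with a 2-pooled-SD shift on the nine
index parameters plus 13 null parameters.  Direction recovery from a
planted two-group study is asserted at 200 independent runs per group
(cosine ≥ 0.95): at 50 runs per group the sampling noise of the scatter
estimate leaves the typical cosine right at ~0.95, so the larger size is
used to test consistency rather than a knife-edge.

Scoring is a dot product and linear, so per-animal mean of run scores
equals the score of per-animal mean features to 1e-12 — asserted directly.
Reconstruction of the ten published group index values from printed group
means carries a ±0.01 tolerance forced by the 1–2 decimal rounding of the
printed inputs (the swing-time entry alone, printed to 0.01 s with weight
1, contributes ±0.005).

## Known limitations

* The published between-group p-values of the source cohorts require
  per-animal raw data that was never published; they are not reproduced.
* The index was designed for thoracic lesions; on cervical dorsal-column
  cohorts the packaged weights do not separate injured from uninjured
  animals (the published cervical cohorts score 0.112 vs 0.120), and this
  package reproduces that behaviour rather than correcting it.
* The exact composition of the original 22-parameter candidate list and
  CatWalk's proprietary NSSP windowing are not public; both are realized
  here as documented, configurable conventions.
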