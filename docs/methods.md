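# Methods

## Sample entropy

For a series `x_1 … x_N`, templates of length `m` are the vectors
`(x_i, …, x_{i+m-1})` for start positions `i = 1 … N − m` (so every
length-`m` template has a length-`m+1` extension; both template pools have
equal size `N − m`, which guarantees `A ≤ B`). Two templates match when
their Chebyshev (maximum-coordinate) distance is at most `r · SD(x)` — a
closed comparison, the Richman–Moorman convention. With `B` the number of
unordered matching pairs at length `m` and `A` the number at `m + 1`,

    SampEn(m, r) = −ln(A / B)   (nats).

Conventions fixed in this package:

- **Pair counting** — unordered pairs `i < j`, identically in the optimized
  path and the brute-force oracle. Ordered-vs-unordered cancels in the
  ratio; fixing one convention lets tests compare counts exactly.
- **SD** — sample standard deviation (`ddof = 1`) everywhere, including the
  tolerance base. Because the pipeline z-scores node series (SD 1), the
  tolerance equals the absolute value `r` there; SampEn is invariant to
  scaling and shifting of the input either way, which a property test
  verifies.
- **Tie-breaking** — distances exactly equal to `r · SD` count as matches.
  Ties have probability zero for continuous data but matter for integer toy
  series; the closed convention is applied consistently in both paths.
- **Undefined ratio** — if `A = 0` or `B = 0` the result is a flagged
  NaN carrying its counts, never an exception or an infinity, so group
  statistics can exclude those nodes explicitly.
- **Minimum length** — `N ≥ m + 2` (at least two templates of each length);
  shorter input is an error. Zero-variance input is a degenerate-input
  error for a single series and a flagged column inside a matrix.

Defaults `m = 3`, `r = 0.3` are the standard choice for parcellated BOLD
series of a few hundred timepoints.

The optimized kernel sorts templates by first coordinate so the inner scan
stops once the first-coordinate gap exceeds the tolerance; it is verified
against a literal pure-Python double loop to 1e−12 on hundreds of mixed
series, and against the analytic i.i.d. Gaussian limit
`−ln(erf(r/2)) ≈ 1.784` for `r = 0.3` (for i.i.d. data the conditional
match probability per added coordinate is `P(|X−Y| ≤ r·σ) = erf(r/2)`,
independent of `m`).

A noiseless sine (period 50 samples) measures ≈ 0.15 at these parameters,
not arbitrarily close to zero: templates half a period apart mirror each
other closely enough to match at length `m` yet diverge at `m + 1`. The
regularity ordering white noise > AR(0.5) > AR(0.9) > sine still holds with
a wide margin on batch means (single 588-sample draws of white and AR(0.5)
overlap, so ordering checks average 5 draws per process).

## Node time-series preparation

Extraction is a plain label-mean: column `k` at time `t` is the mean over
voxels labeled `k`. Inputs must share a voxel grid; no resampling or
spatial processing is performed (registration belongs to the upstream
imaging chain). Nodes absent from the grid are flagged empty, not
fabricated. Each column is then detrended by ordinary least squares on
`{1, t, t², t³}` over the integer time index and z-scored (`ddof = 1`).
The order extract → detrend → z-score is fixed; z-scoring cannot change
SampEn (scale invariance), so the entropy values are determined by the
detrended residuals.

The default 419-node label table (400 cortical in hemisphere blocks of 7
networks, 16 subcortical, 3 cerebellar) is a synthetic stand-in that
reproduces the exact node counts, hemisphere split, and the a-priori ROI
ids — bilateral insula {35, 98–100, 143; 234–236, 302–305, 340} and left
dlPFC {137–142}, 19 nodes in all — while the cortical network boundaries
are approximate block assignments chosen so those ROIs land in plausible
networks. Analyses that depend only on counts, ids and a network partition
are exact; network names should not be over-interpreted.

## Group statistics

- **Node-wise pre/post test** — two-sided paired t on (post − pre) per
  node, complete-case (both sessions required; at least 3 pairs, else the
  node is listed as untested), Benjamini–Hochberg step-up adjustment across
  all tested nodes of a condition. When every difference is exactly zero
  the test reports t = 0, p = 1 rather than 0/0.
- **Effect size** — paired Cohen's d, `d_z = mean(diff)/SD(diff)`. This is
  the only d the t-statistic determines (`d_z = t/√n`); it is fixed
  package-wide.
- **Baseline map** — per subject, the global average over valid nodes; per
  node, a paired t of (node − global) across subjects, BH-adjusted, with
  above/below labels at `p_FDR < 0.05`. With two nodes the two contrasts
  are exactly opposite — a symmetry the tests exercise.
- **Behavior** — one paired t per measure (SJWS total, craving total,
  craving average, Urge-to-Smoke), Bonferroni-corrected by the family size
  (the measures tested together), capped at 1.
- **Entropy–behavior correlation** — Pearson r of per-subject node entropy
  change against behavioral change; `|r| > 0.2` is a reporting screen
  only, and the unscreened table is always available.
- **Confound screens** — pooled-variance two-sample t for sex, one-way
  ANOVA over ethnicity groups with ≥ 2 members, Pearson correlations of
  age / years smoking / education against baseline entropy in the a-priori
  ROIs. These are uncorrected screens and say so in their output.

## Network effects

Per network, all (subject, node) paired reductions (pre − post) are pooled
and summarized as `d = mean/SD`; positive d means entropy fell. Pooling
every pair is the default; a subject-mean mode (average within subject
first) is available because pooled observations are not independent within
subject — for a one-node network the two modes coincide. No network-level
p-values are produced, only effect sizes.

## Synthetic cohorts

Node series are stationary AR(1) processes with unit innovation variance
and 200 burn-in samples. The AR coefficient is the complexity dial: SampEn
decreases monotonically in φ (verified over φ ∈ {0, 0.3, 0.6, 0.9}).
Defaults mirror the study conditions the pipeline targets: 42 subjects,
419 nodes, 588 timepoints per scan, two conditions (dlPFC active, v5
control) × two sessions; baseline φ = 0.2; the 19 a-priori nodes switch to
φ = 0.6 in the active-condition post session only. Per-subject φ jitter
(SD 0.05, drawn once per subject-node and shared across sessions) creates
between-subject heterogeneity without breaking the null. Craving totals
start near 22 (SD 8.25) and drop by 1.55 on average under active
stimulation with between-subject SD 4.0 — obtained by inverting the paired
t-statistic reported for a cohort of this size — and optionally couple to
the subject's mean entropy reduction in the effect nodes
(`behavior_coupling`, default 0, so correlations are null by default).

What the generator does *not* emulate: hemodynamic autocorrelation
structure beyond AR(1), physiological and motion artifacts, spatial
correlation between nodes, scanner drift beyond what cubic detrending
removes, and missing sessions. Passing tests therefore demonstrate that
the pipeline measures what it claims on data with known ground truth — not
that real BOLD satisfies the AR(1) model.

## Validation at scale and problem sizes

The full-scale checks run the complete pipeline at the native problem size
(42 × 419 × 588): 40 null-cohort replicates for false-discovery control
(under a global null the realized FDP is an any-rejection indicator whose
expectation is exactly q, so its 40-replicate mean is a sharp check), and
20 effect-cohort replicates for sensitivity/specificity. The acceptance
script runs one full-scale effect cohort plus 5 null replicates, the
oracle and analytic checks, and the structural counts; sizes were chosen
so a complete run finishes in a few minutes on one CPU.

## Known limitations

- SampEn of short series is biased upward when matches are scarce; at
  N = 588 and m = 3 the match counts are in the thousands and the effect is
  negligible, but results for much shorter series should be treated with
  care (the code enforces only the hard minimum N ≥ m + 2).
- The pooled network d treats within-subject node pairs as independent
  observations; use subject-mean pooling when that assumption matters.
- The label table's network boundaries are approximate (see above).
- No spatial statistics: nodes are exchangeable units here, and no
  cluster-level inference is attempted.
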