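# brainentropy

Sample-entropy analysis of parcellated resting-state BOLD time series, for
studies that ask whether a neuromodulation intervention (e.g. excitatory
rTMS to the left dlPFC, with a visual-cortex control site) changes the
complexity of regional brain activity, and whether that change tracks
behavior such as cigarette craving.

## What it computes

**Sample entropy.** For a node's time series, SampEn(m, r) = −ln(A/B),
where B counts pairs of length-`m` subsequences whose Chebyshev distance is
≤ `r`·SD, and A counts the same pairs extended to length `m+1`. Higher
SampEn = less predictable signal. Defaults m = 3, r = 0.3; conventions
(closed comparison, unordered pairs, sample SD, natural log) are in
`docs/methods.md`. The optimized kernel is verified against a pure-Python
brute-force oracle and the analytic i.i.d.-Gaussian limit −ln(erf(r/2)).

**The pipeline.** 4D NIfTI + integer-label parcellation (419 nodes by
default: 400 cortical, 16 subcortical, 3 cerebellar) → mean node series →
cubic detrend → z-score → SampEn per node per scan → group layer:

- node-wise paired t-tests of post vs pre with Benjamini–Hochberg FDR and
  paired Cohen's d (d_z);
- baseline map of nodes above/below each subject's global-mean entropy;
- behavioral paired tests (SJWS, craving subscale, Urge-to-Smoke) with
  Bonferroni correction;
- Pearson screening of entropy change vs behavior change (|r| > 0.2);
- confound screens (sex, ethnicity, age, years smoking, education);
- network-level Cohen's d of entropy reduction (positive d = entropy fell).

**Synthetic cohorts.** A generator produces AR(1) node series whose
coefficient φ is a monotone complexity dial (higher φ → lower SampEn), a
stimulation effect as φ 0.2 → 0.6 in the 19 a-priori insula/dlPFC nodes of
the active condition's post session, behavioral records, and NIfTI/TSV
fixtures — so the full pipeline is testable with known ground truth.

## Worked example

```python
from brainentropy import (SyntheticCohortConfig, simulate_cohort,
                          build_entropy_table, paired_node_tests,
                          network_effects, generic_label_table)

config = SyntheticCohortConfig(n_subjects=16, n_nodes=20, n_timepoints=400,
                               effect_nodes=(1, 2, 3, 4), seed=42)
cohort = simulate_cohort(config)
entropy = build_entropy_table(cohort.matrices)   # detrend -> z-score -> SampEn

res = paired_node_tests(entropy, "dlPFC")
print(res[res.significant])
```

```
 node_id  n_pairs  t_stat  p_fdr  cohen_d direction
       1       16 -3.4133 0.0193  -0.8533  decrease
       2       16 -6.0058 0.0005  -1.5014  decrease
       3       16 -5.2886 0.0009  -1.3222  decrease
       4       16 -3.9318 0.0089  -0.9830  decrease
```

Exactly the four injected effect nodes survive FDR, all as entropy
decreases (negative t: post < pre). Pooling nodes by network shows the
effect concentrated where it was injected — positive d means reduced
entropy:

```python
labels = generic_label_table(20)
labels.loc[labels.node_id <= 4, "network"] = "target"
labels.loc[labels.node_id > 4, "network"] = "rest"
print(network_effects(entropy, labels, "dlPFC"))
```

```
network  cohen_d  n_nodes  n_pairs direction
 target   1.1193        4       64  decrease
   rest  -0.0555       16      256  increase
```

The same analysis is scriptable from a shell:

```
brainentropy simulate --seed 11 --n-subjects 16 --out run/sim
brainentropy report --scans run/sim/manifest.tsv \
    --behavior run/sim/behavior.tsv --labels run/sim/labels.tsv \
    --out run/report
```

`report` writes `entropy.tsv`, `node_stats.tsv`, `baseline_map.tsv`,
`behavior_tests.tsv`, `correlations.tsv`, `network_effects.tsv` and a
`run_log.json` recording parameters, package version and input hashes.
Identical seeds yield byte-identical outputs.

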