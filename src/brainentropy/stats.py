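"""Group-level statistics on node sample entropy and behavioral scores.

The statistical layer mirrors a pre/post neuromodulation design:

* node-wise paired t-tests of post- minus pre-stimulation SampEn across
  subjects, Benjamini-Hochberg FDR adjustment across nodes, and paired
  Cohen's d (d_z = mean(diff) / SD(diff));
* a baseline map comparing each node against each subject's global-average
  entropy (paired t of node minus global, FDR-adjusted);
* paired t-tests on withdrawal/craving measures with Bonferroni correction
  over the measure family;
* Pearson correlation of per-subject entropy change against behavioral
  change, with a reporting screen at |r| > 0.2;
* confound screens: sex (pooled-variance two-sample t), ethnicity (one-way
  ANOVA), and continuous covariates (Pearson) against baseline entropy.

Entropy values live in a long-form table with one row per
(subject, condition, session, node); invalid (degenerate) nodes carry
``valid = False`` and are excluded from every test on a complete-case basis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .prep import NodeTimeSeriesMatrix, default_roi_sets, normalize_matrix
from .sampen import SampEnParams, compute_sampen_matrix

__all__ = [
    "BEHAVIOR_MEASURES",
    "build_entropy_table",
    "paired_node_tests",
    "baseline_map",
    "behavioral_change_tests",
    "entropy_change",
    "behavior_change",
    "correlate_entropy_behavior",
    "confound_screen",
    "ConfoundReport",
]

BEHAVIOR_MEASURES = ("sjws_total", "sjws_craving_total", "sjws_craving_average", "uts_score")

ENTROPY_COLUMNS = ("subject_id", "condition", "session", "node_id", "sampen", "valid", "note")


def build_entropy_table(
    matrices: Iterable[NodeTimeSeriesMatrix],
    params: SampEnParams = SampEnParams(),
    normalize: bool = True,
) -> pd.DataFrame:
    """SampEn of every node of every scan, as one long-form table.

    Raw matrices are detrended and z-scored first (``normalize=True``, the
    standard pipeline order); already-normalized matrices pass through.
    Degenerate nodes appear with ``valid=False`` and a reason, never
    silently dropped.
    """
    rows: list[tuple] = []
    for mat in matrices:
        if normalize:
            mat = normalize_matrix(mat)
        results = compute_sampen_matrix(mat.values, params, node_ids=mat.node_ids)
        empty = set(mat.empty_nodes)
        degenerate = set(mat.degenerate_nodes)
        for nid, res in zip(mat.node_ids, results):
            nid = int(nid)
            if nid in empty:
                note = "empty node: no voxels in atlas"
            elif nid in degenerate:
                note = "zero-variance node series"
            else:
                note = res.note
            valid = res.defined and note is None
            rows.append(
                (mat.subject_id, mat.condition, mat.session, nid,
                 res.value if valid else np.nan, valid, note)
            )
    return pd.DataFrame(rows, columns=list(ENTROPY_COLUMNS))


def _paired_frame(entropy: pd.DataFrame, condition: str) -> pd.DataFrame:
    sub = entropy[(entropy["condition"] == condition) & entropy["valid"]]
    if sub.empty:
        raise ValueError(f"no valid entropy rows for condition {condition!r}")
    wide = sub.pivot_table(
        index=["subject_id", "node_id"], columns="session", values="sampen", aggfunc="first"
    )
    if "pre" not in wide.columns or "post" not in wide.columns:
        raise ValueError(f"condition {condition!r} lacks a pre or post session")
    return wide.dropna(subset=["pre", "post"]).reset_index()


def _paired_t(diff: np.ndarray) -> tuple[float, float, float]:
    """(t, p, d_z) for paired differences; t=0, p=1 when all diffs are zero."""
    n = diff.size
    sd = diff.std(ddof=1)
    mean = diff.mean()
    if sd == 0:
        if mean == 0:
            return 0.0, 1.0, 0.0
        return float(np.sign(mean) * np.inf), 0.0, float(np.sign(mean) * np.inf)
    t = mean / (sd / np.sqrt(n))
    p = 2 * sps.t.sf(abs(t), n - 1)
    return float(t), float(p), float(mean / sd)


def _direction(t: float) -> str:
    if t < 0:
        return "decrease"
    if t > 0:
        return "increase"
    return "none"


def paired_node_tests(
    entropy: pd.DataFrame,
    condition: str,
    fdr_q: float = 0.05,
    min_pairs: int = 3,
) -> pd.DataFrame:
    """Node-wise paired t-tests of post minus pre SampEn, FDR-adjusted.

    One row per node in the table.  Nodes with fewer than ``min_pairs``
    complete subject pairs are listed with ``tested=False`` and excluded
    from the Benjamini-Hochberg adjustment; adjusted p-values are computed
    across all tested nodes of the condition.  ``significant`` marks
    ``p_fdr < fdr_q``.  Direction follows the sign of t (post < pre means
    "decrease").
    """
    paired = _paired_frame(entropy, condition)
    all_nodes = np.sort(entropy.loc[entropy["condition"] == condition, "node_id"].unique())
    rows = []
    for nid in all_nodes:
        grp = paired[paired["node_id"] == nid]
        n = len(grp)
        if n < min_pairs:
            rows.append(
                dict(node_id=int(nid), n_pairs=n, t_stat=np.nan, df=np.nan, p_raw=np.nan,
                     p_fdr=np.nan, cohen_d=np.nan, direction="none", tested=False,
                     significant=False, note=f"fewer than {min_pairs} complete pairs")
            )
            continue
        diff = (grp["post"] - grp["pre"]).to_numpy()
        t, p, d = _paired_t(diff)
        rows.append(
            dict(node_id=int(nid), n_pairs=n, t_stat=t, df=n - 1, p_raw=p, p_fdr=np.nan,
                 cohen_d=d, direction=_direction(t), tested=True, significant=False, note=None)
        )
    out = pd.DataFrame(rows)
    tested = out["tested"].to_numpy()
    if not tested.any():
        raise ValueError(f"no node has >= {min_pairs} complete pairs for condition {condition!r}")
    p_raw = out.loc[tested, "p_raw"].to_numpy()
    reject, p_fdr, *_ = multipletests(p_raw, alpha=fdr_q, method="fdr_bh")
    out.loc[tested, "p_fdr"] = p_fdr
    out.loc[tested, "significant"] = reject
    return out


def baseline_map(
    entropy: pd.DataFrame,
    fdr_q: float = 0.05,
    min_subjects: int = 3,
) -> pd.DataFrame:
    """Which nodes sit above or below each subject's global-average entropy.

    Uses pre-stimulation rows only (averaged across conditions per subject
    when a subject has two baseline scans).  Per subject the global average
    is the mean over that subject's valid nodes; per node, a paired t of
    (node value - subject global average) across subjects, BH-adjusted
    across nodes.  ``relation`` is "above"/"below" at ``p_fdr < fdr_q``,
    else "none".
    """
    pre = entropy[(entropy["session"] == "pre") & entropy["valid"]]
    if pre.empty:
        raise ValueError("no valid pre-stimulation rows")
    per_subj = pre.groupby(["subject_id", "node_id"], as_index=False)["sampen"].mean()
    glob = per_subj.groupby("subject_id")["sampen"].mean().rename("global_mean")
    if len(glob) < min_subjects:
        raise ValueError(f"need >= {min_subjects} subjects with baseline data, got {len(glob)}")
    merged = per_subj.merge(glob, on="subject_id")
    merged["delta"] = merged["sampen"] - merged["global_mean"]
    rows = []
    for nid, grp in merged.groupby("node_id"):
        n = len(grp)
        if n < min_subjects:
            rows.append(dict(node_id=int(nid), mean_sampen=grp["sampen"].mean(), n_subjects=n,
                             t_vs_global=np.nan, df=np.nan, p_raw=np.nan, p_fdr=np.nan,
                             relation="none", tested=False))
            continue
        t, p, _ = _paired_t(grp["delta"].to_numpy())
        rows.append(dict(node_id=int(nid), mean_sampen=grp["sampen"].mean(), n_subjects=n,
                         t_vs_global=t, df=n - 1, p_raw=p, p_fdr=np.nan,
                         relation="none", tested=True))
    out = pd.DataFrame(rows)
    tested = out["tested"].to_numpy()
    reject, p_fdr, *_ = multipletests(out.loc[tested, "p_raw"].to_numpy(), alpha=fdr_q,
                                      method="fdr_bh")
    out.loc[tested, "p_fdr"] = p_fdr
    sig = np.zeros(len(out), dtype=bool)
    sig[np.flatnonzero(tested)] = reject
    out.loc[sig & (out["t_vs_global"] > 0), "relation"] = "above"
    out.loc[sig & (out["t_vs_global"] < 0), "relation"] = "below"
    return out


def behavioral_change_tests(
    behavior: pd.DataFrame,
    condition: str,
    measures: Sequence[str] = BEHAVIOR_MEASURES,
    bonferroni_family: int | None = None,
) -> pd.DataFrame:
    """Paired t-test per behavioral measure, Bonferroni-corrected.

    The Bonferroni divisor is the number of measures tested together
    (``len(measures)`` unless overridden) and is recorded in the output.
    Subjects lacking either session are dropped per measure and counted.
    """
    family = bonferroni_family if bonferroni_family is not None else len(measures)
    sub = behavior[behavior["condition"] == condition]
    if sub.empty:
        raise ValueError(f"no behavioral rows for condition {condition!r}")
    rows = []
    for measure in measures:
        wide = sub.pivot_table(index="subject_id", columns="session", values=measure,
                               aggfunc="first")
        if "pre" not in wide.columns or "post" not in wide.columns:
            raise ValueError(f"measure {measure!r} lacks a pre or post session")
        n_total = len(wide)
        wide = wide.dropna(subset=["pre", "post"])
        diff = (wide["post"] - wide["pre"]).to_numpy()
        n = diff.size
        if n < 3:
            rows.append(dict(measure=measure, n_pairs=n, n_dropped=n_total - n,
                             t_stat=np.nan, df=np.nan, p_raw=np.nan, p_bonferroni=np.nan,
                             cohen_d=np.nan, family=family))
            continue
        t, p, d = _paired_t(diff)
        rows.append(dict(measure=measure, n_pairs=n, n_dropped=n_total - n, t_stat=t,
                         df=n - 1, p_raw=p, p_bonferroni=min(1.0, p * family),
                         cohen_d=d, family=family))
    return pd.DataFrame(rows)


def entropy_change(entropy: pd.DataFrame, condition: str) -> pd.DataFrame:
    """Per-subject, per-node SampEn change (post minus pre), complete cases."""
    paired = _paired_frame(entropy, condition)
    paired["delta"] = paired["post"] - paired["pre"]
    return paired[["subject_id", "node_id", "delta"]]


def behavior_change(
    behavior: pd.DataFrame, condition: str, measures: Sequence[str] = BEHAVIOR_MEASURES
) -> pd.DataFrame:
    """Per-subject behavioral change (post minus pre) in long form."""
    sub = behavior[behavior["condition"] == condition]
    rows = []
    for measure in measures:
        wide = sub.pivot_table(index="subject_id", columns="session", values=measure,
                               aggfunc="first")
        if "pre" not in wide.columns or "post" not in wide.columns:
            continue
        wide = wide.dropna(subset=["pre", "post"])
        for sid, rec in wide.iterrows():
            rows.append(dict(subject_id=sid, measure=measure, delta=rec["post"] - rec["pre"]))
    return pd.DataFrame(rows, columns=["subject_id", "measure", "delta"])


def correlate_entropy_behavior(
    entropy_changes: pd.DataFrame,
    behavior_changes: pd.DataFrame,
    screen_r: float = 0.2,
    full: bool = False,
    min_pairs: int = 3,
) -> pd.DataFrame:
    """Pearson r between node entropy change and behavioral change.

    One row per (node, measure).  With ``full=False`` rows with
    ``|r| <= screen_r`` are omitted (a reporting filter, not an inference
    step); ``full=True`` returns everything, including undefined
    correlations flagged by ``note``.
    """
    rows = []
    measures = behavior_changes["measure"].unique()
    for measure in measures:
        beh = behavior_changes[behavior_changes["measure"] == measure][["subject_id", "delta"]]
        beh = beh.rename(columns={"delta": "beh_delta"})
        merged = entropy_changes.merge(beh, on="subject_id")
        for nid, grp in merged.groupby("node_id"):
            n = len(grp)
            if n < min_pairs:
                rows.append(dict(node_id=int(nid), measure=measure, r=np.nan, n=n,
                                 note=f"fewer than {min_pairs} complete pairs"))
                continue
            x = grp["delta"].to_numpy()
            y = grp["beh_delta"].to_numpy()
            if x.std() == 0 or y.std() == 0:
                rows.append(dict(node_id=int(nid), measure=measure, r=np.nan, n=n,
                                 note="zero-variance deltas; correlation undefined"))
                continue
            r, _ = sps.pearsonr(x, y)
            rows.append(dict(node_id=int(nid), measure=measure, r=float(r), n=n, note=None))
    out = pd.DataFrame(rows, columns=["node_id", "measure", "r", "n", "note"])
    if not full:
        out = out[out["r"].abs() > screen_r].reset_index(drop=True)
    return out


@dataclass
class ConfoundReport:
    """Sex t-tests, ethnicity ANOVA and covariate correlations on baseline entropy."""

    sex_tests: pd.DataFrame
    ethnicity_anova: pd.DataFrame
    covariate_correlations: pd.DataFrame
    notes: list[str] = field(default_factory=list)

    def as_long_table(self) -> pd.DataFrame:
        """Single tidy table (screen, node_id, covariate, stat, p_raw, note)."""
        frames = []
        if not self.sex_tests.empty:
            s = self.sex_tests.rename(columns={"t_stat": "stat"})
            s["screen"] = "sex_t"
            s["covariate"] = "sex"
            frames.append(s[["screen", "node_id", "covariate", "stat", "p_raw", "note"]])
        if not self.ethnicity_anova.empty:
            e = self.ethnicity_anova.rename(columns={"f_stat": "stat"})
            e["screen"] = "ethnicity_anova"
            e["covariate"] = "ethnicity"
            frames.append(e[["screen", "node_id", "covariate", "stat", "p_raw", "note"]])
        if not self.covariate_correlations.empty:
            c = self.covariate_correlations.rename(columns={"r": "stat"})
            c["screen"] = "pearson"
            frames.append(c[["screen", "node_id", "covariate", "stat", "p_raw", "note"]])
        if not frames:
            return pd.DataFrame(columns=["screen", "node_id", "covariate", "stat", "p_raw", "note"])
        return pd.concat(frames, ignore_index=True)


def confound_screen(
    entropy: pd.DataFrame,
    covariates: pd.DataFrame,
    roi_nodes: Sequence[int] | None = None,
    continuous: Sequence[str] = ("age", "years_smoking", "education"),
) -> ConfoundReport:
    """Screen baseline (pre-stimulation) entropy against subject covariates.

    Sex differences use a pooled-variance independent-samples t-test per
    node; ethnicity uses a one-way ANOVA over groups with at least 2
    members; continuous covariates use Pearson correlation, restricted to
    the a-priori ROI nodes by default.  P-values are uncorrected screens
    (noted in the report), matching their exploratory role.
    """
    pre = entropy[(entropy["session"] == "pre") & entropy["valid"]]
    baseline = pre.groupby(["subject_id", "node_id"], as_index=False)["sampen"].mean()
    merged = baseline.merge(covariates, on="subject_id")
    notes = ["p-values are uncorrected screening statistics; apply multiple-comparison "
             "correction before any confirmatory claim"]
    if roi_nodes is None:
        roi_nodes = default_roi_sets().union

    sex_rows = []
    if "sex" in merged.columns:
        for nid, grp in merged.groupby("node_id"):
            groups = [g["sampen"].to_numpy() for _, g in grp.groupby("sex")]
            groups = [g for g in groups if len(g) >= 3]
            if len(groups) != 2:
                sex_rows.append(dict(node_id=int(nid), t_stat=np.nan, p_raw=np.nan,
                                     note="need two sex groups with >= 3 subjects"))
                continue
            t, p = sps.ttest_ind(groups[0], groups[1], equal_var=True)
            sex_rows.append(dict(node_id=int(nid), t_stat=float(t), p_raw=float(p), note=None))
    else:
        notes.append("sex column absent; sex screen skipped")

    eth_rows = []
    if "ethnicity" in merged.columns:
        for nid, grp in merged.groupby("node_id"):
            groups = [g["sampen"].to_numpy() for _, g in grp.groupby("ethnicity")
                      if len(g) >= 2]
            if len(groups) < 2:
                eth_rows.append(dict(node_id=int(nid), f_stat=np.nan, p_raw=np.nan,
                                     note="fewer than 2 ethnicity groups with >= 2 members"))
                continue
            f, p = sps.f_oneway(*groups)
            eth_rows.append(dict(node_id=int(nid), f_stat=float(f), p_raw=float(p), note=None))
    else:
        notes.append("ethnicity column absent; ANOVA skipped")

    corr_rows = []
    roi = merged[merged["node_id"].isin(set(int(n) for n in roi_nodes))]
    for cov in continuous:
        if cov not in merged.columns:
            notes.append(f"{cov} column absent; correlation skipped")
            continue
        for nid, grp in roi.groupby("node_id"):
            grp = grp.dropna(subset=[cov])
            if len(grp) < 3 or grp[cov].std() == 0 or grp["sampen"].std() == 0:
                corr_rows.append(dict(node_id=int(nid), covariate=cov, r=np.nan, p_raw=np.nan,
                                      note="undefined (n < 3 or zero variance)"))
                continue
            r, p = sps.pearsonr(grp[cov].to_numpy(), grp["sampen"].to_numpy())
            corr_rows.append(dict(node_id=int(nid), covariate=cov, r=float(r), p_raw=float(p),
                                  note=None))

    return ConfoundReport(
        sex_tests=pd.DataFrame(sex_rows, columns=["node_id", "t_stat", "p_raw", "note"]),
        ethnicity_anova=pd.DataFrame(eth_rows, columns=["node_id", "f_stat", "p_raw", "note"]),
        covariate_correlations=pd.DataFrame(
            corr_rows, columns=["node_id", "covariate", "r", "p_raw", "note"]),
        notes=notes,
    )
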