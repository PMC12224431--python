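"""Network-level pooling of node entropy changes.

Nodes belong to exactly one atlas network; the pre/post effect of
stimulation on a network is summarized as a paired Cohen's d over the
pooled (subject, node) reductions in SampEn.  Following the convention of
the underlying analysis, a POSITIVE d denotes a reduction in entropy
(reductions are computed as pre minus post), so stimulation that makes a
network's signal more regular yields d > 0.

Two pooling modes are exposed because the within-subject dependence of
node values is a modelling choice:

* ``"pooled"`` (default): every (subject, node) paired difference is one
  observation;
* ``"subject-mean"``: differences are first averaged over the network's
  nodes within each subject, then d is computed across subjects.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stats import entropy_change

__all__ = ["network_effects"]

POOLING_MODES = ("pooled", "subject-mean")


def network_effects(
    entropy: pd.DataFrame,
    label_table: pd.DataFrame,
    condition: str,
    pooling: str = "pooled",
) -> pd.DataFrame:
    """Cohen's d of the pre-to-post SampEn reduction per atlas network.

    Returns one row per network in the label table: ``cohen_d`` (positive =
    entropy reduced), ``n_nodes`` contributing, ``n_pairs`` pooled
    observations, and ``direction``.  Networks with no testable pairs are
    kept with a ``note`` explaining the skip rather than silently vanishing.
    """
    if pooling not in POOLING_MODES:
        raise ValueError(f"pooling must be one of {POOLING_MODES}, got {pooling!r}")
    deltas = entropy_change(entropy, condition)
    # reduction convention: positive when entropy went down
    deltas = deltas.assign(reduction=-deltas["delta"])
    networks = label_table.set_index("node_id")["network"]
    deltas["network"] = deltas["node_id"].map(networks)
    unknown = deltas["network"].isna()
    if unknown.any():
        bad = sorted(deltas.loc[unknown, "node_id"].unique())
        raise ValueError(f"label table provides no network for nodes {bad[:10]}")
    rows = []
    for network in pd.unique(label_table["network"]):
        grp = deltas[deltas["network"] == network]
        if pooling == "subject-mean":
            pooled = grp.groupby("subject_id")["reduction"].mean().to_numpy()
        else:
            pooled = grp["reduction"].to_numpy()
        n_nodes = grp["node_id"].nunique()
        if pooled.size < 2:
            rows.append(dict(network=network, cohen_d=np.nan, n_nodes=n_nodes,
                             n_pairs=int(pooled.size), direction="none",
                             note="no testable pre/post pairs"))
            continue
        sd = pooled.std(ddof=1)
        mean = pooled.mean()
        d = np.nan if sd == 0 and mean == 0 else (np.inf * np.sign(mean) if sd == 0
                                                  else mean / sd)
        if sd == 0 and mean == 0:
            d = 0.0
        direction = "decrease" if mean > 0 else ("increase" if mean < 0 else "none")
        rows.append(dict(network=network, cohen_d=float(d), n_nodes=n_nodes,
                         n_pairs=int(pooled.size), direction=direction, note=None))
    return pd.DataFrame(rows, columns=["network", "cohen_d", "n_nodes", "n_pairs",
                                       "direction", "note"])
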