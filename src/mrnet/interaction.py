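"""Regulon-pair interaction profiling and consensus clustering of samples.

MR pairs are profiled by the Jaccard overlap of their target sets, by the
sign agreement of their modes on shared targets (co-activated /
co-repressed / opposing), and by the correlation of their per-sample dES
vectors. Paired-activity states cross-classify samples for survival
analysis; tumor subtypes are called by consensus hierarchical clustering
(average linkage, 1 - Pearson distance) over subsampled clusterings.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .datatypes import RegulatoryNetwork
from .io import derive_rng
from .survival import three_way_state

log = logging.getLogger("mrnet")


def jaccard(r1, r2) -> float:
    """Jaccard coefficient |r1 & r2| / |r1 | r2| of two gene sets."""
    s1, s2 = set(r1), set(r2)
    if not s1 or not s2:
        raise ValueError("gene sets must be non-empty")
    return len(s1 & s2) / len(s1 | s2)


@dataclasses.dataclass
class InteractionProfile:
    """Pairwise MR interaction summary."""

    tf1: str
    tf2: str
    jc: float
    co_activated: int
    co_repressed: int
    opposing: int
    des_correlation: float | None = None

    @property
    def n_shared_with_modes(self) -> int:
        return self.co_activated + self.co_repressed + self.opposing


def shared_target_agreement(
    net: RegulatoryNetwork,
    tf1: str,
    tf2: str,
    activity: pd.DataFrame | None = None,
) -> InteractionProfile:
    """Mode agreement of two MRs on their shared targets.

    A shared target with both modes set counts as co-activated (both +1),
    co-repressed (both -1) or opposing. If a per-sample ``activity`` table
    is supplied (long format with columns tf, unit, des), the Pearson
    correlation of the two MRs' dES vectors over shared samples is added.
    """
    r1 = net.regulon(tf1)
    r2 = net.regulon(tf2)
    m1 = dict(zip(r1["target"], r1["mode"]))
    m2 = dict(zip(r2["target"], r2["mode"]))
    shared = set(m1) & set(m2)
    co_act = co_rep = opp = 0
    for g in shared:
        a, b = int(m1[g]), int(m2[g])
        if a == 0 or b == 0:
            continue
        if a == b == 1:
            co_act += 1
        elif a == b == -1:
            co_rep += 1
        else:
            opp += 1
    jc = jaccard(m1.keys(), m2.keys()) if m1 and m2 else 0.0

    des_r = None
    if activity is not None:
        wide = activity.pivot(index="unit", columns="tf", values="des")
        if tf1 in wide.columns and tf2 in wide.columns:
            sub = wide[[tf1, tf2]].dropna()
            if len(sub) >= 3:
                des_r = float(np.corrcoef(sub[tf1], sub[tf2])[0, 1])
    return InteractionProfile(
        tf1=tf1, tf2=tf2, jc=jc,
        co_activated=co_act, co_repressed=co_rep, opposing=opp,
        des_correlation=des_r,
    )


def interaction_profiles(
    net: RegulatoryNetwork, activity: pd.DataFrame | None = None, tfs=None
) -> pd.DataFrame:
    """All-pairs interaction table (jc, mode-agreement counts, dES correlation)."""
    if tfs is None:
        tfs = net.tfs
    rows = []
    for i, tf1 in enumerate(tfs):
        for tf2 in tfs[i + 1:]:
            prof = shared_target_agreement(net, tf1, tf2, activity)
            rows.append(dataclasses.asdict(prof))
    return pd.DataFrame(rows)


def interaction_stratify(
    act1: pd.DataFrame, act2: pd.DataFrame, min_group: int = 10
) -> pd.Series:
    """Cross-classify samples by the joint state of two MRs.

    Each MR contributes its three-way state (active / repressed /
    inconclusive); the 9 joint cells are labelled ``state1|state2``. Cells
    smaller than ``min_group`` are merged into ``other`` (logged).
    """
    s1 = three_way_state(act1)
    s2 = three_way_state(act2)
    shared = s1.index.intersection(s2.index)
    if len(shared) == 0:
        raise ValueError("disjoint sample sets")
    joint = pd.Series(
        [f"{a}|{b}" for a, b in zip(s1.loc[shared], s2.loc[shared])],
        index=shared,
        name="joint_stratum",
    )
    counts = joint.value_counts()
    small = counts.index[counts < min_group]
    if len(small):
        log.info("interaction_stratify: merging %d small cells into 'other'", len(small))
        joint[joint.isin(small)] = "other"
    return joint


# ---------------------------------------------------------------------------
# consensus clustering


def _correlation_distance(x: np.ndarray) -> np.ndarray:
    """Condensed 1 - Pearson distance between rows of x."""
    r = np.corrcoef(x)
    np.clip(r, -1.0, 1.0, out=r)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    return squareform(d, checks=False)


def _hclust_cut(x: np.ndarray, k: int, method: str = "average") -> np.ndarray:
    z = linkage(_correlation_distance(x), method=method)
    return fcluster(z, k, criterion="maxclust")


def consensus_cluster(
    expr: pd.DataFrame,
    k: int,
    n_resample: int = 100,
    subsample_frac: float = 0.8,
    seed: int = 0,
    method: str = "average",
) -> tuple[pd.DataFrame, pd.Series]:
    """Consensus hierarchical clustering of samples into k subtypes.

    ``n_resample`` times, a fraction of samples is drawn without
    replacement, hierarchically clustered (``method`` linkage, 1 - Pearson
    distance over gene profiles) and cut at k. The consensus matrix holds,
    for each sample pair, its co-clustering frequency among resamples where
    both were drawn. The final assignment cuts a hierarchical clustering of
    1 - consensus at k.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if not 0 < subsample_frac <= 1:
        raise ValueError("subsample_frac must be in (0, 1]")
    samples = list(expr.columns)
    n = len(samples)
    m = max(int(round(subsample_frac * n)), 1)
    if m < k:
        raise ValueError("subsample smaller than k")
    x = expr.to_numpy(dtype=float).T    # samples x genes
    rng = derive_rng(seed, "consensus_cluster")

    together = np.zeros((n, n))
    co_sampled = np.zeros((n, n))
    for _ in range(n_resample):
        idx = rng.choice(n, size=m, replace=False)
        labels = _hclust_cut(x[idx], k, method)
        same = labels[:, None] == labels[None, :]
        co_sampled[np.ix_(idx, idx)] += 1
        together[np.ix_(idx, idx)] += same
    with np.errstate(divide="ignore", invalid="ignore"):
        consensus = np.where(co_sampled > 0, together / np.maximum(co_sampled, 1), 0.0)
    consensus = (consensus + consensus.T) / 2

    d = 1.0 - consensus
    np.fill_diagonal(d, 0.0)
    z = linkage(squareform(d, checks=False), method=method)
    assign = fcluster(z, k, criterion="maxclust")
    cm = pd.DataFrame(consensus, index=samples, columns=samples)
    log.info(
        "consensus_cluster: k=%d, %d resamples of %d/%d samples, cluster sizes %s",
        k, n_resample, m, n, np.bincount(assign)[1:].tolist(),
    )
    return cm, pd.Series(assign, index=samples, name="cluster")


def consensus_cdf_area(cm: pd.DataFrame) -> float:
    """Area under the empirical CDF of off-diagonal consensus values."""
    v = cm.to_numpy()
    vals = np.sort(v[np.triu_indices_from(v, k=1)])
    if len(vals) == 0:
        return 0.0
    grid = np.linspace(0, 1, 101)
    cdf = np.searchsorted(vals, grid, side="right") / len(vals)
    return float(np.trapezoid(cdf, grid))


def consensus_k_sweep(
    expr: pd.DataFrame,
    ks=range(2, 7),
    n_resample: int = 100,
    subsample_frac: float = 0.8,
    seed: int = 0,
) -> pd.DataFrame:
    """Consensus CDF areas (and deltas) over a range of k.

    The choice of k remains with the analyst; this reports, per k, the area
    under the consensus CDF and its relative increase over the previous k —
    the usual elbow diagnostic for picking the number of subtypes.
    """
    rows = []
    prev = None
    for k in ks:
        cm, _ = consensus_cluster(
            expr, k, n_resample=n_resample, subsample_frac=subsample_frac, seed=seed
        )
        area = consensus_cdf_area(cm)
        delta = np.nan if prev is None else (area - prev) / prev
        rows.append((k, area, delta))
        prev = area
    return pd.DataFrame(rows, columns=["k", "cdf_area", "delta_area"])
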