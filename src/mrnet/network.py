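"""TF-centered regulatory network inference from expression.

Edges are called by mutual information between a TF's and a candidate
target's expression profile. The MI estimator is rank-based (hence invariant
under strictly monotone transforms of either input): each profile is reduced
to ordinal ranks, cut into B = floor(sqrt(n/5)) equal-frequency bins, and MI
is the plug-in estimate on the BxB joint histogram with a Miller-Madow bias
correction, clipped at zero, in nats.

Edge significance uses a pooled permutation null (one global threshold), an
optional bootstrap-consensus step, DPI pruning of likely-indirect edges, and
Pearson-sign mode assignment.
"""

from __future__ import annotations

import itertools
import logging
from collections import defaultdict

import numpy as np
import pandas as pd

from .datatypes import MIEstimate, NetworkBuildReport, RegulatoryNetwork
from .io import derive_rng

log = logging.getLogger("mrnet")


def _n_bins(n: int) -> int:
    return max(2, int(np.floor(np.sqrt(n / 5.0))))


def _bin_matrix(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-frequency bin indices per row of a (genes x samples) matrix.

    Ordinal ranks (stable tie-break by sample position) guarantee near-equal
    marginal bin counts even on tied data.
    """
    x = np.atleast_2d(x)
    n = x.shape[1]
    order = np.argsort(x, axis=1, kind="stable")
    ranks = np.empty_like(order)
    np.put_along_axis(ranks, order, np.broadcast_to(np.arange(n), x.shape), axis=1)
    return ((ranks * n_bins) // n).astype(np.int64)


def _mi_from_bins(bt: np.ndarray, bins: np.ndarray, n_bins: int) -> np.ndarray:
    """Bias-corrected MI (nats) of one binned vector against many.

    ``bt``: (n,) bin indices; ``bins``: (g, n) bin indices. Vectorized via a
    single bincount over combined cell codes.
    """
    bins = np.atleast_2d(bins)
    g, n = bins.shape
    b2 = n_bins * n_bins
    codes = bins + (n_bins * bt)[None, :] + (np.arange(g) * b2)[:, None]
    counts = np.bincount(codes.ravel(), minlength=g * b2).reshape(g, n_bins, n_bins)
    p = counts / n
    pi = p.sum(axis=1, keepdims=True)   # marginal of the many-vectors axis
    pj = p.sum(axis=2, keepdims=True)   # marginal of bt
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log(p / (pj * pi))
    mi = np.nansum(terms, axis=(1, 2))
    occ_xy = (counts > 0).sum(axis=(1, 2))
    occ_x = (counts.sum(axis=1) > 0).sum(axis=1)
    occ_y = (counts.sum(axis=2) > 0).sum(axis=1)
    mi -= (occ_xy - occ_x - occ_y + 1) / (2.0 * n)   # Miller-Madow correction
    return np.maximum(mi, 0.0)


def mutual_information(x, y, n_bins: int | None = None) -> MIEstimate:
    """MI between two sample vectors, in nats.

    Symmetric in its arguments (bit-exact: per-cell terms are summed in
    sorted order); returns 0 with a degenerate flag for a constant input.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = len(x)
    if n < 8:
        raise ValueError("need at least 8 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    b = _n_bins(n) if n_bins is None else int(n_bins)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return MIEstimate(value=0.0, n_bins=b, n_obs=n, degenerate=True)
    bx = _bin_matrix(x[None, :], b)[0]
    by = _bin_matrix(y[None, :], b)[0]
    codes = bx * b + by
    counts = np.bincount(codes, minlength=b * b).reshape(b, b)
    p = counts / n
    pi, pj = p.sum(axis=1, keepdims=True), p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = (p * np.log(p / (pi * pj))).ravel()
    terms = np.sort(terms[np.isfinite(terms)])
    mi = float(terms.sum())
    occ_xy = int((counts > 0).sum())
    occ_x = int(((counts.sum(axis=1)) > 0).sum())
    occ_y = int(((counts.sum(axis=0)) > 0).sum())
    mi -= (occ_xy - occ_x - occ_y + 1) / (2.0 * n)
    return MIEstimate(value=max(mi, 0.0), n_bins=b, n_obs=n)


def _null_mi(values: np.ndarray, n_perm: int, n_bins: int,
             rng: np.random.Generator) -> np.ndarray:
    """Null MI pool: random gene pairings, each vector permuted independently."""
    g, n = values.shape
    bins = _bin_matrix(values, n_bins)
    ii = rng.integers(0, g, size=n_perm)
    jj = rng.integers(0, g, size=n_perm)
    left = np.take_along_axis(
        bins[ii], np.argsort(rng.random((n_perm, n)), axis=1), axis=1
    )
    right = np.take_along_axis(
        bins[jj], np.argsort(rng.random((n_perm, n)), axis=1), axis=1
    )
    # pairwise MI of matched rows: reuse the bincount kernel row by row via codes
    b2 = n_bins * n_bins
    codes = left * n_bins + right + (np.arange(n_perm) * b2)[:, None]
    counts = np.bincount(codes.ravel(), minlength=n_perm * b2).reshape(
        n_perm, n_bins, n_bins
    )
    p = counts / n
    pi = p.sum(axis=1, keepdims=True)
    pj = p.sum(axis=2, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        mi = np.nansum(p * np.log(p / (pi * pj)), axis=(1, 2))
    occ_xy = (counts > 0).sum(axis=(1, 2))
    occ_x = (counts.sum(axis=1) > 0).sum(axis=1)
    occ_y = (counts.sum(axis=2) > 0).sum(axis=1)
    mi -= (occ_xy - occ_x - occ_y + 1) / (2.0 * n)
    return np.maximum(mi, 0.0)


def permutation_threshold(
    expr: pd.DataFrame,
    tf_list,
    n_perm: int = 1000,
    alpha: float = 1e-3,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> float:
    """Global MI significance threshold from a pooled permutation null.

    MI values of ``n_perm`` random gene pairings (each profile independently
    permuted across samples) form the null pool; the threshold is its
    empirical (1 - alpha) quantile.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if rng is None:
        rng = derive_rng(seed, "permutation_threshold")
    values = expr.to_numpy(dtype=float)
    null = _null_mi(values, n_perm, _n_bins(values.shape[1]), rng)
    thr = float(np.quantile(null, 1.0 - alpha))
    log.info("permutation threshold: %.5f nats (n_perm=%d, alpha=%g)", thr, n_perm, alpha)
    return thr


def _mi_tf_vs_all(values: np.ndarray, tf_rows: np.ndarray, n_bins: int) -> np.ndarray:
    bins = _bin_matrix(values, n_bins)
    out = np.empty((len(tf_rows), values.shape[0]))
    for k, r in enumerate(tf_rows):
        out[k] = _mi_from_bins(bins[r], bins, n_bins)
    return out


def infer_network(
    expr: pd.DataFrame,
    tf_list,
    n_perm: int = 1000,
    alpha: float = 1e-3,
    n_boot: int = 100,
    consensus: float = 0.95,
    seed: int = 0,
    bootstrap: bool = True,
) -> tuple[RegulatoryNetwork, NetworkBuildReport]:
    """Infer the TF -> target network with permutation + bootstrap filtering.

    An edge (tf, gene) survives if its MI exceeds the permutation threshold
    in at least ``consensus * n_boot`` bootstrap resamples of the samples
    (the threshold is recomputed inside each resample from that resample's
    own permutation null, since resampling with replacement shifts the null).
    The retained edge weight is the MI computed on the full data. With
    ``bootstrap=False`` the full-data thresholded network is returned.
    Modes are left unset; see :func:`assign_modes`.
    """
    tf_list = list(dict.fromkeys(tf_list))
    if not tf_list:
        raise ValueError("empty TF list")
    missing = [tf for tf in tf_list if tf not in expr.index]
    if missing:
        raise ValueError(f"TFs missing from expression matrix: {missing[:5]}")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")

    values = expr.to_numpy(dtype=float)
    genes = expr.index.to_numpy()
    n_genes, n = values.shape
    b = _n_bins(n)
    tf_rows = np.array([expr.index.get_loc(tf) for tf in tf_list])
    self_mask = np.zeros((len(tf_rows), n_genes), dtype=bool)
    self_mask[np.arange(len(tf_rows)), tf_rows] = True

    rng = derive_rng(seed, "infer_network")
    mi_full = _mi_tf_vs_all(values, tf_rows, b)
    threshold = permutation_threshold(expr, tf_list, n_perm, alpha, rng=rng)
    pass_full = (mi_full > threshold) & ~self_mask
    n_edges_threshold = int(pass_full.sum())

    if bootstrap:
        need = consensus * n_boot - 1e-9
        votes = np.zeros_like(mi_full, dtype=np.int32)
        for _ in range(n_boot):
            cols = rng.integers(0, n, size=n)
            vb = values[:, cols]
            mi_b = _mi_tf_vs_all(vb, tf_rows, b)
            thr_b = np.quantile(_null_mi(vb, n_perm, b, rng), 1.0 - alpha)
            votes += mi_b > thr_b
        # consensus edges are a subset of the full-data thresholded network
        keep = pass_full & (votes >= need)
    else:
        keep = pass_full
    n_edges_boot = int(keep.sum())

    rows = np.argwhere(keep)
    edges = pd.DataFrame(
        {
            "tf": [tf_list[i] for i, _ in rows],
            "target": [str(genes[j]) for _, j in rows],
            "mi": [mi_full[i, j] for i, j in rows],
            "mode": 0,
        }
    )
    net = RegulatoryNetwork(edges=edges, tf_universe=frozenset(tf_list))
    report = NetworkBuildReport(
        threshold=threshold,
        n_perm=n_perm,
        alpha=alpha,
        n_boot=n_boot if bootstrap else 0,
        consensus=consensus,
        n_edges_threshold=n_edges_threshold,
        n_edges_bootstrap=n_edges_boot,
    )
    report.validate()
    log.info(
        "network: %d TFs, %d edges after threshold, %d after bootstrap",
        len(tf_list), n_edges_threshold, n_edges_boot,
    )
    return net, report


def tf_pair_mi(expr: pd.DataFrame, tf_list) -> dict[tuple[str, str], float]:
    """Full-data MI for every unordered TF pair (conditioning info for DPI)."""
    tf_list = list(dict.fromkeys(tf_list))
    values = expr.loc[tf_list].to_numpy(dtype=float)
    b = _n_bins(values.shape[1])
    bins = _bin_matrix(values, b)
    out: dict[tuple[str, str], float] = {}
    for i, tf1 in enumerate(tf_list):
        if i + 1 < len(tf_list):
            mis = _mi_from_bins(bins[i], bins[i + 1:], b)
            for j, tf2 in enumerate(tf_list[i + 1:]):
                out[(tf1, tf2)] = float(mis[j])
                out[(tf2, tf1)] = float(mis[j])
    return out


def dpi_filter(
    net: RegulatoryNetwork,
    mi_tf_tf: dict[tuple[str, str], float],
    tolerance: float = 0.0,
    report: NetworkBuildReport | None = None,
) -> RegulatoryNetwork:
    """Prune likely-indirect TF-target edges by the data processing inequality.

    For every triplet (tf1, tf2, g) with both TF-target edges present and
    MI(tf1, tf2) available, the strictly weakest of the three MI values is
    marked for removal if (a) it is one of the TF-target edges (TF-TF pairs
    only condition, they are never removed) and (b) it is below each of the
    other two values by more than the absolute ``tolerance`` margin. All
    marks are collected first and removed in one sweep, so the result is
    independent of triplet scan order.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    edges = net.edges
    mi_edge = {(t, g): m for t, g, m in zip(edges["tf"], edges["target"], edges["mi"])}
    parents: dict[str, list[str]] = defaultdict(list)
    for tf, g in zip(edges["tf"], edges["target"]):
        parents[g].append(tf)

    marked: set[tuple[str, str]] = set()
    for g, tfs in parents.items():
        if len(tfs) < 2:
            continue
        for tf1, tf2 in itertools.combinations(sorted(tfs), 2):
            m12 = mi_tf_tf.get((tf1, tf2))
            if m12 is None:
                continue
            m1g = mi_edge[(tf1, g)]
            m2g = mi_edge[(tf2, g)]
            if m1g + tolerance < min(m2g, m12):
                marked.add((tf1, g))
            if m2g + tolerance < min(m1g, m12):
                marked.add((tf2, g))

    if marked:
        keep = [
            (t, g) not in marked for t, g in zip(edges["tf"], edges["target"])
        ]
        edges = edges[keep].reset_index(drop=True)
    out = RegulatoryNetwork(edges=edges, tf_universe=net.tf_universe)
    if report is not None:
        report.n_edges_dpi = len(edges)
        report.validate()
    log.info("dpi_filter(tol=%g): removed %d edges, %d remain", tolerance, len(marked), len(edges))
    return out


def assign_modes(net: RegulatoryNetwork, expr: pd.DataFrame) -> RegulatoryNetwork:
    """Set each edge's mode to the sign of the TF-target Pearson correlation.

    Zero (or undefined) correlation leaves the mode unset (0); the count of
    such edges is logged.
    """
    edges = net.edges.copy()
    if len(edges) == 0:
        return RegulatoryNetwork(edges=edges, tf_universe=net.tf_universe)
    missing = (set(edges["tf"]) | set(edges["target"])) - set(expr.index)
    if missing:
        raise ValueError(f"edge genes missing from expression: {sorted(missing)[:5]}")
    x = expr.to_numpy(dtype=float)
    xc = x - x.mean(axis=1, keepdims=True)
    norms = np.sqrt((xc**2).sum(axis=1))
    pos = {g: i for i, g in enumerate(expr.index)}
    ti = np.array([pos[t] for t in edges["tf"]])
    gi = np.array([pos[g] for g in edges["target"]])
    cov = (xc[ti] * xc[gi]).sum(axis=1)
    denom = norms[ti] * norms[gi]
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom > 0, cov / denom, np.nan)
    mode = np.where(np.isnan(r) | (r == 0), 0, np.sign(r)).astype(int)
    n_unset = int((mode == 0).sum())
    if n_unset:
        log.warning("assign_modes: %d edges with zero/undefined correlation", n_unset)
    edges["mode"] = mode
    return RegulatoryNetwork(edges=edges, tf_universe=net.tf_universe)
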