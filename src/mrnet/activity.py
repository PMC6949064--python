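"""Two-tailed GSEA regulon activity (differential enrichment score, dES).

A regulon with assigned modes is split into positively (A) and negatively
(B) correlated target sets. Each tail receives a weighted Kolmogorov-Smirnov
enrichment score (ES) on a ranked gene list; regulon activity is their
difference, dES = ES_A - ES_B. On a tumor-vs-normal ranking a highly
positive dES means the regulon is induced in the tumor phenotype; on a
per-sample ranking (gene-wise z-scores of the sample against the cohort) it
reads out regulon activity in that sample.

Rankings sort scores descending; ties are broken by gene id lexicographic
order, so results are deterministic.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datatypes import RegulatoryNetwork, SplitRegulon
from .io import derive_rng

log = logging.getLogger("mrnet")

ACTIVITY_COLUMNS = ("tf", "unit", "es_a", "es_b", "des", "p", "degenerate")


def split_regulon(net: RegulatoryNetwork, tf: str, min_tail: int = 5) -> SplitRegulon:
    """Split one TF's regulon into A (mode +1) and B (mode -1) target sets.

    Targets with unset mode are dropped (count recorded). The split is
    testable only if both tails have at least ``min_tail`` members.
    """
    reg = net.regulon(tf)
    a = sorted(reg.loc[reg["mode"] == 1, "target"])
    b = sorted(reg.loc[reg["mode"] == -1, "target"])
    dropped = int((reg["mode"] == 0).sum())
    if dropped:
        log.info("split_regulon(%s): dropped %d unset-mode targets", tf, dropped)
    split = SplitRegulon(tf=tf, a=a, b=b, n_dropped=dropped, min_tail=min_tail)
    if not split.testable:
        log.info(
            "split_regulon(%s): untestable (|A|=%d, |B|=%d < min_tail=%d)",
            tf, len(a), len(b), min_tail,
        )
    return split


def _order_ranking(ranking: pd.Series) -> pd.Series:
    """Sort a gene score Series descending, ties by gene id (lexicographic)."""
    scores = ranking.to_numpy(dtype=float)
    if not np.isfinite(scores).all():
        raise ValueError("ranking scores must be finite")
    if ranking.index.has_duplicates:
        raise ValueError("duplicate gene ids in ranking")
    idx = np.lexsort((ranking.index.to_numpy(), -scores))
    return ranking.iloc[idx]


def _es_core(scores_desc: np.ndarray, hit: np.ndarray, exponent: float) -> tuple[float, bool]:
    """Weighted KS running-sum ES on an ordered list; returns (ES, degenerate).

    Hits step up proportionally to |score|^exponent (normalized); misses
    step down by 1/(N - Nh). ES is the running sum's signed maximum
    deviation from zero; when the positive and negative extremes tie in
    magnitude (within relative 1e-12) the positive one is returned. If all
    hit weights are zero (e.g. an all-zero ranking with exponent > 0),
    uniform hit weights are used and the result is flagged degenerate.
    """
    n = len(scores_desc)
    nh = int(hit.sum())
    if nh == 0 or nh == n:
        raise ValueError("gene set must hit a proper subset of the ranking")
    w = np.abs(scores_desc) ** exponent if exponent != 0 else np.ones(n)
    hw = np.where(hit, w, 0.0)
    nr = hw.sum()
    degenerate = False
    if nr == 0:
        hw = hit.astype(float)
        nr = float(nh)
        degenerate = True
    steps = hw / nr - np.where(hit, 0.0, 1.0 / (n - nh))
    run = np.cumsum(steps)
    hi, lo = float(run.max()), float(run.min())
    tie_tol = 1e-12 * max(hi, -lo, 1.0)
    es = hi if hi + lo >= -tie_tol else lo
    return es, degenerate


def gsea_es(ranking: pd.Series, geneset, exponent: float = 1.0) -> float:
    """GSEA enrichment score of one gene set on a ranked list, in [-1, 1].

    ``ranking`` maps gene id -> score; it is sorted descending internally
    (deterministic tie-break by gene id). Genes of ``geneset`` absent from
    the ranking are ignored; an empty intersection is an error.
    """
    ordered = _order_ranking(ranking)
    members = set(map(str, geneset))
    hit = ordered.index.astype(str).isin(members)
    if not hit.any():
        raise ValueError("gene set does not intersect the ranking")
    if hit.all():
        raise ValueError("gene set covers the whole ranking")
    es, _ = _es_core(ordered.to_numpy(dtype=float), np.asarray(hit), exponent)
    return es


def _des_on_ordered(
    scores: np.ndarray, hit_a: np.ndarray, hit_b: np.ndarray, exponent: float
) -> tuple[float, float, float, bool]:
    es_a, dg_a = _es_core(scores, hit_a, exponent)
    es_b, dg_b = _es_core(scores, hit_b, exponent)
    return es_a, es_b, es_a - es_b, dg_a or dg_b


def _permutation_p(
    scores: np.ndarray,
    n_a: int,
    n_b: int,
    des_obs: float,
    exponent: float,
    n_perm: int,
    rng: np.random.Generator,
) -> float:
    """Add-one smoothed two-sided permutation p for |dES| under random labels."""
    n = len(scores)
    exceed = 0
    for _ in range(n_perm):
        pick = rng.permutation(n)[: n_a + n_b]
        hit_a = np.zeros(n, dtype=bool)
        hit_b = np.zeros(n, dtype=bool)
        hit_a[pick[:n_a]] = True
        hit_b[pick[n_a:]] = True
        _, _, des_p, _ = _des_on_ordered(scores, hit_a, hit_b, exponent)
        if abs(des_p) >= abs(des_obs):
            exceed += 1
    return (exceed + 1) / (n_perm + 1)


def regulon_des_phenotype(
    split: SplitRegulon,
    ranking: pd.Series,
    exponent: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Cohort-level regulon activity on a phenotype ranking.

    ``ranking`` is a per-gene differential statistic (e.g. the moderated t
    of tumor vs normal). Both tails are scored on the same ranking;
    dES = ES_A - ES_B; the permutation p is the add-one smoothed fraction of
    ``n_perm`` random tail assignments with |dES_perm| >= |dES_obs|
    (``n_perm=0`` skips the permutation test).
    """
    if not split.testable:
        raise ValueError(
            f"regulon {split.tf} untestable: tails |A|={len(split.a)}, "
            f"|B|={len(split.b)} below min_tail={split.min_tail}"
        )
    ordered = _order_ranking(ranking)
    genes = ordered.index.astype(str)
    hit_a = np.asarray(genes.isin(set(split.a)))
    hit_b = np.asarray(genes.isin(set(split.b)))
    if hit_a.sum() < split.min_tail or hit_b.sum() < split.min_tail:
        raise ValueError(f"ranking covers fewer than min_tail members of a tail of {split.tf}")
    scores = ordered.to_numpy(dtype=float)
    es_a, es_b, des, degenerate = _des_on_ordered(scores, hit_a, hit_b, exponent)
    p = np.nan
    if n_perm:
        rng = derive_rng(seed, f"des_phenotype:{split.tf}")
        p = _permutation_p(scores, int(hit_a.sum()), int(hit_b.sum()), des, exponent, n_perm, rng)
    row = pd.DataFrame(
        [(split.tf, "phenotype", es_a, es_b, des, p, degenerate)],
        columns=list(ACTIVITY_COLUMNS),
    )
    return row


def sample_rankings(
    expr: pd.DataFrame, center: str = "mean"
) -> pd.DataFrame:
    """Gene-wise z-scores of each sample against the cohort (genes x samples).

    ``center='mean'`` standardizes with the per-gene cohort mean and SD;
    ``center='median'`` uses median and MAD (scaled to SD). Genes with zero
    spread get z = 0 (flagged in the log).
    """
    x = expr.to_numpy(dtype=float)
    if center == "mean":
        loc = x.mean(axis=1, keepdims=True)
        scale = x.std(axis=1, ddof=1, keepdims=True)
    elif center == "median":
        loc = np.median(x, axis=1, keepdims=True)
        scale = 1.4826 * np.median(np.abs(x - np.median(x, axis=1, keepdims=True)), axis=1, keepdims=True)
    else:
        raise ValueError(f"unknown center {center!r}")
    # constant genes: compare extremes exactly, fp noise can leave std ~1e-16
    zero = (x.max(axis=1, keepdims=True) == x.min(axis=1, keepdims=True)) | (scale == 0)
    if zero.any():
        log.warning("sample_rankings: %d genes with zero spread set to z=0", int(zero.sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(zero, 0.0, (x - loc) / scale)
    return pd.DataFrame(z, index=expr.index, columns=expr.columns)


def regulon_des_sample(
    split: SplitRegulon,
    expr: pd.DataFrame,
    samples=None,
    exponent: float = 1.0,
    n_perm: int = 0,
    seed: int = 0,
    center: str = "mean",
) -> pd.DataFrame:
    """Per-sample regulon activity: one (ES_A, ES_B, dES) row per sample.

    Each sample is ranked by its gene-wise z-score against the cohort, then
    scored as in :func:`regulon_des_phenotype`. ``n_perm`` defaults to 0
    here because per-sample permutation p-values are rarely needed and are
    costly across whole cohorts.
    """
    if not split.testable:
        raise ValueError(f"regulon {split.tf} untestable")
    z = sample_rankings(expr, center=center)
    if samples is None:
        samples = list(expr.columns)
    missing = [s for s in samples if s not in expr.columns]
    if missing:
        raise ValueError(f"samples missing from expression: {missing[:5]}")
    genes = z.index.astype(str)
    set_a, set_b = set(split.a), set(split.b)
    in_a = np.asarray(genes.isin(set_a))
    in_b = np.asarray(genes.isin(set_b))
    if in_a.sum() < split.min_tail or in_b.sum() < split.min_tail:
        raise ValueError(f"expression covers fewer than min_tail members of a tail of {split.tf}")
    lex = np.argsort(np.argsort(genes.to_numpy()))

    rows = []
    zv = z.to_numpy()
    col_of = {s: i for i, s in enumerate(z.columns)}
    for s in samples:
        col = zv[:, col_of[s]]
        order = np.lexsort((lex, -col))
        scores = col[order]
        es_a, es_b, des, degenerate = _des_on_ordered(scores, in_a[order], in_b[order], exponent)
        p = np.nan
        if n_perm:
            rng = derive_rng(seed, f"des_sample:{split.tf}:{s}")
            p = _permutation_p(scores, int(in_a.sum()), int(in_b.sum()), des, exponent, n_perm, rng)
        rows.append((split.tf, s, es_a, es_b, des, p, degenerate))
    return pd.DataFrame(rows, columns=list(ACTIVITY_COLUMNS))


def activity_matrix(
    net: RegulatoryNetwork,
    expr: pd.DataFrame,
    tfs=None,
    min_tail: int = 5,
    exponent: float = 1.0,
    center: str = "mean",
) -> pd.DataFrame:
    """Per-sample dES for every testable regulon in the network.

    Returns the long-format activity table (one row per TF x sample).
    Untestable regulons are skipped with a log line.
    """
    if tfs is None:
        tfs = net.tfs
    frames = []
    for tf in tfs:
        split = split_regulon(net, tf, min_tail=min_tail)
        if not split.testable:
            continue
        frames.append(
            regulon_des_sample(split, expr, exponent=exponent, center=center)
        )
    if not frames:
        return pd.DataFrame(columns=list(ACTIVITY_COLUMNS))
    out = pd.concat(frames, ignore_index=True)
    assert (out["des"] == out["es_a"] - out["es_b"]).all()
    return out
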