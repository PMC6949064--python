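"""Master Regulator Analysis: regulon-signature enrichment and evaluation.

Each TF's regulon is tested for overlap with the tumor signature by a
one-sided hypergeometric (Fisher upper-tail) test against the expression
universe, BH-corrected across TFs. Helpers rank-compare MRA results across
cohorts, intersect significant MRs into a consensus set, and score a ranking
against external labels by ROC AUC.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import RegulatoryNetwork
from .preprocess import bh_adjust

log = logging.getLogger("mrnet")

P_FLOOR = 1e-300    # floor for -log10 transforms


def _signature_genes(signature) -> set[str]:
    if isinstance(signature, pd.DataFrame):
        return set(signature.index.astype(str))
    return set(map(str, signature))


def mra_enrich(
    net: RegulatoryNetwork,
    signature,
    universe,
    min_regulon_size: int = 15,
) -> pd.DataFrame:
    """Hypergeometric enrichment of the signature in each regulon.

    Parameters
    ----------
    signature : DataFrame (genes as index) or iterable of gene ids
        The differential-expression signature; must be contained in the
        universe.
    universe : iterable of gene ids
        Background gene set, conventionally all genes in the preprocessed
        expression matrix. Regulon targets are intersected with it before
        testing; regulons smaller than ``min_regulon_size`` after
        intersection are flagged and excluded from testing.

    Returns
    -------
    DataFrame indexed by TF with columns ``regulon_size, overlap, universe,
    p, odds_ratio, fdr, rank, tested``. Ranks order tested TFs by ascending
    p (ties broken by TF id); untested TFs rank last.
    """
    universe = set(map(str, universe))
    if not universe:
        raise ValueError("empty universe")
    sig = _signature_genes(signature)
    outside = sig - universe
    if outside:
        raise ValueError(f"signature genes outside universe: {sorted(outside)[:5]}")
    m = len(universe)
    k_sig = len(sig)

    rows = []
    for tf in sorted(net.tf_universe):
        targets = set(net.edges.loc[net.edges["tf"] == tf, "target"]) & universe
        size = len(targets)
        tested = size >= min_regulon_size
        if not tested:
            rows.append((tf, size, 0, np.nan, np.nan, tested))
            continue
        overlap = len(targets & sig)
        # upper tail P(X >= overlap) with X ~ Hypergeom(m, k_sig, size)
        p = float(stats.hypergeom.sf(overlap - 1, m, k_sig, size))
        a = overlap
        b = size - overlap
        c = k_sig - overlap
        d = m - size - c
        if min(a, b, c, d) == 0:
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        rows.append((tf, size, overlap, p, (a * d) / (b * c), tested))

    res = pd.DataFrame(
        rows, columns=["tf", "regulon_size", "overlap", "p", "odds_ratio", "tested"]
    ).set_index("tf")
    res["universe"] = m
    res["fdr"] = np.nan
    tested_mask = res["tested"].to_numpy()
    if tested_mask.any():
        res.loc[tested_mask, "fdr"] = bh_adjust(res.loc[tested_mask, "p"].to_numpy())
    order = res.reset_index().sort_values(
        ["tested", "p", "tf"], ascending=[False, True, True], na_position="last"
    )["tf"]
    res["rank"] = pd.Series(np.arange(1, len(res) + 1), index=order)
    n_skip = int((~res["tested"]).sum())
    if n_skip:
        log.info("mra_enrich: %d regulons below min size %d skipped", n_skip, min_regulon_size)
    log.info(
        "mra_enrich: %d TFs tested, universe=%d, signature=%d", int(tested_mask.sum()), m, k_sig
    )
    return res[
        ["regulon_size", "overlap", "universe", "p", "odds_ratio", "fdr", "rank", "tested"]
    ]


def consensus_mrs(results: list[pd.DataFrame], alpha: float = 0.05) -> list[str]:
    """TFs with FDR < alpha in every supplied MRA result, sorted."""
    if not results:
        raise ValueError("need at least one MRA result")
    sets = [
        set(r.index[(r["fdr"] < alpha).fillna(False)]) for r in results
    ]
    out = sorted(set.intersection(*sets))
    log.info("consensus_mrs: %d TFs significant in all %d cohorts", len(out), len(results))
    return out


def rank_agreement(a: pd.DataFrame, b: pd.DataFrame, method: str = "pearson") -> float:
    """Ranking agreement R between two MRA results over shared tested TFs.

    Correlation of -log10(p) (p floored at 1e-300); ``method`` is
    ``pearson`` (default) or ``spearman``.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    shared = a.index[a["tested"]].intersection(b.index[b["tested"]])
    if len(shared) < 3:
        raise ValueError("need at least 3 shared tested TFs")
    la = -np.log10(np.maximum(a.loc[shared, "p"].to_numpy(dtype=float), P_FLOOR))
    lb = -np.log10(np.maximum(b.loc[shared, "p"].to_numpy(dtype=float), P_FLOOR))
    if method == "spearman":
        return float(stats.spearmanr(la, lb).statistic)
    return float(np.corrcoef(la, lb)[0, 1])


def roc_evaluate(result: pd.DataFrame, labels) -> float:
    """AUC of the MRA ranking against binary TF labels (Mann-Whitney form).

    AUC is the fraction of (positive, negative) TF pairs in which the
    positive TF has the smaller enrichment p; ties count one half.
    """
    labels = dict(labels)
    shared = [tf for tf in result.index[result["tested"]] if tf in labels]
    y = np.array([int(labels[tf]) for tf in shared])
    if not ((y == 1).any() and (y == 0).any()):
        raise ValueError("need both positive and negative labels")
    score = -result.loc[shared, "p"].to_numpy(dtype=float)   # higher = better
    pos, neg = score[y == 1], score[y == 0]
    greater = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return float((greater + 0.5 * ties) / (len(pos) * len(neg)))
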