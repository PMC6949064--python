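"""Independent brute-force oracles shared by the unit and acceptance tests.

Each oracle re-derives its quantity by direct enumeration or literal
summation, without touching the package's vectorized implementations.
"""

import itertools
from math import comb

import numpy as np
import pandas as pd


def hypergeom_upper_tail(m, k_sig, n_reg, overlap):
    """P(X >= overlap) for X ~ Hypergeom(universe m, successes k_sig, draws n_reg)."""
    total = comb(m, n_reg)
    return sum(
        comb(k_sig, k) * comb(m - k_sig, n_reg - k)
        for k in range(overlap, min(k_sig, n_reg) + 1)
    ) / total


def es_oracle(genes_desc, scores_desc, geneset, exponent):
    """Step-by-step GSEA running-sum on an already-ordered gene list."""
    members = set(geneset)
    n = len(genes_desc)
    hits = [g in members for g in genes_desc]
    nh = sum(hits)
    nr = sum(
        abs(s) ** exponent for g, s in zip(genes_desc, scores_desc) if g in members
    )
    hi = lo = 0.0
    run = 0.0
    for g, s, h in zip(genes_desc, scores_desc, hits):
        if h:
            run += (abs(s) ** exponent) / nr if nr > 0 else 1.0 / nh
        else:
            run -= 1.0 / (n - nh)
        hi = max(hi, run)
        lo = min(lo, run)
    # positive extreme wins magnitude ties (same convention as the package)
    return hi if hi + lo >= -1e-12 * max(hi, -lo, 1.0) else lo


def ordered_series(genes, scores):
    """Descending score order with ties broken by gene id, as documented."""
    s = pd.Series(scores, index=genes, dtype=float)
    idx = np.lexsort((s.index.to_numpy(), -s.to_numpy()))
    return s.iloc[idx]


def dpi_oracle(edges, mi_tt, tol):
    """Surviving TF-target pairs after naive all-triplet DPI enumeration."""
    removed = set()
    mi = {(t, g): m for t, g, m in edges}
    genes = {g for _, g, _ in edges}
    tfs = {t for t, _, _ in edges}
    for t1, t2 in itertools.combinations(sorted(tfs), 2):
        if (t1, t2) not in mi_tt and (t2, t1) not in mi_tt:
            continue
        m12 = mi_tt.get((t1, t2), mi_tt.get((t2, t1)))
        for g in sorted(genes):
            if (t1, g) in mi and (t2, g) in mi:
                m1, m2 = mi[(t1, g)], mi[(t2, g)]
                if m1 + tol < m2 and m1 + tol < m12:
                    removed.add((t1, g))
                if m2 + tol < m1 and m2 + tol < m12:
                    removed.add((t2, g))
    return {(t, g) for t, g, _ in edges} - removed


def km_oracle(times, events):
    """Hand product-limit estimate at each distinct event time."""
    order = np.argsort(times, kind="stable")
    times = np.asarray(times, float)[order]
    events = np.asarray(events, int)[order]
    s = 1.0
    curve = {}
    for t in sorted(set(times[events == 1])):
        n_at_risk = np.sum(times >= t)
        d = np.sum((times == t) & (events == 1))
        s *= 1 - d / n_at_risk
        curve[t] = s
    return curve


def logrank_oracle(groups):
    """Direct O-E summation with hypergeometric variance per event time."""
    times = np.concatenate([np.asarray(t, float) for t, _ in groups])
    events = np.concatenate([np.asarray(e, int) for _, e in groups])
    labels = np.concatenate([np.full(len(t), i) for i, (t, _) in enumerate(groups)])
    k = len(groups)
    o_minus_e = np.zeros(k)
    var = np.zeros((k, k))
    for t in sorted(set(times[events == 1])):
        at_risk = times >= t
        n = at_risk.sum()
        d = ((times == t) & (events == 1)).sum()
        for i in range(k):
            ni = (at_risk & (labels == i)).sum()
            di = ((times == t) & (events == 1) & (labels == i)).sum()
            o_minus_e[i] += di - d * ni / n
        if n > 1:
            for i in range(k):
                ni = (at_risk & (labels == i)).sum()
                for j in range(k):
                    nj = (at_risk & (labels == j)).sum()
                    delta = 1.0 if i == j else 0.0
                    var[i, j] += d * (ni / n) * (delta - nj / n) * (n - d) / (n - 1)
    v = np.linalg.pinv(var[:-1, :-1])
    return float(o_minus_e[:-1] @ v @ o_minus_e[:-1])
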