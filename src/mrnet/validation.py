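"""Planted-truth recovery metrics and calibration experiments.

Everything here evaluates the pipeline against the synthetic generator's
ground truth: edge precision/recall, mode agreement, recovery of planted
master regulators, null-calibration rates of the test statistics, and the
power of the dES-based survival stratification. These functions drive the
package's own validation suite and reports.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .activity import regulon_des_phenotype, regulon_des_sample
from .datatypes import GroundTruth, RegulatoryNetwork, SplitRegulon
from .io import derive_rng
from .mra import mra_enrich
from .network import mutual_information
from .preprocess import moderated_ttest
from .simulate import generate_ground_truth, simulate_cohort, simulate_survival
from .survival import logrank_test, strata_survival, stratify_by_activity
from .activity import split_regulon

log = logging.getLogger("mrnet")


def edge_metrics(truth: GroundTruth, net: RegulatoryNetwork) -> dict[str, float]:
    """Precision/recall of inferred edges and mode agreement vs planted truth.

    Mode agreement is evaluated on recovered planted edges whose target has a
    single planted parent (a multi-parent target has no well-defined
    per-edge marginal sign).
    """
    planted = truth.edge_set()
    found = net.edge_set()
    tp = len(found & planted)
    precision = tp / len(found) if found else 0.0
    recall = tp / len(planted) if planted else 0.0

    parent_count: dict[str, int] = {}
    for _, target in planted:
        parent_count[target] = parent_count.get(target, 0) + 1
    modes = truth.mode_map()
    agree = []
    for tf, g, m in zip(net.edges["tf"], net.edges["target"], net.edges["mode"]):
        if (tf, g) in modes and parent_count[g] == 1 and int(m) != 0:
            agree.append(int(m) == modes[(tf, g)])
    mode_agreement = float(np.mean(agree)) if agree else float("nan")
    return {
        "precision": precision,
        "recall": recall,
        "mode_agreement": mode_agreement,
        "n_edges": len(found),
        "n_planted": len(planted),
    }


def top_k_active_recovery(mra_result: pd.DataFrame, truth: GroundTruth,
                          k: int = 10) -> int:
    """How many of the top-k MRA-ranked TFs are planted-active."""
    top = mra_result[mra_result["rank"] <= k].index
    return int(sum(tf in truth.active_tfs for tf in top))


def planted_signature_metrics(truth: GroundTruth, signature: pd.DataFrame,
                              universe) -> dict[str, float]:
    """Recall of planted PT-shifted genes and FPR among unshifted genes."""
    shifted = set()
    for tf in truth.active_tfs:
        shifted.add(tf)
        shifted.update(t.target for t in truth.regulons[tf])
    sig = set(signature.index)
    null_genes = set(universe) - shifted
    return {
        "recall": len(sig & shifted) / len(shifted),
        "fpr": len(sig & null_genes) / len(null_genes),
        "n_shifted": len(shifted),
    }


def mi_gaussian_error(seed: int = 0, rho: float = 0.8, n: int = 10000) -> float:
    """|MI_hat - (-0.5 ln(1-rho^2))| on one bivariate-normal sample."""
    rng = derive_rng(seed, "mi_gaussian")
    x = rng.standard_normal(n)
    y = rho * x + np.sqrt(1 - rho**2) * rng.standard_normal(n)
    return abs(mutual_information(x, y).value - (-0.5 * np.log(1 - rho**2)))


def moderated_t_type1(seed: int = 0, n_genes: int = 10000,
                      n_per_class: int = 10, alpha: float = 0.05) -> float:
    """Fraction of null genes with moderated-t p below alpha."""
    rng = derive_rng(seed, "modt_type1")
    expr = pd.DataFrame(
        rng.standard_normal((n_genes, 2 * n_per_class)),
        index=[f"g{i}" for i in range(n_genes)],
        columns=[f"s{j}" for j in range(2 * n_per_class)],
    )
    classes = pd.Series(
        ["PT"] * n_per_class + ["NT"] * n_per_class, index=expr.columns
    )
    de = moderated_ttest(expr, classes)
    return float((de.table["p"] < alpha).mean())


def logrank_type1(seed: int = 0, n_rep: int = 500, n_per_group: int = 100,
                  alpha: float = 0.05) -> float:
    """Log-rank rejection rate under equal exponential hazards."""
    rng = derive_rng(seed, "logrank_type1")
    rej = 0
    for _ in range(n_rep):
        g1 = (rng.exponential(50, n_per_group), np.ones(n_per_group, int))
        g2 = (rng.exponential(50, n_per_group), np.ones(n_per_group, int))
        rej += logrank_test([g1, g2]).p < alpha
    return rej / n_rep


def des_null_rejection(seed: int = 0, n_rep: int = 200, n_genes: int = 200,
                       tail: int = 10, n_perm: int = 1000,
                       alpha: float = 0.05) -> float:
    """dES permutation-p rejection rate for random tails on random rankings."""
    rng = derive_rng(seed, "des_null")
    rej = 0
    for rep in range(n_rep):
        genes = [f"g{i:04d}" for i in range(n_genes)]
        scores = pd.Series(rng.standard_normal(n_genes), index=genes)
        pick = rng.permutation(n_genes)[: 2 * tail]
        split = SplitRegulon(
            tf="T",
            a=[genes[i] for i in pick[:tail]],
            b=[genes[i] for i in pick[tail:]],
        )
        row = regulon_des_phenotype(
            split, scores, n_perm=n_perm, seed=int(rng.integers(2**31))
        )
        rej += row["p"].iloc[0] < alpha
    return rej / n_rep


def batch_shift_residual(seed: int = 0, delta: float = 3.0,
                         n_genes: int = 100, n_per_batch: int = 30) -> float:
    """Max |between-batch gene-mean difference| after adjusting a planted
    constant shift in a zero-interaction (duplicated-samples) design."""
    from .preprocess import batch_adjust

    rng = derive_rng(seed, "batch_residual")
    base = rng.normal(7, 1, n_genes)[:, None] + rng.standard_normal(n_per_batch)[None, :]
    x = pd.DataFrame(
        np.hstack([base, base + delta]),
        index=[f"g{i}" for i in range(n_genes)],
        columns=[f"s{j}" for j in range(2 * n_per_batch)],
    )
    batches = pd.Series(
        ["B1"] * n_per_batch + ["B2"] * n_per_batch, index=x.columns
    )
    adj = batch_adjust(x, batches)
    m1 = adj.iloc[:, :n_per_batch].mean(axis=1)
    m2 = adj.iloc[:, n_per_batch:].mean(axis=1)
    return float(np.abs(m1 - m2).max())


def survival_linkage_replicate(seed: int, n_pt: int = 300, beta: float = -1.0,
                               tf: str = "TF001") -> float:
    """One survival-linkage experiment: p of active_high vs pooled repressed.

    A cohort is simulated with ``beta`` as the log-hazard coefficient of one
    active TF; per-sample dES of that TF's planted regulon (computed on the
    tumor submatrix) stratifies the tumors, and the log-rank p compares the
    active_high stratum against the pooled repressed strata.
    """
    base = generate_ground_truth(seed=seed, survival_beta={tf: beta})
    truth = GroundTruth(
        gene_ids=base.gene_ids,
        regulons=base.regulons,
        active_tfs=frozenset(base.active_tfs | {tf}),
        delta=base.delta,
        survival_beta=base.survival_beta,
    )
    cohort = simulate_cohort(truth, n_pt=n_pt, n_nt=100, n_batches=1, seed=seed)
    annot = simulate_survival(cohort, seed=seed)
    reg = truth.regulons[tf]
    net = RegulatoryNetwork(
        edges=pd.DataFrame(
            {"tf": tf, "target": [t.target for t in reg],
             "mi": 1.0, "mode": [t.mode for t in reg]}
        ),
        tf_universe={tf},
    )
    split = split_regulon(net, tf)
    pt = [s for s in cohort.expression.columns
          if annot.set_index("sample_id").loc[s, "tissue_class"] == "PT"]
    act = regulon_des_sample(split, cohort.expression[pt])
    strata = stratify_by_activity(act)
    _, lr = strata_survival(
        strata, annot, groups=["active_high", ("repressed_high", "repressed_low")]
    )
    return lr.p


def survival_linkage_power(seed: int = 0, n_rep: int = 100, n_pt: int = 300,
                           beta: float = -1.0, alpha: float = 0.05) -> float:
    """Fraction of replicates where the activity strata separate survival."""
    rng = derive_rng(seed, "survival_linkage")
    hits = 0
    for _ in range(n_rep):
        rep_seed = int(rng.integers(2**31))
        hits += survival_linkage_replicate(rep_seed, n_pt=n_pt, beta=beta) < alpha
    return hits / n_rep
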