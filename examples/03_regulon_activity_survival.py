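"""Per-sample regulon activity (two-tailed GSEA dES) and survival strata.

Computes dES = ES_A - ES_B for one planted regulon in every tumor sample,
stratifies patients into active/repressed (high/low) groups and compares
their survival with a log-rank test. The planted hazard coefficient is
negative, so high regulon activity should be protective.
"""

import pandas as pd

import mrnet

tf = "TF001"
base = mrnet.generate_ground_truth(seed=7, survival_beta={tf: -1.0})
truth = mrnet.GroundTruth(
    gene_ids=base.gene_ids, regulons=base.regulons,
    active_tfs=frozenset(base.active_tfs | {tf}),
    delta=base.delta, survival_beta=base.survival_beta,
)
cohort = mrnet.simulate_cohort(truth, n_pt=300, n_nt=100, n_batches=1, seed=7)
annot = mrnet.simulate_survival(cohort, seed=7)

reg = truth.regulons[tf]
net = mrnet.RegulatoryNetwork(
    edges=pd.DataFrame(
        {"tf": tf, "target": [t.target for t in reg],
         "mi": 1.0, "mode": [t.mode for t in reg]}
    ),
    tf_universe={tf},
)
split = mrnet.split_regulon(net, tf)
print(f"{tf} regulon: {len(split.a)} positive (A), {len(split.b)} negative (B) targets")

pt = annot.loc[annot["tissue_class"] == "PT", "sample_id"].tolist()
activity = mrnet.regulon_des_sample(split, cohort.expression[pt])
print(f"per-sample dES over {len(activity)} tumors: "
      f"mean {activity['des'].mean():+.3f}, range "
      f"[{activity['des'].min():+.3f}, {activity['des'].max():+.3f}]")

strata = mrnet.stratify_by_activity(activity)
print("strata:", strata.value_counts().to_dict())

curves, lr = mrnet.strata_survival(
    strata, annot, groups=["active_high", ("repressed_high", "repressed_low")]
)
print(f"log-rank active_high vs repressed: chi2={lr.statistic:.2f}, p={lr.p:.2e}")
# p << 0.05 with the active_high curve on top: tumors in which the regulon
# is induced outlive those in which it is repressed, as planted (beta = -1).
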