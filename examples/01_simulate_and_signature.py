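"""Simulate a tumor/normal cohort and derive its differential signature.

Builds the default desk-scale cohort (20 TFs, 10 of them with a +2 log2
tumor shift, 2,000 genes, 150 tumor + 100 adjacent-normal samples across
3 batches), removes the batch effects, and thresholds the moderated-t
results into the tumor signature.
"""

import mrnet

truth = mrnet.generate_ground_truth(seed=7)
cohort = mrnet.simulate_cohort(truth, seed=7)
print(f"cohort: {cohort.expression.shape[0]} genes x {cohort.expression.shape[1]} samples")
print(cohort.annotation["tissue_class"].value_counts().to_dict())

batches = cohort.annotation.set_index("sample_id")["batch_id"]
expr = mrnet.batch_adjust(cohort.expression, batches)

classes = cohort.annotation.set_index("sample_id")["tissue_class"]
de = mrnet.moderated_ttest(expr, classes)
signature = mrnet.build_signature(de, fdr_cut=0.05, fc_cut=1.5)

up = (signature["direction"] == "up").sum()
print(f"signature: {len(signature)} genes at FDR<0.05 and fold change>1.5 "
      f"({up} up, {len(signature) - up} down)")

metrics = mrnet.planted_signature_metrics(cohort.truth, signature, expr.index)
print(f"recall of planted tumor-shifted genes: {metrics['recall']:.3f}; "
      f"false-positive rate among null genes: {metrics['fpr']:.4f}")
# A recall near 1 with FPR near 0 means the moderated-t + fold-change screen
# recovers almost exactly the genes the generator actually shifted in tumors.
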