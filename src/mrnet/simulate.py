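"""Synthetic cohorts with planted regulatory structure.

The generator emulates the statistical shape of a multi-study tumor/normal
expression compendium on the log2 scale: a set of TFs, each driving a signed
regulon; a subset of TFs with a tumor-specific activity shift; additive
per-batch effects; and survival times whose hazard depends on planted TF
activity. The model is linear-Gaussian:

    TF      = baseline + delta * 1[active, PT] + batch + eps
    target  = baseline + mode * strength * (TF deviation) + batch + eps
    other   = baseline + batch + eps

with eps ~ Normal(0, noise_sd) i.i.d. per gene and sample. TF activity is
identified with TF expression; there is no hidden-activity layer.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datatypes import GroundTruth, SimulatedCohort, TargetSpec
from .io import derive_rng

log = logging.getLogger("mrnet")

#: Planted coupling strengths are drawn uniformly from this range: direct,
#: detectably strong regulation at microarray-like noise levels.
STRENGTH_RANGE = (0.6, 1.0)

BASELINE_MEAN = 7.0     # log2 intensity scale of a typical array
BASELINE_SD = 1.0
BATCH_OFFSET_SD = 0.5   # per-gene additive batch effect


def generate_ground_truth(
    n_tf: int = 20,
    n_genes: int = 2000,
    targets_per_tf: int = 50,
    frac_negative_mode: float = 0.3,
    n_active_tfs: int = 10,
    delta: float = 2.0,
    seed: int = 0,
    strength_range: tuple[float, float] = STRENGTH_RANGE,
    survival_beta: dict[str, float] | None = None,
) -> GroundTruth:
    """Plant a TF -> target network with signed modes and active TFs.

    Parameters
    ----------
    n_tf, n_genes, targets_per_tf
        Network scale. The first ``n_tf`` gene ids are TFs; targets are drawn
        per TF without replacement from the non-TF genes (regulons of distinct
        TFs may overlap).
    frac_negative_mode
        Probability that a planted edge is repressive (mode -1).
    n_active_tfs, delta
        Number of TFs carrying a tumor-specific shift of ``delta`` log2 units.
    survival_beta
        Optional per-TF log-hazard coefficients (default: all zero).
    """
    if not 0 <= frac_negative_mode <= 1:
        raise ValueError("frac_negative_mode must be in [0, 1]")
    if n_active_tfs > n_tf:
        raise ValueError(f"n_active_tfs={n_active_tfs} exceeds n_tf={n_tf}")
    if targets_per_tf > n_genes - n_tf:
        raise ValueError("targets_per_tf exceeds the number of non-TF genes")
    if targets_per_tf < 2:
        raise ValueError("each regulon needs at least 2 targets")

    rng = derive_rng(seed, "ground_truth")
    tf_ids = [f"TF{i + 1:03d}" for i in range(n_tf)]
    gene_ids = tf_ids + [f"G{j + 1:05d}" for j in range(n_genes - n_tf)]
    pool = np.array(gene_ids[n_tf:])

    regulons: dict[str, list[TargetSpec]] = {}
    for tf in tf_ids:
        targets = rng.choice(pool, size=targets_per_tf, replace=False)
        modes = np.where(rng.random(targets_per_tf) < frac_negative_mode, -1, 1)
        strengths = rng.uniform(*strength_range, size=targets_per_tf)
        regulons[tf] = [
            TargetSpec(str(t), int(m), float(s))
            for t, m, s in zip(targets, modes, strengths)
        ]

    active = frozenset(rng.choice(tf_ids, size=n_active_tfs, replace=False).tolist())
    beta = dict(survival_beta or {})
    unknown = set(beta) - set(tf_ids)
    if unknown:
        raise ValueError(f"survival_beta for unknown TFs: {sorted(unknown)}")
    truth = GroundTruth(
        gene_ids=gene_ids,
        regulons=regulons,
        active_tfs=active,
        delta=float(delta),
        survival_beta={tf: beta.get(tf, 0.0) for tf in tf_ids},
    )
    log.info(
        "ground truth: %d TFs, %d genes, %d targets/TF, %d active (delta=%g), seed=%d",
        n_tf, n_genes, targets_per_tf, n_active_tfs, delta, seed,
    )
    return truth


def simulate_cohort(
    truth: GroundTruth,
    n_pt: int = 150,
    n_nt: int = 100,
    n_batches: int = 3,
    noise_sd: float = 0.7,
    seed: int = 0,
    batch_offset_sd: float = BATCH_OFFSET_SD,
    batch_scale_range: tuple[float, float] = (1.0, 1.0),
) -> SimulatedCohort:
    """Simulate log2 expression for a paired tumor (PT) / non-tumor (NT) cohort.

    Samples are assigned to batches round-robin after shuffling, so every
    batch mixes both tissue classes (no class/batch confounding). Batch
    effects are additive per gene by default; ``batch_scale_range`` other
    than (1, 1) additionally scales the noise term per batch.
    """
    if n_pt < 2 or n_nt < 2:
        raise ValueError("need at least 2 samples per tissue class")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    genes = truth.gene_ids
    gene_pos = {g: i for i, g in enumerate(genes)}
    for tf, targets in truth.regulons.items():
        if tf not in gene_pos:
            raise ValueError(f"truth TF {tf!r} not among gene_ids")
        for t in targets:
            if t.target not in gene_pos:
                raise ValueError(f"truth target {t.target!r} not among gene_ids")

    rng = derive_rng(seed, "cohort")
    n = n_pt + n_nt
    n_genes = len(genes)
    sample_ids = [f"PT{i + 1:04d}" for i in range(n_pt)] + [
        f"NT{i + 1:04d}" for i in range(n_nt)
    ]
    is_pt = np.array([s.startswith("PT") for s in sample_ids])

    order = rng.permutation(n)
    batch_idx = np.empty(n, dtype=int)
    batch_idx[order] = np.arange(n) % n_batches
    if np.bincount(batch_idx, minlength=n_batches).min() < 3:
        raise ValueError("every batch needs at least 3 samples")
    batch_ids = [f"B{b + 1}" for b in range(n_batches)]

    baseline = rng.normal(BASELINE_MEAN, BASELINE_SD, size=n_genes)
    if n_batches > 1:
        offsets = rng.normal(0.0, batch_offset_sd, size=(n_batches, n_genes))
        offsets -= offsets.mean(axis=0)  # identifiable: effects sum to zero
        scales = rng.uniform(*batch_scale_range, size=(n_batches, n_genes))
    else:
        offsets = np.zeros((1, n_genes))
        scales = np.ones((1, n_genes))

    eps = rng.normal(0.0, noise_sd, size=(n_genes, n)) if noise_sd > 0 else np.zeros(
        (n_genes, n)
    )
    x = np.tile(baseline[:, None], (1, n))
    # biological signal: TF deviations propagate to targets before batch/noise
    for tf, targets in truth.regulons.items():
        ti = gene_pos[tf]
        dev = scales[batch_idx, ti] * eps[ti]
        if tf in truth.active_tfs:
            dev = dev + truth.delta * is_pt
        x[ti] += dev - scales[batch_idx, ti] * eps[ti]  # delta part only; eps added below
        for t in targets:
            x[gene_pos[t.target]] += t.mode * t.strength * dev
    x += offsets[batch_idx].T + scales[batch_idx].T * eps

    expr = pd.DataFrame(x, index=pd.Index(genes, name="gene_id"), columns=sample_ids)
    annot = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "tissue_class": np.where(is_pt, "PT", "NT"),
            "batch_id": [batch_ids[b] for b in batch_idx],
            "cohort_id": "SIM",
            "survival_time": np.nan,
            "event": np.nan,
        }
    )
    truth_out = GroundTruth(
        gene_ids=list(genes),
        regulons=truth.regulons,
        active_tfs=truth.active_tfs,
        delta=truth.delta,
        survival_beta=dict(truth.survival_beta),
        batch_offsets={b: offsets[i].copy() for i, b in enumerate(batch_ids)},
        batch_scales={b: scales[i].copy() for i, b in enumerate(batch_ids)},
    )
    log.info(
        "cohort: %d PT + %d NT, %d batches, noise_sd=%g, seed=%d",
        n_pt, n_nt, n_batches, noise_sd, seed,
    )
    return SimulatedCohort(expression=expr, annotation=annot, truth=truth_out)


def simulate_survival(
    cohort: SimulatedCohort,
    baseline_hazard: float = 0.02,
    censor_rate: float = 0.01,
    seed: int = 0,
) -> pd.DataFrame:
    """Fill survival columns for the PT samples of a simulated cohort.

    Event times are exponential with proportional hazards on standardized TF
    expression: rate = baseline_hazard * exp(sum_tf beta_tf * z(TF)), where z
    standardizes each TF's expression across the PT samples. Censoring times
    are exponential with ``censor_rate`` (0 disables censoring); the recorded
    time is the minimum and the event indicator marks death before censoring.
    Times are in months.
    """
    if baseline_hazard <= 0:
        raise ValueError("baseline_hazard must be > 0")
    if censor_rate < 0:
        raise ValueError("censor_rate must be >= 0")
    annot = cohort.annotation.copy()
    pt_mask = annot["tissue_class"] == "PT"
    if not pt_mask.any():
        raise ValueError("cohort has no PT samples")
    pt_samples = annot.loc[pt_mask, "sample_id"].tolist()
    expr_pt = cohort.expression[pt_samples]

    eta = np.zeros(len(pt_samples))
    for tf, beta in cohort.truth.survival_beta.items():
        if beta == 0.0:
            continue
        x = expr_pt.loc[tf].to_numpy()
        sd = x.std(ddof=1)
        if sd == 0:
            raise ValueError(f"TF {tf!r} has zero variance among PT samples")
        eta += beta * (x - x.mean()) / sd

    rng = derive_rng(seed, "survival")
    rate = baseline_hazard * np.exp(eta)
    event_time = rng.exponential(1.0 / rate)
    if censor_rate > 0:
        censor_time = rng.exponential(1.0 / censor_rate, size=len(pt_samples))
    else:
        censor_time = np.full(len(pt_samples), np.inf)
    observed = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(float)

    annot.loc[pt_mask, "survival_time"] = observed
    annot.loc[pt_mask, "event"] = event
    log.info(
        "survival: %d PT samples, baseline_hazard=%g, censor_rate=%g, %d events",
        len(pt_samples), baseline_hazard, censor_rate, int(event.sum()),
    )
    return annot
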