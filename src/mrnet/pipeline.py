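"""End-to-end orchestration: cohort -> signature -> network -> MRA -> activity.

`run_discovery` chains the stages on in-memory objects; `run_all` adds
simulation and file output for the CLI. Each stage draws its randomness
from a documented stream derived from the single run seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import pandas as pd

from . import io
from .activity import activity_matrix
from .datatypes import NetworkBuildReport, RegulatoryNetwork, SimulatedCohort
from .io import RunConfig
from .mra import mra_enrich
from .network import assign_modes, dpi_filter, infer_network, tf_pair_mi
from .preprocess import batch_adjust, build_signature, collapse_duplicates, moderated_ttest
from .simulate import generate_ground_truth, simulate_cohort, simulate_survival

log = logging.getLogger("mrnet")


@dataclasses.dataclass
class DiscoveryResult:
    expression: pd.DataFrame            # preprocessed
    de: object
    signature: pd.DataFrame
    network: RegulatoryNetwork
    report: NetworkBuildReport
    mra: pd.DataFrame
    activity: pd.DataFrame | None = None


def preprocess_expression(
    expr: pd.DataFrame, annot: pd.DataFrame, config: RunConfig
) -> pd.DataFrame:
    """Collapse duplicate genes, then batch-adjust if more than one batch."""
    expr = collapse_duplicates(expr, method=config.collapse)
    batches = annot.set_index("sample_id")["batch_id"]
    if batches.reindex(expr.columns).nunique() > 1:
        expr = batch_adjust(expr, batches)
    return expr


def run_discovery(
    expr: pd.DataFrame,
    annot: pd.DataFrame,
    tf_list,
    config: RunConfig | None = None,
    compute_activity: bool = False,
) -> DiscoveryResult:
    """Full MR discovery on one cohort.

    Stages: preprocessing (duplicate collapse + batch adjustment),
    moderated-t PT/NT signature, MI network inference with permutation and
    bootstrap filtering, DPI pruning, Pearson mode assignment, and
    hypergeometric MRA against the expression universe. Per-sample regulon
    activity is optional (it is the most expensive stage on large cohorts).
    """
    config = config or RunConfig()
    expr = preprocess_expression(expr, annot, config)
    classes = annot.set_index("sample_id")["tissue_class"]
    de = moderated_ttest(expr, classes)
    signature = build_signature(
        de, fdr_cut=config.fdr_cut, fc_cut=config.fc_cut, fc_scale=config.fc_scale
    )
    net, report = infer_network(
        expr,
        tf_list,
        n_perm=config.n_perm,
        alpha=config.alpha,
        n_boot=config.n_boot,
        consensus=config.consensus,
        seed=config.rng_seed,
    )
    mi_tt = tf_pair_mi(expr, tf_list)
    net = dpi_filter(net, mi_tt, tolerance=config.dpi_tolerance, report=report)
    net = assign_modes(net, expr)
    mra = mra_enrich(
        net,
        signature,
        universe=expr.index,
        min_regulon_size=config.min_regulon_size,
    )
    act = None
    if compute_activity:
        act = activity_matrix(
            net, expr, min_tail=config.min_tail, exponent=config.exponent
        )
    return DiscoveryResult(
        expression=expr, de=de, signature=signature,
        network=net, report=report, mra=mra, activity=act,
    )


def simulate_all(config: RunConfig) -> SimulatedCohort:
    """Simulate a full cohort (ground truth, expression, survival) per config."""
    truth = generate_ground_truth(
        n_tf=config.n_tf,
        n_genes=config.n_genes,
        targets_per_tf=config.targets_per_tf,
        frac_negative_mode=config.frac_negative_mode,
        n_active_tfs=config.n_active_tfs,
        delta=config.delta,
        seed=config.rng_seed,
    )
    cohort = simulate_cohort(
        truth,
        n_pt=config.n_pt,
        n_nt=config.n_nt,
        n_batches=config.n_batches,
        noise_sd=config.noise_sd,
        seed=config.rng_seed,
    )
    cohort.annotation = simulate_survival(
        cohort,
        baseline_hazard=config.baseline_hazard,
        censor_rate=config.censor_rate,
        seed=config.rng_seed,
    )
    return cohort


def write_cohort(cohort: SimulatedCohort, out: str | Path) -> None:
    """Write a simulated cohort: expression/annotation TSV + truth GMT/TSV."""
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    io.write_expression(cohort.expression, out / "expression.tsv")
    io.write_annotation(cohort.annotation, out / "annotation.tsv")
    truth = cohort.truth
    io.write_gmt(
        {tf: [t.target for t in ts] for tf, ts in truth.regulons.items()},
        out / "truth_regulons.gmt",
        description="planted_regulon",
    )
    rows = [
        (tf, t.target, t.mode, t.strength, int(tf in truth.active_tfs),
         truth.survival_beta.get(tf, 0.0))
        for tf, ts in truth.regulons.items() for t in ts
    ]
    pd.DataFrame(
        rows, columns=["tf", "target", "mode", "strength", "active", "survival_beta"]
    ).to_csv(out / "truth_edges.tsv", sep="\t", index=False)
    with open(out / "tfs.txt", "w", encoding="utf8") as fh:
        fh.writelines(f"{tf}\n" for tf in truth.tfs)


def run_all(config: RunConfig, out: str | Path) -> DiscoveryResult:
    """Simulate a cohort and run the full discovery, writing all outputs."""
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    cohort = simulate_all(config)
    write_cohort(cohort, out / "cohort")
    result = run_discovery(
        cohort.expression,
        cohort.annotation,
        cohort.truth.tfs,
        config,
        compute_activity=True,
    )
    io.write_expression(result.expression, out / "expression_preprocessed.tsv")
    result.signature.to_csv(out / "signature.tsv", sep="\t", index_label="gene_id")
    io.write_network(result.network, out / "network.tsv")
    with open(out / "network_report.json", "w", encoding="utf8") as fh:
        json.dump(dataclasses.asdict(result.report), fh, indent=2)
    result.mra.to_csv(out / "mra.tsv", sep="\t", index_label="tf")
    if result.activity is not None:
        result.activity.to_csv(out / "activity.tsv", sep="\t", index=False)
    config.to_file(out / "config.txt")
    log.info("run_all: outputs written to %s", out)
    return result
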