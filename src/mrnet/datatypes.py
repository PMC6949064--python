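"""Shared data containers for the master-regulator pipeline.

Expression matrices are plain ``pandas.DataFrame`` objects (genes x samples,
log2 scale) and sample annotation tables are DataFrames with a fixed column
set; the structured results of each stage (networks, ground truth, regulon
splits, build reports) are the small dataclasses below.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

#: Required columns of a sample-annotation table.
ANNOTATION_COLUMNS = (
    "sample_id",
    "tissue_class",
    "batch_id",
    "cohort_id",
    "survival_time",
    "event",
)

#: Columns of a network edge table. ``mode`` is +1 / -1, or 0 when unset.
EDGE_COLUMNS = ("tf", "target", "mi", "mode")


class TargetSpec(NamedTuple):
    """One planted regulatory link: target gene, sign and coupling strength."""

    target: str
    mode: int          # +1 induced, -1 repressed
    strength: float    # in (0, 1]


@dataclass
class RegulatoryNetwork:
    """TF -> target network with MI weights and (optionally) signed modes.

    Attributes
    ----------
    edges : pandas.DataFrame
        Columns ``tf, target, mi, mode``; at most one row per (tf, target);
        ``mode`` is +1, -1 or 0 (unset).
    tf_universe : frozenset of str
        All TFs considered during inference (a TF may have zero edges).
    """

    edges: pd.DataFrame
    tf_universe: frozenset

    def __post_init__(self) -> None:
        self.edges = pd.DataFrame(self.edges, columns=list(EDGE_COLUMNS)).reset_index(
            drop=True
        )
        self.tf_universe = frozenset(self.tf_universe)
        self.validate()

    def validate(self) -> None:
        e = self.edges
        if len(e) == 0:
            return
        if (e["tf"] == e["target"]).any():
            raise ValueError("self-edges are not allowed")
        unknown = set(e["tf"]) - self.tf_universe
        if unknown:
            raise ValueError(f"edge TFs missing from tf_universe: {sorted(unknown)[:5]}")
        if (np.asarray(e["mi"], dtype=float) < 0).any():
            raise ValueError("negative MI weight")
        if e.duplicated(subset=["tf", "target"]).any():
            raise ValueError("duplicate (tf, target) edge")
        if not np.isin(np.asarray(e["mode"], dtype=int), (-1, 0, 1)).all():
            raise ValueError("mode must be +1, -1 or 0 (unset)")

    @property
    def tfs(self) -> list[str]:
        """TFs that have at least one edge, sorted."""
        return sorted(set(self.edges["tf"]))

    def regulon(self, tf: str) -> pd.DataFrame:
        """Edge rows of one TF's regulon."""
        if tf not in self.tf_universe:
            raise KeyError(f"unknown TF {tf!r}")
        return self.edges[self.edges["tf"] == tf].reset_index(drop=True)

    def edge_set(self) -> set[tuple[str, str]]:
        return set(zip(self.edges["tf"], self.edges["target"]))


@dataclass
class GroundTruth:
    """Planted structure of a simulated cohort — the acceptance surface.

    ``regulons`` maps each TF symbol to its planted targets; ``active_tfs``
    carry a tumor-specific expression shift of ``delta`` log2 units;
    ``survival_beta`` are per-TF log-hazard coefficients on standardized TF
    expression; ``batch_offsets``/``batch_scales`` (per-batch, per-gene) are
    filled in by the cohort simulator.
    """

    gene_ids: list[str]
    regulons: dict[str, list[TargetSpec]]
    active_tfs: frozenset
    delta: float
    survival_beta: dict[str, float] = field(default_factory=dict)
    batch_offsets: dict[str, np.ndarray] = field(default_factory=dict)
    batch_scales: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def tfs(self) -> list[str]:
        return sorted(self.regulons)

    def edge_set(self) -> set[tuple[str, str]]:
        return {(tf, t.target) for tf, ts in self.regulons.items() for t in ts}

    def mode_map(self) -> dict[tuple[str, str], int]:
        return {(tf, t.target): t.mode for tf, ts in self.regulons.items() for t in ts}


@dataclass
class SimulatedCohort:
    """Expression + annotation + the ground truth that generated them."""

    expression: pd.DataFrame
    annotation: pd.DataFrame
    truth: GroundTruth


@dataclass
class MIEstimate:
    """Mutual information of one gene pair, in nats.

    ``n_bins`` is the per-axis grid size of the equal-frequency estimator;
    ``degenerate`` marks a constant input (MI defined as 0).
    """

    value: float
    n_bins: int
    n_obs: int
    degenerate: bool = False


@dataclass
class NetworkBuildReport:
    """Provenance of one network build; edge counts are per filtering stage."""

    threshold: float
    n_perm: int
    alpha: float
    n_boot: int
    consensus: float
    n_edges_threshold: int
    n_edges_bootstrap: int
    n_edges_dpi: int | None = None

    def validate(self) -> None:
        counts = [self.n_edges_threshold, self.n_edges_bootstrap]
        if self.n_edges_dpi is not None:
            counts.append(self.n_edges_dpi)
        if any(b > a for a, b in zip(counts, counts[1:])):
            raise ValueError("edge counts must be non-increasing across stages")


@dataclass
class SplitRegulon:
    """A regulon split by mode into positive (A) and negative (B) target sets."""

    tf: str
    a: list[str]
    b: list[str]
    n_dropped: int = 0      # unset-mode targets dropped from the split
    min_tail: int = 5

    @property
    def testable(self) -> bool:
        return len(self.a) >= self.min_tail and len(self.b) >= self.min_tail
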