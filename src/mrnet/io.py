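"""Readers, writers, run configuration and logging.

One tabular dialect is used throughout: tab-separated UTF-8 text with '.'
decimals. Gene sets travel as GMT, networks as a 4-column edge list.
Missing survival fields are encoded as empty strings.
"""

from __future__ import annotations

import dataclasses
import logging
import zlib
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import ANNOTATION_COLUMNS, EDGE_COLUMNS, RegulatoryNetwork

log = logging.getLogger("mrnet")


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )


def derive_rng(seed: int, stream: str) -> np.random.Generator:
    """Independent, reproducible RNG stream for one pipeline stage.

    All stages derive their generator from the single run seed plus a stable
    stage label, so partial re-runs reproduce full-run results exactly.
    """
    key = zlib.crc32(stream.encode("utf8"))
    return np.random.default_rng(np.random.SeedSequence((int(seed), key)))


# ---------------------------------------------------------------------------
# expression matrices


def validate_expression(expr: pd.DataFrame) -> pd.DataFrame:
    """Enforce expression-matrix invariants (finite, unique gene/sample ids)."""
    if expr.index.has_duplicates:
        dups = expr.index[expr.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids: {dups[:5]}")
    if expr.columns.has_duplicates:
        dups = expr.columns[expr.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids: {dups[:5]}")
    values = expr.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValueError("expression matrix must be numeric")
    if not np.isfinite(values).all():
        g, s = np.argwhere(~np.isfinite(values))[0]
        raise ValueError(
            f"non-finite expression value for gene {expr.index[g]!r}, "
            f"sample {expr.columns[s]!r}"
        )
    return expr


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples log2 expression TSV.

    The header row holds sample ids, the first column gene ids. Duplicate
    gene rows are rejected here — collapsing duplicates is a preprocessing
    step, not a parsing default.
    """
    with open(path, encoding="utf8") as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    seen = [s for s in set(header) if header.count(s) > 1]
    if seen:
        raise ValueError(f"duplicate sample ids in {path}: {sorted(seen)[:5]}")
    raw = pd.read_csv(path, sep="\t", index_col=0, keep_default_na=False, dtype=str)
    raw.index = raw.index.astype(str)
    probe = raw.apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(probe.isna().to_numpy())
    if len(bad):
        g, s = bad[0]
        raise ValueError(
            f"non-numeric cell {raw.iloc[g, s]!r} for gene {raw.index[g]!r}, "
            f"sample {raw.columns[s]!r} in {path}"
        )
    # float() parsing is correctly rounded, so write->read round-trips exactly
    return validate_expression(raw.astype(float))


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    validate_expression(expr)
    expr.to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# sample annotation


def validate_annotation(annot: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ANNOTATION_COLUMNS if c not in annot.columns]
    if missing:
        raise ValueError(f"annotation missing columns: {missing}")
    if annot["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in annotation")
    bad = set(annot["tissue_class"]) - {"PT", "NT"}
    if bad:
        raise ValueError(f"tissue_class must be PT or NT, got {sorted(bad)}")
    t_na = annot["survival_time"].isna()
    e_na = annot["event"].isna()
    if (t_na != e_na).any():
        raise ValueError("survival_time must be present iff event is present")
    times = annot.loc[~t_na, "survival_time"]
    if (times < 0).any():
        raise ValueError("negative survival_time")
    if not annot.loc[~e_na, "event"].isin([0, 1]).all():
        raise ValueError("event must be 0 or 1")
    return annot


def read_annotation(path: str | Path) -> pd.DataFrame:
    annot = pd.read_csv(path, sep="\t", keep_default_na=False, dtype=str)
    for col in ("survival_time", "event"):
        annot[col] = pd.to_numeric(annot[col].replace("", np.nan))
    return validate_annotation(annot)


def write_annotation(annot: pd.DataFrame, path: str | Path) -> None:
    validate_annotation(annot)
    out = annot.copy()
    out["event"] = out["event"].map(lambda v: "" if pd.isna(v) else str(int(v)))
    out["survival_time"] = out["survival_time"].map(
        lambda v: "" if pd.isna(v) else repr(float(v))
    )
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene sets (GMT)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT file into ``{set_name: ordered unique member list}``."""
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has <3 fields")
            name = fields[0]
            members = list(dict.fromkeys(m for m in fields[2:] if m))
            sets[name] = members
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path, description: str = "") -> None:
    with open(path, "w", encoding="utf8") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")


# ---------------------------------------------------------------------------
# networks


def write_network(net: RegulatoryNetwork, path: str | Path) -> None:
    net.validate()
    out = net.edges.copy()
    out["mode"] = out["mode"].map(lambda m: "" if int(m) == 0 else f"{int(m):+d}")
    out["mi"] = out["mi"].map(lambda v: repr(float(v)))
    out.to_csv(path, sep="\t", index=False, columns=list(EDGE_COLUMNS))


def read_network(path: str | Path, tf_universe=None) -> RegulatoryNetwork:
    raw = pd.read_csv(path, sep="\t", keep_default_na=False, dtype=str)
    missing = [c for c in EDGE_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"network file missing columns: {missing}")
    edges = pd.DataFrame(
        {
            "tf": raw["tf"],
            "target": raw["target"],
            "mi": pd.to_numeric(raw["mi"]),
            "mode": [0 if m == "" else int(m) for m in raw["mode"]],
        }
    )
    if tf_universe is None:
        tf_universe = set(edges["tf"])
    return RegulatoryNetwork(edges=edges, tf_universe=frozenset(tf_universe))


def read_tf_list(path: str | Path) -> list[str]:
    """One TF symbol per line; blank lines ignored, order preserved."""
    with open(path, encoding="utf8") as fh:
        tfs = [line.strip() for line in fh if line.strip()]
    return list(dict.fromkeys(tfs))


# ---------------------------------------------------------------------------
# run configuration


@dataclasses.dataclass
class RunConfig:
    """All stage parameters with their defaults, plus the single run seed."""

    rng_seed: int = 0
    # synthetic cohort
    n_tf: int = 20
    n_genes: int = 2000
    targets_per_tf: int = 50
    frac_negative_mode: float = 0.3
    n_active_tfs: int = 10
    delta: float = 2.0
    n_pt: int = 150
    n_nt: int = 100
    n_batches: int = 3
    noise_sd: float = 0.7
    baseline_hazard: float = 0.02
    censor_rate: float = 0.01
    # preprocessing / signature
    collapse: str = "max-mean"          # or "mean"
    fdr_cut: float = 0.05
    fc_cut: float = 1.5
    fc_scale: str = "linear"            # or "log2"
    # network inference
    alpha: float = 1e-3
    n_perm: int = 1000
    n_boot: int = 100
    consensus: float = 0.95
    dpi_tolerance: float = 0.0
    # MRA
    min_regulon_size: int = 15
    mra_alpha: float = 0.05
    # regulon activity
    exponent: float = 1.0
    min_tail: int = 5
    activity_n_perm: int = 1000
    # clustering
    k: int = 3
    n_resample: int = 100
    subsample_frac: float = 0.8

    def __post_init__(self) -> None:
        checks = [
            (0 <= self.frac_negative_mode <= 1, "frac_negative_mode in [0,1]"),
            (self.n_active_tfs <= self.n_tf, "n_active_tfs <= n_tf"),
            (self.noise_sd >= 0, "noise_sd >= 0"),
            (0 < self.alpha < 1, "alpha in (0,1)"),
            (self.n_perm >= 100, "n_perm >= 100"),
            (self.n_boot >= 1, "n_boot >= 1"),
            (0 < self.consensus <= 1, "consensus in (0,1]"),
            (self.dpi_tolerance >= 0, "dpi_tolerance >= 0"),
            (self.collapse in ("max-mean", "mean"), "collapse in {max-mean, mean}"),
            (self.fc_scale in ("linear", "log2"), "fc_scale in {linear, log2}"),
            (0 < self.subsample_frac <= 1, "subsample_frac in (0,1]"),
            (self.k >= 2, "k >= 2"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(f"invalid RunConfig: {msg}")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Parse a ``key = value`` text config (``#`` comments allowed)."""
        kwargs: dict = {}
        fields = {f.name: f.type for f in dataclasses.fields(cls)}
        defaults = cls()
        with open(path, encoding="utf8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected 'key = value'")
                key, value = (part.strip() for part in line.split("=", 1))
                if key not in fields:
                    raise ValueError(f"{path}:{lineno}: unknown parameter {key!r}")
                kind = type(getattr(defaults, key))
                kwargs[key] = value if kind is str else kind(float(value)) if kind is int else kind(value)
        return cls(**kwargs)

    def to_file(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf8") as fh:
            for f in dataclasses.fields(self):
                fh.write(f"{f.name} = {getattr(self, f.name)}\n")

    def log(self, stage: str) -> None:
        log.info("%s: config=%s", stage, dataclasses.asdict(self))
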