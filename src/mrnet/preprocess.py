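"""Preprocessing and the tumor/normal differential-expression signature.

Three steps: collapse duplicate gene rows, remove additive/multiplicative
batch effects by parametric empirical-Bayes adjustment, and score PT-vs-NT
differential expression with an empirical-Bayes moderated t-statistic
(pooled two-class variance shrunk toward a scaled inverse-chi-square prior
fitted across genes).
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .io import validate_expression

log = logging.getLogger("mrnet")


def collapse_duplicates(expr: pd.DataFrame, method: str = "max-mean") -> pd.DataFrame:
    """Collapse duplicate gene rows to one row per gene id.

    ``max-mean`` (default) keeps, for each duplicated gene, the row with the
    largest mean across samples — the standard probe-collapse rule, which
    preserves within-row covariance. ``mean`` averages the duplicate rows
    instead.
    """
    if method not in ("max-mean", "mean"):
        raise ValueError(f"unknown collapse method {method!r}")
    if not expr.index.has_duplicates:
        return expr
    if method == "mean":
        out = expr.groupby(level=0, sort=False).mean()
    else:
        row_means = expr.mean(axis=1).to_numpy()
        keep = np.zeros(len(expr), dtype=bool)
        best: dict[str, int] = {}
        for i, g in enumerate(expr.index):
            j = best.get(g)
            if j is None or row_means[i] > row_means[j]:
                best[g] = i
        keep[list(best.values())] = True
        out = expr.iloc[keep]
    log.info("collapse_duplicates(%s): %d -> %d rows", method, len(expr), len(out))
    return validate_expression(out)


# ---------------------------------------------------------------------------
# batch adjustment (parametric empirical Bayes, location/scale model)


def batch_adjust(expr: pd.DataFrame, batches: pd.Series | dict, *,
                 max_iter: int = 100, tol: float = 1e-8) -> pd.DataFrame:
    """Remove per-batch location/scale effects by empirical-Bayes shrinkage.

    Per gene, the data are standardized against the (batch-size weighted)
    grand mean and pooled variance; per-batch additive effects (gamma) and
    variance inflation (delta^2) are estimated, shrunk toward a normal and an
    inverse-gamma prior fitted across genes by moments, then removed. Each
    gene is re-centered to its pre-adjustment grand mean afterwards, so batch
    adjustment never moves a gene's overall level.

    A single batch is an identity operation. A batch in which every gene has
    zero variance is rejected as degenerate.
    """
    batches = pd.Series(batches)
    batch_of = batches.reindex(expr.columns)
    if batch_of.isna().any():
        raise ValueError("every sample needs a batch label")
    levels = batch_of.unique().tolist()
    if len(levels) == 1:
        return expr.copy()
    counts = batch_of.value_counts()
    if counts.min() < 2:
        raise ValueError("every batch needs at least 2 samples")

    x = expr.to_numpy(dtype=float)
    n_genes, n = x.shape
    groups = [np.flatnonzero((batch_of == b).to_numpy()) for b in levels]
    n_b = np.array([len(g) for g in groups], dtype=float)

    batch_mean = np.stack([x[:, g].mean(axis=1) for g in groups], axis=1)
    grand = batch_mean @ (n_b / n)
    # pooled variance of residuals around the per-batch means (design fit)
    sample_batch = np.empty(n, dtype=int)
    for j, g in enumerate(groups):
        sample_batch[g] = j
    resid = x - batch_mean[:, sample_batch]
    var_pooled = (resid**2).mean(axis=1)
    if (var_pooled == 0).any():
        raise ValueError("gene(s) with zero within-batch variance everywhere")
    xs = (x - grand[:, None]) / np.sqrt(var_pooled)[:, None]

    gamma_hat = np.stack([xs[:, g].mean(axis=1) for g in groups], axis=1)
    delta_hat = np.stack([xs[:, g].var(axis=1, ddof=1) for g in groups], axis=1)
    if (delta_hat.max(axis=0) == 0).any() and n_genes > 0:
        # a batch with zero variance for every gene cannot be scale-adjusted
        dead = [levels[j] for j in range(len(levels)) if delta_hat[:, j].max() == 0]
        if dead:
            raise ValueError(f"batch(es) with zero variance for every gene: {dead}")

    gamma_bar = gamma_hat.mean(axis=0)
    tau2 = gamma_hat.var(axis=0, ddof=1)
    d_mean = delta_hat.mean(axis=0)
    d_var = delta_hat.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        a_prior = (2 * d_var + d_mean**2) / d_var
        b_prior = (d_mean * d_var + d_mean**3) / d_var

    gamma_star = gamma_hat.copy()
    delta_star = delta_hat.copy()
    for j, g in enumerate(groups):
        if tau2[j] == 0 or not np.isfinite(a_prior[j]):
            # degenerate prior (identical effects across genes): no shrinkage
            gamma_star[:, j] = gamma_bar[j] if tau2[j] == 0 else gamma_hat[:, j]
            continue
        g_old = gamma_hat[:, j].copy()
        d_old = delta_hat[:, j].copy()
        nj = n_b[j]
        for _ in range(max_iter):
            g_new = (nj * tau2[j] * gamma_hat[:, j] + d_old * gamma_bar[j]) / (
                nj * tau2[j] + d_old
            )
            ssq = ((xs[:, g] - g_new[:, None]) ** 2).sum(axis=1)
            d_new = (0.5 * ssq + b_prior[j]) / (nj / 2 + a_prior[j] - 1)
            change = max(
                np.abs(g_new - g_old).max() / (np.abs(g_old).max() + 1e-12),
                np.abs(d_new - d_old).max() / (np.abs(d_old).max() + 1e-12),
            )
            g_old, d_old = g_new, d_new
            if change < tol:
                break
        gamma_star[:, j], delta_star[:, j] = g_old, d_old

    adj = xs.copy()
    for j, g in enumerate(groups):
        adj[:, g] = (xs[:, g] - gamma_star[:, [j]]) / np.sqrt(delta_star[:, [j]])
    out = adj * np.sqrt(var_pooled)[:, None] + grand[:, None]
    out += (x.mean(axis=1) - out.mean(axis=1))[:, None]  # preserve grand means

    log.info("batch_adjust: %d batches %s, %d genes", len(levels), levels, n_genes)
    return pd.DataFrame(out, index=expr.index, columns=expr.columns)


# ---------------------------------------------------------------------------
# moderated t


@dataclasses.dataclass
class DEResult:
    """Full per-gene differential-expression table (PT minus NT)."""

    table: pd.DataFrame     # mean_pt, mean_nt, log2fc, var_residual, var_shrunk, t, p
    df_residual: float
    df_prior: float
    var_prior: float

    def validate(self) -> None:
        v = self.table
        lo = np.minimum(v["var_residual"], self.var_prior) - 1e-12
        hi = np.maximum(v["var_residual"], self.var_prior) + 1e-12
        ok = (v["var_shrunk"] >= lo) & (v["var_shrunk"] <= hi)
        if not ok.all():
            raise ValueError("shrunken variance outside [residual, prior] bracket")


def _fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moments fit of (d0, s0^2) on log residual variances (Smyth 2004 style).

    Returns ``d0 = inf`` when the observed spread of log-variances is no
    larger than the sampling spread (complete shrinkage).
    """
    pos = s2 > 0
    if not pos.any():
        raise ValueError("all residual variances are zero: degenerate fit")
    z = np.log(s2[pos])
    e = z - special.digamma(df / 2) + np.log(df / 2)
    e_mean = e.mean()
    n = len(e)
    e_var = ((e - e_mean) ** 2).sum() / (n - 1) if n > 1 else 0.0
    target = e_var - special.polygamma(1, df / 2)
    if target <= 0:
        return np.inf, float(np.exp(e_mean))
    # invert trigamma(d0/2) = target by monotone bisection
    lo, hi = 1e-8, 1e8
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if special.polygamma(1, mid) > target:
            lo = mid
        else:
            hi = mid
    d0 = 2 * np.sqrt(lo * hi)
    s0 = np.exp(e_mean + special.digamma(d0 / 2) - np.log(d0 / 2))
    return float(d0), float(s0)


def moderated_ttest(
    expr: pd.DataFrame,
    classes: pd.Series | dict,
    *,
    d0_override: float | None = None,
) -> DEResult:
    """Empirical-Bayes moderated two-sample t-test, PT minus NT, per gene.

    The pooled residual variance (df = n - 2) is shrunk toward a prior
    (d0, s0^2) fitted by closed-form moments on the log residual variances;
    p-values use a t-distribution with d0 + df degrees of freedom. Forcing
    ``d0_override=0`` recovers the classical pooled t exactly;
    ``d0_override=inf`` shrinks every gene fully to s0^2.
    """
    classes = pd.Series(classes).reindex(expr.columns)
    if classes.isna().any():
        raise ValueError("every sample needs a class label")
    bad = set(classes) - {"PT", "NT"}
    if bad:
        raise ValueError(f"class labels must be PT/NT, got {sorted(bad)}")
    pt = expr.loc[:, (classes == "PT").to_numpy()].to_numpy(dtype=float)
    nt = expr.loc[:, (classes == "NT").to_numpy()].to_numpy(dtype=float)
    n1, n2 = pt.shape[1], nt.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 samples per class")
    df = n1 + n2 - 2

    mean_pt, mean_nt = pt.mean(axis=1), nt.mean(axis=1)
    ss = ((pt - mean_pt[:, None]) ** 2).sum(axis=1) + (
        (nt - mean_nt[:, None]) ** 2
    ).sum(axis=1)
    s2 = ss / df
    log2fc = mean_pt - mean_nt

    if d0_override is not None:
        d0 = float(d0_override)
        s0 = float("nan") if d0 == 0 else _fit_variance_prior(s2, df)[1]
    else:
        d0, s0 = _fit_variance_prior(s2, df)
        if d0 < 0:  # moment fit failure: fall back to the classical t
            log.warning("moderated_ttest: negative prior df, falling back to d0=0")
            d0 = 0.0
    if np.isinf(d0):
        s2_shrunk = np.full_like(s2, s0)
        df_total = np.inf
    elif d0 == 0:
        s0 = float("nan")
        s2_shrunk = s2
        df_total = float(df)
    else:
        s2_shrunk = (d0 * s0 + df * s2) / (d0 + df)
        df_total = float(d0 + df)

    se = np.sqrt(s2_shrunk * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, log2fc / se, np.inf * np.sign(log2fc))
    if np.isinf(df_total):
        p = 2 * stats.norm.sf(np.abs(t))
    else:
        p = 2 * stats.t.sf(np.abs(t), df_total)

    table = pd.DataFrame(
        {
            "mean_pt": mean_pt,
            "mean_nt": mean_nt,
            "log2fc": log2fc,
            "var_residual": s2,
            "var_shrunk": s2_shrunk,
            "t": t,
            "p": p,
        },
        index=expr.index,
    )
    result = DEResult(
        table=table, df_residual=float(df), df_prior=float(d0), var_prior=float(s0)
        if not np.isnan(s0) else float("nan"),
    )
    if not np.isnan(s0):
        result.validate()
    log.info(
        "moderated_ttest: %d genes, n=%d+%d, d0=%.4g, s0^2=%.4g",
        len(table), n1, n2, d0, s0,
    )
    return result


def bh_adjust(p: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def build_signature(
    de: DEResult,
    fdr_cut: float = 0.05,
    fc_cut: float = 1.5,
    fc_scale: str = "linear",
) -> pd.DataFrame:
    """Threshold a DE table into the tumor signature.

    Keeps genes with BH FDR < ``fdr_cut`` and fold change above ``fc_cut``;
    with the default linear scale the fold-change rule is 2^|log2FC| >
    fc_cut, with ``fc_scale='log2'`` it is |log2FC| > fc_cut. Columns:
    gene (index), log2fc, t, p, fdr, direction (up/down).
    """
    if fc_scale not in ("linear", "log2"):
        raise ValueError(f"unknown fc_scale {fc_scale!r}")
    tab = de.table
    fdr = bh_adjust(tab["p"].to_numpy())
    abs_lfc = tab["log2fc"].abs().to_numpy()
    fc_ok = (2.0**abs_lfc > fc_cut) if fc_scale == "linear" else (abs_lfc > fc_cut)
    keep = (fdr < fdr_cut) & fc_ok
    sig = pd.DataFrame(
        {
            "log2fc": tab["log2fc"],
            "t": tab["t"],
            "p": tab["p"],
            "fdr": fdr,
            "direction": np.where(tab["log2fc"] > 0, "up", "down"),
        },
        index=tab.index,
    )[keep]
    if len(sig) == 0:
        log.warning("build_signature: empty signature at fdr<%g, fc>%g", fdr_cut, fc_cut)
    else:
        log.info(
            "signature: %d genes (%.0f%% up) at fdr<%g, fc>%g (%s)",
            len(sig), 100 * (sig["direction"] == "up").mean(), fdr_cut, fc_cut, fc_scale,
        )
    return sig
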