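"""Bulk RNA-seq differential expression.

Two-group comparison on log2-CPM with empirical-Bayes variance moderation,
Benjamini-Hochberg FDR, and the fold-change/FDR selection rule used for the
GnRH-response gene list (|log2FC| >= 2 at FDR < 0.05, with a 16-fold tier).

The moderated statistic shrinks per-gene residual variances toward a prior:
s~_g^2 = (d0 s0^2 + d s_g^2) / (d0 + d), with the prior degrees of freedom d0
and prior variance s0^2 estimated by method of moments on log s_g^2 (the
scaled-F moment equations). Precision weighting of observations is not
applied; the stage operates on unweighted log2-CPM.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from lbt2kit.io import CountMatrix

logger = logging.getLogger("lbt2kit")


def tpm(counts: np.ndarray | CountMatrix, lengths: np.ndarray) -> np.ndarray:
    """Transcripts per million: (c/L) / sum(c/L) * 1e6, per column."""
    if isinstance(counts, CountMatrix):
        counts = counts.dense()
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if np.any(lengths <= 0):
        raise ValueError("gene lengths must be positive")
    if counts.ndim == 1:
        counts = counts[:, None]
        squeeze = True
    else:
        squeeze = False
    rate = counts / lengths[:, None]
    colsum = rate.sum(axis=0)
    zero = colsum == 0
    if zero.any():
        logger.warning("%d all-zero columns in TPM input", int(zero.sum()))
        colsum[zero] = 1.0
    out = rate / colsum[None, :] * 1e6
    return out[:, 0] if squeeze else out


def log_cpm(counts: np.ndarray, pseudocount: float = 0.5) -> np.ndarray:
    """log2(CPM + pseudocount) per column."""
    counts = np.asarray(counts, dtype=float)
    libsize = counts.sum(axis=0)
    libsize[libsize == 0] = 1.0
    return np.log2(counts / libsize[None, :] * 1e6 + pseudocount)


# ---------------------------------------------------------------------------
# Empirical-Bayes variance moderation
# ---------------------------------------------------------------------------


@dataclass
class ModeratedPrior:
    """Scaled-F prior for residual variances: s_g^2 ~ s0^2 F(d, d0)."""

    d0: float  # prior df; inf means complete shrinkage
    s02: float  # prior variance
    d: float  # residual df per gene


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration (monotone, convex)."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(75):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def estimate_prior(s2: np.ndarray, d: float, fallback_d0: float = 4.0) -> ModeratedPrior:
    """Method-of-moments fit of (d0, s0^2) from the spread of log s_g^2.

    If the observed spread of log s_g^2 does not exceed what residual
    sampling alone predicts, d0 is infinite and every variance is shrunk to
    the common value. A non-finite moment estimate falls back to d0 = 4.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0)
    if ok.sum() < 2 or d <= 0:
        logger.warning("too few positive variances; using complete shrinkage")
        return ModeratedPrior(np.inf, float(np.nanmean(s2[ok])) if ok.any() else 1.0, d)
    z = np.log(s2[ok])
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, d / 2.0))
    if not np.isfinite(evar):
        logger.warning("non-finite moment estimate; falling back to d0=%g", fallback_d0)
        d0 = fallback_d0
        s02 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
        return ModeratedPrior(d0, s02, d)
    if evar <= 0:
        return ModeratedPrior(np.inf, float(np.exp(emean)), d)
    d0 = 2.0 * _trigamma_inverse(evar)
    s02 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return ModeratedPrior(d0, s02, d)


def squeeze_var(s2: np.ndarray, prior: ModeratedPrior) -> np.ndarray:
    """Posterior (shrunk) variances s~_g^2 = (d0 s0^2 + d s_g^2)/(d0 + d)."""
    if np.isinf(prior.d0):
        return np.full_like(np.asarray(s2, dtype=float), prior.s02)
    return (prior.d0 * prior.s02 + prior.d * np.asarray(s2, dtype=float)) / (prior.d0 + prior.d)


def moderated_t_test(
    counts: CountMatrix,
    groups: np.ndarray | list,
    control: str | None = None,
    d0: float | None = None,
) -> pd.DataFrame:
    """Moderated two-group test on log2-CPM.

    log2FC is treated minus control group mean of log2(CPM + 0.5). Setting
    ``d0=0`` disables shrinkage (ordinary two-sample t with pooled variance).

    Returns a DataFrame with gene, logCPM, log2FC, t, p, q columns (q added
    by BH across all tested genes).
    """
    groups = np.asarray(groups, dtype=object)
    levels = pd.unique(groups)
    if len(levels) != 2:
        raise ValueError(f"exactly two group levels required, got {list(levels)}")
    if control is None:
        control = levels[0]
    treated = [lv for lv in levels if lv != control][0]
    a = groups == treated
    b = groups == control
    n1, n2 = int(a.sum()), int(b.sum())
    if min(n1, n2) < 2:
        raise ValueError("at least 2 replicates per group required")

    y = log_cpm(counts.dense())
    mean_a = y[:, a].mean(axis=1)
    mean_b = y[:, b].mean(axis=1)
    lfc = mean_a - mean_b
    d = float(n1 + n2 - 2)
    ss = ((y[:, a] - mean_a[:, None]) ** 2).sum(axis=1) + (
        (y[:, b] - mean_b[:, None]) ** 2
    ).sum(axis=1)
    s2 = ss / d

    if np.all(s2 == 0):
        logger.warning("zero residual variance in all genes; d0 treated as infinite")
        prior = ModeratedPrior(np.inf, float(np.mean(s2)) or 1e-12, d)
    elif d0 is not None:
        if d0 == 0:
            prior = ModeratedPrior(0.0, 1.0, d)  # s0^2 irrelevant at d0=0
        else:
            p0 = estimate_prior(s2, d)
            prior = ModeratedPrior(float(d0), p0.s02, d)
    else:
        prior = estimate_prior(s2, d)

    s2_post = squeeze_var(s2, prior)
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, lfc / se, 0.0)
    df_total = prior.d0 + d
    if np.isinf(df_total):
        df_total = d * counts.n_genes  # cap at total pooled df
    df_total = min(df_total, d * counts.n_genes)
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    out = pd.DataFrame(
        {
            "gene": counts.gene_ids,
            "logCPM": y.mean(axis=1),
            "log2FC": lfc,
            "t": t,
            "p": p,
        }
    )
    out["q"] = bh_fdr(out["p"].to_numpy())
    out.attrs["prior"] = prior
    return out


# ---------------------------------------------------------------------------
# BH FDR and selection
# ---------------------------------------------------------------------------


def bh_fdr(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving on input index.

    q_(i) = min_{j>=i} p_(j) m / j, capped at 1. NaN p-values propagate as
    NaN and are excluded from m.
    """
    p = np.asarray(pvalues, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    if pv.size == 0:
        return q
    if pv.min() < 0 or pv.max() > 1:
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    qv = np.empty(m)
    qv[order] = np.minimum(ranked, 1.0)
    q[ok] = qv
    return q


def select_de(
    results: pd.DataFrame, lfc_threshold: float = 2.0, fdr_threshold: float = 0.05
) -> pd.DataFrame:
    """Apply the FC/FDR selection rule; adds selected and tier16fold flags.

    selected: q < fdr_threshold and |log2FC| >= lfc_threshold.
    tier16fold: q < fdr_threshold and |log2FC| >= 4 (the 16-fold gene list).
    """
    out = results.copy()
    if len(out) == 0:
        out["selected"] = pd.Series(dtype=bool)
        out["tier16fold"] = pd.Series(dtype=bool)
        return out
    sig = out["q"] < fdr_threshold
    out["selected"] = sig & (out["log2FC"].abs() >= lfc_threshold)
    out["tier16fold"] = sig & (out["log2FC"].abs() >= 4.0)
    return out
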