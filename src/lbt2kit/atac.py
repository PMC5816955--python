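"""ATAC-seq analytics over fragments, peaks and gene models.

Fragment-length periodicity (nucleosomal ~200 bp spacing), peak feature
classification, TSS meta-profiles, top-peak selection, accessibility-to-
expression integration via nearest-TSS peak assignment, PWM log-odds motif
scanning, and footprint notch detection in per-base coverage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from lbt2kit.io import GeneModel

logger = logging.getLogger("lbt2kit")

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


# ---------------------------------------------------------------------------
# Fragment-length periodicity
# ---------------------------------------------------------------------------


@dataclass
class PeriodicityResult:
    period: int  # bp, argmax autocorrelation lag
    autocorrelation: float  # at the dominant lag (normalized)
    pvalue: float  # permutation p-value for the peak autocorrelation


def estimate_periodicity(
    lengths: np.ndarray,
    lag_range: tuple[int, int] = (120, 350),
    max_length: int = 1000,
    min_length: int = 100,
    median_window: int = 151,
    n_permutations: int = 200,
    seed: int = 0,
) -> PeriodicityResult:
    """Dominant period of the fragment-length histogram.

    The 1-bp histogram over [0, max_length] is detrended by subtracting a
    running median (window ``median_window``); the dominant period is the
    argmax of the autocorrelation of the detrended histogram over
    ``lag_range``. The autocorrelation uses only bins at or above
    ``min_length``: nucleosomal periodicity lives in the >=1-nucleosome
    ladder, and the sharp sub-nucleosomal onset would otherwise alias into
    the lag search. Significance comes from a permutation null that shuffles
    the detrended histogram values.
    """
    lengths = np.asarray(lengths)
    if lengths.size < 1000:
        raise ValueError("need >= 1000 fragments for a stable period estimate")
    hist = np.bincount(np.clip(lengths, 0, max_length), minlength=max_length + 1).astype(float)
    baseline = ndimage.median_filter(hist, size=median_window, mode="nearest")
    det = (hist - baseline)[min_length:]

    def _ac(x: np.ndarray) -> np.ndarray:
        denom = float(np.sum(x * x))
        if denom == 0:
            return np.zeros(lag_range[1] - lag_range[0] + 1)
        return np.array(
            [np.sum(x[:-lag] * x[lag:]) / denom for lag in range(lag_range[0], lag_range[1] + 1)]
        )

    ac = _ac(det)
    best = int(np.argmax(ac))
    period = lag_range[0] + best
    obs = float(ac[best])

    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    for i in range(n_permutations):
        null[i] = np.max(_ac(rng.permutation(det)))
    pvalue = float((np.sum(null >= obs) + 1) / (n_permutations + 1))
    return PeriodicityResult(period, obs, pvalue)


# ---------------------------------------------------------------------------
# Peak classification and selection
# ---------------------------------------------------------------------------


def peak_positions(peaks: pd.DataFrame) -> np.ndarray:
    """Summit position per peak (start + summit offset), midpoint fallback."""
    if "summit" in peaks.columns:
        summit = peaks["summit"].to_numpy()
        pos = peaks["start"].to_numpy() + np.where(
            summit >= 0, summit, (peaks["end"] - peaks["start"]).to_numpy() // 2
        )
    else:
        pos = (peaks["start"].to_numpy() + peaks["end"].to_numpy()) // 2
    return pos.astype(int)


def classify_peaks(
    peaks: pd.DataFrame,
    genes: Sequence[GeneModel],
    promoter_window: tuple[int, int] = (-1000, 100),
) -> tuple[np.ndarray, pd.Series]:
    """Classify each peak summit as promoter/exon/intron/intergenic.

    The promoter window is strand-aware around the TSS (default -1000/+100
    in the direction of transcription). Precedence: promoter > exon >
    intron > intergenic. Returns (per-peak class, class fractions).
    """
    chroms_seen = {g.chrom for g in genes}
    pos = peak_positions(peaks)
    classes = np.full(len(peaks), "intergenic", dtype=object)
    lo, hi = promoter_window
    for i, (chrom, x) in enumerate(zip(peaks["chrom"], pos)):
        if chrom not in chroms_seen:
            logger.warning("peak on chromosome %s absent from annotation", chrom)
            continue
        label = "intergenic"
        for g in genes:
            if g.chrom != chrom:
                continue
            if g.strand == "+":
                prom = (g.tss + lo, g.tss + hi)
            else:
                prom = (g.tss - hi + 1, g.tss - lo + 1)
            if prom[0] <= x < prom[1]:
                label = "promoter"
                break
            if g.start <= x < g.end:
                inside_exon = any(s <= x < e for s, e in g.exons)
                label = "exon" if inside_exon else "intron"
                # keep scanning: another gene's promoter could still win
        classes[i] = label
    fractions = pd.Series(classes).value_counts(normalize=True)
    fractions = fractions.reindex(["promoter", "exon", "intron", "intergenic"], fill_value=0.0)
    return classes, fractions


def top_peaks(peaks: pd.DataFrame, n: int = 2000) -> pd.DataFrame:
    """The n highest-score peaks; ties break by (chrom, start)."""
    if n > len(peaks):
        logger.warning("requested %d peaks but only %d available", n, len(peaks))
        n = len(peaks)
    out = peaks.sort_values(
        ["score", "chrom", "start"], ascending=[False, True, True], kind="mergesort"
    )
    return out.head(n).reset_index(drop=True)


# ---------------------------------------------------------------------------
# TSS meta-profile
# ---------------------------------------------------------------------------


def tss_profile(
    fragments: pd.DataFrame,
    genes: Sequence[GeneModel],
    window: int = 3000,
    binsize: int = 50,
) -> pd.DataFrame:
    """Aggregate fragment-midpoint density around TSSs, strand-oriented.

    Midpoints are mapped to TSS-relative coordinates (negated on the minus
    strand so upstream is negative for every gene), binned, summed over
    genes, and normalized so the outermost 10% of bins average 1. Returns a
    frame with bin centers and density; the central enrichment ratio
    (center bin over edge mean) is stored in ``.attrs``.
    """
    mids = ((fragments["start"].to_numpy() + fragments["end"].to_numpy()) // 2).astype(int)
    frag_chrom = fragments["chrom"].to_numpy()
    edges = np.arange(-window, window + binsize, binsize)
    counts = np.zeros(len(edges) - 1)
    by_chrom = {}
    for c in np.unique(frag_chrom):
        sel = frag_chrom == c
        m = np.sort(mids[sel])
        by_chrom[c] = m
    for g in genes:
        m = by_chrom.get(g.chrom)
        if m is None:
            continue
        lo = np.searchsorted(m, g.tss - window)
        hi = np.searchsorted(m, g.tss + window + 1)
        rel = m[lo:hi] - g.tss
        if g.strand == "-":
            rel = -rel
        counts += np.histogram(rel, bins=edges)[0]
    if counts.sum() == 0:
        logger.warning("no fragments in any TSS window; flat zero profile")
    n_edge = max(1, int(0.1 * len(counts) / 2))
    edge_mean = float(np.mean(np.concatenate([counts[:n_edge], counts[-n_edge:]])))
    density = counts / edge_mean if edge_mean > 0 else counts
    centers = (edges[:-1] + edges[1:]) / 2
    out = pd.DataFrame({"position": centers, "density": density})
    center_bin = float(density[np.argmin(np.abs(centers))])
    out.attrs["central_enrichment"] = center_bin if edge_mean > 0 else np.inf
    return out


# ---------------------------------------------------------------------------
# Accessibility-expression integration
# ---------------------------------------------------------------------------


def max_peak_per_gene(
    peaks: pd.DataFrame, genes: Sequence[GeneModel]
) -> tuple[pd.DataFrame, np.ndarray]:
    """Assign each peak to the gene with the nearest TSS; keep the max score.

    Distance is from the peak summit to the TSS; ties go to the upstream
    (smaller-coordinate) gene. Genes without any assigned peak score 0.
    Returns (per-gene table, per-peak gene assignment index).
    """
    pos = peak_positions(peaks)
    gene_ids = np.array([g.gene_id for g in genes], dtype=object)
    scores = np.zeros(len(genes))
    assignment = np.full(len(peaks), -1)
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for gi, g in enumerate(genes):
        by_chrom.setdefault(g.chrom, ([], []))
        by_chrom[g.chrom][0].append(g.tss)
        by_chrom[g.chrom][1].append(gi)
    sorted_chrom = {
        c: (np.array(t)[np.argsort(t, kind="mergesort")], np.array(i)[np.argsort(t, kind="mergesort")])
        for c, (t, i) in by_chrom.items()
    }
    for pi, (chrom, x) in enumerate(zip(peaks["chrom"], pos)):
        if chrom not in sorted_chrom:
            continue
        tss, gidx = sorted_chrom[chrom]
        j = np.searchsorted(tss, x)
        cands = [k for k in (j - 1, j) if 0 <= k < len(tss)]
        # nearest TSS; ties -> smaller coordinate (upstream gene)
        best = min(cands, key=lambda k: (abs(int(tss[k]) - int(x)), int(tss[k])))
        gi = int(gidx[best])
        assignment[pi] = gi
        scores[gi] = max(scores[gi], float(peaks["score"].iloc[pi]))
    table = pd.DataFrame({"gene": gene_ids, "max_peak_score": scores})
    return table, assignment


def accessibility_expression_association(
    gene_scores: pd.DataFrame, expression: pd.Series | dict
) -> tuple[float, float]:
    """Spearman rank correlation between per-gene peak score and expression."""
    expr = pd.Series(expression)
    merged = gene_scores.set_index("gene").join(expr.rename("expr"), how="inner").dropna()
    rho, p = stats.spearmanr(merged["max_peak_score"], merged["expr"])
    return float(rho), float(p)


# ---------------------------------------------------------------------------
# PWM scanning
# ---------------------------------------------------------------------------

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class PositionWeightMatrix:
    """Log-odds PWM over A,C,G,T vs a uniform background."""

    log_odds: np.ndarray  # width x 4

    def __post_init__(self) -> None:
        self.log_odds = np.asarray(self.log_odds, dtype=float)
        if self.log_odds.ndim != 2 or self.log_odds.shape[1] != 4:
            raise ValueError("PWM must be width x 4")
        if not np.all(np.isfinite(self.log_odds)):
            raise ValueError("PWM entries must be finite")

    @property
    def width(self) -> int:
        return self.log_odds.shape[0]

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    @classmethod
    def from_counts(cls, counts: np.ndarray, pseudocount: float = 0.5) -> "PositionWeightMatrix":
        counts = np.asarray(counts, dtype=float) + pseudocount
        probs = counts / counts.sum(axis=1, keepdims=True)
        return cls(np.log2(probs / 0.25))

    @classmethod
    def from_consensus(cls, word: str) -> "PositionWeightMatrix":
        counts = np.zeros((len(word), 4))
        for i, b in enumerate(word.upper()):
            counts[i, _BASE_INDEX[b]] = 100.0
        return cls.from_counts(counts)


def _encode(sequence: str, n_neutral: bool) -> np.ndarray:
    seq = np.frombuffer(sequence.upper().encode(), dtype=np.uint8)
    code = np.full(seq.shape, 4, dtype=np.int8)
    for base, i in _BASE_INDEX.items():
        code[seq == ord(base)] = i
    return code


def pwm_scan(
    sequence: str,
    pwm: PositionWeightMatrix,
    threshold: float,
    n_neutral: bool = False,
) -> pd.DataFrame:
    """Scan both strands; report offsets where the log-odds score >= threshold.

    N bases contribute -inf unless ``n_neutral`` (then 0). Minus-strand hits
    are reported at the forward-strand offset of the match window.
    """
    w = pwm.width
    rows = []
    for strand, seq in (("+", sequence), ("-", sequence.translate(COMPLEMENT)[::-1])):
        code = _encode(seq, n_neutral)
        L = len(code)
        if L < w:
            continue
        lo = np.hstack([pwm.log_odds, np.full((w, 1), 0.0 if n_neutral else -np.inf)])
        windows = np.lib.stride_tricks.sliding_window_view(code, w)
        scores = lo[np.arange(w)[None, :], windows].sum(axis=1)
        hits = np.flatnonzero(scores >= threshold)
        for h in hits:
            pos = int(h) if strand == "+" else L - w - int(h)
            rows.append((pos, strand, float(scores[h])))
    return pd.DataFrame(rows, columns=["position", "strand", "score"]).sort_values(
        ["position", "strand"]
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Footprint notch detection
# ---------------------------------------------------------------------------


@dataclass
class FootprintCall:
    notch_start: int  # within-peak coordinates
    notch_end: int
    dip_depth_ratio: float  # 1 - notch mean / flank mean
    motif_position: Optional[int] = None
    motif_score: Optional[float] = None


def cut_site_coverage(
    fragments: pd.DataFrame, chrom: str, start: int, end: int, smooth: int = 5
) -> np.ndarray:
    """Per-base transposase cut-site (fragment end) counts over [start, end).

    A boxcar of width ``smooth`` (1 disables) stabilizes the sparse per-base
    signal before notch detection.
    """
    sel = fragments["chrom"] == chrom
    cuts = np.concatenate(
        [fragments.loc[sel, "start"].to_numpy(), fragments.loc[sel, "end"].to_numpy() - 1]
    )
    cuts = cuts[(cuts >= start) & (cuts < end)]
    cov = np.bincount(cuts - start, minlength=end - start).astype(float)
    if smooth > 1:
        cov = ndimage.uniform_filter1d(cov, size=smooth, mode="nearest")
    return cov


def detect_notch(
    coverage: np.ndarray,
    min_depth_ratio: float = 0.5,
    width_range: tuple[int, int] = (6, 30),
    flank: int = 20,
    pwm: Optional[PositionWeightMatrix] = None,
    sequence: Optional[str] = None,
    pwm_threshold: Optional[float] = None,
) -> list[FootprintCall]:
    """Find footprint notches: local coverage dips inside an open region.

    Candidate runs are maximal stretches below (1 - min_depth_ratio) times
    the global median; a run becomes a call when its width is inside
    ``width_range`` and every value is below (1 - min_depth_ratio) times the
    mean of the ``flank`` bases on each side. With a PWM (and sequence), a
    call additionally requires a motif match overlapping the notch.
    """
    cov = np.asarray(coverage, dtype=float)
    lo_w, hi_w = width_range
    if cov.size < hi_w + 2 * flank:
        logger.warning("region shorter than notch width + flanks; skipped")
        return []
    med = float(np.median(cov))
    if med <= 0:
        return []
    below = cov < (1.0 - min_depth_ratio) * med
    calls: list[FootprintCall] = []
    i = 0
    n = cov.size
    while i < n:
        if not below[i]:
            i += 1
            continue
        j = i
        while j < n and below[j]:
            j += 1
        width = j - i
        if lo_w <= width <= hi_w and i - flank >= 0 and j + flank <= n:
            flank_mean = float(np.mean(np.concatenate([cov[i - flank : i], cov[j : j + flank]])))
            if flank_mean > 0 and np.all(cov[i:j] < (1.0 - min_depth_ratio) * flank_mean):
                dip = 1.0 - float(np.mean(cov[i:j])) / flank_mean
                call = FootprintCall(i, j, dip)
                if pwm is not None and sequence is not None:
                    thr = pwm_threshold if pwm_threshold is not None else 0.8 * pwm.max_score
                    hits = pwm_scan(sequence, pwm, thr)
                    overlap = hits[(hits["position"] < j) & (hits["position"] + pwm.width > i)]
                    if len(overlap) == 0:
                        i = j
                        continue
                    best = overlap.loc[overlap["score"].idxmax()]
                    call.motif_position = int(best["position"])
                    call.motif_score = float(best["score"])
                calls.append(call)
        i = j
    return calls
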