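"""Synthetic multi-omic data generator.

Emulates the statistical structure of a gonadotrope (LbT2) GnRH-response
study: droplet single-cell UMI matrices for a vehicle and a treated
condition, replicate bulk RNA-seq counts sharing the same ground truth,
ATAC-seq fragments/peaks over a toy genome with nucleosomal fragment-length
periodicity and planted transcription-factor footprints, and qPCR Ct tables.

Counts follow a gamma-Poisson (negative binomial) model with
variance = mu + phi * mu^2; phi = 0 degenerates to Poisson. Every planted
effect is recorded in a ground-truth object so downstream stages can be
tested for recovery.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from lbt2kit.io import CountMatrix, GeneModel

logger = logging.getLogger("lbt2kit")

PHASES = ("G1/S", "S", "G2/M", "M", "M/G1")
CONDITIONS = ("vehicle", "gnrh")


@dataclass
class SimConfig:
    """Generative parameters for all simulators.

    Defaults emulate the study scale: ~2,000 cells per condition over 10,000
    genes at a depth giving ~4,000 detected genes per cell, 4 bulk replicates
    per condition, and an ATAC fragment model with ~200 bp nucleosomal
    periodicity.
    """

    n_genes: int = 10_000
    n_cells_per_condition: int = 2_000
    n_bulk_replicates_per_condition: int = 4
    mean_depth_per_cell: float = 12_000.0
    mean_depth_per_bulk_sample: float = 1e7
    base_mean_distribution: tuple[float, float] = (0.0, 1.5)  # log-normal (loc, scale)
    dispersion: float = 0.1  # NB phi; variance = mu + phi mu^2
    bulk_dispersion: float = 0.05
    library_size_sigma: float = 0.3  # per-cell size factor ~ lognormal(0, sigma)
    phase_fractions: tuple[float, ...] = (0.30, 0.20, 0.20, 0.15, 0.15)
    phase_marker_counts: int = 40
    phase_effect: float = 4.0  # multiplicative amplitude at the peak phase
    n_response_genes: int = 100
    response_log2fc_distribution: tuple[float, float] = (3.0, 1.0)  # |lfc| ~ N, clipped >= 1
    response_up_fraction: float = 0.85
    # ATAC toy genome
    genome_length: int = 10_000_000
    chrom: str = "chrSim"
    n_atac_genes: int = 200
    n_peaks: int = 400
    peak_width: int = 400
    peak_promoter_frac: float = 0.55
    peak_intron_frac: float = 0.25
    mean_fragments_per_peak: float = 200.0
    background_fragment_frac: float = 0.10
    nucleosome_spacing: int = 200
    subnucleosomal_fraction: float = 0.5
    nucleosomal_weights: tuple[float, float, float] = (0.6, 0.3, 0.1)
    footprint_sites: tuple = ()  # (peak index, offset within peak, width)
    # qPCR
    qpcr_baseline_ct: float = 35.0
    qpcr_noise_sd: float = 0.2
    qpcr_n_technical: int = 3
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "n_genes",
            "n_cells_per_condition",
            "n_bulk_replicates_per_condition",
            "n_atac_genes",
            "n_peaks",
            "genome_length",
            "nucleosome_spacing",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        vals = [v for v in asdict(self).values() if isinstance(v, (int, float))]
        if not np.all(np.isfinite(vals)):
            raise ValueError("non-finite parameter in SimConfig")
        fr = np.asarray(self.phase_fractions, dtype=float)
        if len(fr) != 5 or fr.min() < 0 or abs(fr.sum() - 1.0) > 1e-8:
            raise ValueError("phase_fractions must be 5 non-negative values summing to 1")
        if self.phase_effect < 1:
            raise ValueError("phase_effect must be >= 1")
        if not 0 <= self.subnucleosomal_fraction <= 1:
            raise ValueError("subnucleosomal_fraction must be in [0, 1]")
        if self.n_bulk_replicates_per_condition < 2:
            logger.warning("fewer than 2 bulk replicates: DE stage requires >= 2")


@dataclass
class GroundTruth:
    """Generative parameters actually drawn, for downstream recovery tests."""

    gene_ids: np.ndarray
    base_mean: np.ndarray  # mu_g, scaled to sum to mean cell depth
    dispersion: np.ndarray  # phi_g
    gene_lengths: np.ndarray  # bp, for bulk TPM
    phase_multipliers: np.ndarray  # genes x 5, == 1 for non-markers
    treatment_log2fc: np.ndarray  # beta_g, == 0 for non-responders
    marker_genes: dict = field(default_factory=dict)  # phase -> gene index array
    response_genes: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    cell_phase: dict = field(default_factory=dict)  # condition -> per-cell phase index
    size_factors: dict = field(default_factory=dict)  # condition -> per-cell s_c


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, phi) -> np.ndarray:
    """Negative binomial with variance mu + phi mu^2 via gamma-Poisson."""
    mean = np.asarray(mean, dtype=float)
    phi = np.broadcast_to(np.asarray(phi, dtype=float), mean.shape)
    out = np.empty(mean.shape, dtype=np.int64)
    poisson = phi == 0
    if poisson.any():
        out[poisson] = rng.poisson(mean[poisson])
    if (~poisson).any():
        shape = 1.0 / phi[~poisson]
        lam = rng.gamma(shape, mean[~poisson] / shape)
        out[~poisson] = rng.poisson(lam)
    return out


# ---------------------------------------------------------------------------
# Ground truth and single-cell counts
# ---------------------------------------------------------------------------


def draw_ground_truth(config: SimConfig, rng=None) -> GroundTruth:
    """Draw per-gene generative parameters shared by the SC and bulk stages.

    Phase markers multiply expression with a clipped-cosine profile over
    cyclic phase distance: amplitude at the marker's own phase, a shoulder at
    the two adjacent phases, nothing two phases away. Marker genes are drawn
    from the upper half of the base-mean distribution (curated phase
    signatures consist of reliably detected transcripts).
    """
    config.validate()
    rng = _rng(config.seed if rng is None else rng)
    loc, scale = config.base_mean_distribution
    base = rng.lognormal(loc, scale, config.n_genes)
    gene_ids = np.array([f"gene{i:05d}" for i in range(config.n_genes)], dtype=object)
    lengths = np.rint(rng.lognormal(np.log(2000.0), 0.6, config.n_genes)).astype(int)
    lengths = np.clip(lengths, 200, None)

    # phase markers: 5 disjoint sets from the top half of expression
    order = np.argsort(base)
    upper = order[config.n_genes // 2 :]
    n_marker = 5 * config.phase_marker_counts
    marker_pool = rng.choice(upper, size=min(n_marker, len(upper)), replace=False)
    multipliers = np.ones((config.n_genes, 5))
    marker_genes = {}
    amp = config.phase_effect
    for k, phase in enumerate(PHASES):
        idx = marker_pool[k * config.phase_marker_counts : (k + 1) * config.phase_marker_counts]
        marker_genes[phase] = np.sort(idx)
        for j in range(5):
            d = min((j - k) % 5, (k - j) % 5)  # cyclic distance
            w = max(0.0, np.cos(2 * np.pi * d / 5))
            multipliers[idx, j] = 1.0 + (amp - 1.0) * w

    # treatment responders, disjoint from markers
    non_marker = np.setdiff1d(np.arange(config.n_genes), marker_pool)
    resp = rng.choice(non_marker, size=min(config.n_response_genes, len(non_marker)), replace=False)
    beta = np.zeros(config.n_genes)
    m, s = config.response_log2fc_distribution
    mag = np.clip(rng.normal(m, s, len(resp)), 1.0, None)
    sign = np.where(rng.random(len(resp)) < config.response_up_fraction, 1.0, -1.0)
    beta[resp] = mag * sign

    base = base / base.sum() * config.mean_depth_per_cell  # mu_g sums to mean depth
    return GroundTruth(
        gene_ids=gene_ids,
        base_mean=base,
        dispersion=np.full(config.n_genes, config.dispersion),
        gene_lengths=lengths,
        phase_multipliers=multipliers,
        treatment_log2fc=beta,
        marker_genes=marker_genes,
        response_genes=np.sort(resp),
    )


def simulate_condition_counts(
    config: SimConfig,
    truth: GroundTruth,
    treated: bool,
    seed,
    condition: Optional[str] = None,
) -> CountMatrix:
    """Simulate one condition's gene x cell UMI matrix.

    Per cell: phase ~ phase_fractions, size factor s_c ~ lognormal(0, sigma),
    lambda_{g,c} = s_c mu_g m_{g,phase} 2^{beta_g I(treated)},
    counts ~ NB(lambda, phi_g).
    """
    rng = _rng(seed)
    n_cells = config.n_cells_per_condition
    phases = rng.choice(5, size=n_cells, p=np.asarray(config.phase_fractions))
    s = rng.lognormal(0.0, config.library_size_sigma, n_cells)
    mu = truth.base_mean[:, None] * truth.phase_multipliers[:, phases]
    if treated:
        mu = mu * (2.0 ** truth.treatment_log2fc)[:, None]
    mu = mu * s[None, :]
    counts = _nb_sample(rng, mu, truth.dispersion[:, None])
    condition = condition or ("gnrh" if treated else "vehicle")
    barcodes = np.array([f"{condition}-{i:05d}" for i in range(n_cells)], dtype=object)
    truth.cell_phase[condition] = phases
    truth.size_factors[condition] = s
    return CountMatrix(
        counts,
        truth.gene_ids,
        barcodes,
        unit_labels=np.full(n_cells, condition, dtype=object),
    )


def simulate_sc_counts(config: SimConfig, rng=None) -> tuple[dict, GroundTruth]:
    """Simulate UMI matrices for both conditions plus the shared ground truth."""
    ss = np.random.SeedSequence(config.seed if rng is None else rng)
    truth_seed, veh_seed, trt_seed = ss.spawn(3)
    truth = draw_ground_truth(config, np.random.default_rng(truth_seed))
    matrices = {
        "vehicle": simulate_condition_counts(config, truth, False, np.random.default_rng(veh_seed)),
        "gnrh": simulate_condition_counts(config, truth, True, np.random.default_rng(trt_seed)),
    }
    return matrices, truth


# ---------------------------------------------------------------------------
# Bulk counts
# ---------------------------------------------------------------------------


def simulate_bulk_counts(config: SimConfig, truth: GroundTruth, seed=None) -> CountMatrix:
    """Simulate replicate bulk RNA-seq counts from the shared ground truth.

    Read counts are proportional to molecule abundance times transcript
    length (read sequencing samples bases, not molecules), so bulk TPM
    recovers the molecular abundance mu_g. Cell phases are integrated out:
    the bulk expectation uses the phase-averaged multiplier.
    """
    config.validate()
    if config.mean_depth_per_bulk_sample <= 0:
        raise ValueError("bulk depth must be positive (all-zero matrix rejected)")
    rng = _rng(config.seed + 1 if seed is None else seed)
    fr = np.asarray(config.phase_fractions)
    phase_avg = truth.phase_multipliers @ fr  # per-gene mean multiplier
    cols, names, labels = [], [], []
    for cond in CONDITIONS:
        mu = truth.base_mean * phase_avg * truth.gene_lengths
        if cond == "gnrh":
            mu = mu * 2.0**truth.treatment_log2fc
        mu = mu / mu.sum() * config.mean_depth_per_bulk_sample
        for r in range(config.n_bulk_replicates_per_condition):
            cols.append(_nb_sample(rng, mu, config.bulk_dispersion))
            names.append(f"{cond}_rep{r + 1}")
            labels.append(cond)
    return CountMatrix(
        np.column_stack(cols),
        truth.gene_ids,
        np.array(names, dtype=object),
        unit_labels=np.array(labels, dtype=object),
    )


# ---------------------------------------------------------------------------
# ATAC: toy genome, peaks, fragments, footprints
# ---------------------------------------------------------------------------


@dataclass
class AtacTruth:
    """Planted structure of the simulated ATAC dataset."""

    genes: list  # GeneModel
    expressed: np.ndarray  # bool per gene
    expression_level: np.ndarray  # per gene, arbitrary units (0 for silent)
    peak_class: np.ndarray  # planted class per peak
    footprints: pd.DataFrame  # peak, notch_start, notch_end (peak-relative), motif
    peak_sequences: dict  # peak name -> sequence (only peaks with footprints)


def sample_fragment_lengths(config: SimConfig, n: int, rng) -> np.ndarray:
    """Draw fragment lengths from the subnucleosomal + nucleosomal mixture.

    Subnucleosomal: 38 + Exponential(mean 45) (short, mostly < 150 bp).
    Nucleosomal: normal components at 1x, 2x, 3x nucleosome_spacing with
    sd 0.14 x spacing and weights nucleosomal_weights.
    """
    rng = _rng(rng)
    n_sub = rng.binomial(n, config.subnucleosomal_fraction)
    sub = 38.0 + rng.exponential(45.0, n_sub)
    w = np.asarray(config.nucleosomal_weights, dtype=float)
    w = w / w.sum()
    comp = rng.choice(3, size=n - n_sub, p=w) + 1
    nuc = rng.normal(comp * config.nucleosome_spacing, 0.14 * config.nucleosome_spacing)
    lengths = np.concatenate([sub, nuc])
    rng.shuffle(lengths)
    return np.clip(np.rint(lengths), 20, 1000).astype(int)


def _place_genes(config: SimConfig, rng) -> list[GeneModel]:
    """Lay non-overlapping genes left-to-right with random gaps and exons."""
    genes = []
    pos = 5_000
    mean_gap = max(
        1_000, (config.genome_length - 20_000 * config.n_atac_genes) // (config.n_atac_genes + 1)
    )
    for i in range(config.n_atac_genes):
        pos += int(rng.integers(2_000, 2 * mean_gap))
        length = int(rng.integers(5_000, 40_000))
        if pos + length > config.genome_length - 5_000:
            break
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(3, 9))
        # partition the span into alternating exon/intron blocks
        cuts = np.sort(rng.choice(np.arange(200, length - 200), 2 * n_exons - 2, replace=False))
        bounds = np.concatenate([[0], cuts, [length]])
        exons = [
            (pos + int(bounds[2 * j]), pos + int(bounds[2 * j + 1])) for j in range(n_exons)
        ]
        genes.append(GeneModel(f"tgene{i:04d}", config.chrom, strand, pos, pos + length, exons))
        pos += length
    return genes


def simulate_atac(
    config: SimConfig, seed=None
) -> tuple[list[GeneModel], pd.DataFrame, pd.DataFrame, AtacTruth]:
    """Simulate a toy ATAC dataset: gene models, fragments (BED-like), peaks.

    Peaks are planted at promoters of an "expressed" gene subset, inside
    introns, and at intergenic sites; promoter peak scores increase with the
    gene's expression level so that accessibility-expression integration has
    signal to recover. Footprint sites deplete transposase cut sites within
    the notch and record a planted SP1-like motif in the peak sequence.
    """
    config.validate()
    rng = _rng(config.seed + 2 if seed is None else seed)
    genes = _place_genes(config, rng)
    n_genes = len(genes)
    expressed = rng.random(n_genes) < 0.5
    level = np.where(expressed, rng.lognormal(3.0, 1.0, n_genes), 0.0)

    half = config.peak_width // 2
    n_prom = int(round(config.n_peaks * config.peak_promoter_frac))
    n_intr = int(round(config.n_peaks * config.peak_intron_frac))
    n_dist = config.n_peaks - n_prom - n_intr

    peaks = []  # (start, end, summit_abs, score, planted_class)
    expressed_idx = np.flatnonzero(expressed)
    prom_genes = rng.choice(expressed_idx, size=n_prom, replace=n_prom > len(expressed_idx))
    for gi in prom_genes:
        g = genes[gi]
        summit = g.tss + int(rng.integers(-100, 50)) * (1 if g.strand == "+" else -1)
        score = 50.0 + 100.0 * np.log1p(level[gi]) + rng.normal(0, 10)
        peaks.append((summit - half, summit + half, summit, max(score, 10.0), "promoter"))

    intron_candidates = []
    for gi, g in enumerate(genes):
        for (e1s, e1e), (e2s, _) in zip(g.exons, g.exons[1:]):
            if e2s - e1e > config.peak_width + 200:
                intron_candidates.append((e1e, e2s))
    for _ in range(n_intr):
        lo, hi = intron_candidates[int(rng.integers(len(intron_candidates)))]
        summit = int(rng.integers(lo + half + 50, hi - half - 50))
        peaks.append((summit - half, summit + half, summit, 30.0 + rng.exponential(40.0), "intron"))

    # intergenic: outside gene spans and promoter windows
    spans = [(max(0, g.start - 2_000), g.end + 2_000) for g in genes]
    for _ in range(n_dist):
        for _try in range(100):
            summit = int(rng.integers(half + 1, config.genome_length - half - 1))
            if not any(s <= summit < e for s, e in spans):
                break
        peaks.append((summit - half, summit + half, summit, 20.0 + rng.exponential(30.0), "intergenic"))

    peak_df = pd.DataFrame(peaks, columns=["start", "end", "summit_abs", "score", "planted_class"])
    peak_df.insert(0, "chrom", config.chrom)
    peak_df["name"] = [f"peak{i:05d}" for i in range(len(peak_df))]
    peak_df["strand"] = "."
    peak_df["signal"] = peak_df["score"]
    peak_df["pvalue"] = peak_df["score"] / 10.0
    peak_df["qvalue"] = peak_df["score"] / 12.0
    peak_df["summit"] = peak_df["summit_abs"] - peak_df["start"]

    # footprints: notch intervals in peak-relative coordinates
    fp_rows, peak_seqs = [], {}
    motif = "GGGGCGGGGC"  # SP1-like GC box
    notches: dict[int, list[tuple[int, int]]] = {}
    for (pi, offset, width) in config.footprint_sites:
        pi = int(pi)
        notches.setdefault(pi, []).append((int(offset), int(offset) + int(width)))
        seq = "".join(rng.choice(list("ACGT"), size=config.peak_width))
        seq = seq[: int(offset)] + motif[: int(width)] + seq[int(offset) + len(motif[: int(width)]) :]
        name = peak_df["name"].iloc[pi]
        peak_seqs[name] = seq[: config.peak_width]
        fp_rows.append((name, int(offset), int(offset) + int(width), motif[: int(width)]))
    footprints = pd.DataFrame(fp_rows, columns=["peak", "notch_start", "notch_end", "motif"])

    # fragments: midpoints around summits; cut sites avoid planted notches
    frags = []
    for pi, row in peak_df.iterrows():
        n_frag = rng.poisson(config.mean_fragments_per_peak)
        lengths = sample_fragment_lengths(config, n_frag, rng)
        mids = rng.normal(row["summit_abs"], config.peak_width / 5.0, n_frag)
        starts = np.rint(mids - lengths / 2.0).astype(int)
        ends = starts + lengths
        if pi in notches:
            iv = [(row["start"] + a, row["start"] + b) for a, b in notches[pi]]
            for _ in range(40):  # resample fragments whose cut sites hit a notch
                hit = np.zeros(n_frag, dtype=bool)
                for a, b in iv:
                    hit |= ((starts >= a) & (starts < b)) | ((ends - 1 >= a) & (ends - 1 < b))
                if not hit.any():
                    break
                mids = rng.normal(row["summit_abs"], config.peak_width / 5.0, int(hit.sum()))
                starts[hit] = np.rint(mids - lengths[hit] / 2.0).astype(int)
                ends[hit] = starts[hit] + lengths[hit]
        frags.append(np.column_stack([starts, ends]))
    n_bg = rng.poisson(
        config.background_fragment_frac * config.mean_fragments_per_peak * len(peak_df)
    )
    bg_len = sample_fragment_lengths(config, n_bg, rng)
    bg_start = rng.integers(0, config.genome_length - 1000, n_bg)
    frags.append(np.column_stack([bg_start, bg_start + bg_len]))
    frag_arr = np.vstack(frags)
    frag_arr = frag_arr[frag_arr[:, 0] >= 0]
    frag_df = pd.DataFrame(frag_arr, columns=["start", "end"])
    frag_df.insert(0, "chrom", config.chrom)
    frag_df["name"] = "."
    frag_df["score"] = 0
    frag_df["strand"] = "."

    truth = AtacTruth(
        genes=genes,
        expressed=expressed,
        expression_level=level,
        peak_class=peak_df["planted_class"].to_numpy(),
        footprints=footprints,
        peak_sequences=peak_seqs,
    )
    peak_out = peak_df.drop(columns=["planted_class", "summit_abs"])
    peak_out = peak_out[
        ["chrom", "start", "end", "name", "score", "strand", "signal", "pvalue", "qvalue", "summit"]
    ]
    return genes, frag_df, peak_out, truth


# ---------------------------------------------------------------------------
# qPCR Ct tables
# ---------------------------------------------------------------------------


def simulate_qpcr_ct(
    truth: GroundTruth,
    reference_gene: str,
    genes: Optional[Sequence[str]] = None,
    n_technical: int = 3,
    noise_sd: float = 0.2,
    baseline_ct: float = 35.0,
    n_biological: int = 4,
    seed=0,
) -> pd.DataFrame:
    """Simulate a tidy Ct table (40-cycle assay, Ct capped at 40).

    Ct = baseline - log_1.93(expression) + Gaussian technical noise, where
    expression is the ground-truth phase-averaged mean with the treatment
    effect applied in the treated condition. Zero expression caps at Ct 40.
    """
    rng = _rng(seed)
    gene_list = list(genes) if genes is not None else list(truth.gene_ids[truth.response_genes][:8])
    if reference_gene not in set(truth.gene_ids):
        raise ValueError(f"reference gene {reference_gene!r} not in ground truth")
    if reference_gene not in gene_list:
        gene_list = [reference_gene] + gene_list
    idx = {g: i for i, g in enumerate(truth.gene_ids)}
    rows = []
    log_eff = np.log(1.93)
    for cond in CONDITIONS:
        for b in range(n_biological):
            sample = f"{cond}_bio{b + 1}"
            for gname in gene_list:
                gi = idx[gname]
                expr = truth.base_mean[gi]
                if cond == "gnrh":
                    expr = expr * 2.0 ** truth.treatment_log2fc[gi]
                for t in range(n_technical):
                    if expr <= 0:
                        ct = 40.0
                    else:
                        ct = baseline_ct - np.log(expr) / log_eff + rng.normal(0, noise_sd)
                        ct = min(ct, 40.0)
                    rows.append((sample, cond, gname, t + 1, round(float(ct), 4)))
    return pd.DataFrame(rows, columns=["sample", "condition", "gene", "replicate", "ct"])
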