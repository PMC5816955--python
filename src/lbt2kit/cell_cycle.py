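"""Five-phase cell-cycle scoring, cyclic ordering, and phase-conditioned
treatment-response testing.

Each cell is scored against gene sets enriched in the five cycle phases
(G1/S, S, G2/M, M, M/G1): the raw score is the mean per-gene-standardized
expression over the set, optionally refined by dropping genes poorly
correlated with their set's score; scores are then z-scored across cells
within each phase and across phases within each cell. The assigned phase is
the per-cell argmax, and cells are ordered around the cycle by grouping on
assigned phase and sorting within a phase by the next-minus-previous phase
score contrast, yielding a smooth traversal of the cycle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from lbt2kit import bulk_de
from lbt2kit.io import ExpressionMatrix

logger = logging.getLogger("lbt2kit")

PHASES = ("G1/S", "S", "G2/M", "M", "M/G1")


@dataclass
class PhaseGeneSets:
    """Ordered five-phase marker gene sets (cyclic order fixed)."""

    sets: dict  # phase -> list of gene ids

    def __post_init__(self) -> None:
        if tuple(self.sets.keys()) != PHASES:
            self.sets = {p: list(self.sets[p]) for p in PHASES}
        for p in PHASES:
            if not self.sets[p]:
                raise ValueError(f"empty gene set for phase {p}")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PhaseGeneSets":
        df = pd.read_csv(path, sep="\t", header=None, names=["phase", "gene"], comment="#")
        unknown = set(df["phase"]) - set(PHASES)
        if unknown:
            raise ValueError(f"unknown phases in gene-set file: {sorted(unknown)}")
        return cls({p: df.loc[df["phase"] == p, "gene"].tolist() for p in PHASES})

    def to_tsv(self, path: str | Path) -> None:
        rows = [(p, g) for p in PHASES for g in self.sets[p]]
        pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


@dataclass
class PhaseScoreMatrix:
    """Cells x 5 phase scores with optional assignment and progression rank."""

    cell_ids: np.ndarray
    raw: np.ndarray  # cells x 5
    normalized: np.ndarray  # cells x 5, two-step z-scored
    kept_genes: dict = field(default_factory=dict)  # phase -> genes surviving refinement
    assigned: np.ndarray | None = None  # phase index per cell
    rank: np.ndarray | None = None  # progression rank per cell (0..n-1)

    def assigned_phase_names(self) -> np.ndarray:
        return np.array([PHASES[i] for i in self.assigned], dtype=object)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.normalized, columns=list(PHASES))
        df.insert(0, "cell", self.cell_ids)
        if self.assigned is not None:
            df["phase"] = self.assigned_phase_names()
        if self.rank is not None:
            df["progression_rank"] = self.rank
        return df


def _zscore_cols(x: np.ndarray, axis: int, what: str) -> np.ndarray:
    mean = x.mean(axis=axis, keepdims=True)
    sd = x.std(axis=axis, ddof=1, keepdims=True)
    zero = sd == 0
    if zero.any():
        logger.warning("zero variance in %s; scores set to 0", what)
        sd = np.where(zero, 1.0, sd)
    return np.where(np.broadcast_to(zero, x.shape), 0.0, (x - mean) / sd)


def phase_scores(
    expr: ExpressionMatrix,
    sets: PhaseGeneSets,
    refine: bool = True,
    refine_corr_threshold: float = 0.3,
) -> PhaseScoreMatrix:
    """Score each cell against the five phase gene sets.

    ``expr`` should be on the log2(SC-TPM + 1) scale; genes are standardized
    across cells internally. Refinement keeps only genes whose expression
    correlates with their phase's raw score at or above the threshold,
    falling back to the unrefined set (with a warning) if nothing survives.
    """
    gene_index = {g: i for i, g in enumerate(expr.gene_ids)}
    z = _zscore_cols(expr.values, axis=1, what="per-gene expression")  # genes x cells
    n_cells = z.shape[1]

    raw = np.zeros((n_cells, 5))
    kept: dict = {}
    for k, phase in enumerate(PHASES):
        idx = [gene_index[g] for g in sets.sets[phase] if g in gene_index]
        if not idx:
            raise ValueError(f"no genes of phase set {phase} present in matrix")
        score = z[idx].mean(axis=0)
        if refine:
            keep = []
            for gi in idx:
                sd = z[gi].std()
                r = 0.0 if sd == 0 or score.std() == 0 else float(np.corrcoef(z[gi], score)[0, 1])
                if r >= refine_corr_threshold:
                    keep.append(gi)
            if keep:
                idx = keep
                score = z[idx].mean(axis=0)
            else:
                logger.warning("no genes survive refinement for %s; using unrefined set", phase)
        kept[phase] = [expr.gene_ids[gi] for gi in idx]
        raw[:, k] = score

    normalized = _zscore_cols(raw, axis=0, what="per-phase scores")  # across cells
    normalized = _zscore_cols(normalized, axis=1, what="within-cell scores")  # across phases
    return PhaseScoreMatrix(expr.unit_ids, raw, normalized, kept)


def assign_and_order(scores: PhaseScoreMatrix) -> PhaseScoreMatrix:
    """Assign each cell to its argmax phase and rank cells around the cycle.

    Ties break toward the earlier phase in cyclic order. Within a phase,
    cells sort ascending by (score of next phase - score of previous phase),
    so cells entering the phase precede cells leaving it.
    """
    z = scores.normalized
    assigned = np.argmax(z, axis=1)  # argmax takes the first (earlier) on ties
    n = z.shape[0]
    order_keys = np.empty(n)
    for k in range(5):
        sel = assigned == k
        order_keys[sel] = z[sel, (k + 1) % 5] - z[sel, (k - 1) % 5]
    order = np.lexsort((order_keys, assigned))
    rank = np.empty(n, dtype=int)
    rank[order] = np.arange(n)
    return PhaseScoreMatrix(scores.cell_ids, scores.raw, z, scores.kept_genes, assigned, rank)


def phase_conditioned_response(
    expr: ExpressionMatrix,
    scores: PhaseScoreMatrix,
    treatment: np.ndarray | list,
    genes: list,
    min_cells: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-phase treatment-response summary and tests for selected genes.

    The phase assignment must come from scoring the pooled (both-condition)
    cell set. For each gene, reports per phase x condition n/mean/SD of the
    supplied expression, a Kruskal-Wallis test of phase effect within each
    condition, and a Wilcoxon rank-sum test of treatment effect within each
    phase; all p-values BH-corrected jointly across genes x tests. Strata
    with fewer than ``min_cells`` cells are skipped and flagged.
    """
    if scores.assigned is None:
        raise ValueError("run assign_and_order first")
    treatment = np.asarray(treatment, dtype=object)
    if len(treatment) != expr.values.shape[1]:
        raise ValueError("treatment labels must match cells")
    conditions = pd.unique(treatment)
    if len(conditions) != 2:
        raise ValueError("exactly two treatment levels required")
    gene_index = {g: i for i, g in enumerate(expr.gene_ids)}

    summary_rows, test_rows = [], []
    for gene in genes:
        gi = gene_index[gene]
        y = expr.values[gi]
        for k, phase in enumerate(PHASES):
            for cond in conditions:
                sel = (scores.assigned == k) & (treatment == cond)
                n = int(sel.sum())
                summary_rows.append(
                    (
                        gene,
                        phase,
                        cond,
                        n,
                        float(y[sel].mean()) if n else np.nan,
                        float(y[sel].std(ddof=1)) if n > 1 else np.nan,
                        n < min_cells,
                    )
                )
        # (a) phase effect within each condition
        for cond in conditions:
            groups = [
                y[(scores.assigned == k) & (treatment == cond)]
                for k in range(5)
                if ((scores.assigned == k) & (treatment == cond)).sum() >= min_cells
            ]
            if len(groups) >= 2 and any(np.ptp(g) > 0 for g in groups):
                p = float(stats.kruskal(*groups).pvalue)
            else:
                p = np.nan
            test_rows.append((gene, "phase_effect", cond, "all", p))
        # (b) treatment effect within each phase
        for k, phase in enumerate(PHASES):
            ga = y[(scores.assigned == k) & (treatment == conditions[0])]
            gb = y[(scores.assigned == k) & (treatment == conditions[1])]
            if len(ga) >= min_cells and len(gb) >= min_cells:
                p = float(stats.mannwhitneyu(ga, gb, alternative="two-sided").pvalue)
            else:
                p = np.nan
            test_rows.append((gene, "treatment_effect", "both", phase, p))

    summary = pd.DataFrame(
        summary_rows, columns=["gene", "phase", "condition", "n", "mean", "sd", "flagged"]
    )
    tests = pd.DataFrame(test_rows, columns=["gene", "test", "condition", "phase", "p"])
    tests["q"] = bulk_de.bh_fdr(tests["p"].to_numpy())
    return summary, tests
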