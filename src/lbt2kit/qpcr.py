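"""qPCR arbitrary-unit quantification.

Expression in arbitrary units from cycle-threshold values normalized to a
reference gene (Rps11 in the assay this mirrors):

    E = 2500 * 1.93 ** (Ct_reference - Ct_gene)

The constants are fixed assay calibration values (1.93 the amplification
efficiency per cycle, 2500 the scale at delta-Ct zero). Technical replicates
are averaged on the Ct scale before the transform. Ct values at the 40-cycle
cap mark below-detection measurements.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

SCALE = 2500.0
EFFICIENCY = 1.93
CT_CAP = 40.0


def ct_to_units(ct_reference: float, ct_gene: float) -> float:
    """E = 2500 * 1.93 ** (Ct_ref - Ct_gene), in arbitrary units."""
    ct_reference = float(ct_reference)
    ct_gene = float(ct_gene)
    if not (np.isfinite(ct_reference) and np.isfinite(ct_gene)):
        raise ValueError("Ct values must be finite")
    return SCALE * EFFICIENCY ** (ct_reference - ct_gene)


def summarize_replicates(
    records: pd.DataFrame, reference_gene: str
) -> pd.DataFrame:
    """Per-sample per-gene expression from a tidy Ct table.

    ``records`` needs columns sample, gene, ct (extra columns pass through
    grouping untouched). Technical replicates are averaged on the Ct scale;
    E is computed from the mean gene Ct against the mean reference-gene Ct
    of the same sample. Samples lacking the reference are flagged with no E;
    measurements at the 40-cycle cap are flagged below detection.
    """
    needed = {"sample", "gene", "ct"}
    if not needed <= set(records.columns):
        raise ValueError(f"Ct table must have columns {sorted(needed)}")
    mean_ct = (
        records.groupby(["sample", "gene"], sort=False)["ct"].mean().rename("mean_ct").reset_index()
    )
    ref = mean_ct[mean_ct["gene"] == reference_gene].set_index("sample")["mean_ct"]
    rows = []
    for _, row in mean_ct.iterrows():
        sample, gene, ct_g = row["sample"], row["gene"], row["mean_ct"]
        if sample not in ref.index:
            rows.append((sample, gene, ct_g, np.nan, True, False))
            continue
        e = ct_to_units(ref.loc[sample], ct_g)
        rows.append((sample, gene, ct_g, e, False, ct_g >= CT_CAP))
    return pd.DataFrame(
        rows,
        columns=["sample", "gene", "mean_ct", "expression", "missing_reference", "below_detection"],
    )
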