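"""Per-experiment differential abundance: background filter, t-tests, QC.

Candidates are proteins significantly upregulated under bafilomycin A1
(lysosomal blockade): two-sample equal-variance Student's t-test on
imputed log2 intensities, two-tailed p < alpha, and positive
log2(BafA1:vehicle) fold change.  The volcano coordinates are
x = log2 fold change, y = -log10 p.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .imputation import ImputedMatrix
from .io import BAFA1, VEHICLE, ExperimentDesign


def filter_background(
    matrix: ImputedMatrix, design: ExperimentDesign, min_observed: int = 2
) -> ImputedMatrix:
    """Drop proteins never genuinely quantified above background.

    A protein is kept when at least ``min_observed`` of its values within
    a single condition group are real measurements (not imputations), in
    any experiment of the design.  Proteins whose every value is imputed
    are always removed.
    """
    if min_observed < 1:
        raise ValueError("min_observed must be >= 1")
    observed = matrix.observed_mask
    keep = pd.Series(False, index=observed.index)
    for exp in design.experiments:
        for cond in (VEHICLE, BAFA1):
            cols = design.sample_ids(exp, cond)
            keep |= observed[cols].sum(axis=1) >= min_observed
    return matrix.subset(observed.index[keep])


def ttest_volcano(
    matrix: ImputedMatrix, design: ExperimentDesign, alpha: float = 0.05
) -> pd.DataFrame:
    """Student's t-test of BafA1 vs vehicle per protein.

    Returns one row per protein with columns ``protein_id``, ``log2fc``
    (mean BafA1 - mean vehicle), ``t_stat``, ``p_value``, ``n_vehicle``,
    ``n_bafa1``, ``candidate`` and the volcano ordinate
    ``neg_log10_p``.  Imputed values participate; the test is the
    pooled-variance (equal-variance) form with
    df = n_vehicle + n_bafa1 - 2.
    """
    veh_cols = design.sample_ids(condition=VEHICLE)
    baf_cols = design.sample_ids(condition=BAFA1)
    if len(veh_cols) < 2 or len(baf_cols) < 2:
        raise ValueError("each condition needs >= 2 samples for the t-test")
    veh = matrix.values[veh_cols].to_numpy(dtype=float)
    baf = matrix.values[baf_cols].to_numpy(dtype=float)
    t_stat, p_value = stats.ttest_ind(baf, veh, axis=1, equal_var=True)
    # zero pooled variance: identical groups carry no evidence
    degenerate = ~np.isfinite(t_stat)
    t_stat = np.where(degenerate, 0.0, t_stat)
    p_value = np.where(degenerate, 1.0, p_value)
    log2fc = baf.mean(axis=1) - veh.mean(axis=1)
    out = pd.DataFrame(
        {
            "protein_id": matrix.protein_ids,
            "log2fc": log2fc,
            "t_stat": t_stat,
            "p_value": p_value,
            "n_vehicle": len(veh_cols),
            "n_bafa1": len(baf_cols),
            "neg_log10_p": -np.log10(p_value),
        }
    )
    out["candidate"] = (out["p_value"] < alpha) & (out["log2fc"] > 0)
    return out


def replicate_correlation(
    matrix: ImputedMatrix, design: ExperimentDesign
) -> dict[str, pd.DataFrame]:
    """Pearson r between replicate pairs within each condition.

    Correlations are computed over proteins genuinely observed in both
    members of a pair; pairs sharing fewer than 3 such proteins get NaN.
    Returns one symmetric sample x sample frame per condition (keys
    ``"vehicle"`` and ``"bafa1"``), unit diagonal.
    """
    out: dict[str, pd.DataFrame] = {}
    values = matrix.values
    observed = matrix.observed_mask
    for cond in (VEHICLE, BAFA1):
        cols = design.sample_ids(condition=cond)
        if len(cols) < 2:
            raise ValueError(f"condition {cond!r} needs >= 2 replicates")
        r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
        for i, a in enumerate(cols):
            for b in cols[i + 1:]:
                both = observed[a] & observed[b]
                if both.sum() < 3:
                    r.loc[a, b] = r.loc[b, a] = np.nan
                    continue
                rr = stats.pearsonr(values.loc[both, a], values.loc[both, b])
                r.loc[a, b] = r.loc[b, a] = rr.statistic
        out[cond] = r
    return out


def volcano_plot(table: pd.DataFrame, path: str, alpha: float = 0.05) -> None:
    """Scatter log2 fold change against -log10 p, candidates in red."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    cand = table["candidate"]
    ax.scatter(table.loc[~cand, "log2fc"], table.loc[~cand, "neg_log10_p"],
               s=8, c="grey", alpha=0.6)
    ax.scatter(table.loc[cand, "log2fc"], table.loc[cand, "neg_log10_p"],
               s=10, c="red")
    ax.axhline(-np.log10(alpha), ls="--", lw=0.8, c="black")
    ax.set_xlabel("log2(BafA1 : vehicle)")
    ax.set_ylabel("-log10 p")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
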