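"""Weighted Z-score (Stouffer) meta-analysis across experiments with BH FDR.

Each experiment's two-tailed p-value is converted to a signed normal
deviate, z = sign(log2fc) * Phi^-1(1 - p/2), so concordant experiments
reinforce and discordant ones cancel.  Experiments are combined with
square-root-of-sample-size weights,

    z_meta = sum_i sqrt(n_i) z_i / sqrt(sum_i n_i),

n_i being the TOTAL sample count of experiment i, and converted back to
a two-tailed p.  Benjamini-Hochberg q-values are computed across the set
of proteins detected in every experiment.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExperimentDesign

# floor before the inverse normal so p underflow cannot produce inf z
_P_FLOOR = 1e-300


def p_to_signed_z(p_two_tailed: float, direction: float) -> float:
    """Signed normal deviate of a two-tailed p, sign from the effect.

    ``direction`` is any value whose sign carries the effect direction
    (typically the log2 fold change); direction 0 yields z = 0.
    """
    if not 0.0 < p_two_tailed <= 1.0:
        raise ValueError(f"p must be in (0, 1], got {p_two_tailed}")
    z = stats.norm.isf(max(p_two_tailed, _P_FLOOR) / 2.0)
    return float(np.sign(direction) * z)


def stouffer_weighted(
    z_list: Sequence[float], n_list: Sequence[float]
) -> tuple[float, float]:
    """Combine signed z-scores with sqrt(n) weights.

    Returns (z_meta, two-tailed p_meta).  A single study passes through
    unchanged.
    """
    if len(z_list) == 0 or len(z_list) != len(n_list):
        raise ValueError("z_list and n_list must be equal-length, non-empty")
    n = np.asarray(n_list, dtype=float)
    if (n < 1).any():
        raise ValueError("sample sizes must be >= 1")
    z = np.asarray(z_list, dtype=float)
    z_meta = float(np.sum(np.sqrt(n) * z) / np.sqrt(np.sum(n)))
    p_meta = float(2.0 * stats.norm.sf(abs(z_meta)))
    return z_meta, min(p_meta, 1.0)


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Step-up BH q-values, returned in input order.

    q_i = min_{j: p_(j) >= p_(i)} p_(j) * m / rank(j), clipped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def meta_analyse(
    tables: dict[str, pd.DataFrame],
    design: ExperimentDesign,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Meta-analyse per-experiment differential tables.

    ``tables`` maps experiment id -> differential table (as produced by
    :func:`degradome.differential.ttest_volcano`).  Only proteins present
    in every experiment enter; per protein the signed z of each
    experiment is combined with that experiment's total-n weight, and BH
    correction runs across the intersection.  Returns columns
    ``protein_id``, ``z_<experiment>`` per experiment, ``z_meta``,
    ``p_meta``, ``q_value``, ``significant``.
    """
    if len(tables) < 2:
        raise ValueError("meta-analysis needs >= 2 experiments")
    exps = [e for e in design.experiments if e in tables]
    if set(exps) != set(tables):
        missing = set(tables) - set(exps)
        raise ValueError(f"experiments absent from design: {sorted(missing)}")
    shared: list[str] | None = None
    for exp in exps:
        ids = list(tables[exp]["protein_id"])
        shared = ids if shared is None else [p for p in shared if p in set(ids)]
    if not shared:
        import warnings

        warnings.warn("no protein detected in every experiment", stacklevel=2)
        cols = ["protein_id", *(f"z_{e}" for e in exps), "z_meta",
                "p_meta", "q_value", "significant"]
        return pd.DataFrame(columns=cols)
    z_cols = {}
    for exp in exps:
        t = tables[exp].set_index("protein_id").loc[shared]
        z_cols[exp] = [
            p_to_signed_z(p, fc)
            for p, fc in zip(t["p_value"], t["log2fc"])
        ]
    n_list = [design.n_per_experiment[e] for e in exps]
    z_meta = np.empty(len(shared))
    p_meta = np.empty(len(shared))
    for i in range(len(shared)):
        z_meta[i], p_meta[i] = stouffer_weighted(
            [z_cols[e][i] for e in exps], n_list
        )
    q = benjamini_hochberg(p_meta)
    out = pd.DataFrame({"protein_id": shared})
    for exp in exps:
        out[f"z_{exp}"] = z_cols[exp]
    out["z_meta"] = z_meta
    out["p_meta"] = p_meta
    out["q_value"] = q
    out["significant"] = q < fdr_threshold
    return out
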