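"""Inclusion filters, log2 transform and the proteinase-K control exclusion.

The order of operations mirrors the analysis the pipeline automates:
decoy/contaminant rows are dropped, proteins with too few MS/MS spectral
counts in either condition group are removed, surviving intensities are
log2-transformed (zeros become missing), and — after candidate calling —
proteins that also survived proteinase K in the RAPIGest detergent
control are excluded as digestion-resistant artefacts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .io import BAFA1, VEHICLE, ExperimentDesign, LfqTable


@dataclass
class IntensityMatrix:
    """Protein x sample log2 intensity matrix with an observed mask.

    ``values`` are finite wherever ``observed_mask`` is True; entries
    with mask False were not quantified and hold NaN placeholders until
    imputation fills them.
    """

    values: pd.DataFrame
    observed_mask: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.shape != self.observed_mask.shape:
            raise ValueError("values and observed_mask shapes differ")
        obs = self.observed_mask.to_numpy(dtype=bool)
        if not np.isfinite(self.values.to_numpy()[obs]).all():
            raise ValueError("non-finite value marked as observed")

    @property
    def protein_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


def remove_flagged(table: LfqTable) -> LfqTable:
    """Drop reverse-decoy, contaminant and identified-by-site-only rows."""
    keep = ~table.flags.any(axis=1)
    return table.subset(table.flags.index[keep])


def filter_spectral_counts(
    table: LfqTable,
    design: ExperimentDesign,
    min_total: int = 3,
    mode: Literal["summed", "per_replicate"] = "summed",
) -> LfqTable:
    """Keep proteins with enough MS/MS evidence in BOTH condition groups.

    In ``summed`` mode (default) a protein passes an experiment when its
    spectral counts summed over the replicates of each condition reach
    ``min_total`` (default 3, i.e. "more than two counts across the
    replicates").  ``per_replicate`` instead requires ``min_total`` in
    every single replicate.  With several experiments a protein is kept
    if it passes in at least one experiment.
    """
    if min_total < 0:
        raise ValueError("min_total must be >= 0")
    absent = [s for s in design.all_sample_ids if s not in table.msms.columns]
    if absent:
        raise KeyError(f"design sample(s) missing from table: {absent}")
    keep = pd.Series(False, index=table.msms.index)
    for exp in design.experiments:
        ok = pd.Series(True, index=table.msms.index)
        for cond in (VEHICLE, BAFA1):
            counts = table.msms[design.sample_ids(exp, cond)]
            if mode == "summed":
                ok &= counts.sum(axis=1) >= min_total
            else:
                ok &= (counts >= min_total).all(axis=1)
        keep |= ok
    return table.subset(table.msms.index[keep])


def log2_transform(table: LfqTable, design: ExperimentDesign) -> IntensityMatrix:
    """log2-transform raw LFQ intensities; zeros/NaN become missing.

    Sample columns follow the design order.  Raises on negative input.
    """
    raw = table.lfq[design.all_sample_ids].to_numpy(dtype=float)
    raw = np.nan_to_num(raw, nan=0.0)
    if (raw < 0).any():
        raise ValueError("negative LFQ intensity cannot be log-transformed")
    observed = raw > 0
    values = np.full_like(raw, np.nan)
    values[observed] = np.log2(raw[observed])
    idx = table.lfq.index
    cols = design.all_sample_ids
    return IntensityMatrix(
        values=pd.DataFrame(values, index=idx, columns=cols),
        observed_mask=pd.DataFrame(observed, index=idx, columns=cols),
    )


def exclude_protk_resistant(
    candidates: Iterable[str], rapigest_candidates: Iterable[str]
) -> set[str]:
    """Remove proteinase-K-resistant artefacts from a candidate set.

    Proteins that still resisted digestion when the RAPIGest detergent
    had dissolved all membranes cannot owe their protection to the
    autophagosomal membrane; the set difference drops them.
    """
    return set(candidates) - set(rapigest_candidates)
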