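"""Downshifted-Gaussian imputation of missing log2 LFQ intensities.

Label-free missingness is left-censored: low-abundance proteins drop out
preferentially (missing not at random).  Each missing entry is therefore
replaced by a draw from a narrowed copy of its own sample's observed
distribution shifted into the low-intensity tail: for a sample column
with observed mean m and standard deviation s, draws come from

    Normal(m - downshift * s, (width_factor * s)^2)

with ``downshift = 1.8`` and ``width_factor = 0.25`` by default (the
Perseus convention).  Imputation is per sample column; a single seeded
generator fills columns left to right, rows top to bottom, so a given
seed reproduces the matrix bit-for-bit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import IntensityMatrix


@dataclass(frozen=True)
class ImputationParams:
    """Downshift (in observed-sd units), width shrink factor and seed."""

    width_factor: float = 0.25
    downshift: float = 1.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width_factor <= 0:
            raise ValueError("width_factor must be > 0")
        if self.downshift < 0:
            raise ValueError("downshift must be >= 0")


@dataclass
class ImputedMatrix:
    """Complete log2 matrix plus the mask of entries that were imputed."""

    values: pd.DataFrame
    imputed_mask: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.shape != self.imputed_mask.shape:
            raise ValueError("values and imputed_mask shapes differ")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("imputed matrix must be fully finite")

    @property
    def observed_mask(self) -> pd.DataFrame:
        return ~self.imputed_mask

    @property
    def protein_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def subset(self, protein_ids) -> "ImputedMatrix":
        ids = list(protein_ids)
        return ImputedMatrix(
            values=self.values.loc[ids].copy(),
            imputed_mask=self.imputed_mask.loc[ids].copy(),
        )


def fit_sample_distribution(
    values: np.ndarray, observed: np.ndarray
) -> tuple[float, float]:
    """Mean and sample sd (n-1 denominator) of a column's observed values.

    Needs at least two observed values; with all values equal the sd is
    zero and downstream draws collapse to a point mass at the mean.
    """
    obs = np.asarray(values, dtype=float)[np.asarray(observed, dtype=bool)]
    if obs.size < 2:
        raise ValueError(
            "need >= 2 observed values per sample to fit its distribution; "
            "widen the observation filter"
        )
    return float(obs.mean()), float(obs.std(ddof=1))


def impute_downshifted(
    matrix: IntensityMatrix, params: ImputationParams = ImputationParams()
) -> ImputedMatrix:
    """Fill missing entries with downshifted-Gaussian draws per sample.

    Observed entries are never modified; the returned mask marks exactly
    the formerly missing entries.  Draws are not truncated.
    """
    rng = np.random.default_rng(params.seed)
    values = matrix.values.to_numpy(dtype=float).copy()
    observed = matrix.observed_mask.to_numpy(dtype=bool)
    for j in range(values.shape[1]):
        col_obs = observed[:, j]
        m, s = fit_sample_distribution(values[:, j], col_obs)
        if s == 0.0:
            warnings.warn(
                f"sample {matrix.sample_ids[j]!r}: zero observed sd, "
                "imputing a point mass",
                stacklevel=2,
            )
        n_missing = int((~col_obs).sum())
        if n_missing:
            values[~col_obs, j] = rng.normal(
                m - params.downshift * s, params.width_factor * s, n_missing
            )
    return ImputedMatrix(
        values=pd.DataFrame(
            values, index=matrix.values.index, columns=matrix.values.columns
        ),
        imputed_mask=~matrix.observed_mask.copy(),
    )
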