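import numpy as np
import pandas as pd
import pytest

from degradome.io import ExperimentDesign, LfqTable, SampleInfo


def make_table(lfq: dict, msms: dict | None = None,
               flags: pd.DataFrame | None = None) -> LfqTable:
    """Build an LfqTable from plain dicts of sample -> values."""
    lfq_df = pd.DataFrame(lfq)
    lfq_df.index = pd.Index(
        [f"P{i:03d}" for i in range(len(lfq_df))], name="protein_id"
    )
    if msms is None:
        msms_df = pd.DataFrame(0, index=lfq_df.index, columns=lfq_df.columns)
    else:
        msms_df = pd.DataFrame(msms, index=lfq_df.index).astype(int)
    if flags is None:
        flags = pd.DataFrame(
            False, index=lfq_df.index,
            columns=["reverse", "contaminant", "site_only"],
        )
    else:
        flags = flags.set_axis(lfq_df.index)
    genes = pd.Series("", index=lfq_df.index, name="gene_name")
    return LfqTable(lfq=lfq_df, msms=msms_df, flags=flags, gene_names=genes)


def make_design(n_vehicle: int = 4, n_bafa1: int = 4,
                experiment: str = "exp1") -> ExperimentDesign:
    samples = [
        SampleInfo(f"{experiment}_vehicle_{r}", "vehicle", r, experiment)
        for r in range(1, n_vehicle + 1)
    ] + [
        SampleInfo(f"{experiment}_bafa1_{r}", "bafa1", r, experiment)
        for r in range(1, n_bafa1 + 1)
    ]
    return ExperimentDesign(samples)


@pytest.fixture
def design44() -> ExperimentDesign:
    return make_design(4, 4)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
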