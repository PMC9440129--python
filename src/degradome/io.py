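"""Readers and writers for protein-group quantification tables and experiment designs.

Two tabular dialects are supported:

* ``maxquant`` — the ``proteinGroups.txt`` layout produced by MaxQuant:
  per-sample columns named ``LFQ intensity <sample>`` and
  ``MS/MS count <sample>``, with decoy/contaminant flag columns
  (``Reverse``, ``Potential contaminant``, ``Only identified by site``)
  marked by ``+``.
* ``generic`` — a flat TSV with a ``protein_id`` column, optional
  ``gene_name``, per-sample columns prefixed ``lfq_`` and ``msms_``, and
  optional boolean flag columns ``reverse``/``contaminant``/``site_only``.

The experiment design is a TSV with columns ``sample_id``, ``condition``
(``vehicle`` or ``bafa1``; ``dmso`` is accepted as an alias for
``vehicle``), ``replicate`` and ``experiment``.

An LFQ intensity of zero (or an empty/NaN cell) encodes "not quantified".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

FLAG_NAMES = ("reverse", "contaminant", "site_only")

_MAXQUANT_FLAG_COLUMNS = {
    "Reverse": "reverse",
    "Potential contaminant": "contaminant",
    "Only identified by site": "site_only",
}

_MAXQUANT_ID_COLUMNS = ("Majority protein IDs", "Protein IDs")

VEHICLE = "vehicle"
BAFA1 = "bafa1"
_CONDITION_ALIASES = {"dmso": VEHICLE, "ctrl": VEHICLE, "control": VEHICLE}


class TableFormatError(ValueError):
    """Raised when an input table violates the documented dialect."""


@dataclass
class LfqTable:
    """Per-protein LFQ intensities, spectral counts and QC flags.

    All three frames share the same index of unique protein identifiers;
    ``lfq`` and ``msms`` share sample columns.  ``lfq`` holds raw (linear)
    intensities with 0 meaning "not quantified"; ``msms`` holds MS/MS
    spectral counts; ``flags`` holds booleans for ``reverse``,
    ``contaminant`` and ``site_only``.
    """

    lfq: pd.DataFrame
    msms: pd.DataFrame
    flags: pd.DataFrame
    gene_names: pd.Series

    def __post_init__(self) -> None:
        idx = self.lfq.index
        if idx.has_duplicates:
            dupes = idx[idx.duplicated()].unique().tolist()
            raise TableFormatError(f"duplicate protein_id(s): {dupes}")
        if not (self.msms.index.equals(idx) and self.flags.index.equals(idx)):
            raise TableFormatError("lfq/msms/flags indices differ")
        # counts default to 0 for samples quantified but never fragmented
        missing = [s for s in self.lfq.columns if s not in self.msms.columns]
        for s in missing:
            self.msms[s] = 0
        self.msms = self.msms[list(self.lfq.columns)]
        if (self.lfq.fillna(0.0).to_numpy() < 0).any():
            raise TableFormatError("negative LFQ intensity")

    @property
    def protein_ids(self) -> list[str]:
        return list(self.lfq.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.lfq.columns)

    def __len__(self) -> int:
        return len(self.lfq)

    def subset(self, protein_ids: Iterable[str]) -> "LfqTable":
        """Row subset preserving the order given in ``protein_ids``."""
        ids = list(protein_ids)
        return LfqTable(
            lfq=self.lfq.loc[ids].copy(),
            msms=self.msms.loc[ids].copy(),
            flags=self.flags.loc[ids].copy(),
            gene_names=self.gene_names.loc[ids].copy(),
        )


@dataclass(frozen=True)
class SampleInfo:
    sample_id: str
    condition: str  # vehicle | bafa1
    replicate: int
    experiment: str


@dataclass
class ExperimentDesign:
    """Maps each sample to (condition, replicate, experiment).

    ``n_per_experiment`` counts all design rows of an experiment and is
    the n that weights that experiment in the meta-analysis (e.g. n = 8
    for a 4 + 4 replicate study).
    """

    samples: list[SampleInfo]
    n_per_experiment: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        if not self.samples:
            raise ValueError("experiment design has no samples")
        seen: set[str] = set()
        for s in self.samples:
            if s.sample_id in seen:
                raise ValueError(f"duplicate sample_id {s.sample_id!r} in design")
            seen.add(s.sample_id)
            if s.condition not in (VEHICLE, BAFA1):
                raise ValueError(
                    f"condition {s.condition!r} not in {{vehicle, bafa1}}"
                )
            if s.replicate < 1:
                raise ValueError("replicate numbers start at 1")
        self.n_per_experiment = {}
        for s in self.samples:
            self.n_per_experiment[s.experiment] = (
                self.n_per_experiment.get(s.experiment, 0) + 1
            )
        for exp in self.experiments:
            for cond in (VEHICLE, BAFA1):
                if len(self.sample_ids(exp, cond)) < 2:
                    raise ValueError(
                        f"experiment {exp!r} needs >= 2 {cond} samples"
                    )

    @property
    def experiments(self) -> list[str]:
        out: list[str] = []
        for s in self.samples:
            if s.experiment not in out:
                out.append(s.experiment)
        return out

    @property
    def all_sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def sample_ids(self, experiment: str | None = None,
                   condition: str | None = None) -> list[str]:
        return [
            s.sample_id
            for s in self.samples
            if (experiment is None or s.experiment == experiment)
            and (condition is None or s.condition == condition)
        ]

    def restrict(self, experiment: str) -> "ExperimentDesign":
        return ExperimentDesign(
            [s for s in self.samples if s.experiment == experiment]
        )


def read_protein_table(
    path: str | Path, dialect: Literal["maxquant", "generic"] = "maxquant"
) -> LfqTable:
    """Read a protein-group quantification table.

    In the ``maxquant`` dialect the protein identifier is the first
    semicolon-separated accession of the majority-protein-ID column.
    Empty or NaN intensity cells are read as 0 (not quantified).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if dialect == "maxquant":
        return _parse_maxquant(df)
    if dialect == "generic":
        return _parse_generic(df)
    raise ValueError(f"unknown dialect {dialect!r}")


def _to_float(col: pd.Series) -> pd.Series:
    out = pd.to_numeric(col.replace("", "0"), errors="coerce").fillna(0.0)
    return out.astype(float)


def _parse_maxquant(df: pd.DataFrame) -> LfqTable:
    id_col = next((c for c in _MAXQUANT_ID_COLUMNS if c in df.columns), None)
    lfq_cols = {c: c[len("LFQ intensity "):] for c in df.columns
                if c.startswith("LFQ intensity ")}
    missing = []
    if id_col is None:
        missing.append("Majority protein IDs")
    if not lfq_cols:
        missing.append("LFQ intensity <sample>")
    if missing:
        raise TableFormatError(f"missing required column(s): {missing}")
    protein_id = df[id_col].str.split(";").str[0]
    lfq = pd.DataFrame(
        {s: _to_float(df[c]) for c, s in lfq_cols.items()}
    )
    msms = pd.DataFrame(
        {
            s: _to_float(df[f"MS/MS count {s}"]).round().astype(int)
            for s in lfq_cols.values()
            if f"MS/MS count {s}" in df.columns
        }
    )
    flags = pd.DataFrame(index=df.index)
    for col, name in _MAXQUANT_FLAG_COLUMNS.items():
        flags[name] = (df[col] == "+") if col in df.columns else False
    genes = df["Gene names"] if "Gene names" in df.columns else pd.Series(
        "", index=df.index
    )
    for frame in (lfq, msms, flags):
        frame.index = protein_id
    genes = genes.copy()
    genes.index = protein_id
    genes.name = "gene_name"
    lfq.index.name = msms.index.name = flags.index.name = "protein_id"
    if msms.empty:
        msms = pd.DataFrame(0, index=lfq.index, columns=lfq.columns)
    return LfqTable(lfq=lfq, msms=msms, flags=flags, gene_names=genes)


def _parse_generic(df: pd.DataFrame) -> LfqTable:
    if "protein_id" not in df.columns:
        raise TableFormatError("missing required column(s): ['protein_id']")
    lfq_cols = {c: c[len("lfq_"):] for c in df.columns if c.startswith("lfq_")}
    if not lfq_cols:
        raise TableFormatError("missing required column(s): ['lfq_<sample>']")
    idx = pd.Index(df["protein_id"], name="protein_id")
    lfq = pd.DataFrame({s: _to_float(df[c]) for c, s in lfq_cols.items()})
    msms = pd.DataFrame(
        {
            s: _to_float(df[f"msms_{s}"]).round().astype(int)
            for s in lfq_cols.values()
            if f"msms_{s}" in df.columns
        }
    )
    flags = pd.DataFrame(index=df.index)
    for name in FLAG_NAMES:
        if name in df.columns:
            flags[name] = df[name].str.lower().isin(("true", "1", "+"))
        else:
            flags[name] = False
    genes = df["gene_name"] if "gene_name" in df.columns else pd.Series(
        "", index=df.index
    )
    for frame in (lfq, msms, flags):
        frame.index = idx
    genes = genes.copy()
    genes.index = idx
    genes.name = "gene_name"
    if msms.empty:
        msms = pd.DataFrame(0, index=lfq.index, columns=lfq.columns)
    return LfqTable(lfq=lfq, msms=msms, flags=flags, gene_names=genes)


def write_protein_table(table: LfqTable, path: str | Path) -> None:
    """Write an :class:`LfqTable` in the generic dialect (round-trips)."""
    out = pd.DataFrame(index=table.lfq.index)
    out["gene_name"] = table.gene_names
    for s in table.sample_ids:
        out[f"lfq_{s}"] = table.lfq[s].map(lambda v: format(v, ".17g"))
    for s in table.sample_ids:
        out[f"msms_{s}"] = table.msms[s]
    for name in FLAG_NAMES:
        out[name] = table.flags[name].map({True: "true", False: "false"})
    out.to_csv(path, sep="\t", index=True, lineterminator="\n")


def read_design(path: str | Path) -> ExperimentDesign:
    """Read an experiment design TSV and validate it."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["sample_id", "condition", "replicate", "experiment"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableFormatError(f"design missing required column(s): {missing}")
    samples = []
    for _, row in df.iterrows():
        cond = str(row["condition"]).strip().lower()
        cond = _CONDITION_ALIASES.get(cond, cond)
        samples.append(
            SampleInfo(
                sample_id=str(row["sample_id"]),
                condition=cond,
                replicate=int(row["replicate"]),
                experiment=str(row["experiment"]),
            )
        )
    return ExperimentDesign(samples)


def write_design(design: ExperimentDesign, path: str | Path) -> None:
    pd.DataFrame(
        [
            (s.sample_id, s.condition, s.replicate, s.experiment)
            for s in design.samples
        ],
        columns=["sample_id", "condition", "replicate", "experiment"],
    ).to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_results_table(rows: pd.DataFrame, path: str | Path) -> None:
    """Write a results table (differential or meta) as TSV.

    Column order is preserved as given; floats are serialised with
    full (round-trip) precision so the file re-reads to identical values.
    """
    out = rows.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].map(
                lambda v: "" if pd.isna(v) else format(v, ".17g")
            )
    out.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_results_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", float_precision="round_trip")
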