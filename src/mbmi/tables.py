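"""Tabular containers for lipidomic cohorts.

A :class:`LipidTable` bundles the samples x species concentration matrix with
the per-sample annotation (batch, sample type) and per-species metadata
(lipid class, display name) that the QC and modelling stages need.  Phenotypes
travel as a plain :class:`pandas.DataFrame` indexed by sample id.

Everything is read and written as plain tab-separated text so any stage of the
pipeline can be replaced by a hand-built fixture.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Allowed values of the per-sample ``sample_type`` annotation.
SAMPLE_TYPES = ("cohort", "PQC", "TQC", "NIST")


@dataclass
class LipidTable:
    """Samples x species lipid concentration matrix plus annotations.

    Parameters
    ----------
    data:
        Concentrations (relative, strictly positive), one row per sample and
        one column per species; the index is the sample id.
    samples:
        Per-sample annotation with columns ``batch`` and ``sample_type``,
        index-aligned with ``data``.
    species:
        Per-species metadata indexed by species id with at least a
        ``lipid_class`` column.
    """

    data: pd.DataFrame
    samples: pd.DataFrame
    species: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.species is None:
            self.species = pd.DataFrame(
                {"lipid_class": "unknown"}, index=self.data.columns
            )
        if not self.data.index.equals(self.samples.index):
            raise ValueError("data and samples must share the same index")
        missing = set(self.data.columns) - set(self.species.index)
        if missing:
            raise ValueError(f"species metadata missing for: {sorted(missing)[:5]} ...")
        bad = set(self.samples["sample_type"].unique()) - set(SAMPLE_TYPES)
        if bad:
            raise ValueError(f"unknown sample_type values: {sorted(bad)}")
        if self.samples["batch"].isna().any():
            raise ValueError("every sample must have a batch label")

    # ------------------------------------------------------------------
    @property
    def species_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return len(self.data)

    def subset(self, sample_type: str | None = None, batch=None) -> "LipidTable":
        """Return a view restricted to a sample type and/or batch."""
        mask = pd.Series(True, index=self.data.index)
        if sample_type is not None:
            mask &= self.samples["sample_type"] == sample_type
        if batch is not None:
            mask &= self.samples["batch"] == batch
        return LipidTable(
            self.data.loc[mask], self.samples.loc[mask], self.species
        )

    def cohort(self) -> "LipidTable":
        return self.subset(sample_type="cohort")

    def copy(self) -> "LipidTable":
        return LipidTable(self.data.copy(), self.samples.copy(), self.species.copy())

    # ------------------------------------------------------------------
    def validate_positive(self) -> None:
        if not np.all(self.data.to_numpy() > 0):
            bad = self.data.columns[(self.data <= 0).any(axis=0)]
            raise ValueError(
                f"non-positive concentrations in species: {list(bad[:5])}"
            )

    # ------------------------------------------------------------------
    def write(self, prefix: str | Path) -> None:
        """Write ``<prefix>.lipids.tsv`` and ``<prefix>.species.tsv``.

        The lipids table carries the sample annotation as leading columns so a
        single file round-trips the full object.
        """
        prefix = Path(prefix)
        out = pd.concat([self.samples, self.data], axis=1)
        out.to_csv(prefix.with_suffix(".lipids.tsv"), sep="\t", index_label="sample_id")
        self.species.to_csv(
            prefix.with_suffix(".species.tsv"), sep="\t", index_label="species_id"
        )

    @classmethod
    def read(cls, prefix: str | Path) -> "LipidTable":
        prefix = Path(prefix)
        raw = pd.read_csv(prefix.with_suffix(".lipids.tsv"), sep="\t", index_col="sample_id")
        species = pd.read_csv(
            prefix.with_suffix(".species.tsv"), sep="\t", index_col="species_id"
        )
        ann_cols = [c for c in ("batch", "sample_type") if c in raw.columns]
        samples = raw[ann_cols]
        data = raw.drop(columns=ann_cols)
        data.columns.name = species.index.name
        return cls(data, samples, species)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")


def write_phenotypes(phenotypes: pd.DataFrame, path: str | Path) -> None:
    phenotypes.to_csv(path, sep="\t", index_label="sample_id")
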