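"""Core in-memory containers shared across the toolkit.

Genotypes are held as reference-allele dosage matrices: each entry counts
how many copies of the reference allele an individual carries at a marker
(0, 1 or 2), with ``-1`` marking a missing call.  The marker map is a
pandas DataFrame carrying, per marker, chromosome, 1-based physical
position, genetic-map position in centimorgans, and the two alleles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = np.int8(-1)

#: required columns of a marker map
MARKER_COLUMNS = ("chrom", "pos", "cm", "ref", "alt")


@dataclass
class GenotypeMatrix:
    """Individuals x biallelic markers, coded by reference-allele dosage.

    Parameters
    ----------
    dosage : (n_individuals, n_markers) int8 array
        Reference-allele dosage in {0, 1, 2}; -1 for missing.
    samples : list of str
        Individual identifiers, one per row.
    markers : pandas.DataFrame
        Marker map with columns ``chrom, pos, cm, ref, alt`` (``pos``
        1-based).  Rows ordered by chromosome then position.
    """

    dosage: np.ndarray
    samples: list[str]
    markers: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.ndim != 2:
            raise ValueError("dosage must be 2-D (individuals x markers)")
        if self.dosage.shape[0] != len(self.samples):
            raise ValueError(
                f"{self.dosage.shape[0]} dosage rows but {len(self.samples)} samples"
            )
        if self.dosage.shape[1] != len(self.markers):
            raise ValueError(
                f"{self.dosage.shape[1]} dosage columns but {len(self.markers)} markers"
            )
        missing = [c for c in MARKER_COLUMNS if c not in self.markers.columns]
        if missing:
            raise ValueError(f"marker map lacks columns: {missing}")

    @property
    def n_individuals(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosage.shape[1]

    def row(self, sample: str) -> np.ndarray:
        return self.dosage[self.samples.index(sample)]

    def subset_markers(self, index: np.ndarray) -> "GenotypeMatrix":
        """New matrix restricted to the given marker indices (order kept)."""
        index = np.asarray(index)
        return GenotypeMatrix(
            dosage=self.dosage[:, index],
            samples=list(self.samples),
            markers=self.markers.iloc[index].reset_index(drop=True),
        )

    def subset_individuals(self, rows: np.ndarray | list[int]) -> "GenotypeMatrix":
        rows = np.asarray(rows, dtype=np.int64)
        return GenotypeMatrix(
            dosage=self.dosage[rows],
            samples=[self.samples[i] for i in rows],
            markers=self.markers,
        )

    def concat(self, other: "GenotypeMatrix") -> "GenotypeMatrix":
        """Stack two cohorts sharing a marker map."""
        if len(self.markers) != len(other.markers) or not np.array_equal(
            self.markers["pos"].to_numpy(), other.markers["pos"].to_numpy()
        ):
            raise ValueError("marker maps differ; cannot concatenate cohorts")
        return GenotypeMatrix(
            dosage=np.vstack([self.dosage, other.dosage]),
            samples=list(self.samples) + list(other.samples),
            markers=self.markers,
        )


@dataclass
class Pedigree:
    """Roles and parentage of simulated individuals."""

    records: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["id", "role", "parent1", "parent2"]
        )
    )

    def add(self, ind_id: str, role: str, parent1: str | None = None,
            parent2: str | None = None) -> None:
        self.records.loc[len(self.records)] = [ind_id, role, parent1, parent2]


def heterozygosity(dosage: np.ndarray) -> np.ndarray:
    """Per-individual fraction of heterozygous calls among non-missing."""
    dosage = np.atleast_2d(dosage)
    nonmiss = (dosage >= 0).sum(axis=1)
    het = (dosage == 1).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(nonmiss > 0, het / np.maximum(nonmiss, 1), np.nan)
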