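"""Core domain types for cross-species complex-abundance profiling.

Conventions shared by every type here:

* A missing abundance means "not detected"; it is represented as NaN and
  is never conflated with zero. A zero MS1 area is treated as not
  detected, because a detected precursor always has a positive peak area.
* Accessions are case-sensitive opaque strings. No version/isoform
  suffix stripping happens unless a caller explicitly enables it in the
  I/O layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd


class DataModelError(ValueError):
    """Raised when an input violates a domain-type invariant."""


@dataclass
class SpeciesQuantTable:
    """Protein-level quantification for one species.

    Parameters
    ----------
    species:
        Species identifier (e.g. ``"xla"``).
    peptides:
        DataFrame indexed by accession, one integer column per replicate
        (``rep1``, ``rep2``, ...): unique-peptide counts.
    abundance:
        DataFrame with identical index/columns: summed MS1 precursor
        areas, NaN where the protein was not detected in that replicate.
    """

    species: str
    peptides: pd.DataFrame
    abundance: pd.DataFrame

    def __post_init__(self) -> None:
        if self.peptides.index.has_duplicates:
            dup = self.peptides.index[self.peptides.index.duplicated()][0]
            raise DataModelError(
                f"duplicate accession {dup!r} in table for species {self.species!r}"
            )
        if list(self.peptides.index) != list(self.abundance.index):
            raise DataModelError("peptide and abundance tables must share an index")
        if self.n_replicates < 1:
            raise DataModelError("at least one replicate column is required")
        if self.peptides.shape[1] != self.abundance.shape[1]:
            raise DataModelError("replicate count must match between counts and areas")
        if (self.peptides.to_numpy() < 0).any():
            raise DataModelError("unique-peptide counts must be non-negative")
        ab = self.abundance.to_numpy(dtype=float)
        if (ab[~np.isnan(ab)] < 0).any():
            raise DataModelError("abundances must be non-negative")
        # zero area carries no detection evidence: normalize to missing
        self.abundance = self.abundance.where(self.abundance > 0)

    @property
    def n_replicates(self) -> int:
        return self.peptides.shape[1]

    @property
    def accessions(self) -> pd.Index:
        return self.peptides.index

    def __len__(self) -> int:
        return len(self.peptides)


@dataclass
class OrthologMap:
    """Many-to-one map from species-native accessions to reference accessions."""

    pairs: Mapping[str, str]

    def __post_init__(self) -> None:
        self.pairs = dict(self.pairs)

    def get(self, accession: str) -> str | None:
        return self.pairs.get(accession)

    def __len__(self) -> int:
        return len(self.pairs)

    def as_series(self) -> pd.Series:
        return pd.Series(self.pairs, name="reference_accession", dtype=object)


@dataclass
class ReferenceQuantMatrix:
    """Reference-accession x species matrix of normalized mean abundances.

    ``values`` holds NaN for (protein, species) cells with no detected
    contributing entry; the detection flag is exactly ``values.notna()``.
    """

    values: pd.DataFrame
    #: contributing detected entries per cell (homeolog merges have > 1)
    n_contributors: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        v = self.values.to_numpy(dtype=float)
        if (v[~np.isnan(v)] < 0).any():
            raise DataModelError("reference matrix values must be non-negative")

    @property
    def species(self) -> list[str]:
        return list(self.values.columns)

    @property
    def detected(self) -> pd.DataFrame:
        return self.values.notna()

    def detected_sets(self) -> dict[str, set[str]]:
        """Per-species set of detected reference accessions."""
        det = self.detected
        return {s: set(det.index[det[s]]) for s in det.columns}


@dataclass(frozen=True)
class ComplexDefinition:
    """One catalogued protein complex: id, display name, member accessions."""

    complex_id: str
    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not isinstance(self.members, frozenset):
            object.__setattr__(self, "members", frozenset(self.members))
        if len(self.members) < 1:
            raise DataModelError(f"complex {self.complex_id!r} has no members")

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class ComplexScoreMatrix:
    """Coverage-weighted complex abundance scores per species.

    Invariant: ``scores == 0`` exactly where ``coverage == 0``.
    """

    scores: pd.DataFrame
    coverage: pd.DataFrame
    names: pd.Series = field(default=None)  # type: ignore[assignment]
    sizes: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.scores.shape != self.coverage.shape:
            raise DataModelError("score and coverage matrices must align")
        if self.names is None:
            self.names = pd.Series("", index=self.scores.index, dtype=object)
        if self.sizes is None:
            self.sizes = pd.Series(0, index=self.scores.index, dtype=int)
        s = self.scores.to_numpy(dtype=float)
        c = self.coverage.to_numpy(dtype=float)
        if (s < 0).any():
            raise DataModelError("scores must be non-negative")
        if ((c < 0) | (c > 1)).any():
            raise DataModelError("coverage must lie in [0, 1]")
        if ((c == 0) != (s == 0)).any():
            raise DataModelError("score must be zero exactly where coverage is zero")


@dataclass
class ClusterAssignment:
    """Cluster labels in 1..k for a set of items."""

    labels: pd.Series
    k: int
    method: str
    seed: int | None = None

    def __post_init__(self) -> None:
        present = set(self.labels.unique())
        if not present <= set(range(1, self.k + 1)):
            raise DataModelError("labels must lie in 1..k")
        if self.method == "kmeans" and present != set(range(1, self.k + 1)):
            raise DataModelError("k-means output must use every label in 1..k")


@dataclass(frozen=True)
class DigestParams:
    """In-silico tryptic digestion settings (Proteome Ruler convention)."""

    cleave_after: tuple[str, ...] = ("K", "R")
    proline_block: bool = True
    missed_cleavages: int = 0
    min_length: int = 7
    max_length: int = 30

    def __post_init__(self) -> None:
        if self.min_length < 1 or self.min_length > self.max_length:
            raise DataModelError("require 1 <= min_length <= max_length")
        if self.missed_cleavages < 0:
            raise DataModelError("missed_cleavages must be >= 0")


@dataclass(frozen=True)
class FilterPolicy:
    """Bipartite complex-coverage filter thresholds.

    Complexes need ``min_members`` subunits; small complexes (size up to
    ``small_max_size``) must reach ``small_min_coverage`` in at least one
    species, larger ones ``large_min_coverage``.
    """

    min_members: int = 3
    small_max_size: int = 5
    small_min_coverage: float = 0.40
    large_min_coverage: float = 0.20

    def __post_init__(self) -> None:
        for c in (self.small_min_coverage, self.large_min_coverage):
            if not 0.0 <= c <= 1.0:
                raise DataModelError("coverage thresholds must lie in [0, 1]")
        if self.min_members < 1:
            raise DataModelError("min_members must be >= 1")

    def required_coverage(self, size: int) -> float:
        return self.small_min_coverage if size <= self.small_max_size else self.large_min_coverage


@dataclass
class PRMTable:
    """Targeted (PRM) peptide peak areas plus per-sample MS1 mean intensities."""

    areas: pd.DataFrame  # peptide x sample
    ms1_means: pd.Series  # per sample
    peptide_to_protein: Mapping[str, str]

    def __post_init__(self) -> None:
        self.peptide_to_protein = dict(self.peptide_to_protein)
        if (self.areas.to_numpy(dtype=float) < 0).any():
            raise DataModelError("peak areas must be non-negative")
        if list(self.ms1_means.index) != list(self.areas.columns):
            raise DataModelError("MS1 means must be indexed by the sample columns")
        missing = [p for p in self.areas.index if p not in self.peptide_to_protein]
        if missing:
            raise DataModelError(f"peptides without a protein assignment: {missing[:3]}")


def unique_items(items: Iterable[str]) -> list[str]:
    """Order-preserving deduplication."""
    seen: set[str] = set()
    out: list[str] = []
    for it in items:
        if it not in seen:
            seen.add(it)
            out.append(it)
    return out
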