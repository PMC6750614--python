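"""Proteome assembly: from per-species quant tables to a reference matrix.

The processing order mirrors a label-free cross-species workflow:

1. ``quantifiability_filter`` drops proteins with too little unique-peptide
   evidence (>= 2 unique peptides in every replicate, or >= 4 in one).
2. ``median_normalize`` puts every sample (species x replicate column) on
   a common scale: one multiplicative factor per sample so each sample's
   median detected abundance equals the grand median of per-sample medians.
3. ``collapse_to_reference`` averages detected replicates per protein and
   then averages all species-native entries that map to the same
   reference-species accession, yielding one abundance per (reference
   protein, species).

Supporting computations — pairwise fold changes, in-silico tryptic peptide
counting, and the PRM peptide-to-protein roll-up — also live here.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datatypes import (
    DataModelError,
    DigestParams,
    OrthologMap,
    PRMTable,
    ReferenceQuantMatrix,
    SpeciesQuantTable,
)

logger = logging.getLogger(__name__)

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")


def quantifiability_filter(table: SpeciesQuantTable) -> SpeciesQuantTable:
    """Keep proteins with >=2 unique peptides in every replicate, or >=4 in one.

    With a single replicate the rule degenerates to requiring >=4 unique
    peptides. The number of dropped rows is logged.
    """
    pep = table.peptides
    if table.n_replicates >= 2:
        keep = (pep >= 2).all(axis=1) | (pep >= 4).any(axis=1)
    else:
        keep = (pep >= 4).all(axis=1)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("%s: quantifiability filter dropped %d of %d proteins",
                    table.species, dropped, len(table))
    return SpeciesQuantTable(
        species=table.species,
        peptides=pep.loc[keep].copy(),
        abundance=table.abundance.loc[keep].copy(),
    )


def _sample_frames(tables: list[SpeciesQuantTable]) -> list[tuple[str, str, pd.Series]]:
    """Flatten tables into (species, replicate, abundance column) samples."""
    out = []
    for t in tables:
        for rep in t.abundance.columns:
            out.append((t.species, rep, t.abundance[rep]))
    return out


def median_normalize(tables: list[SpeciesQuantTable]) -> list[SpeciesQuantTable]:
    """Scale each sample so its median detected abundance hits the grand median.

    The grand median is the median of the per-sample medians, so the
    normalized data keeps the magnitude scale of the input. Missing cells
    stay missing.
    """
    medians: dict[tuple[str, str], float] = {}
    for species, rep, col in _sample_frames(tables):
        if col.notna().sum() == 0:
            raise DataModelError(f"sample {species}/{rep} has no detected values")
        medians[(species, rep)] = float(col.median(skipna=True))
    grand = float(np.median(list(medians.values())))
    out = []
    for t in tables:
        ab = t.abundance.copy()
        for rep in ab.columns:
            ab[rep] = ab[rep] * (grand / medians[(t.species, rep)])
        out.append(SpeciesQuantTable(species=t.species, peptides=t.peptides.copy(), abundance=ab))
    return out


def collapse_to_reference(
    tables: list[SpeciesQuantTable], omap: OrthologMap
) -> ReferenceQuantMatrix:
    """Average replicates, then average entries sharing a reference accession.

    Replicate averaging uses the detected replicates only (missing
    replicates are excluded, not zero-filled). Species-native accessions
    without an ortholog mapping are dropped with a logged count. A cell is
    detected iff at least one contributing entry was detected.
    """
    if len(omap) == 0:
        raise DataModelError("ortholog map is empty")
    mapping = omap.as_series()
    columns: dict[str, pd.Series] = {}
    contributors: dict[str, pd.Series] = {}
    for t in tables:
        per_protein = t.abundance.mean(axis=1, skipna=True)  # NaN iff never detected
        mapped_ref = mapping.reindex(per_protein.index)
        n_unmapped = int(mapped_ref.isna().sum())
        if n_unmapped:
            logger.info("%s: dropped %d unmapped accession(s)", t.species, n_unmapped)
        ok = mapped_ref.notna()
        grouped = per_protein[ok].groupby(mapped_ref[ok])
        columns[t.species] = grouped.mean()  # skips NaN entries
        contributors[t.species] = grouped.count()
        n_multi = int((contributors[t.species] > 1).sum())
        if n_multi:
            logger.info("%s: %d reference accession(s) averaged from multiple "
                        "entries (e.g. homeologs)", t.species, n_multi)
    values = pd.DataFrame(columns)
    values.index.name = "reference_accession"
    values = values.sort_index()
    n_contrib = pd.DataFrame(contributors).reindex(values.index).fillna(0).astype(int)
    return ReferenceQuantMatrix(values=values, n_contributors=n_contrib)


def pairwise_fold_changes(
    matrix: ReferenceQuantMatrix, species_a: str, species_b: str
) -> pd.DataFrame:
    """Abundance ratios A/B over proteins detected in both species.

    Returns a DataFrame with columns ``ratio`` and ``log2_ratio`` indexed
    by reference accession; proteins missing in either species are absent.
    """
    for sp in (species_a, species_b):
        if sp not in matrix.values.columns:
            raise DataModelError(f"species {sp!r} not present in the matrix")
    a = matrix.values[species_a]
    b = matrix.values[species_b]
    both = a.notna() & b.notna()
    ratio = (a[both] / b[both]).rename("ratio")
    out = ratio.to_frame()
    out["log2_ratio"] = np.log2(out["ratio"])
    return out


def enriched_at(fold_changes: pd.DataFrame, threshold: float = 1.5) -> pd.Series:
    """Boolean flag: ratio at or above the enrichment threshold."""
    return fold_changes["ratio"] >= threshold


def tryptic_fragments(sequence: str, params: DigestParams = DigestParams()) -> list[str]:
    """All digestion fragments (before length filtering).

    Cleavage occurs after each residue in ``params.cleave_after`` (K/R for
    trypsin), suppressed before proline when the proline block is on.
    With ``missed_cleavages`` = m, every run of up to m+1 consecutive
    fully-cleaved fragments is also emitted.
    """
    seq = sequence.upper().rstrip("*")
    bad = set(seq) - AMINO_ACIDS
    if bad:
        raise DataModelError(f"non-amino-acid character(s) {sorted(bad)} in sequence")
    cleave = set(params.cleave_after)
    pieces: list[str] = []
    start = 0
    for i, aa in enumerate(seq):
        if aa in cleave and not (
            params.proline_block and i + 1 < len(seq) and seq[i + 1] == "P"
        ):
            pieces.append(seq[start : i + 1])
            start = i + 1
    if start < len(seq):
        pieces.append(seq[start:])
    if params.missed_cleavages == 0:
        return pieces
    out: list[str] = []
    for i in range(len(pieces)):
        for m in range(params.missed_cleavages + 1):
            if i + m < len(pieces):
                out.append("".join(pieces[i : i + m + 1]))
    return out


def theoretical_tryptic_peptides(
    sequence: str, params: DigestParams = DigestParams()
) -> int:
    """Count theoretical tryptic peptides with length within the bounds."""
    return sum(
        params.min_length <= len(p) <= params.max_length
        for p in tryptic_fragments(sequence, params)
    )


def prm_rollup(prm: PRMTable) -> pd.DataFrame:
    """Roll PRM peptide peak areas up to protein x sample values.

    1. Each peptide area is divided by its sample's mean MS1 intensity.
    2. Each peptide's normalized values are scaled to that peptide's mean
       across all runs (so every peptide averages 1 across samples).
    3. The protein value per sample is the mean of its peptides' scaled
       values.

    Peptides that are zero in every sample carry no signal and are
    excluded with a warning.
    """
    if (prm.ms1_means <= 0).any():
        raise DataModelError("per-sample MS1 mean intensities must be positive")
    normalized = prm.areas.div(prm.ms1_means, axis=1)
    all_zero = (normalized == 0).all(axis=1)
    if all_zero.any():
        logger.warning("excluding %d peptide(s) with zero area in every sample",
                       int(all_zero.sum()))
        normalized = normalized.loc[~all_zero]
    scaled = normalized.div(normalized.mean(axis=1), axis=0)
    protein = pd.Series(
        [prm.peptide_to_protein[p] for p in scaled.index], index=scaled.index
    )
    rolled = scaled.groupby(protein).mean()
    rolled.index.name = "protein"
    return rolled


def scaled_peptide_values(prm: PRMTable) -> pd.DataFrame:
    """Peptide x sample values after the two PRM normalization steps."""
    normalized = prm.areas.div(prm.ms1_means, axis=1)
    normalized = normalized.loc[~(normalized == 0).all(axis=1)]
    return normalized.div(normalized.mean(axis=1), axis=0)
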