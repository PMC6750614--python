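"""Complex-level inference from the cross-species reference matrix.

A catalogued complex is considered observable when enough of its subunits
are detected: complexes need at least three members, small complexes
(up to five members) must reach 40% subunit coverage in at least one
species, and larger complexes 20%. For each species the complex then
receives a coverage-weighted abundance score,

    score(c, s) = mean(abundance of detected members of c in s) * coverage(c, s)

where coverage is the detected fraction of the complex's full catalogued
membership. The score is zero exactly when no member is detected. The
module also extracts the conserved subset (coefficient of variation of
the per-species scores below a threshold) and expands a binary PPI graph
into candidate complexes via maximal-clique enumeration.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import (
    ComplexDefinition,
    ComplexScoreMatrix,
    FilterPolicy,
    ReferenceQuantMatrix,
)


def compute_coverage(
    complex_def: ComplexDefinition, detected: dict[str, set[str]]
) -> dict[str, float]:
    """Detected fraction of the complex's catalogued members, per species.

    The denominator is always the full database membership, including
    subunits never seen in any species.
    """
    n = complex_def.size
    return {
        species: len(complex_def.members & det) / n for species, det in detected.items()
    }


@dataclass(frozen=True)
class FilterRecord:
    """One row of the complex-filter report."""

    complex_id: str
    size: int
    best_coverage: float
    passed: bool
    reason: str


def filter_complexes(
    db: list[ComplexDefinition],
    detected: dict[str, set[str]],
    policy: FilterPolicy = FilterPolicy(),
) -> tuple[list[ComplexDefinition], list[FilterRecord]]:
    """Apply the size and bipartite coverage filters.

    Complexes below ``policy.min_members`` are removed outright; the rest
    must reach the size-dependent coverage threshold in at least one
    species. Returns the passing complexes and a per-complex report.
    """
    passing: list[ComplexDefinition] = []
    report: list[FilterRecord] = []
    for c in db:
        coverage = compute_coverage(c, detected)
        best = max(coverage.values()) if coverage else 0.0
        if c.size < policy.min_members:
            rec = FilterRecord(c.complex_id, c.size, best, False,
                               f"fewer than {policy.min_members} members")
        else:
            needed = policy.required_coverage(c.size)
            if best >= needed:
                rec = FilterRecord(c.complex_id, c.size, best, True, "passed")
            else:
                rec = FilterRecord(c.complex_id, c.size, best, False,
                                   f"best coverage {best:.3f} < {needed:.2f}")
        report.append(rec)
        if rec.passed:
            passing.append(c)
    return passing, report


def score_complex(
    complex_def: ComplexDefinition, matrix: ReferenceQuantMatrix
) -> dict[str, float]:
    """Coverage-weighted mean abundance of the complex, per species.

    ``mean`` runs over the members detected in that species ("quantified
    components"); the weight is the coverage against the full membership.
    A species detecting no member scores exactly zero.
    """
    members = sorted(complex_def.members)
    present = [m for m in members if m in matrix.values.index]
    sub = matrix.values.reindex(present)
    out: dict[str, float] = {}
    for species in matrix.species:
        vals = sub[species].dropna() if present else pd.Series(dtype=float)
        if len(vals) == 0:
            out[species] = 0.0
        else:
            out[species] = float(vals.mean()) * (len(vals) / complex_def.size)
    return out


def build_score_matrix(
    db_passing: list[ComplexDefinition], matrix: ReferenceQuantMatrix
) -> ComplexScoreMatrix:
    """Score every passing complex in every species."""
    detected = matrix.detected_sets()
    species = matrix.species
    scores = np.zeros((len(db_passing), len(species)))
    coverage = np.zeros_like(scores)
    for i, c in enumerate(db_passing):
        s = score_complex(c, matrix)
        cov = compute_coverage(c, detected)
        for j, sp in enumerate(species):
            scores[i, j] = s[sp]
            coverage[i, j] = cov[sp]
    idx = pd.Index([c.complex_id for c in db_passing], name="complex_id")
    return ComplexScoreMatrix(
        scores=pd.DataFrame(scores, index=idx, columns=species),
        coverage=pd.DataFrame(coverage, index=idx, columns=species),
        names=pd.Series([c.name for c in db_passing], index=idx),
        sizes=pd.Series([c.size for c in db_passing], index=idx),
    )


def low_variance_complexes(
    scores: ComplexScoreMatrix, threshold: float = 0.20
) -> pd.Index:
    """Complexes whose per-species scores vary less than ``threshold`` (CV).

    CV = population standard deviation / mean of the per-species scores.
    Complexes with zero coverage in any species are excluded up front;
    an all-zero score vector is excluded rather than an error.
    """
    if scores.scores.shape[1] < 2:
        raise ValueError("need at least two species for a variance filter")
    full = (scores.coverage > 0).all(axis=1)
    sub = scores.scores.loc[full]
    mean = sub.mean(axis=1)
    ok = mean > 0
    cv = sub.loc[ok].std(axis=1, ddof=0) / mean[ok]
    return cv.index[cv < threshold]


def expand_ppi_to_complexes(
    graph: nx.Graph, min_size: int = 3, id_prefix: str = "PPI"
) -> list[ComplexDefinition]:
    """All maximal cliques of size >= ``min_size``, as candidate complexes.

    Output order is deterministic: cliques sorted by their sorted member
    tuples; ids are ``{prefix}_{i}`` in that order.
    """
    cliques = sorted(
        tuple(sorted(c)) for c in nx.find_cliques(graph) if len(c) >= min_size
    )
    return [
        ComplexDefinition(
            complex_id=f"{id_prefix}_{i + 1}",
            name="/".join(members),
            members=frozenset(members),
        )
        for i, members in enumerate(cliques)
    ]


def filter_report_frame(report: list[FilterRecord]) -> pd.DataFrame:
    """Filter report as a DataFrame, for TSV export."""
    return pd.DataFrame(
        [
            {
                "complex_id": r.complex_id,
                "size": r.size,
                "best_coverage": r.best_coverage,
                "passed": r.passed,
                "reason": r.reason,
            }
            for r in report
        ]
    )
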