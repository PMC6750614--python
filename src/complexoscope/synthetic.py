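"""Synthetic multi-species proteomes with known ground truth.

The generator emulates the design of a four-vertebrate cardiac proteome
comparison: four species measured in biological duplicate by label-free
MS1 quantification, with

* species-enrichment *archetypes* — each reference protein follows one
  abundance pattern across species (enriched in one species, shared
  between the mammals, or uniform),
* log-normal replicate noise around the archetype expectation,
* per-cell missingness (a protein simply not detected in one sample),
* homeolog (".L"/".S") duplication for a configurable fraction of
  proteins in one designated allotetraploid species, both copies mapping
  to the same reference accession,
* unique-peptide counts drawn so a configurable fraction of rows fails
  the quantifiability rule,
* planted complexes whose members share an archetype (so their score
  profiles inherit that archetype), optionally salted with decoy members
  that are never expressed, and
* a PPI graph of planted cliques over a sparse random background.

All randomness flows from one integer seed through deterministic
per-table substreams, so fixtures are bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import (
    ComplexDefinition,
    DataModelError,
    OrthologMap,
    SpeciesQuantTable,
)
from . import io as cio

DEFAULT_SPECIES = ("mmu", "ssc", "xtr", "xla")

AA = "ACDEFGHIKLMNPQRSTVWY"


def default_archetypes(species: tuple[str, ...], fold: float = 5.0) -> dict[str, tuple[float, ...]]:
    """One enriched archetype per species, a mammal-shared one, and a uniform one."""
    n = len(species)
    arch: dict[str, tuple[float, ...]] = {}
    for i, sp in enumerate(species):
        arch[f"{sp}_enriched"] = tuple(fold if j == i else 1.0 for j in range(n))
    if n >= 4:
        arch["mammal_shared"] = tuple(fold if j < 2 else 1.0 for j in range(n))
    arch["uniform"] = tuple(1.0 for _ in range(n))
    return arch


@dataclass
class SyntheticConfig:
    """Study-design parameters for the synthetic generator."""

    seed: int = 0
    species: tuple[str, ...] = DEFAULT_SPECIES
    n_replicates: int = 2
    n_reference_proteins: int = 600
    archetypes: dict[str, tuple[float, ...]] = field(default_factory=dict)
    enrichment_fold: float = 5.0
    base_median: float = 1e6
    base_sigma: float = 1.0
    noise_sigma: float = 0.1
    missingness: float = 0.1
    allotetraploid: str = "xla"
    homeolog_fraction: float = 0.4
    unquantifiable_fraction: float = 0.1
    n_complexes: int = 60
    complex_size_range: tuple[int, int] = (3, 8)
    decoy_fraction: float = 0.0
    n_planted_cliques: int = 8
    clique_size_range: tuple[int, int] = (3, 6)
    background_density: float = 0.01

    def __post_init__(self) -> None:
        if not self.archetypes:
            self.archetypes = default_archetypes(self.species, self.enrichment_fold)
        for name, mult in self.archetypes.items():
            if len(mult) != len(self.species):
                raise DataModelError(f"archetype {name!r}: need one multiplier per species")
            if any(m <= 0 for m in mult):
                raise DataModelError(f"archetype {name!r}: multipliers must be positive")
        for p in (self.missingness, self.homeolog_fraction,
                  self.unquantifiable_fraction, self.decoy_fraction,
                  self.background_density):
            if not 0.0 <= p <= 1.0:
                raise DataModelError("probabilities must lie in [0, 1]")
        if self.noise_sigma < 0 or self.base_sigma < 0:
            raise DataModelError("sigma must be >= 0")
        if self.complex_size_range[0] < 3:
            raise DataModelError("planted complexes need at least 3 members")
        if self.clique_size_range[0] < 3:
            raise DataModelError("planted cliques need at least 3 members")
        if self.allotetraploid not in self.species:
            raise DataModelError(f"allotetraploid {self.allotetraploid!r} not in species")

    def _rng(self, stream: str) -> np.random.Generator:
        """Deterministic substream derived from the global seed and a label."""
        label = int.from_bytes(stream.encode(), "big") % (2**31)
        return np.random.default_rng(np.random.SeedSequence(entropy=self.seed, spawn_key=(label,)))


@dataclass
class ProteomeTruth:
    """Ground truth underlying one generated multi-species proteome."""

    archetype: pd.Series          # reference accession -> archetype name
    base_abundance: pd.Series     # reference accession -> base abundance
    expected: pd.DataFrame        # reference accession x species expectation
    homeolog: pd.Series           # reference accession -> duplicated in allotetraploid?
    quantifiable: dict[str, pd.Series]  # species -> native accession -> passes rule


def generate_multispecies_proteome(
    config: SyntheticConfig,
) -> tuple[dict[str, SpeciesQuantTable], OrthologMap, ProteomeTruth]:
    """Generate per-species quant tables, the ortholog map, and the truth."""
    rng = config._rng("proteome")
    n = config.n_reference_proteins
    refs = [f"REF{i:05d}" for i in range(1, n + 1)]
    arch_names = list(config.archetypes)
    archetype = pd.Series(rng.choice(arch_names, size=n), index=refs, name="archetype")
    base = pd.Series(
        config.base_median * np.exp(rng.normal(0.0, config.base_sigma, size=n)),
        index=refs, name="base_abundance",
    )
    mult = pd.DataFrame(
        [config.archetypes[a] for a in archetype], index=refs, columns=list(config.species)
    )
    expected = mult.mul(base, axis=0)
    homeolog = pd.Series(
        rng.random(n) < config.homeolog_fraction, index=refs, name="homeolog"
    )

    tables: dict[str, SpeciesQuantTable] = {}
    pairs: dict[str, str] = {}
    quantifiable: dict[str, pd.Series] = {}
    for sp in config.species:
        rng_sp = config._rng(f"species:{sp}")
        native: list[str] = []
        native_ref: list[str] = []
        for ref in refs:
            if sp == config.allotetraploid and homeolog[ref]:
                for copy in (".L", ".S"):
                    native.append(f"{ref}_{sp}{copy}")
                    native_ref.append(ref)
            else:
                native.append(f"{ref}_{sp}")
                native_ref.append(ref)
        m = len(native)
        exp = expected.loc[native_ref, sp].to_numpy()
        if config.noise_sigma > 0:
            noise = np.exp(rng_sp.normal(0.0, config.noise_sigma, size=(m, config.n_replicates)))
        else:
            noise = np.ones((m, config.n_replicates))
        ab = exp[:, None] * noise
        if config.missingness > 0:
            ab[rng_sp.random((m, config.n_replicates)) < config.missingness] = np.nan
        fails = rng_sp.random(m) < config.unquantifiable_fraction
        pep = 2 + rng_sp.poisson(4.0, size=(m, config.n_replicates))
        # failing rows: every replicate <= 1 unique peptide, so neither clause holds
        pep[fails] = np.minimum(rng_sp.poisson(0.8, size=(int(fails.sum()), config.n_replicates)), 1)
        cols = [f"rep{i + 1}" for i in range(config.n_replicates)]
        idx = pd.Index(native, name="accession")
        tables[sp] = SpeciesQuantTable(
            species=sp,
            peptides=pd.DataFrame(pep, index=idx, columns=cols),
            abundance=pd.DataFrame(ab, index=idx, columns=cols),
        )
        for acc, ref in zip(native, native_ref):
            pairs[acc] = ref
        quantifiable[sp] = pd.Series(~fails, index=idx, name="quantifiable")

    truth = ProteomeTruth(
        archetype=archetype,
        base_abundance=base,
        expected=expected,
        homeolog=homeolog,
        quantifiable=quantifiable,
    )
    return tables, OrthologMap(pairs), truth


def generate_complex_db(
    config: SyntheticConfig, truth: ProteomeTruth
) -> tuple[list[ComplexDefinition], pd.Series]:
    """Planted complexes drawing members from a single archetype each.

    A ``decoy_fraction`` of each complex's nominal size is added as decoy
    members that are never expressed, exercising the coverage filter.
    Returns the complexes and a truth series complex_id -> archetype.
    """
    rng = config._rng("complexes")
    by_arch = {a: list(idx) for a, idx in truth.archetype.groupby(truth.archetype).groups.items()}
    arch_names = sorted(by_arch)
    lo, hi = config.complex_size_range
    complexes: list[ComplexDefinition] = []
    arch_of: dict[str, str] = {}
    n_decoys = 0
    for i in range(config.n_complexes):
        arch = arch_names[i % len(arch_names)]
        size = int(rng.integers(lo, hi + 1))
        pool = by_arch[arch]
        n_real = max(1, round(size * (1 - config.decoy_fraction)))
        if n_real > len(pool):
            raise DataModelError(
                f"complex size {n_real} exceeds the {len(pool)} proteins of archetype {arch!r}"
            )
        members = set(rng.choice(pool, size=n_real, replace=False))
        for _ in range(size - n_real):
            n_decoys += 1
            members.add(f"DECOY{n_decoys:04d}")
        cid = f"CPX{i + 1:04d}"
        complexes.append(
            ComplexDefinition(complex_id=cid, name=f"planted {arch} complex {i + 1}",
                              members=frozenset(members))
        )
        arch_of[cid] = arch
    return complexes, pd.Series(arch_of, name="archetype")


def generate_ppi_graph(
    config: SyntheticConfig,
) -> tuple[nx.Graph, list[frozenset[str]]]:
    """Union of planted cliques and Erdős–Rényi background edges.

    Cliques are vertex-disjoint over the reference accessions; background
    edges are sampled at ``background_density`` over all accessions.
    """
    rng = config._rng("ppi")
    lo, hi = config.clique_size_range
    refs = [f"REF{i:05d}" for i in range(1, config.n_reference_proteins + 1)]
    graph: nx.Graph = nx.Graph()
    graph.add_nodes_from(refs)
    available = list(refs)
    planted: list[frozenset[str]] = []
    for _ in range(config.n_planted_cliques):
        size = int(rng.integers(lo, hi + 1))
        if size > len(available):
            raise DataModelError("not enough proteins left to plant another clique")
        pick_idx = rng.choice(len(available), size=size, replace=False)
        members = [available[j] for j in sorted(pick_idx)]
        for j in sorted(pick_idx, reverse=True):
            del available[j]
        planted.append(frozenset(members))
        for a_i in range(size):
            for b_i in range(a_i + 1, size):
                graph.add_edge(members[a_i], members[b_i])
    if config.background_density > 0:
        n = len(refs)
        iu = np.triu_indices(n, k=1)
        mask = rng.random(len(iu[0])) < config.background_density
        for a_i, b_i in zip(iu[0][mask], iu[1][mask]):
            graph.add_edge(refs[a_i], refs[b_i])
    return graph, planted


def generate_fasta(config: SyntheticConfig, accessions: list[str]) -> dict[str, str]:
    """Random protein sequences (log-normal lengths around ~300 aa)."""
    rng = config._rng("fasta")
    out: dict[str, str] = {}
    for acc in accessions:
        length = max(30, int(np.exp(rng.normal(np.log(300.0), 0.4))))
        out[acc] = "".join(rng.choice(list(AA), size=length))
    return out


def write_fixture_dir(config: SyntheticConfig, outdir: str | Path) -> Path:
    """Write a complete fixture: quant tables, map, complex DB, PPI, FASTA, truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables, omap, truth = generate_multispecies_proteome(config)
    complexes, complex_truth = generate_complex_db(config, truth)
    graph, planted = generate_ppi_graph(config)
    for sp, table in tables.items():
        cio.write_quant_table(table, outdir / f"quant_{sp}.tsv")
    cio.write_ortholog_map(omap, outdir / "ortholog_map.tsv")
    cio.write_complex_db(complexes, outdir / "complex_db.tsv")
    cio.write_ppi_edges(graph, outdir / "ppi_edges.tsv")
    native = sorted(omap.pairs)
    cio.write_fasta(generate_fasta(config, native), outdir / "proteins.fasta")
    truth_blob = {
        "seed": config.seed,
        "species": list(config.species),
        "archetype": truth.archetype.to_dict(),
        "base_abundance": truth.base_abundance.to_dict(),
        "homeolog": {k: bool(v) for k, v in truth.homeolog.items()},
        "quantifiable": {sp: {k: bool(v) for k, v in s.items()}
                         for sp, s in truth.quantifiable.items()},
        "complex_archetype": complex_truth.to_dict(),
        "planted_cliques": [sorted(c) for c in planted],
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth_blob, fh, indent=2)
        fh.write("\n")
    return outdir
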