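import numpy as np
import pandas as pd
import pytest

from complexoscope import (
    DigestParams,
    OrthologMap,
    PRMTable,
    collapse_to_reference,
    enriched_at,
    median_normalize,
    pairwise_fold_changes,
    prm_rollup,
    quantifiability_filter,
    theoretical_tryptic_peptides,
)
from complexoscope.assembly import scaled_peptide_values, tryptic_fragments
from complexoscope.datatypes import DataModelError

from conftest import make_quant_table


def brute_force_digest_count(seq, params):
    """Independent position-by-position splitter used as the digest oracle."""
    sites = [i + 1 for i, aa in enumerate(seq[:-1])
             if aa in params.cleave_after
             and not (params.proline_block and seq[i + 1] == "P")]
    if seq and seq[-1] in params.cleave_after:
        sites.append(len(seq))
    bounds = [0] + [s for s in sites if s < len(seq)] + [len(seq)]
    count = 0
    for i in range(len(bounds) - 1):
        for j in range(i + 1, min(i + 2 + params.missed_cleavages, len(bounds))):
            n = bounds[j] - bounds[i]
            if params.min_length <= n <= params.max_length:
                count += 1
    return count


class TestQuantifiabilityFilter:
    @pytest.mark.parametrize(
        "counts,kept",
        [
            ((2, 2), True),   # two unique peptides in both replicates
            ((4, 0), True),   # four unique peptides in one replicate
            ((3, 1), False),  # fails both clauses
            ((0, 5), True),
            ((2, 1), False),
            ((1, 1), False),
        ],
    )
    def test_two_replicate_rule(self, counts, kept):
        t = make_quant_table("sp", {"P1": (10.0, 10.0)}, peptides={"P1": counts})
        assert (len(quantifiability_filter(t)) == 1) is kept

    def test_single_replicate_requires_four(self):
        t = make_quant_table("sp", {"P1": (10.0,), "P2": (10.0,)},
                             peptides={"P1": (4,), "P2": (3,)})
        kept = quantifiability_filter(t)
        assert list(kept.accessions) == ["P1"]


class TestMedianNormalize:
    def test_forced_arithmetic_example(self):
        # sample medians 4 and 2; grand median 3 -> factors 0.75 and 1.5
        t1 = make_quant_table("a", {"P1": (2.0,), "P2": (4.0,), "P3": (6.0,)})
        t2 = make_quant_table("b", {"P1": (1.0,), "P2": (2.0,), "P3": (3.0,)})
        n1, n2 = median_normalize([t1, t2])
        assert list(n1.abundance["rep1"]) == [1.5, 3.0, 4.5]
        assert list(n2.abundance["rep1"]) == [1.5, 3.0, 4.5]
        assert n1.abundance["rep1"].median() == n2.abundance["rep1"].median() == 3.0

    def test_single_sample_unchanged(self):
        t = make_quant_table("a", {"P1": (2.0,), "P2": (8.0,)})
        (n,) = median_normalize([t])
        pd.testing.assert_frame_equal(n.abundance, t.abundance)

    def test_medians_agree_after_normalization(self, rng):
        tables = [
            make_quant_table(f"s{i}", {f"P{j}": tuple(rng.lognormal(10, 1, 2))
                                       for j in range(25)})
            for i in range(4)
        ]
        normalized = median_normalize(tables)
        medians = [t.abundance[c].median() for t in normalized for c in t.abundance]
        assert np.allclose(medians, medians[0], rtol=1e-12)

    def test_missing_cells_stay_missing(self):
        t1 = make_quant_table("a", {"P1": (2.0, np.nan), "P2": (4.0, 4.0), "P3": (6.0, 2.0)})
        t2 = make_quant_table("b", {"P1": (1.0, 1.0), "P2": (2.0, 3.0), "P3": (3.0, 9.0)})
        (n1, _) = median_normalize([t1, t2])
        assert np.isnan(n1.abundance.loc["P1", "rep2"])

    def test_empty_sample_is_an_error(self):
        t = make_quant_table("a", {"P1": (np.nan, 1.0)})
        with pytest.raises(DataModelError, match="a/rep1"):
            median_normalize([t])


class TestCollapseToReference:
    def test_entries_sharing_reference_are_averaged(self):
        t = make_quant_table("xla", {"X1": (10.0, 10.0), "X2": (20.0, 20.0)})
        m = collapse_to_reference([t], OrthologMap({"X1": "H1", "X2": "H1"}))
        assert m.values.loc["H1", "xla"] == 15.0

    def test_identity_map_gives_replicate_means(self):
        t = make_quant_table("xla", {"X1": (10.0, 30.0), "X2": (5.0, np.nan)})
        m = collapse_to_reference([t], OrthologMap({"X1": "X1", "X2": "X2"}))
        assert m.values.loc["X1", "xla"] == 20.0
        # missing replicate excluded from the mean, not zero-filled
        assert m.values.loc["X2", "xla"] == 5.0

    def test_undetected_entry_leaves_cell_missing(self):
        t = make_quant_table("xla", {"X1": (np.nan, np.nan)})
        m = collapse_to_reference([t], OrthologMap({"X1": "H2"}))
        assert np.isnan(m.values.loc["H2", "xla"])
        assert not m.detected.loc["H2", "xla"]

    def test_unmapped_accessions_dropped(self):
        t = make_quant_table("xla", {"X1": (1.0, 1.0), "X9": (2.0, 2.0)})
        m = collapse_to_reference([t], OrthologMap({"X1": "H1"}))
        assert list(m.values.index) == ["H1"]

    def test_idempotent_under_identity_map(self):
        t = make_quant_table("a", {"P1": (4.0, 6.0), "P2": (np.nan, 2.0)})
        m1 = collapse_to_reference([t], OrthologMap({"P1": "P1", "P2": "P2"}))
        again = make_quant_table("a", {p: (m1.values.loc[p, "a"],)
                                       for p in m1.values.index})
        m2 = collapse_to_reference([again], OrthologMap({"P1": "P1", "P2": "P2"}))
        pd.testing.assert_frame_equal(m1.values, m2.values)

    def test_multi_entry_references_are_counted(self):
        t = make_quant_table("xla", {"X1.L": (10.0, 10.0), "X1.S": (20.0, 20.0),
                                     "X2": (5.0, 5.0)})
        m = collapse_to_reference(
            [t], OrthologMap({"X1.L": "H1", "X1.S": "H1", "X2": "H2"}))
        assert m.n_contributors.loc["H1", "xla"] == 2
        assert m.n_contributors.loc["H2", "xla"] == 1

    def test_empty_map_is_an_error(self):
        t = make_quant_table("a", {"P1": (1.0, 1.0)})
        with pytest.raises(DataModelError, match="empty"):
            collapse_to_reference([t], OrthologMap({}))


class TestFoldChanges:
    def make_matrix(self):
        t1 = make_quant_table("A", {"H1": (30.0,), "H2": (7.0,), "H3": (5.0,)})
        t2 = make_quant_table("B", {"H1": (10.0,), "H2": (7.0,), "H4": (2.0,)})
        omap = OrthologMap({h: h for h in ["H1", "H2", "H3", "H4"]})
        return collapse_to_reference([t1, t2], omap)

    def test_ratio_and_enrichment_flag(self):
        fc = pairwise_fold_changes(self.make_matrix(), "A", "B")
        assert fc.loc["H1", "ratio"] == 3.0
        assert fc.loc["H2", "ratio"] == 1.0
        flags = enriched_at(fc, threshold=1.5)
        assert bool(flags["H1"]) and not bool(flags["H2"])

    def test_only_both_detected_proteins_included(self):
        fc = pairwise_fold_changes(self.make_matrix(), "A", "B")
        assert set(fc.index) == {"H1", "H2"}

    def test_unknown_species_rejected(self):
        with pytest.raises(DataModelError, match="'C'"):
            pairwise_fold_changes(self.make_matrix(), "A", "C")


class TestTrypticDigest:
    WIDE = DigestParams(min_length=1, max_length=10**6)

    @pytest.mark.parametrize(
        "seq,params,expected",
        [
            ("AAGKLLRCC", WIDE, 3),                       # AAGK | LLR | CC
            ("AAGKPLLR", WIDE, 1),                        # proline blocks the K site
            ("AAGKLLRCC", DigestParams(), 0),             # all pieces shorter than 7
            ("AAGKPLLR", DigestParams(min_length=1, max_length=10**6,
                                      proline_block=False), 2),
            ("MKRAAAAKEEE", DigestParams(min_length=1, max_length=10**6,
                                         missed_cleavages=1), 7),
        ],
    )
    def test_worked_examples(self, seq, params, expected):
        assert theoretical_tryptic_peptides(seq, params) == expected

    def test_non_amino_acid_rejected(self):
        with pytest.raises(DataModelError, match="B"):
            theoretical_tryptic_peptides("AKBXR", self.WIDE)

    def test_fragment_lengths_sum_to_sequence_length(self, rng):
        aas = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        for _ in range(100):
            seq = "".join(rng.choice(aas, size=rng.integers(1, 120)))
            frags = tryptic_fragments(seq, self.WIDE)
            assert sum(len(f) for f in frags) == len(seq)

    def test_counts_match_brute_force_splitter(self, rng):
        aas = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        params_grid = [
            DigestParams(min_length=1, max_length=10**6),
            DigestParams(),
            DigestParams(proline_block=False, min_length=1, max_length=10**6),
            DigestParams(missed_cleavages=2, min_length=5, max_length=40),
        ]
        for _ in range(250):
            seq = "".join(rng.choice(aas, size=rng.integers(1, 200)))
            for params in params_grid:
                assert theoretical_tryptic_peptides(seq, params) == \
                    brute_force_digest_count(seq, params), (seq, params)

    def test_matches_pyteomics_cleavage(self, rng):
        """Cross-check the no-missed-cleavage digest against pyteomics."""
        from pyteomics.parser import icleave
        aas = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        params = DigestParams(min_length=1, max_length=10**6)
        for _ in range(50):
            seq = "".join(rng.choice(aas, size=rng.integers(5, 150)))
            ours = sorted(tryptic_fragments(seq, params))
            theirs = sorted(p for _, p in icleave(seq, r"[KR](?!P)", 0))
            assert ours == theirs


class TestPrmRollup:
    def make_table(self, areas, ms1, pep2prot):
        samples = [f"s{i + 1}" for i in range(len(ms1))]
        return PRMTable(
            areas=pd.DataFrame(areas, columns=samples).set_axis(
                list(pep2prot), axis=0),
            ms1_means=pd.Series(ms1, index=samples, dtype=float),
            peptide_to_protein=pep2prot,
        )

    def test_worked_two_sample_example(self):
        # areas (4,1), MS1 means (2,1): normalized (2,1), mean 1.5, scaled (4/3, 2/3)
        prm = self.make_table([[4.0, 1.0]], [2.0, 1.0], {"pep1": "prot1"})
        out = prm_rollup(prm)
        assert np.allclose(out.loc["prot1"], [4 / 3, 2 / 3])

    def test_uniform_input_is_a_fixed_point(self):
        prm = self.make_table([[5.0, 5.0], [5.0, 5.0]], [3.0, 3.0],
                              {"p1": "A", "p2": "A"})
        assert np.allclose(prm_rollup(prm), 1.0)

    def test_protein_value_is_mean_of_peptides(self):
        prm = self.make_table([[1.2, 0.8], [0.8, 1.2]], [1.0, 1.0],
                              {"p1": "A", "p2": "A"})
        out = prm_rollup(prm)
        assert np.allclose(out.loc["A"], [1.0, 1.0])

    def test_scaled_values_average_one_per_peptide(self, rng):
        areas = rng.lognormal(2, 1, size=(8, 5))
        pep2prot = {f"p{i}": f"prot{i % 3}" for i in range(8)}
        prm = self.make_table(areas, rng.lognormal(0, 0.5, 5), pep2prot)
        scaled = scaled_peptide_values(prm)
        assert np.allclose(scaled.mean(axis=1), 1.0)

    def test_all_zero_peptide_excluded(self):
        prm = self.make_table([[0.0, 0.0], [2.0, 2.0]], [1.0, 1.0],
                              {"p1": "A", "p2": "A"})
        out = prm_rollup(prm)
        assert np.allclose(out.loc["A"], [1.0, 1.0])

    def test_nonpositive_ms1_mean_rejected(self):
        prm = self.make_table([[1.0, 1.0]], [1.0, 1.0], {"p1": "A"})
        prm.ms1_means["s1"] = 0.0
        with pytest.raises(DataModelError, match="positive"):
            prm_rollup(prm)
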