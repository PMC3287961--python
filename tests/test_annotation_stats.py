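"""Functional matrices, location and proteome summaries, pI/MW/GC."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from panhog.annotation_stats import (
    DEFAULT_PKA,
    NO_ASSOCIATION,
    conserved_fraction_by_class,
    functional_matrix,
    gene_gc,
    isoelectric_point,
    location_summary,
    matrix_from_cells,
    molecular_weight,
    net_charge,
    percent,
    proteome_summary,
    round_half_away,
    summarize_counts,
    superclass_matrix,
)
from panhog.classification import HOGLabel
from panhog.datasets import (
    FUNCTIONAL_MATRIX_CELLS,
    FUNCTIONAL_MATRIX_OCCUPANCIES,
    NINE_GENOME_PRINTED_PCT,
    NINE_GENOME_SUMMARY,
)
from panhog.io_formats import ReferenceAssociation, ReferenceTier
from panhog.orthology import HOG

PROTEIN = st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=30)


def make_hog(cid, members):
    return HOG(cluster_id=cid, members=frozenset(members),
               occupancy=len({g for g, _ in members}), mean_identity=50.0,
               min_identity=40.0, max_identity=60.0)


class TestFunctionalMatrix:
    def _setup(self, categories):
        members = [(f"g{i}", f"g{i}_p") for i in range(1, 10)]
        members[0] = ("ref", "ref_p")
        hog = make_hog("HOG0001", members)
        labels = {"HOG0001": HOGLabel("HOG0001", core=True)}
        prok = ReferenceAssociation(ReferenceTier.PROK, {})
        # plant one association per category via duplicate reference members
        hogs = [hog]
        for i, cat in enumerate(categories):
            prok.mapping[f"ref_p{i}" if i else "ref_p"] = (f"PC{i}", cat)
        return hogs, labels, prok

    def test_single_category_single_cell(self):
        hogs, labels, prok = self._setup(
            ["Translation, ribosomal structure and biogenesis"])
        mat = functional_matrix(hogs, labels, [prok], "ref", n_genomes=9)
        assert mat.loc["Translation, ribosomal structure and biogenesis", 9] == 1
        assert mat.to_numpy().sum() == 1

    def test_unassociated_cluster_counted_separately(self):
        hogs, labels, _ = self._setup([])
        mat = functional_matrix(hogs, labels, [], "ref", n_genomes=9)
        assert mat.loc[NO_ASSOCIATION, 9] == 1

    def test_multi_category_cluster_increments_both_cells(self):
        members = [("ref", "ref_a"), ("g2", "g2_p")]
        hog = make_hog("HOG0001", members)
        labels = {"HOG0001": HOGLabel("HOG0001", core=False)}
        prok = ReferenceAssociation(ReferenceTier.PROK, {
            "ref_a": ("PC1", "Transcription")})
        # second member of the reference genome maps to a different category
        hog2 = make_hog("HOG0002", [("ref", "ref_b"), ("ref", "ref_c"),
                                    ("g2", "g2_q")])
        labels["HOG0002"] = HOGLabel("HOG0002", core=False)
        prok.mapping["ref_b"] = ("PC2", "Cell motility")
        prok.mapping["ref_c"] = ("PC3", "Defense mechanisms")
        mat = functional_matrix([hog, hog2], labels, [prok], "ref", n_genomes=2)
        assert mat.loc["Transcription", 2] == 1
        assert mat.loc["Cell motility", 2] == 1
        assert mat.loc["Defense mechanisms", 2] == 1

    def test_unknown_category_is_hard_error(self):
        hogs, labels, prok = self._setup(["Alchemy"])
        with pytest.raises(ValueError, match="Alchemy"):
            functional_matrix(hogs, labels, [prok], "ref", n_genomes=9)


@pytest.fixture(scope="module")
def matrix():
    return matrix_from_cells(FUNCTIONAL_MATRIX_CELLS,
                             FUNCTIONAL_MATRIX_OCCUPANCIES)


class TestPublishedMatrixArithmetic:
    def test_metabolism_row_sums(self, matrix):
        sup = superclass_matrix(matrix)
        assert int(sup.loc["Metabolism"].sum()) == 613
        assert int(sup.loc["Metabolism", 9]) == 283

    def test_metabolism_conserved_fraction(self, matrix):
        assert conserved_fraction_by_class(matrix)["Metabolism"] == 46

    def test_single_cell_matrix_fully_conserved(self):
        cells = {"Transcription": [0, 0, 0, 0, 0, 0, 0, 5]}
        mat = matrix_from_cells(cells, FUNCTIONAL_MATRIX_OCCUPANCIES)
        fractions = conserved_fraction_by_class(mat)
        assert fractions["Information Transfer and Storage"] == 100
        assert fractions["Metabolism"] is None


class TestLocationSummary:
    def test_all_chromosomal_has_no_plasmid_rows(self, small_sim, small_result):
        frame = location_summary(small_result.hogs, small_result.labels_final,
                                 {p.genome_id: p for p in small_sim.base})
        assert set(frame.replicon_class) <= {"chromosome", "megaplasmid"}
        assert (frame.n_members > 0).all()

    def test_planted_unique_location_recovered(self, small_sim, small_result):
        """Members of unique clusters sit on the replicon class the
        simulation planted."""
        frame = location_summary(small_result.hogs, small_result.labels_final,
                                 {p.genome_id: p for p in small_sim.base})
        unique = frame[frame.class_label.isin(["tucHOG", "nucHOG"])]
        planted = {}
        for fam in small_sim.truth.of_kind("unique_true", "unique_decoy"):
            planted[fam.replicon_class.value] = (
                planted.get(fam.replicon_class.value, 0)
                + sum(len(p) for g, p in fam.members.items()
                      if g.startswith("G")))
        got = unique.groupby("replicon_class").n_members.sum().to_dict()
        assert got == planted


class TestProteomeSummary:
    def test_published_percentages_reproduced(self):
        from panhog.datasets import PRINTED_PCT_INCONSISTENCIES
        for genome, (size, clustered, core) in NINE_GENOME_SUMMARY.items():
            s = summarize_counts(genome, size, clustered, core)
            printed = NINE_GENOME_PRINTED_PCT[genome]
            # one printed cell contradicts its own printed counts; the
            # arithmetic must reproduce what the counts give
            expect_clustered = PRINTED_PCT_INCONSISTENCIES.get(
                (genome, "clustered_pct"), printed[0])
            expect_core = PRINTED_PCT_INCONSISTENCIES.get(
                (genome, "core_pct"), printed[1])
            assert (s.clustered_pct, s.core_pct) == (expect_clustered, expect_core)

    def test_empty_clustering_gives_zero(self, small_sim):
        s = proteome_summary(small_sim.base[0], [], {})
        assert (s.clustered, s.clustered_pct, s.core, s.core_pct) == (0, 0.0, 0, 0.0)

    def test_rounding_half_away_from_zero(self):
        assert round_half_away(0.05, 1) == 0.1
        assert round_half_away(82.75, 1) == 82.8
        assert percent(1, 8, 1) == 12.5
        with pytest.raises(ZeroDivisionError):
            percent(1, 0)


class TestIsoelectricPoint:
    def test_single_glycine_is_terminal_midpoint(self):
        expect = (DEFAULT_PKA["Nterm"] + DEFAULT_PKA["Cterm"]) / 2
        assert isoelectric_point("G") == pytest.approx(expect, abs=1e-3)

    @settings(max_examples=40, deadline=None)
    @given(seq=PROTEIN)
    def test_charge_at_pi_is_zero(self, seq):
        pi = isoelectric_point(seq)
        assert abs(net_charge(seq, pi)) < 1e-3

    def test_acidic_and_basic_extremes(self):
        # brute pH-grid scan agrees: poly-D crosses zero below 4.5,
        # poly-K above 9
        assert isoelectric_point("DDDD") < 4.5
        assert isoelectric_point("KKKK") > 9.0

    @settings(max_examples=30, deadline=None)
    @given(seq=PROTEIN)
    def test_appending_acidic_residue_never_raises_pi(self, seq):
        assert isoelectric_point(seq + "D") <= isoelectric_point(seq) + 1e-3


class TestMolecularWeightAndGC:
    def test_diglycine_hand_sum(self):
        from panhog.annotation_stats import AVERAGE_RESIDUE_MASS, WATER_MASS
        expect = (2 * AVERAGE_RESIDUE_MASS["G"] + WATER_MASS) / 1000
        assert molecular_weight("GG") == pytest.approx(expect)

    def test_agrees_with_protparam(self):
        from Bio.SeqUtils.ProtParam import ProteinAnalysis
        seq = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"
        ours = molecular_weight(seq) * 1000
        theirs = ProteinAnalysis(seq).molecular_weight()
        assert ours == pytest.approx(theirs, rel=1e-3)

    def test_gc_values(self):
        assert gene_gc("ATGC") == 50.0
        assert gene_gc("AT") == 0.0
        with pytest.raises(ValueError):
            gene_gc("")

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            molecular_weight("")
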