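"""Core/accessory partitioning, reference association and the unique screen."""

import pytest

from panhog.classification import (
    BOOKKEEPING_CATEGORIES,
    BookkeepingSummary,
    HOGLabel,
    associate_reference,
    bookkeeping,
    classify_core,
    screen_added_genomes,
    screen_outgroup,
)
from panhog.datasets import BOOKKEEPING_COUNTS
from panhog.io_formats import Proteome, ProteinRecord, ReferenceAssociation, ReferenceTier
from panhog.orthology import HOG
from panhog.pipeline import analyze_pangenome
from panhog.synthetic_data import SimulationConfig, simulate_pangenome
from conftest import SMALL_CONFIG


def make_hog(cid, members):
    return HOG(cluster_id=cid, members=frozenset(members),
               occupancy=len({g for g, _ in members}), mean_identity=50.0,
               min_identity=40.0, max_identity=60.0)


class TestClassifyCore:
    BASE = [f"g{i}" for i in range(1, 10)]

    def test_full_occupancy_is_core(self):
        hog = make_hog("HOG0001", [(g, f"{g}_p") for g in self.BASE])
        labels = classify_core([hog], self.BASE)
        assert labels["HOG0001"].class_label == "cHOG"

    def test_partial_occupancy_is_accessory(self):
        hog = make_hog("HOG0001", [(g, f"{g}_p") for g in self.BASE[:-1]])
        labels = classify_core([hog], self.BASE)
        assert labels["HOG0001"].class_label == "aHOG"

    def test_foreign_genome_rejected(self):
        hog = make_hog("HOG0001", [("gX", "p"), ("g1", "q")])
        with pytest.raises(ValueError, match="gX"):
            classify_core([hog], self.BASE)

    def test_planted_core_families_labeled_core(self, small_sim, small_result):
        base_ids = set(small_sim.config.base_genome_ids)
        members_to_cluster = {frozenset(h.members): h.cluster_id
                              for h in small_result.hogs}
        fams = small_sim.truth.of_kind("core", "unique_true", "unique_decoy")
        hits = 0
        for fam in fams:
            key = frozenset((g, p) for g, ps in fam.members.items()
                            if g in base_ids for p in ps)
            cid = members_to_cluster.get(key)
            if cid and small_result.labels_initial[cid].core:
                hits += 1
        assert hits / len(fams) >= 0.95


class TestAssociateReference:
    def _hogs(self):
        return [make_hog("HOG0001", [("ref", "ref_p1"), ("g2", "g2_p1")]),
                make_hog("HOG0002", [("ref", "ref_p2"), ("g2", "g2_p2")])]

    def _labels(self, hogs):
        return {h.cluster_id: HOGLabel(cluster_id=h.cluster_id, core=True)
                for h in hogs}

    def test_prok_only_association_is_not_unique(self):
        hogs = self._hogs()
        prok = ReferenceAssociation(ReferenceTier.PROK,
                                    {"ref_p1": ("PC1", "Transcription")})
        labels = associate_reference(hogs, [prok], "ref", self._labels(hogs))
        assert labels["HOG0001"].prok_ref and not labels["HOG0001"].euk_ref
        assert not labels["HOG0001"].unique
        assert labels["HOG0001"].class_label == "cHOG"

    def test_unassociated_core_cluster_is_unique_candidate(self):
        hogs = self._hogs()
        labels = associate_reference(hogs, [], "ref", self._labels(hogs))
        assert labels["HOG0002"].unique
        assert labels["HOG0002"].class_label == "ucHOG"

    def test_missing_reference_member_warns(self):
        hogs = [make_hog("HOG0001", [("g2", "p1"), ("g3", "p2")])]
        labels = {"HOG0001": HOGLabel("HOG0001", core=True)}
        with pytest.warns(UserWarning, match="no member"):
            out = associate_reference(hogs, [], "ref", labels)
        assert out["HOG0001"].unique

    def test_published_association_split_gives_89_unique(self):
        """799 core clusters: 422 dual-tier + 288 prok-only leaves 89 unique."""
        labels = {}
        for i in range(799):
            lab = HOGLabel(f"HOG{i:04d}", core=True)
            if i < 422:
                lab.prok_ref = lab.euk_ref = True
            elif i < 422 + 288:
                lab.prok_ref = True
            lab.unique = not lab.prok_ref and not lab.euk_ref
            labels[lab.cluster_id] = lab
        n_unique = sum(BOOKKEEPING_CATEGORIES["ucHOGs"](l)
                       for l in labels.values())
        assert n_unique == 89


def tiny_proteomes():
    core_seq = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQAPILSRVGDGTQDNLSGAEKAVQV"
    other = "WWPGHHNNCCYYFFDDEEKKRRSSTTMMAALLIIVVGGPPQQHHWWNNCCYYFFDDE"
    base = {
        "g1": Proteome("g1", [ProteinRecord("g1_p1", "g1", core_seq)]),
        "g2": Proteome("g2", [ProteinRecord("g2_p1", "g2", core_seq)]),
    }
    hog = make_hog("HOG0001", [("g1", "g1_p1"), ("g2", "g2_p1")])
    labels = {"HOG0001": HOGLabel("HOG0001", core=True, unique=True)}
    return base, hog, labels, core_seq, other


class TestScreenAddedGenomes:
    def test_exact_copy_retains_cluster(self, scheme):
        base, hog, labels, core_seq, _ = tiny_proteomes()
        added = [Proteome("a1", [ProteinRecord("a1_p1", "a1", core_seq)])]
        out, removed = screen_added_genomes([hog], labels, added, base, scheme)
        assert removed == []
        assert out["HOG0001"].core

    def test_missing_homolog_relabels_accessory(self, scheme):
        base, hog, labels, _, other = tiny_proteomes()
        added = [Proteome("a1", [ProteinRecord("a1_p1", "a1", other)])]
        out, removed = screen_added_genomes([hog], labels, added, base, scheme)
        assert removed == ["HOG0001"]
        assert out["HOG0001"].class_label == "aHOG"
        assert not out["HOG0001"].unique

    def test_empty_added_set_is_identity(self, scheme):
        base, hog, labels, _, _ = tiny_proteomes()
        out, removed = screen_added_genomes([hog], labels, [], base, scheme)
        assert removed == []
        assert out["HOG0001"].core and out["HOG0001"].unique

    def test_overlapping_added_genome_rejected(self, scheme):
        base, hog, labels, core_seq, _ = tiny_proteomes()
        added = [Proteome("g1", [ProteinRecord("g1_q", "g1", core_seq)])]
        with pytest.raises(ValueError, match="overlaps"):
            screen_added_genomes([hog], labels, added, base, scheme)

    def test_deleted_families_are_exactly_the_removed_ones(self):
        """Deleting planted core families from an added genome removes
        exactly those clusters in the screen."""
        config = SimulationConfig(**{**SMALL_CONFIG,
                                     "deletion_plan": {"F0002": ["A01"],
                                                       "F0005": ["A01"]}})
        sim = simulate_pangenome(config)
        result = analyze_pangenome(sim.base, sim.added, sim.outgroup,
                                   sim.associations,
                                   reference_genome_id=sim.reference_genome_id,
                                   seed=7)
        removed_families = set()
        cluster_of = {frozenset(h.members): h.cluster_id for h in result.hogs}
        for fam_id in ("F0002", "F0005"):
            fam = sim.truth.families[fam_id]
            key = frozenset((g, p) for g, ps in fam.members.items()
                            if g.startswith("G") for p in ps)
            removed_families.add(cluster_of[key])
        assert set(result.removed_by_added_screen) == removed_families


class TestScreenOutgroup:
    def test_planted_homolog_gives_nearly_unique(self, small_sim, small_result):
        cluster_of = {frozenset(h.members): h.cluster_id
                      for h in small_result.hogs}
        for fam in small_sim.truth.of_kind("unique_decoy"):
            key = frozenset((g, p) for g, ps in fam.members.items()
                            if g.startswith("G") for p in ps)
            label = small_result.labels_final[cluster_of[key]]
            assert label.class_label == "nucHOG"
            assert label.outgroup_hits >= 1

    def test_no_candidate_gives_truly_unique(self, scheme):
        base, hog, labels, _, other = tiny_proteomes()
        outgroup = Proteome("outgroup", [ProteinRecord("og1", "outgroup", other)])
        out, tuc, nuc = screen_outgroup([hog], labels, outgroup, base, scheme)
        assert tuc == ["HOG0001"] and nuc == []
        assert out["HOG0001"].class_label == "tucHOG"

    def test_empty_outgroup_means_all_truly_unique(self, small_sim):
        result = analyze_pangenome(
            small_sim.base, [], None, small_sim.associations,
            reference_genome_id=small_sim.reference_genome_id, seed=7)
        for cid, label in result.labels_final.items():
            if label.core and label.unique:
                assert label.class_label == "tucHOG"
        assert result.nuchogs == []

    def test_enlarging_outgroup_never_unmakes_homologs(self, small_sim, scheme):
        """Monotonicity: adding outgroup sequences can only move clusters
        from truly to nearly unique."""
        half = Proteome("outgroup",
                        sorted(small_sim.outgroup.records,
                               key=lambda r: r.protein_id)[:10])
        full = small_sim.outgroup
        base = {p.genome_id: p for p in small_sim.base}
        result = analyze_pangenome(
            small_sim.base, small_sim.added, None, small_sim.associations,
            reference_genome_id=small_sim.reference_genome_id, seed=7)
        hogs = result.hogs
        labels = result.labels_final
        out_half, tuc_h, nuc_h = screen_outgroup(hogs, labels, half, base,
                                                 scheme, seed=7)
        out_full, tuc_f, nuc_f = screen_outgroup(hogs, labels, full, base,
                                                 scheme, seed=7)
        assert set(nuc_h) <= set(nuc_f)
        assert set(tuc_f) <= set(tuc_h)


class TestBookkeeping:
    def test_published_counts_conserve(self):
        summary = BookkeepingSummary.from_counts(
            BOOKKEEPING_COUNTS, total=BOOKKEEPING_COUNTS["cHOGs"][3]
                                      + BOOKKEEPING_COUNTS["aHOGs"][3])
        assert summary.rows["cHOGs"].final == 784
        assert summary.rows["tucHOGs"].final == 55
        assert summary.rows["nucHOGs"].final == 28
        assert summary.rows["ucHOGs"].final == 83

    def test_violated_conservation_rejected(self):
        with pytest.raises(ValueError, match="final"):
            BookkeepingSummary.from_counts({"cHOGs": (10, 1, 0, 10)})

    def test_noop_relabeling_has_no_flows(self):
        labels = {f"HOG{i}": HOGLabel(f"HOG{i}", core=i % 2 == 0)
                  for i in range(10)}
        summary = bookkeeping(labels, labels)
        for row in summary.rows.values():
            assert row.removed == 0 and row.added == 0

    def test_differing_universes_rejected(self):
        a = {"HOG1": HOGLabel("HOG1", core=True)}
        b = {"HOG2": HOGLabel("HOG2", core=True)}
        with pytest.raises(ValueError, match="different clusters"):
            bookkeeping(a, b)

    def test_pipeline_bookkeeping_conserves(self, small_result):
        small_result.bookkeeping.validate()
        rows = small_result.bookkeeping.rows
        assert rows["cHOGs"].final + rows["aHOGs"].final == len(small_result.hogs)
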