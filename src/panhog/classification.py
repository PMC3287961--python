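"""Core/accessory partitioning and the clade-signature screen.

A cluster present in every base genome is *core* (cHOG); anything else is
*accessory* (aHOG).  Core clusters with no association to either reference
ortholog tier (the COG/KOG stand-ins) are *unique* candidates (ucHOG).  Those
survive two sequential screens modelled on how signature families are vetted
when new genomes and outgroup databases appear:

1. every newly added ingroup genome must contain a significant homolog of the
   cluster, otherwise the cluster drops back to accessory;
2. the cluster's members are searched against an outgroup protein database;
   a single outgroup sequence passing the homolog confidence test makes the
   cluster *nearly unique* (nucHOG), otherwise it is *truly unique* (tucHOG)
   — a clade signature family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .align import (
    CLUSTER_CONFIDENCE,
    DEFAULT_N_SHUFFLES,
    HOMOLOG_CONFIDENCE,
    ScoringScheme,
    local_score,
    randomized_significance,
)
from .io_formats import Proteome, ReferenceAssociation, ReferenceTier
from .orthology import DEFAULT_MIN_SCORE, HOG, pair_rng

#: minimum raw local score for an outgroup database hit to count as a
#: candidate homolog.  Deliberately stricter than the within-pair best-hit
#: cutoff: best-hit tables keep only each query's maximum, whereas the
#: outgroup screen keeps every pair above threshold, so a database hit must
#: be individually meaningful (raw 80 with BLOSUM62 11/1 corresponds to a
#: chance expectation well below one hit per screened family at this
#: database scale, while genuine cross-clade homologs at >=40% identity over
#: >=80 residues score far above it).
DEFAULT_OUTGROUP_MIN_SCORE = 80.0


@dataclass
class HOGLabel:
    """Classification state of one cluster."""

    cluster_id: str
    core: bool
    prok_ref: bool = False
    euk_ref: bool = False
    arch_ref: bool = False
    unique: bool = False
    unique_kind: Optional[str] = None  # "truly" | "nearly" | None
    outgroup_hits: int = 0
    removed_by_added_screen: bool = False

    @property
    def class_label(self) -> str:
        if not self.core:
            return "aHOG"
        if self.unique:
            if self.unique_kind == "truly":
                return "tucHOG"
            if self.unique_kind == "nearly":
                return "nucHOG"
            return "ucHOG"
        return "cHOG"


def classify_core(
    hogs: Sequence[HOG],
    base_genome_ids: Iterable[str],
) -> dict[str, HOGLabel]:
    """Label clusters core (present in every base genome) or accessory."""
    base = set(base_genome_ids)
    labels: dict[str, HOGLabel] = {}
    for hog in hogs:
        extra = hog.genome_ids - base
        if extra:
            raise ValueError(
                f"cluster {hog.cluster_id} contains genomes outside the base "
                f"set: {sorted(extra)}")
        labels[hog.cluster_id] = HOGLabel(cluster_id=hog.cluster_id,
                                          core=hog.occupancy == len(base))
    return labels


def associate_reference(
    hogs: Sequence[HOG],
    associations: Iterable[ReferenceAssociation],
    reference_genome_id: str,
    labels: Mapping[str, HOGLabel],
) -> dict[str, HOGLabel]:
    """Flag clusters whose reference-genome members map into each tier.

    Core clusters with neither a prokaryotic- nor a eukaryotic-tier
    association become unique candidates (ucHOGs).
    """
    by_tier = {a.tier: a for a in associations}
    out: dict[str, HOGLabel] = {}
    for hog in hogs:
        label = replace(labels[hog.cluster_id])
        ref_members = hog.members_of(reference_genome_id)
        if label.core and not ref_members:
            warnings.warn(
                f"core cluster {hog.cluster_id} has no member from reference "
                f"genome {reference_genome_id!r}; treated as unassociated",
                stacklevel=2)
        for tier, attr in ((ReferenceTier.PROK, "prok_ref"),
                           (ReferenceTier.EUK, "euk_ref"),
                           (ReferenceTier.ARCH, "arch_ref")):
            assoc = by_tier.get(tier)
            hit = assoc is not None and any(pid in assoc for pid in ref_members)
            setattr(label, attr, hit)
        label.unique = label.core and not label.prok_ref and not label.euk_ref
        out[label.cluster_id] = label
    return out


def _member_sequences(hog: HOG, proteomes: Mapping[str, Proteome]) -> list[tuple[str, str]]:
    return [(pid, proteomes[gid][pid].aa_seq) for gid, pid in sorted(hog.members)]


def screen_added_genomes(
    hogs: Sequence[HOG],
    labels: Mapping[str, HOGLabel],
    added_proteomes: Sequence[Proteome],
    proteomes: Mapping[str, Proteome],
    scheme: ScoringScheme,
    min_score: float = DEFAULT_MIN_SCORE,
    confidence: float = CLUSTER_CONFIDENCE,
    n_shuffles: int = DEFAULT_N_SHUFFLES,
    seed: int = 0,
) -> tuple[dict[str, HOGLabel], list[str]]:
    """Require every added genome to contain a homolog of each core cluster.

    A core cluster is retained iff, in every added genome, at least one
    protein's best local hit among the cluster members passes the cluster
    significance confidence.  Clusters that fail are relabeled accessory.
    Returns the updated labels and the removed cluster ids.
    """
    base_ids = set(proteomes)
    for added in added_proteomes:
        if added.genome_id in base_ids:
            raise ValueError(
                f"added genome {added.genome_id!r} overlaps the base set")
    out = {cid: replace(lab) for cid, lab in labels.items()}
    removed: list[str] = []
    for hog in hogs:
        label = out[hog.cluster_id]
        if not label.core:
            continue
        members = _member_sequences(hog, proteomes)
        ok = True
        for added in added_proteomes:
            if not _genome_has_homolog(members, added, scheme, min_score,
                                       confidence, n_shuffles, seed,
                                       hog.cluster_id):
                ok = False
                break
        if not ok:
            label.core = False
            label.unique = False
            label.unique_kind = None
            label.removed_by_added_screen = True
            removed.append(hog.cluster_id)
    return out, removed


def _genome_has_homolog(members, added: Proteome, scheme, min_score,
                        confidence, n_shuffles, seed, cluster_id) -> bool:
    candidates = []
    for rec in added.records:
        best_pid, best_seq, best = None, None, min_score
        for pid, seq in members:
            s = local_score(rec.aa_seq, seq, scheme)
            if s > best or (s == best and best_pid is None):
                best_pid, best_seq, best = pid, seq, s
        if best_pid is not None:
            candidates.append((best, rec.protein_id, rec.aa_seq, best_pid, best_seq))
    candidates.sort(key=lambda c: (-c[0], c[1]))
    for _, added_pid, added_seq, member_pid, member_seq in candidates:
        rng = pair_rng(seed, added_pid, member_pid, cluster_id)
        sig = randomized_significance(added_seq, member_seq, scheme,
                                      n_shuffles=n_shuffles, rng=rng)
        if sig.significant(confidence):
            return True
    return False


def screen_outgroup(
    hogs: Sequence[HOG],
    labels: Mapping[str, HOGLabel],
    outgroup: Proteome,
    proteomes: Mapping[str, Proteome],
    scheme: ScoringScheme,
    min_score: float = DEFAULT_OUTGROUP_MIN_SCORE,
    confidence: float = HOMOLOG_CONFIDENCE,
    n_shuffles: int = DEFAULT_N_SHUFFLES,
    seed: int = 0,
) -> tuple[dict[str, HOGLabel], list[str], list[str]]:
    """Split unique candidates into truly unique and nearly unique clusters.

    Candidate outgroup hits are outgroup proteins with a local alignment at
    or above ``min_score`` to at least one member; each candidate is then
    tested with the randomized global significance against every member.  One
    (member, outgroup) pair above the confidence level makes the cluster
    nearly unique; ``outgroup_hits`` records how many candidates confirmed.
    """
    out = {cid: replace(lab) for cid, lab in labels.items()}
    tuc: list[str] = []
    nuc: list[str] = []
    outgroup_records = sorted(outgroup.records, key=lambda r: r.protein_id)
    for hog in hogs:
        label = out[hog.cluster_id]
        if not (label.core and label.unique):
            continue
        members = _member_sequences(hog, proteomes)
        n_hits = 0
        for rec in outgroup_records:
            if not any(local_score(rec.aa_seq, seq, scheme) >= min_score
                       for _, seq in members):
                continue
            for member_pid, seq in members:
                rng = pair_rng(seed, rec.protein_id, member_pid, hog.cluster_id)
                sig = randomized_significance(rec.aa_seq, seq, scheme,
                                              n_shuffles=n_shuffles, rng=rng)
                if sig.significant(confidence):
                    n_hits += 1
                    break
        label.outgroup_hits = n_hits
        label.unique_kind = "nearly" if n_hits >= 1 else "truly"
        (nuc if n_hits >= 1 else tuc).append(hog.cluster_id)
    return out, tuc, nuc


# ---------------------------------------------------------------------------
# Bookkeeping

#: category name -> membership predicate on a HOGLabel; mirrors the rows of a
#: before/after reclassification accounting table
BOOKKEEPING_CATEGORIES: dict[str, callable] = {
    "cHOGs": lambda l: l.core,
    "cHOGs_prok_ref_only": lambda l: l.core and l.prok_ref and not l.euk_ref,
    "cHOGs_prok_and_euk_ref": lambda l: l.core and l.prok_ref and l.euk_ref,
    "ucHOGs": lambda l: l.core and l.unique,
    "nucHOGs": lambda l: l.core and l.unique_kind == "nearly",
    "tucHOGs": lambda l: l.core and l.unique_kind == "truly",
    "aHOGs": lambda l: not l.core,
    "aHOGs_prok_ref_only": lambda l: not l.core and l.prok_ref and not l.euk_ref,
    "aHOGs_prok_and_euk_ref": lambda l: not l.core and l.prok_ref and l.euk_ref,
    "aHOGs_unassociated": lambda l: not l.core and not l.prok_ref and not l.euk_ref,
}


@dataclass
class BookkeepingRow:
    initial: int
    removed: int
    added: int
    final: int

    def conserved(self) -> bool:
        return self.final == self.initial - self.removed + self.added


@dataclass
class BookkeepingSummary:
    """Before/after accounting of cluster categories.

    Every row satisfies final = initial − removed + added, and the final
    core + accessory counts partition the cluster universe.
    """

    rows: dict[str, BookkeepingRow] = field(default_factory=dict)
    total: Optional[int] = None

    def validate(self) -> None:
        for name, row in self.rows.items():
            if not row.conserved():
                raise ValueError(f"bookkeeping row {name!r} violates "
                                 "final = initial - removed + added")
        if self.total is not None and "cHOGs" in self.rows and "aHOGs" in self.rows:
            if self.rows["cHOGs"].final + self.rows["aHOGs"].final != self.total:
                raise ValueError("core + accessory final counts != total clusters")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"category": name, "initial": r.initial, "removed": r.removed,
              "added": r.added, "final": r.final}
             for name, r in self.rows.items()]
        ).set_index("category")

    @classmethod
    def from_counts(cls, counts: Mapping[str, tuple[int, int, int, int]],
                    total: Optional[int] = None) -> "BookkeepingSummary":
        summary = cls(rows={name: BookkeepingRow(*vals)
                            for name, vals in counts.items()}, total=total)
        summary.validate()
        return summary


def bookkeeping(
    before: Mapping[str, HOGLabel],
    after: Mapping[str, HOGLabel],
) -> BookkeepingSummary:
    """Per-category initial/removed/added/final counts between two labelings
    of the same cluster universe."""
    if set(before) != set(after):
        raise ValueError("before/after labelings cover different clusters")
    rows: dict[str, BookkeepingRow] = {}
    for name, pred in BOOKKEEPING_CATEGORIES.items():
        set_b = {cid for cid, lab in before.items() if pred(lab)}
        set_a = {cid for cid, lab in after.items() if pred(lab)}
        rows[name] = BookkeepingRow(
            initial=len(set_b),
            removed=len(set_b - set_a),
            added=len(set_a - set_b),
            final=len(set_a),
        )
    summary = BookkeepingSummary(rows=rows, total=len(before))
    summary.validate()
    return summary
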