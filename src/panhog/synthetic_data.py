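"""Synthetic pan-genomes with planted family structure.

The generator emulates the study design of a family-level pan-proteome
survey: several ingroup proteomes share planted *core* families (present in
every genome, including genomes added later), *accessory* families (present
in a subset, with a bimodal occupancy distribution), *clade-unique* core
families absent from any outgroup (split into truly unique families and
decoys that carry a planted outgroup homolog), and per-genome singletons.
Replicons (chromosome versus megaplasmid), coding sequences with a
GC-biased codon choice, and reference-tier associations are planted so that
every downstream stage — clustering, classification, the signature screen
and the reports — can be scored against a machine-readable truth table.

Members of a family are independent descendants of a random ancestor,
substituted at i.i.d. positions (no indels) to an exact ancestor identity;
the family-level identity target is interpreted as the expected *pairwise*
identity between members, so members are generated at the square root of it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from Bio.Data import CodonTable

from .annotation_stats import ALL_CATEGORIES
from .io_formats import (
    Proteome,
    ProteinRecord,
    ReferenceAssociation,
    ReferenceTier,
    RepliconClass,
    write_associations,
    write_proteome,
)

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"

#: Robinson–Robinson background amino-acid frequencies
DEFAULT_AA_FREQ: dict[str, float] = {
    "A": 0.0780, "C": 0.0152, "D": 0.0535, "E": 0.0668, "F": 0.0397,
    "G": 0.0733, "H": 0.0229, "I": 0.0514, "K": 0.0586, "L": 0.0901,
    "M": 0.0241, "N": 0.0449, "P": 0.0520, "Q": 0.0426, "R": 0.0512,
    "S": 0.0712, "T": 0.0584, "V": 0.0644, "W": 0.0132, "Y": 0.0321,
}


@dataclass
class SimulationConfig:
    """Planted pan-genome structure; defaults are the package's standard
    desk-scale study conditions."""

    n_base_genomes: int = 5
    n_added_genomes: int = 2
    n_core_families: int = 60
    n_accessory_families: int = 40
    n_unique_true: int = 8
    n_unique_decoy: int = 4
    n_singletons_per_genome: int = 15
    n_outgroup_random: int = 200
    length_range: tuple[int, int] = (80, 300)
    identity_range: tuple[float, float] = (0.30, 0.80)
    decoy_identity_range: tuple[float, float] = (0.45, 0.55)
    occupancy_p2: float = 0.35
    occupancy_p3: float = 0.20
    chromosomal_fraction_unique: float = 0.9
    chromosomal_fraction_other: float = 0.85
    gc_target: float = 0.62
    dual_association_fraction: float = 0.60
    accessory_association_fraction: float = 0.15
    aa_freq: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_AA_FREQ))
    deletion_plan: dict[str, list[str]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_base_genomes", "n_added_genomes", "n_core_families",
                     "n_accessory_families", "n_unique_true", "n_unique_decoy",
                     "n_singletons_per_genome", "n_outgroup_random"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.identity_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("identity_range must lie in (0, 1]")
        if self.occupancy_p2 + self.occupancy_p3 > 1 + 1e-9:
            raise ValueError("occupancy probabilities exceed 1")

    @property
    def base_genome_ids(self) -> list[str]:
        return [f"G{i + 1:02d}" for i in range(self.n_base_genomes)]

    @property
    def added_genome_ids(self) -> list[str]:
        return [f"A{i + 1:02d}" for i in range(self.n_added_genomes)]

    def occupancy_distribution(self) -> dict[int, float]:
        """Accessory occupancy distribution over 2..n_base_genomes-1
        (bimodal: mass at 2 and 3, remainder uniform above)."""
        support = list(range(2, self.n_base_genomes))
        if not support:
            raise ValueError("accessory families need >= 3 base genomes")
        probs: dict[int, float] = {}
        remainder_support = [k for k in support if k >= 4]
        if 2 in support:
            probs[2] = self.occupancy_p2
        if 3 in support:
            probs[3] = self.occupancy_p3
        rest = 1.0 - sum(probs.values())
        if remainder_support:
            for k in remainder_support:
                probs[k] = rest / len(remainder_support)
        else:
            # no room above 3: renormalize over what exists
            total = sum(probs.values())
            probs = {k: v / total for k, v in probs.items()}
        return probs


@dataclass
class PlantedFamily:
    family_id: str
    kind: str  # core | accessory | unique_true | unique_decoy | singleton
    members: dict[str, list[str]]  # genome_id -> protein ids
    replicon_class: RepliconClass
    target_identity: float
    outgroup_homologs: list[str] = field(default_factory=list)

    @property
    def base_occupancy(self) -> int:
        return sum(1 for gid in self.members if gid.startswith("G"))

    def occupancy_in(self, genome_ids: list[str]) -> int:
        return sum(1 for gid in self.members if gid in genome_ids)


@dataclass
class TruthTable:
    """Planted family structure: the answer key for recovery analysis."""

    families: dict[str, PlantedFamily] = field(default_factory=dict)

    def of_kind(self, *kinds: str) -> list[PlantedFamily]:
        return [f for f in self.families.values() if f.kind in kinds]

    @property
    def protein_to_family(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for fam in self.families.values():
            for pids in fam.members.values():
                for pid in pids:
                    if pid in out:
                        raise ValueError(f"protein id {pid} reused across families")
                    out[pid] = fam.family_id
        return out

    def all_protein_ids(self) -> set[str]:
        return set(self.protein_to_family)

    def to_frame(self):
        import pandas as pd
        rows = []
        for fam in self.families.values():
            for gid, pids in sorted(fam.members.items()):
                for pid in pids:
                    rows.append({"family_id": fam.family_id, "kind": fam.kind,
                                 "genome_id": gid, "protein_id": pid,
                                 "replicon_class": fam.replicon_class.value,
                                 "target_identity": fam.target_identity})
        return pd.DataFrame(rows, columns=["family_id", "kind", "genome_id",
                                           "protein_id", "replicon_class",
                                           "target_identity"])


@dataclass
class SimulatedPangenome:
    base: list[Proteome]
    added: list[Proteome]
    outgroup: Proteome
    truth: TruthTable
    associations: list[ReferenceAssociation]
    config: SimulationConfig

    @property
    def reference_genome_id(self) -> str:
        return self.config.base_genome_ids[0]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for prot in [*self.base, *self.added, self.outgroup]:
            write_proteome(prot, outdir / f"{prot.genome_id}.faa",
                           outdir / f"{prot.genome_id}.annotation.tsv")
        write_associations(self.associations, outdir / "associations.tsv")
        self.truth.to_frame().to_csv(outdir / "truth.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# sequence-level primitives

def random_protein(length: int, rng: np.random.Generator,
                   aa_freq: Optional[dict[str, float]] = None) -> str:
    freqs = aa_freq or DEFAULT_AA_FREQ
    letters = list(freqs)
    p = np.array([freqs[a] for a in letters], dtype=float)
    p /= p.sum()
    return "".join(rng.choice(letters, size=length, p=p))


def mutate_protein(ancestor: str, target_identity: float,
                   rng: np.random.Generator,
                   aa_freq: Optional[dict[str, float]] = None) -> str:
    """Substitute random positions until exact-position identity to the
    ancestor equals ``round(target_identity * L) / L``; length preserved."""
    if not (0 < target_identity <= 1):
        raise ValueError("target_identity must be in (0, 1]")
    length = len(ancestor)
    n_keep = round(target_identity * length)
    if n_keep < 1:
        raise ValueError("target identity below one residue; nothing conserved")
    n_sub = length - n_keep
    if n_sub == 0:
        return ancestor
    freqs = aa_freq or DEFAULT_AA_FREQ
    letters = list(freqs)
    p = np.array([freqs[a] for a in letters], dtype=float)
    p /= p.sum()
    positions = rng.choice(length, size=n_sub, replace=False)
    seq = list(ancestor)
    for pos in positions:
        new = seq[pos]
        while new == seq[pos]:
            new = rng.choice(letters, p=p)
        seq[pos] = new
    return "".join(seq)


def _codon_tables() -> tuple[dict[str, list[str]], list[str]]:
    table = CodonTable.unambiguous_dna_by_id[1]
    by_aa: dict[str, list[str]] = {}
    for codon, aa in table.forward_table.items():
        by_aa.setdefault(aa, []).append(codon)
    for codons in by_aa.values():
        codons.sort()
    return by_aa, sorted(table.stop_codons)


def _gc_count(codon: str) -> int:
    return sum(1 for b in codon if b in "GC")


def solve_gc_bias(gc_target: float, aa_freq: dict[str, float]) -> float:
    """Exponential codon-choice tilt beta with weight exp(beta*GC(codon)),
    solved so the expected coding GC under ``aa_freq`` hits ``gc_target``."""
    by_aa, _ = _codon_tables()

    def expected_gc(beta: float) -> float:
        total = 0.0
        for aa, freq in aa_freq.items():
            codons = by_aa[aa]
            w = np.exp([beta * _gc_count(c) for c in codons])
            w /= w.sum()
            total += freq * sum(wi * _gc_count(c) for wi, c in zip(w, codons))
        return total / 3.0

    lo, hi = -15.0, 15.0
    if not (expected_gc(lo) <= gc_target <= expected_gc(hi)):
        raise ValueError(f"gc_target {gc_target} unreachable by codon choice")
    for _ in range(80):
        mid = (lo + hi) / 2.0
        if expected_gc(mid) < gc_target:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def back_translate(aa_seq: str, beta: float, rng: np.random.Generator,
                   include_stop: bool = True) -> str:
    """GC-tilted back-translation under the standard genetic code."""
    by_aa, stops = _codon_tables()
    parts = []
    for aa in aa_seq:
        codons = by_aa.get(aa)
        if codons is None:  # X or unknown: pick uniformly over all sense codons
            codons = sorted(c for cs in by_aa.values() for c in cs)
        w = np.exp([beta * _gc_count(c) for c in codons])
        w /= w.sum()
        parts.append(rng.choice(codons, p=w))
    if include_stop:
        w = np.exp([beta * _gc_count(c) for c in stops])
        w /= w.sum()
        parts.append(rng.choice(stops, p=w))
    return "".join(parts)


# ---------------------------------------------------------------------------
# pan-genome assembly

def _draw_occupancy(config: SimulationConfig, rng: np.random.Generator) -> int:
    dist = config.occupancy_distribution()
    ks = sorted(dist)
    return int(rng.choice(ks, p=np.array([dist[k] for k in ks])))


def simulate_pangenome(config: SimulationConfig) -> SimulatedPangenome:
    """Generate base and added proteomes, an outgroup database, planted
    reference associations and the truth table, deterministically under
    ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    beta = solve_gc_bias(config.gc_target, config.aa_freq)
    base_ids = config.base_genome_ids
    added_ids = config.added_genome_ids
    if not base_ids:
        raise ValueError("need at least one base genome")
    reference_genome = base_ids[0]

    # family layout: ids are assigned in generation order
    plan: list[tuple[str, str]] = []  # (family_id, kind)
    idx = 0
    for _ in range(config.n_core_families):
        idx += 1
        plan.append((f"F{idx:04d}", "core"))
    for _ in range(config.n_accessory_families):
        idx += 1
        plan.append((f"F{idx:04d}", "accessory"))
    for _ in range(config.n_unique_true):
        idx += 1
        plan.append((f"F{idx:04d}", "unique_true"))
    for _ in range(config.n_unique_decoy):
        idx += 1
        plan.append((f"F{idx:04d}", "unique_decoy"))

    family_ids = {fid for fid, _ in plan}
    for fid, genomes in config.deletion_plan.items():
        if fid not in family_ids:
            raise ValueError(f"deletion plan names unknown family {fid!r}")
        kind = dict(plan)[fid]
        if kind == "accessory":
            raise ValueError(f"deletion plan targets accessory family {fid!r}")
        for gid in genomes:
            if gid not in added_ids:
                raise ValueError(
                    f"deletion plan for {fid!r} names non-added genome {gid!r}")

    records: dict[str, list[ProteinRecord]] = {g: [] for g in [*base_ids, *added_ids]}
    outgroup_records: list[ProteinRecord] = []
    truth = TruthTable()
    prok = ReferenceAssociation(tier=ReferenceTier.PROK)
    euk = ReferenceAssociation(tier=ReferenceTier.EUK)

    for fam_id, kind in plan:
        length = int(rng.integers(config.length_range[0],
                                  config.length_range[1] + 1))
        pairwise_target = float(rng.uniform(*config.identity_range))
        member_identity = float(np.sqrt(pairwise_target))
        ancestor = random_protein(length, rng, config.aa_freq)

        if kind == "accessory":
            occ = _draw_occupancy(config, rng)
            genomes = sorted(rng.choice(base_ids, size=occ, replace=False))
        else:
            genomes = [*base_ids, *added_ids]
            deleted = set(config.deletion_plan.get(fam_id, []))
            genomes = [g for g in genomes if g not in deleted]

        chrom_p = (config.chromosomal_fraction_unique
                   if kind in ("unique_true", "unique_decoy")
                   else config.chromosomal_fraction_other)
        replicon_class = (RepliconClass.CHROMOSOME
                          if rng.random() < chrom_p
                          else RepliconClass.MEGAPLASMID)

        fam = PlantedFamily(family_id=fam_id, kind=kind, members={},
                            replicon_class=replicon_class,
                            target_identity=pairwise_target)
        for gid in genomes:
            aa = mutate_protein(ancestor, member_identity, rng, config.aa_freq)
            pid = f"{gid}_{fam_id}"
            records[gid].append(_make_record(pid, gid, aa, replicon_class,
                                             beta, rng))
            fam.members.setdefault(gid, []).append(pid)

        if kind == "unique_decoy":
            host = next(g for g in base_ids if g in fam.members)
            member_seq = next(r.aa_seq for r in records[host]
                              if r.protein_id == f"{host}_{fam_id}")
            decoy_identity = float(rng.uniform(*config.decoy_identity_range))
            og_seq = mutate_protein(member_seq, decoy_identity, rng,
                                    config.aa_freq)
            og_pid = f"OG_{fam_id}"
            outgroup_records.append(ProteinRecord(
                protein_id=og_pid, genome_id="outgroup", aa_seq=og_seq))
            fam.outgroup_homologs.append(og_pid)

        if kind == "core" and reference_genome in fam.members:
            ref_pid = fam.members[reference_genome][0]
            category = str(rng.choice(ALL_CATEGORIES))
            prok.mapping[ref_pid] = (f"PC{fam_id[1:]}", category)
            if rng.random() < config.dual_association_fraction:
                euk.mapping[ref_pid] = (f"EC{fam_id[1:]}", category)
        elif kind == "accessory" and reference_genome in fam.members:
            if rng.random() < config.accessory_association_fraction:
                ref_pid = fam.members[reference_genome][0]
                category = str(rng.choice(ALL_CATEGORIES))
                prok.mapping[ref_pid] = (f"PC{fam_id[1:]}", category)
                if rng.random() < 0.5:
                    euk.mapping[ref_pid] = (f"EC{fam_id[1:]}", category)

        truth.families[fam_id] = fam

    # per-genome singletons, unrelated to any family
    for gid in [*base_ids, *added_ids]:
        for i in range(config.n_singletons_per_genome):
            length = int(rng.integers(config.length_range[0],
                                      config.length_range[1] + 1))
            aa = random_protein(length, rng, config.aa_freq)
            pid = f"{gid}_S{i + 1:04d}"
            rc = (RepliconClass.CHROMOSOME
                  if rng.random() < config.chromosomal_fraction_other
                  else RepliconClass.MEGAPLASMID)
            records[gid].append(_make_record(pid, gid, aa, rc, beta, rng))
            fam = PlantedFamily(family_id=f"SGL_{pid}", kind="singleton",
                                members={gid: [pid]}, replicon_class=rc,
                                target_identity=1.0)
            truth.families[fam.family_id] = fam

    # unrelated outgroup proteins
    for i in range(config.n_outgroup_random):
        length = int(rng.integers(config.length_range[0],
                                  config.length_range[1] + 1))
        outgroup_records.append(ProteinRecord(
            protein_id=f"OG_R{i + 1:04d}", genome_id="outgroup",
            aa_seq=random_protein(length, rng, config.aa_freq)))

    proteomes = {gid: _assemble_proteome(gid, recs)
                 for gid, recs in records.items()}
    outgroup = Proteome(genome_id="outgroup", records=outgroup_records,
                        display_name="synthetic outgroup database")
    return SimulatedPangenome(
        base=[proteomes[g] for g in base_ids],
        added=[proteomes[g] for g in added_ids],
        outgroup=outgroup,
        truth=truth,
        associations=[prok, euk],
        config=config,
    )


def _make_record(pid: str, gid: str, aa: str, replicon_class: RepliconClass,
                 beta: float, rng: np.random.Generator) -> ProteinRecord:
    nt = back_translate(aa, beta, rng)
    replicon_id = "chr" if replicon_class is RepliconClass.CHROMOSOME else "pMP1"
    strand = "+" if rng.random() < 0.5 else "-"
    return ProteinRecord(protein_id=pid, genome_id=gid, aa_seq=aa,
                         replicon_id=replicon_id, replicon_class=replicon_class,
                         nt_seq=nt, start=1, end=len(nt), strand=strand)


def _assemble_proteome(genome_id: str, recs: list[ProteinRecord]) -> Proteome:
    # lay genes end to end per replicon with a fixed intergenic gap
    cursor: dict[str, int] = {}
    placed = []
    for rec in recs:
        start = cursor.get(rec.replicon_id, 1)
        length = len(rec.nt_seq) if rec.nt_seq else 3 * len(rec.aa_seq)
        rec.start, rec.end = start, start + length - 1
        cursor[rec.replicon_id] = rec.end + 101
        placed.append(rec)
    replicons = {"chr": RepliconClass.CHROMOSOME, "pMP1": RepliconClass.MEGAPLASMID}
    return Proteome(genome_id=genome_id, records=placed, replicons=replicons)
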