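"""Readers and writers for the pipeline's external representations.

Proteomes travel as multi-record protein FASTA plus an optional tab-separated
annotation table assigning each protein to a replicon (chromosome or
megaplasmid) with 1-based inclusive coordinates.  Reference-cluster
associations (the COG/KOG-style tiers used for functional assignment) and the
final cluster membership tables are plain TSV.  All tables are UTF-8,
tab-delimited, with ``#`` comment lines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")
#: residues silently collapsed to ``X`` on load (ambiguity / selenocysteine)
AMBIGUOUS_TO_X = {"B", "Z", "U", "J", "O"}


class RepliconClass(str, Enum):
    CHROMOSOME = "chromosome"
    MEGAPLASMID = "megaplasmid"
    UNKNOWN = "unknown"


@dataclass
class ProteinRecord:
    """One predicted protein with its genomic context.

    Coordinates are 1-based inclusive (GFF convention); ``nt_seq`` is the
    coding nucleotide sequence when available, with or without the stop codon.
    """

    protein_id: str
    genome_id: str
    aa_seq: str
    replicon_id: str = "unknown"
    replicon_class: RepliconClass = RepliconClass.UNKNOWN
    nt_seq: Optional[str] = None
    start: Optional[int] = None
    end: Optional[int] = None
    strand: str = "unknown"

    def __post_init__(self) -> None:
        if not self.aa_seq:
            raise ValueError(f"protein {self.protein_id!r}: empty amino-acid sequence")
        if self.start is not None and self.end is not None and self.end < self.start:
            raise ValueError(f"protein {self.protein_id!r}: end < start")
        if self.nt_seq is not None:
            n, m = len(self.nt_seq), len(self.aa_seq)
            if n not in (3 * m, 3 * (m + 1)):
                warnings.warn(
                    f"protein {self.protein_id!r}: nt_seq length {n} does not match "
                    f"3*{m} or 3*({m}+1); keeping sequence",
                    stacklevel=2,
                )

    def __len__(self) -> int:
        return len(self.aa_seq)


@dataclass
class Proteome:
    """All predicted proteins of one genome plus its replicon catalog."""

    genome_id: str
    records: list[ProteinRecord] = field(default_factory=list)
    display_name: str = ""
    replicons: dict[str, RepliconClass] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.protein_id in seen:
                raise ValueError(
                    f"duplicate protein_id {rec.protein_id!r} in genome {self.genome_id!r}"
                )
            seen.add(rec.protein_id)
        if not self.display_name:
            self.display_name = self.genome_id

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, protein_id: str) -> ProteinRecord:
        try:
            return self._index[protein_id]
        except AttributeError:
            self._index = {r.protein_id: r for r in self.records}
            return self._index[protein_id]

    @property
    def protein_ids(self) -> list[str]:
        return [r.protein_id for r in self.records]


class ReferenceTier(str, Enum):
    """Reference ortholog-cluster tiers (prokaryotic / eukaryotic / archaeal)."""

    PROK = "prok_ref"
    EUK = "euk_ref"
    ARCH = "arch_ref"


@dataclass
class ReferenceAssociation:
    """protein_id -> (reference cluster id, functional category) for one tier."""

    tier: ReferenceTier
    mapping: dict[str, tuple[str, str]] = field(default_factory=dict)

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self.mapping

    def get(self, protein_id: str):
        return self.mapping.get(protein_id)


def _clean_aa(seq: str, protein_id: str) -> str:
    seq = seq.upper().rstrip("*")
    if "*" in seq:
        raise ValueError(f"protein {protein_id!r}: internal stop codon '*'")
    out = []
    warned = False
    for ch in seq:
        if ch in STANDARD_AA or ch == "X":
            out.append(ch)
        elif ch in AMBIGUOUS_TO_X:
            if not warned:
                warnings.warn(
                    f"protein {protein_id!r}: ambiguous residue(s) mapped to X",
                    stacklevel=3,
                )
                warned = True
            out.append("X")
        else:
            raise ValueError(f"protein {protein_id!r}: invalid residue {ch!r}")
    return "".join(out)


def read_proteome(
    fasta_path: str | Path,
    annotation_path: str | Path | None = None,
    genome_id: str | None = None,
    display_name: str = "",
) -> Proteome:
    """Read a protein FASTA (and optional annotation TSV) into a :class:`Proteome`.

    The annotation table has a header line
    ``protein_id replicon_id replicon_class start end strand``; proteins
    absent from it get replicon ``unknown``.  Sequences are uppercased,
    trailing ``*`` stop characters stripped, and B/Z/U/J/O mapped to X.
    """
    fasta_path = Path(fasta_path)
    if genome_id is None:
        genome_id = fasta_path.stem
    ann: dict[str, dict] = {}
    replicons: dict[str, RepliconClass] = {}
    if annotation_path is not None:
        table = pd.read_csv(annotation_path, sep="\t", comment="#", dtype=str)
        required = {"protein_id", "replicon_id", "replicon_class", "start", "end", "strand"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"annotation table missing columns: {sorted(missing)}")
        for row in table.itertuples(index=False):
            ann[row.protein_id] = {
                "replicon_id": row.replicon_id,
                "replicon_class": RepliconClass(row.replicon_class),
                "start": int(row.start),
                "end": int(row.end),
                "strand": row.strand,
            }
            replicons.setdefault(row.replicon_id, RepliconClass(row.replicon_class))

    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        pid = rec.id
        if pid in seen:
            raise ValueError(f"duplicate protein_id {pid!r} in {fasta_path}")
        seen.add(pid)
        a = ann.get(pid)
        records.append(
            ProteinRecord(
                protein_id=pid,
                genome_id=genome_id,
                aa_seq=_clean_aa(str(rec.seq), pid),
                replicon_id=a["replicon_id"] if a else "unknown",
                replicon_class=a["replicon_class"] if a else RepliconClass.UNKNOWN,
                start=a["start"] if a else None,
                end=a["end"] if a else None,
                strand=a["strand"] if a else "unknown",
            )
        )
    if not records:
        raise ValueError(f"empty FASTA: {fasta_path}")
    return Proteome(genome_id=genome_id, records=records,
                    display_name=display_name, replicons=replicons)


def write_proteome(proteome: Proteome, fasta_path: str | Path,
                   annotation_path: str | Path | None = None) -> None:
    """Inverse of :func:`read_proteome` (lossless for all annotated fields)."""
    seq_records = [
        SeqRecord(Seq(rec.aa_seq), id=rec.protein_id, description="")
        for rec in proteome.records
    ]
    SeqIO.write(seq_records, str(fasta_path), "fasta")
    if annotation_path is not None:
        rows = [
            {
                "protein_id": r.protein_id,
                "replicon_id": r.replicon_id,
                "replicon_class": r.replicon_class.value,
                "start": r.start if r.start is not None else 1,
                "end": r.end if r.end is not None else 3 * len(r.aa_seq),
                "strand": r.strand,
            }
            for r in proteome.records
        ]
        pd.DataFrame(rows).to_csv(annotation_path, sep="\t", index=False)


def read_associations(path: str | Path) -> list[ReferenceAssociation]:
    """Read a reference-association TSV with columns
    ``tier protein_id ref_cluster_id functional_category``."""
    table = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"tier", "protein_id", "ref_cluster_id", "functional_category"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"association table missing columns: {sorted(missing)}")
    by_tier: dict[ReferenceTier, ReferenceAssociation] = {}
    for row in table.itertuples(index=False):
        tier = ReferenceTier(row.tier)
        assoc = by_tier.setdefault(tier, ReferenceAssociation(tier=tier))
        cat = "" if pd.isna(row.functional_category) else row.functional_category
        assoc.mapping[row.protein_id] = (row.ref_cluster_id, cat)
    return list(by_tier.values())


def write_associations(associations: Iterable[ReferenceAssociation],
                       path: str | Path) -> None:
    rows = []
    for assoc in associations:
        for pid in sorted(assoc.mapping):
            ref_id, cat = assoc.mapping[pid]
            rows.append({"tier": assoc.tier.value, "protein_id": pid,
                         "ref_cluster_id": ref_id, "functional_category": cat})
    pd.DataFrame(rows, columns=["tier", "protein_id", "ref_cluster_id",
                                "functional_category"]).to_csv(path, sep="\t", index=False)


CLUSTER_TABLE_COLUMNS = [
    "cluster_id",
    "class_label",
    "genome_id",
    "protein_id",
    "replicon_id",
    "replicon_class",
    "prok_ref",
    "euk_ref",
    "arch_ref",
]


def write_cluster_table(
    clusters,
    path: str | Path,
    labels: Mapping[str, object] | None = None,
    proteomes: Mapping[str, Proteome] | None = None,
    associations: Iterable[ReferenceAssociation] | None = None,
) -> None:
    """Write one row per (cluster, member), sorted by cluster, genome, protein.

    ``clusters`` is an iterable of cluster objects exposing ``cluster_id`` and
    ``members`` as (genome_id, protein_id) pairs; ``labels`` maps cluster_id
    to a label object with a ``class_label`` string (optional).
    """
    assoc_by_tier: dict[str, ReferenceAssociation] = {}
    for a in associations or []:
        assoc_by_tier[a.tier.value] = a
    rows = []
    for cluster in clusters:
        label = labels.get(cluster.cluster_id) if labels else None
        for genome_id, protein_id in sorted(cluster.members):
            rec = None
            if proteomes and genome_id in proteomes:
                try:
                    rec = proteomes[genome_id][protein_id]
                except KeyError:
                    rec = None
            row = {
                "cluster_id": cluster.cluster_id,
                "class_label": getattr(label, "class_label", "") if label else "",
                "genome_id": genome_id,
                "protein_id": protein_id,
                "replicon_id": rec.replicon_id if rec else "unknown",
                "replicon_class": rec.replicon_class.value if rec else "unknown",
            }
            for tier in ("prok_ref", "euk_ref", "arch_ref"):
                assoc = assoc_by_tier.get(tier)
                hit = assoc.get(protein_id) if assoc else None
                row[tier] = hit[0] if hit else ""
            rows.append(row)
    frame = pd.DataFrame(rows, columns=CLUSTER_TABLE_COLUMNS)
    frame = frame.sort_values(["cluster_id", "genome_id", "protein_id"],
                              kind="stable")
    frame.to_csv(path, sep="\t", index=False)


def read_cluster_table(path: str | Path) -> pd.DataFrame:
    """Read a cluster table back as a DataFrame (round-trip of membership)."""
    return pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")


def read_gff3_replicons(path: str | Path) -> pd.DataFrame:
    """Minimal GFF3 adapter: extract CDS rows as an annotation-style table,
    mapping GFF ``seqid`` to ``replicon_id`` (class left ``unknown``)."""
    rows = []
    with open(path) as handle:
        for line in handle:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] != "CDS":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            pid = attrs.get("protein_id") or attrs.get("ID")
            if pid is None:
                continue
            rows.append({
                "protein_id": pid,
                "replicon_id": parts[0],
                "replicon_class": "unknown",
                "start": int(parts[3]),
                "end": int(parts[4]),
                "strand": parts[6] if parts[6] in "+-" else "unknown",
            })
    return pd.DataFrame(rows, columns=["protein_id", "replicon_id",
                                       "replicon_class", "start", "end", "strand"])
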