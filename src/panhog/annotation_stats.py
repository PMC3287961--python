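"""Functional, locational and physicochemical summaries of clusters.

Covers the standard read-outs of a pan-proteome study: a functional-category
by genome-occupancy matrix (with COG-style categories grouped into four
super-classes), per-super-class conserved fractions, chromosome-versus-
megaplasmid location tallies for each cluster class, per-genome clustered /
core summaries, and per-protein statistics (isoelectric point, molecular
weight, gene G+C content).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from Bio.SeqUtils import gc_fraction

from .classification import HOGLabel
from .io_formats import (
    Proteome,
    ReferenceAssociation,
    ReferenceTier,
    RepliconClass,
)
from .orthology import HOG

#: COG-style functional categories grouped into four super-classes, in the
#: canonical reporting order
SUPER_CLASSES: dict[str, list[str]] = {
    "Information Transfer and Storage": [
        "Translation, ribosomal structure and biogenesis",
        "RNA processing and modification",
        "Transcription",
        "Replication, recombination and repair",
        "Chromatin structure and dynamics",
    ],
    "Cellular Processes and signaling": [
        "Cell cycle control, cell division, chromosome partitioning",
        "Defense mechanisms",
        "Signal transduction mechanisms",
        "Cell wall/membrane/envelope biogenesis",
        "Cell motility",
        "Intracellular trafficking, secretion, and vesicular transport",
        "Posttranslational modification, protein turnover, assembly",
    ],
    "Metabolism": [
        "Energy production and conversion",
        "Carbohydrate transport and metabolism",
        "Amino acid transport and metabolism",
        "Nucleotide transport and metabolism",
        "Coenzyme transport and metabolism",
        "Lipid transport and metabolism",
        "Inorganic ion transport and metabolism",
        "Secondary metabolites biosynthesis, transport and catabolism",
    ],
    "Poorly characterized": [
        "General function prediction only",
        "Function unknown",
    ],
}

NO_ASSOCIATION = "no reference association"

ALL_CATEGORIES: list[str] = [c for cats in SUPER_CLASSES.values() for c in cats]

CATEGORY_TO_SUPER: dict[str, str] = {
    cat: sup for sup, cats in SUPER_CLASSES.items() for cat in cats
}


def round_half_away(x: float, decimals: int = 0) -> float:
    """Round half away from zero at the given precision (report convention)."""
    factor = 10 ** decimals
    scaled = x * factor
    rounded = math.floor(abs(scaled) + 0.5) * (1 if scaled >= 0 else -1)
    return rounded / factor


def percent(numerator: float, denominator: float, decimals: int = 1) -> float:
    """Percentage rounded half away from zero at the printed precision."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    return round_half_away(100.0 * numerator / denominator, decimals)


def functional_matrix(
    hogs: Sequence[HOG],
    labels: Mapping[str, HOGLabel],
    associations: Iterable[ReferenceAssociation],
    reference_genome_id: str,
    n_genomes: Optional[int] = None,
) -> pd.DataFrame:
    """Cluster counts per (functional category, genome occupancy).

    A cluster whose reference-genome members map to k > 1 categories
    increments k cells (multi-counting), so column sums may exceed cluster
    counts; clusters with no reference association are tallied in a dedicated
    row.  Rows follow the canonical category order; columns are occupancy
    2..N.
    """
    prok = next((a for a in associations if a.tier == ReferenceTier.PROK), None)
    if n_genomes is None:
        n_genomes = max((h.occupancy for h in hogs), default=2)
    cols = list(range(2, n_genomes + 1))
    matrix = pd.DataFrame(0, index=[NO_ASSOCIATION] + ALL_CATEGORIES,
                          columns=cols)
    for hog in hogs:
        categories: set[str] = set()
        if prok is not None:
            for pid in hog.members_of(reference_genome_id):
                hit = prok.get(pid)
                if hit is not None and hit[1]:
                    if hit[1] not in CATEGORY_TO_SUPER:
                        raise ValueError(
                            f"unknown functional category {hit[1]!r} "
                            f"(protein {pid})")
                    categories.add(hit[1])
        if not categories:
            matrix.loc[NO_ASSOCIATION, hog.occupancy] += 1
        else:
            for cat in categories:
                matrix.loc[cat, hog.occupancy] += 1
    return matrix


def matrix_from_cells(cells: Mapping[str, Sequence[int]],
                      occupancies: Sequence[int]) -> pd.DataFrame:
    """Build a functional matrix from already-tabulated per-category counts
    (e.g. a published table)."""
    matrix = pd.DataFrame(0, index=[NO_ASSOCIATION] + ALL_CATEGORIES,
                          columns=list(occupancies))
    for cat, counts in cells.items():
        if cat != NO_ASSOCIATION and cat not in CATEGORY_TO_SUPER:
            raise ValueError(f"unknown functional category {cat!r}")
        matrix.loc[cat] = list(counts)
    return matrix


def superclass_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Collapse a functional matrix to its four super-class rows."""
    rows = {}
    for sup, cats in SUPER_CLASSES.items():
        rows[sup] = matrix.loc[cats].sum(axis=0)
    return pd.DataFrame(rows).T


def conserved_fraction_by_class(matrix: pd.DataFrame) -> dict[str, Optional[int]]:
    """Percent of each super-class's clusters conserved in all genomes.

    Computed as 100 × (count in the highest-occupancy column) / (row total),
    rounded to the nearest integer; empty super-classes report None.
    """
    sup = superclass_matrix(matrix)
    last = sup.columns[-1]
    out: dict[str, Optional[int]] = {}
    for name, row in sup.iterrows():
        total = int(row.sum())
        if total == 0:
            out[name] = None
        else:
            out[name] = int(percent(int(row[last]), total, decimals=0))
    return out


def location_summary(
    hogs: Sequence[HOG],
    labels: Mapping[str, HOGLabel],
    proteomes: Mapping[str, Proteome],
) -> pd.DataFrame:
    """Member counts per (cluster class, genome, replicon class)."""
    rows: dict[tuple[str, str, str], int] = {}
    for hog in hogs:
        label = labels[hog.cluster_id].class_label
        for genome_id, pid in sorted(hog.members):
            rc = RepliconClass.UNKNOWN
            if genome_id in proteomes:
                try:
                    rc = proteomes[genome_id][pid].replicon_class
                except KeyError:
                    pass
            key = (label, genome_id, rc.value)
            rows[key] = rows.get(key, 0) + 1
    frame = pd.DataFrame(
        [{"class_label": k[0], "genome_id": k[1], "replicon_class": k[2],
          "n_members": v} for k, v in sorted(rows.items())])
    if frame.empty:
        frame = pd.DataFrame(columns=["class_label", "genome_id",
                                      "replicon_class", "n_members"])
    return frame


@dataclass
class ProteomeSummary:
    genome_id: str
    proteome_size: int
    clustered: int
    clustered_pct: float
    core: int
    core_pct: float


def summarize_counts(genome_id: str, proteome_size: int, clustered: int,
                     core: int) -> ProteomeSummary:
    """Per-genome summary from raw counts (percentages to one decimal)."""
    return ProteomeSummary(
        genome_id=genome_id,
        proteome_size=proteome_size,
        clustered=clustered,
        clustered_pct=percent(clustered, proteome_size) if proteome_size else 0.0,
        core=core,
        core_pct=percent(core, proteome_size) if proteome_size else 0.0,
    )


def proteome_summary(
    proteome: Proteome,
    hogs: Sequence[HOG],
    labels: Mapping[str, HOGLabel],
) -> ProteomeSummary:
    """Clustered and core protein counts/fractions for one genome."""
    clustered: set[str] = set()
    core: set[str] = set()
    for hog in hogs:
        mine = {pid for gid, pid in hog.members if gid == proteome.genome_id}
        clustered |= mine
        if labels[hog.cluster_id].core:
            core |= mine
    return summarize_counts(proteome.genome_id, len(proteome),
                            len(clustered), len(core))


# ---------------------------------------------------------------------------
# Physicochemical statistics

#: EMBOSS-style pKa values for the ionizable groups
DEFAULT_PKA: dict[str, float] = {
    "Nterm": 8.6,
    "Cterm": 3.6,
    "C": 8.5,
    "D": 3.9,
    "E": 4.1,
    "H": 6.5,
    "K": 10.8,
    "R": 12.5,
    "Y": 10.1,
}

_POSITIVE = ("K", "R", "H")
_NEGATIVE = ("D", "E", "C", "Y")


def net_charge(aa_seq: str, ph: float,
               pka: Mapping[str, float] = DEFAULT_PKA) -> float:
    """Net charge of a protein at a given pH (Henderson–Hasselbalch)."""
    charge = 1.0 / (1.0 + 10 ** (ph - pka["Nterm"]))
    charge -= 1.0 / (1.0 + 10 ** (pka["Cterm"] - ph))
    for res in _POSITIVE:
        n = aa_seq.count(res)
        if n:
            charge += n / (1.0 + 10 ** (ph - pka[res]))
    for res in _NEGATIVE:
        n = aa_seq.count(res)
        if n:
            charge -= n / (1.0 + 10 ** (pka[res] - ph))
    return charge


def isoelectric_point(aa_seq: str,
                      pka: Mapping[str, float] = DEFAULT_PKA,
                      tol: float = 1e-4) -> float:
    """pH at which the protein's net charge is zero (bisection to ``tol``)."""
    if not aa_seq:
        raise ValueError("empty sequence")
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = (lo + hi) / 2.0
        if net_charge(aa_seq, mid, pka) > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


#: average (isotope-averaged) residue masses, Da; X uses the mean of the 20
AVERAGE_RESIDUE_MASS: dict[str, float] = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
AVERAGE_RESIDUE_MASS["X"] = sum(AVERAGE_RESIDUE_MASS.values()) / 20
WATER_MASS = 18.01524


def molecular_weight(aa_seq: str) -> float:
    """Average molecular weight in kDa (residue masses + one water)."""
    if not aa_seq:
        raise ValueError("empty sequence")
    mass = sum(AVERAGE_RESIDUE_MASS[res] for res in aa_seq) + WATER_MASS
    return mass / 1000.0


def gene_gc(nt_seq: str) -> float:
    """G+C content of a coding sequence, percent."""
    if not nt_seq:
        raise ValueError("empty sequence")
    return 100.0 * gc_fraction(nt_seq)


def class_protein_stats(
    hogs: Sequence[HOG],
    labels: Mapping[str, HOGLabel],
    proteomes: Mapping[str, Proteome],
) -> pd.DataFrame:
    """Unweighted per-protein averages of pI, MW and gene G+C per class.

    Averages are computed per protein and then averaged, so large clusters do
    not dominate small ones.
    """
    buckets: dict[str, list[tuple[float, float, Optional[float]]]] = {}
    for hog in hogs:
        cl = labels[hog.cluster_id].class_label
        for gid, pid in sorted(hog.members):
            rec = proteomes[gid][pid]
            gc = gene_gc(rec.nt_seq) if rec.nt_seq else None
            buckets.setdefault(cl, []).append(
                (isoelectric_point(rec.aa_seq), molecular_weight(rec.aa_seq), gc))
    rows = []
    for cl in sorted(buckets):
        vals = buckets[cl]
        gcs = [g for _, _, g in vals if g is not None]
        rows.append({
            "class_label": cl,
            "n_proteins": len(vals),
            "mean_pI": sum(v[0] for v in vals) / len(vals),
            "mean_mw_kda": sum(v[1] for v in vals) / len(vals),
            "mean_gene_gc_pct": sum(gcs) / len(gcs) if gcs else float("nan"),
        })
    return pd.DataFrame(rows, columns=["class_label", "n_proteins", "mean_pI",
                                       "mean_mw_kda", "mean_gene_gc_pct"])
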