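"""Bundled reference tallies from the nine-genome haloarchaeal survey.

These small tables hold the published per-genome proteome counts, the
functional-category-by-occupancy cluster matrix, and the before/after
cluster-category accounting for the nine-to-thirteen genome update of the
haloarchaeal core-proteome study.  They serve as ground truth for the report
arithmetic (percentages, conserved fractions, bookkeeping conservation) —
the pipeline itself is validated against simulated pan-genomes.
"""

from __future__ import annotations

from .annotation_stats import NO_ASSOCIATION

#: genome -> (proteome size, clustered proteins, core proteins)
NINE_GENOME_SUMMARY: dict[str, tuple[int, int, int]] = {
    "Halobacterium sp. NRC-1": (2626, 2174, 857),
    "Haloarcula marismortui": (4240, 3464, 893),
    "Natronomonas pharaonis": (2822, 2285, 847),
    "Haloquadratum walsbyi": (2626, 2108, 835),
    "Halorubrum lacusprofundi": (3913, 3166, 870),
    "Halogeometricum borinquense": (4303, 3209, 891),
    "Halomicrobium mukohataei": (3548, 2902, 858),
    "Halorhabdus utahensis": (3160, 2334, 856),
    "Haloferax volcanii": (4074, 3240, 870),
}

#: genome -> (clustered %, core %) as printed (one decimal).  The
#: *Haloarcula marismortui* core percentage is printed as 23.1 in the source
#: table but is inconsistent with its own printed counts (893/4240 = 21.1);
#: see PRINTED_PCT_INCONSISTENCIES.
NINE_GENOME_PRINTED_PCT: dict[str, tuple[float, float]] = {
    "Halobacterium sp. NRC-1": (82.8, 32.6),
    "Haloarcula marismortui": (81.7, 23.1),
    "Natronomonas pharaonis": (81.0, 30.0),
    "Haloquadratum walsbyi": (80.3, 31.8),
    "Halorubrum lacusprofundi": (80.9, 22.2),
    "Halogeometricum borinquense": (74.6, 20.7),
    "Halomicrobium mukohataei": (81.8, 24.2),
    "Halorhabdus utahensis": (73.9, 27.1),
    "Haloferax volcanii": (79.5, 21.4),
}

#: printed percentage cells that contradict their own printed counts;
#: maps (genome, column) -> the value the printed counts actually give
PRINTED_PCT_INCONSISTENCIES: dict[tuple[str, str], float] = {
    ("Haloarcula marismortui", "core_pct"): 21.1,
}

#: occupancy columns of the functional matrix
FUNCTIONAL_MATRIX_OCCUPANCIES = list(range(2, 10))

#: functional category -> cluster counts at occupancy 2..9 (multi-counted:
#: a cluster mapping to several categories appears in each)
FUNCTIONAL_MATRIX_CELLS: dict[str, list[int]] = {
    NO_ASSOCIATION: [1276, 650, 375, 215, 164, 140, 168, 89],
    "Translation, ribosomal structure and biogenesis": [2, 4, 2, 2, 1, 4, 10, 108],
    "RNA processing and modification": [0, 0, 0, 1, 0, 0, 0, 0],
    "Transcription": [7, 5, 4, 6, 3, 5, 10, 49],
    "Replication, recombination and repair": [11, 4, 6, 5, 6, 2, 11, 57],
    "Chromatin structure and dynamics": [0, 0, 0, 0, 0, 0, 0, 3],
    "Cell cycle control, cell division, chromosome partitioning": [4, 1, 0, 1, 0, 2, 3, 4],
    "Defense mechanisms": [6, 2, 2, 1, 0, 2, 1, 5],
    "Signal transduction mechanisms": [7, 2, 7, 2, 2, 2, 8, 8],
    "Cell wall/membrane/envelope biogenesis": [5, 7, 3, 0, 2, 1, 11, 13],
    "Cell motility": [2, 2, 3, 0, 2, 2, 12, 1],
    "Intracellular trafficking, secretion, and vesicular transport": [0, 1, 0, 1, 0, 1, 6, 14],
    "Posttranslational modification, protein turnover, assembly": [2, 2, 3, 2, 5, 5, 4, 44],
    "Energy production and conversion": [3, 4, 9, 6, 7, 12, 20, 51],
    "Carbohydrate transport and metabolism": [7, 0, 2, 5, 3, 3, 12, 17],
    "Amino acid transport and metabolism": [7, 10, 8, 5, 13, 13, 12, 66],
    "Nucleotide transport and metabolism": [1, 2, 1, 1, 0, 3, 3, 46],
    "Coenzyme transport and metabolism": [2, 0, 0, 0, 4, 10, 24, 51],
    "Lipid transport and metabolism": [1, 2, 0, 2, 8, 14, 9, 16],
    "Inorganic ion transport and metabolism": [4, 7, 3, 5, 18, 16, 11, 22],
    "Secondary metabolites biosynthesis, transport and catabolism": [1, 3, 2, 2, 4, 3, 3, 14],
    "General function prediction only": [11, 9, 12, 16, 17, 22, 36, 114],
    "Function unknown": [7, 8, 5, 4, 9, 10, 16, 76],
}

#: category -> (initial, removed, added, final) across the 9 -> 13 genome
#: reclassification
BOOKKEEPING_COUNTS: dict[str, tuple[int, int, int, int]] = {
    "cHOGs": (799, 15, 0, 784),
    "cHOGs_prok_ref_only": (288, 6, 0, 282),
    "cHOGs_prok_and_euk_ref": (422, 3, 0, 419),
    "ucHOGs": (89, 6, 0, 83),
    "nucHOGs": (29, 1, 0, 28),
    "tucHOGs": (60, 5, 0, 55),
    "aHOGs": (3656, 0, 15, 3671),
    "aHOGs_prok_ref_only": (409, 0, 6, 415),
    "aHOGs_prok_and_euk_ref": (259, 0, 3, 262),
    "aHOGs_unassociated": (2988, 0, 6, 2994),
}

#: headline cluster totals of the survey
TOTAL_PROTEINS = 31312
TOTAL_HOGS = 4455
N_CHOGS_9 = 799
N_UCHOGS_9 = 89
N_CHOG_DUAL_ASSOCIATED = 422
N_CHOG_PROK_ONLY = 288
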