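"""Best-reciprocal-hit orthology and cluster (HOG) construction.

Orthologous groups are built in three stages: (1) all-vs-all local alignment
between each ordered genome pair gives a best-hit table per direction; (2)
mutual best hits become candidate ortholog edges, each annotated with the
randomized global-alignment significance of the pair; (3) edges passing the
cluster confidence level form a graph whose multi-genome connected components
are the orthologous groups.

Connected components (rather than triangle merging) are used deliberately:
they admit two-genome clusters, which dominate the occupancy distribution of
real pan-genomes.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np

from .align import (
    CLUSTER_CONFIDENCE,
    DEFAULT_N_SHUFFLES,
    ScoringScheme,
    SignificanceResult,
    global_align,
    local_score,
    randomized_significance,
)
from .io_formats import Proteome

#: minimum raw local-alignment score for best-hit candidacy
DEFAULT_MIN_SCORE = 50.0


@dataclass
class BestHitTable:
    """Directed best hits from every query protein to one target genome."""

    query_genome: str
    target_genome: str
    scheme_key: tuple
    hits: dict[str, tuple[str, float]] = field(default_factory=dict)

    def best(self, protein_id: str) -> Optional[tuple[str, float]]:
        return self.hits.get(protein_id)


@dataclass
class BRHEdge:
    """A mutual best hit between two genomes, with its significance call.

    Protein a sorts lexicographically before protein b.
    """

    protein_a: str
    protein_b: str
    genome_a: str
    genome_b: str
    score: float
    significance: SignificanceResult
    percent_identity: float


@dataclass
class HOG:
    """One orthologous group: members, genome occupancy, identity summary."""

    cluster_id: str
    members: frozenset[tuple[str, str]]  # (genome_id, protein_id)
    occupancy: int
    mean_identity: float
    min_identity: float
    max_identity: float
    edges: list[BRHEdge] = field(default_factory=list)

    @property
    def protein_ids(self) -> set[str]:
        return {pid for _, pid in self.members}

    @property
    def genome_ids(self) -> set[str]:
        return {gid for gid, _ in self.members}

    def members_of(self, genome_id: str) -> list[str]:
        return sorted(pid for gid, pid in self.members if gid == genome_id)


def pair_rng(seed: int, *tokens: str) -> np.random.Generator:
    """Deterministic, order-independent RNG for a labelled computation.

    Seeding from a CRC over the sorted tokens makes per-pair randomization
    reproducible regardless of genome input order.
    """
    digest = zlib.crc32("\x1f".join(sorted(tokens)).encode()) & 0x7FFFFFFF
    return np.random.default_rng((seed & 0x7FFFFFFF, digest))


def best_hits(
    query: Proteome,
    target: Proteome,
    scheme: ScoringScheme,
    min_score: float = DEFAULT_MIN_SCORE,
) -> BestHitTable:
    """All-vs-all local alignment of ``query`` proteins against ``target``.

    Keeps, per query protein, the maximal-scoring target at or above
    ``min_score``; ties break to the lexicographically smallest target id.
    """
    if query.genome_id == target.genome_id:
        raise ValueError("best_hits requires two distinct genomes")
    table = BestHitTable(query_genome=query.genome_id,
                         target_genome=target.genome_id,
                         scheme_key=scheme.key())
    targets = sorted(target.records, key=lambda r: r.protein_id)
    for q in query.records:
        best_id, best_score = None, min_score
        for t in targets:
            s = local_score(q.aa_seq, t.aa_seq, scheme)
            if s > best_score or (s == best_score and best_id is None and s >= min_score):
                best_id, best_score = t.protein_id, s
        if best_id is not None:
            table.hits[q.protein_id] = (best_id, best_score)
    return table


def reciprocal_best_hits(
    forward: BestHitTable,
    reverse: BestHitTable,
    proteome_a: Proteome,
    proteome_b: Proteome,
    scheme: ScoringScheme,
    n_shuffles: int = DEFAULT_N_SHUFFLES,
    seed: int = 0,
) -> list[BRHEdge]:
    """Mutual best hits between two genomes, annotated with significance.

    Each surviving pair is re-aligned globally against ``n_shuffles``
    composition-preserved permutations to attach a Z-score/confidence.
    """
    if forward.scheme_key != reverse.scheme_key:
        raise ValueError("best-hit tables built with different scoring schemes")
    if (forward.query_genome != reverse.target_genome
            or forward.target_genome != reverse.query_genome):
        raise ValueError("best-hit tables do not describe mirrored genome pairs")
    edges: list[BRHEdge] = []
    for qid, (tid, score) in forward.hits.items():
        back = reverse.hits.get(tid)
        if back is None or back[0] != qid:
            continue
        seq_a = proteome_a[qid].aa_seq
        seq_b = proteome_b[tid].aa_seq
        id_a, id_b = qid, tid
        gen_a, gen_b = forward.query_genome, forward.target_genome
        if id_b < id_a:
            id_a, id_b = id_b, id_a
            gen_a, gen_b = gen_b, gen_a
            seq_a, seq_b = seq_b, seq_a
        rng = pair_rng(seed, id_a, id_b)
        sig = randomized_significance(seq_a, seq_b, scheme,
                                      n_shuffles=n_shuffles, rng=rng)
        identity = global_align(seq_a, seq_b, scheme).percent_identity
        edges.append(BRHEdge(protein_a=id_a, protein_b=id_b,
                             genome_a=gen_a, genome_b=gen_b,
                             score=score, significance=sig,
                             percent_identity=identity))
    edges.sort(key=lambda e: (e.protein_a, e.protein_b))
    return edges


def build_hogs(
    edges: Iterable[BRHEdge],
    confidence_threshold: float = CLUSTER_CONFIDENCE,
) -> list[HOG]:
    """Cluster validated reciprocal-best-hit edges into orthologous groups.

    Edges at or below ``confidence_threshold`` are discarded; connected
    components of the surviving graph with members from at least two genomes
    become clusters, numbered by their smallest member protein id.
    """
    graph = nx.Graph()
    for edge in edges:
        if not edge.significance.significant(confidence_threshold):
            continue
        graph.add_node((edge.genome_a, edge.protein_a))
        graph.add_node((edge.genome_b, edge.protein_b))
        graph.add_edge((edge.genome_a, edge.protein_a),
                       (edge.genome_b, edge.protein_b), data=edge)
    components = []
    for comp in nx.connected_components(graph):
        genomes = {gid for gid, _ in comp}
        if len(genomes) < 2 or len(comp) < 2:
            continue
        components.append(comp)
    components.sort(key=lambda comp: min(pid for _, pid in comp))
    hogs = []
    for i, comp in enumerate(components, start=1):
        comp_edges = [d["data"] for _, _, d in graph.subgraph(comp).edges(data=True)]
        identities = [e.percent_identity for e in comp_edges]
        hogs.append(HOG(
            cluster_id=f"HOG{i:04d}",
            members=frozenset(comp),
            occupancy=len({gid for gid, _ in comp}),
            mean_identity=float(np.mean(identities)),
            min_identity=float(np.min(identities)),
            max_identity=float(np.max(identities)),
            edges=sorted(comp_edges, key=lambda e: (e.protein_a, e.protein_b)),
        ))
    return hogs


def all_vs_all_brh(
    proteomes: Sequence[Proteome],
    scheme: ScoringScheme,
    min_score: float = DEFAULT_MIN_SCORE,
    n_shuffles: int = DEFAULT_N_SHUFFLES,
    seed: int = 0,
) -> list[BRHEdge]:
    """Reciprocal best hits over every unordered genome pair."""
    by_id = {p.genome_id: p for p in sorted(proteomes, key=lambda p: p.genome_id)}
    genome_ids = sorted(by_id)
    edges: list[BRHEdge] = []
    for i, ga in enumerate(genome_ids):
        for gb in genome_ids[i + 1:]:
            fwd = best_hits(by_id[ga], by_id[gb], scheme, min_score)
            rev = best_hits(by_id[gb], by_id[ga], scheme, min_score)
            edges.extend(reciprocal_best_hits(fwd, rev, by_id[ga], by_id[gb],
                                              scheme, n_shuffles=n_shuffles,
                                              seed=seed))
    edges.sort(key=lambda e: (e.protein_a, e.protein_b))
    return edges


def occupancy_histogram(hogs: Iterable[HOG], n_genomes: int) -> dict[int, int]:
    """Cluster counts per genome occupancy, for occupancy 2..n_genomes."""
    hist = {k: 0 for k in range(2, n_genomes + 1)}
    for hog in hogs:
        hist[hog.occupancy] += 1
    return hist


def clustered_fraction(proteome: Proteome, hogs: Iterable[HOG]) -> float:
    """Fraction of a genome's proteins that belong to any cluster."""
    clustered = set()
    for hog in hogs:
        clustered.update(pid for gid, pid in hog.members
                         if gid == proteome.genome_id)
    return len(clustered) / len(proteome)
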