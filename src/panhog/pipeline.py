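"""End-to-end orchestration: read → cluster → classify → screen → report.

The stage order is fixed: proteomes are read, all-vs-all best hits and
reciprocal best hits computed over the base genomes, significance-validated
edges clustered, clusters partitioned into core/accessory, associated with
the reference tiers, screened against the added genomes and then against the
outgroup database, and finally summarized.  Every run writes a manifest
(config hash, seed, version) so results can be reproduced bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import __version__
from .align import CLUSTER_CONFIDENCE, DEFAULT_N_SHUFFLES, HOMOLOG_CONFIDENCE, ScoringScheme
from .annotation_stats import (
    class_protein_stats,
    conserved_fraction_by_class,
    functional_matrix,
    location_summary,
    proteome_summary,
)
from .classification import (
    DEFAULT_OUTGROUP_MIN_SCORE,
    BookkeepingSummary,
    HOGLabel,
    associate_reference,
    bookkeeping,
    classify_core,
    screen_added_genomes,
    screen_outgroup,
)
from .io_formats import (
    Proteome,
    ReferenceAssociation,
    read_associations,
    read_proteome,
    write_cluster_table,
)
from .orthology import (
    DEFAULT_MIN_SCORE,
    HOG,
    all_vs_all_brh,
    build_hogs,
    occupancy_histogram,
)

logger = logging.getLogger("panhog")


class PipelineError(RuntimeError):
    """A stage failed; the message carries the stage name and context."""


@dataclass
class PipelineConfig:
    """File-based pipeline configuration (one YAML document)."""

    proteomes: list[dict]  # [{genome_id, fasta, annotation?}, ...]
    added_proteomes: list[dict] = field(default_factory=list)
    associations: Optional[str] = None
    outgroup: Optional[str] = None
    reference_genome: Optional[str] = None
    gap_open: float = 11.0
    gap_extend: float = 1.0
    min_score: float = DEFAULT_MIN_SCORE
    outgroup_min_score: float = DEFAULT_OUTGROUP_MIN_SCORE
    n_shuffles: int = DEFAULT_N_SHUFFLES
    cluster_confidence: float = CLUSTER_CONFIDENCE
    outgroup_confidence: float = HOMOLOG_CONFIDENCE
    seed: int = 0
    outdir: str = "panhog_out"

    def __post_init__(self) -> None:
        for name in ("cluster_confidence", "outgroup_confidence"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle)
        return cls(**data)

    def config_hash(self) -> str:
        payload = yaml.safe_dump(self.__dict__, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    hogs: list[HOG]
    labels_initial: dict[str, HOGLabel]
    labels_final: dict[str, HOGLabel]
    removed_by_added_screen: list[str]
    tuchogs: list[str]
    nuchogs: list[str]
    bookkeeping: BookkeepingSummary
    occupancy: dict[int, int]
    functional: pd.DataFrame
    conserved_fractions: dict
    locations: pd.DataFrame
    summaries: pd.DataFrame
    protein_stats: pd.DataFrame

    def check_partition_invariants(self) -> None:
        """Assert the class-partition identities that must hold on every run."""
        labels = self.labels_final
        chog = {c for c, l in labels.items() if l.core}
        ahog = {c for c, l in labels.items() if not l.core}
        uchog = {c for c, l in labels.items() if l.core and l.unique}
        tuc = {c for c, l in labels.items() if l.unique_kind == "truly"}
        nuc = {c for c, l in labels.items() if l.unique_kind == "nearly"}
        assert tuc | nuc == uchog and not (tuc & nuc), \
            "tucHOG and nucHOG must partition ucHOG"
        assert uchog <= chog, "ucHOG must be a subset of cHOG"
        assert chog | ahog == set(labels) and not (chog & ahog), \
            "cHOG and aHOG must partition all clusters"
        self.bookkeeping.validate()


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - re-tag with stage name
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %-18s %6.1f s", name, time.perf_counter() - t0)
            return out
        return wrapper
    return deco


def analyze_pangenome(
    base: Sequence[Proteome],
    added: Sequence[Proteome] = (),
    outgroup: Optional[Proteome] = None,
    associations: Sequence[ReferenceAssociation] = (),
    reference_genome_id: Optional[str] = None,
    scheme: Optional[ScoringScheme] = None,
    min_score: float = DEFAULT_MIN_SCORE,
    outgroup_min_score: float = DEFAULT_OUTGROUP_MIN_SCORE,
    n_shuffles: int = DEFAULT_N_SHUFFLES,
    cluster_confidence: float = CLUSTER_CONFIDENCE,
    outgroup_confidence: float = HOMOLOG_CONFIDENCE,
    seed: int = 0,
) -> PipelineResult:
    """Run the full analysis on in-memory proteomes."""
    scheme = scheme or ScoringScheme()
    if reference_genome_id is None:
        reference_genome_id = sorted(p.genome_id for p in base)[0]
    by_id = {p.genome_id: p for p in base}

    edges = _stage("best_reciprocal_hits")(all_vs_all_brh)(
        base, scheme, min_score=min_score, n_shuffles=n_shuffles, seed=seed)
    hogs = _stage("build_hogs")(build_hogs)(edges, cluster_confidence)
    labels = _stage("classify_core")(classify_core)(hogs, list(by_id))
    labels = _stage("associate_reference")(associate_reference)(
        hogs, associations, reference_genome_id, labels)
    labels_initial = {cid: lab for cid, lab in labels.items()}

    if added:
        labels, removed = _stage("screen_added_genomes")(screen_added_genomes)(
            hogs, labels, added, by_id, scheme, min_score=min_score,
            confidence=cluster_confidence, n_shuffles=n_shuffles, seed=seed)
    else:
        removed = []
    if outgroup is not None and len(outgroup.records) > 0:
        labels, tuc, nuc = _stage("screen_outgroup")(screen_outgroup)(
            hogs, labels, outgroup, by_id, scheme,
            min_score=outgroup_min_score,
            confidence=outgroup_confidence, n_shuffles=n_shuffles, seed=seed)
    else:
        # vacuous screen: nothing can be a homolog, every candidate is truly unique
        tuc, nuc = [], []
        labels = {cid: replace(lab) for cid, lab in labels.items()}
        for lab in labels.values():
            if lab.core and lab.unique:
                lab.unique_kind = "truly"
                tuc.append(lab.cluster_id)

    books = _stage("bookkeeping")(bookkeeping)(labels_initial, labels)
    occupancy = occupancy_histogram(hogs, n_genomes=len(by_id))
    functional = _stage("functional_matrix")(functional_matrix)(
        hogs, labels, associations, reference_genome_id, n_genomes=len(by_id))
    fractions = conserved_fraction_by_class(functional)
    locations = location_summary(hogs, labels, by_id)
    summaries = pd.DataFrame([
        vars(proteome_summary(p, hogs, labels))
        for p in sorted(base, key=lambda p: p.genome_id)
    ])
    stats = _stage("protein_stats")(class_protein_stats)(hogs, labels, by_id)

    result = PipelineResult(
        hogs=hogs, labels_initial=labels_initial, labels_final=labels,
        removed_by_added_screen=removed, tuchogs=sorted(tuc),
        nuchogs=sorted(nuc), bookkeeping=books, occupancy=occupancy,
        functional=functional, conserved_fractions=fractions,
        locations=locations, summaries=summaries, protein_stats=stats)
    result.check_partition_invariants()
    return result


def write_results(result: PipelineResult, outdir: str | Path,
                  base: Sequence[Proteome],
                  associations: Sequence[ReferenceAssociation] = (),
                  config: Optional[PipelineConfig] = None) -> None:
    """Write all tabular outputs plus the run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    by_id = {p.genome_id: p for p in base}
    write_cluster_table(result.hogs, outdir / "clusters.tsv",
                        labels=result.labels_final, proteomes=by_id,
                        associations=associations)
    result.bookkeeping.to_frame().to_csv(outdir / "bookkeeping.tsv", sep="\t")
    result.functional.to_csv(outdir / "functional_matrix.tsv", sep="\t")
    result.locations.to_csv(outdir / "location_summary.tsv", sep="\t", index=False)
    result.summaries.to_csv(outdir / "proteome_summaries.tsv", sep="\t", index=False)
    result.protein_stats.to_csv(outdir / "protein_stats.tsv", sep="\t", index=False)
    pd.DataFrame(sorted(result.occupancy.items()),
                 columns=["occupancy", "n_clusters"]).to_csv(
        outdir / "occupancy_histogram.tsv", sep="\t", index=False)
    manifest = {
        "version": __version__,
        "seed": config.seed if config else None,
        "config_hash": config.config_hash() if config else None,
        "n_clusters": len(result.hogs),
        "conserved_fractions": result.conserved_fractions,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """File-driven entry point: load inputs per the config, analyze, write."""
    def load(entry: dict) -> Proteome:
        return read_proteome(entry["fasta"], entry.get("annotation"),
                             genome_id=entry.get("genome_id"))

    try:
        base = [load(e) for e in config.proteomes]
        added = [load(e) for e in config.added_proteomes]
        outgroup = read_proteome(config.outgroup) if config.outgroup else None
        associations = (read_associations(config.associations)
                        if config.associations else [])
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage 'read_inputs' failed: {exc}") from exc

    scheme = ScoringScheme(gap_open=config.gap_open,
                           gap_extend=config.gap_extend)
    result = analyze_pangenome(
        base, added, outgroup, associations,
        reference_genome_id=config.reference_genome,
        scheme=scheme, min_score=config.min_score,
        outgroup_min_score=config.outgroup_min_score,
        n_shuffles=config.n_shuffles,
        cluster_confidence=config.cluster_confidence,
        outgroup_confidence=config.outgroup_confidence,
        seed=config.seed)
    write_results(result, config.outdir, base, associations, config)
    return result
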