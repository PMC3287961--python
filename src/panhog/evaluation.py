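"""Scoring pipeline output against a simulation's planted truth.

A planted family counts as *recovered* when some cluster's member set equals
exactly the family's members across the base genomes; recovery of class
labels is then read off the final labelling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from scipy.stats import chisquare

from .pipeline import PipelineResult
from .synthetic_data import SimulatedPangenome


@dataclass
class RecoveryReport:
    n_core_planted: int
    n_core_recovered: int          # single cHOG, exact members, correct occupancy
    n_unique_true_planted: int
    n_unique_true_as_tuc: int
    n_unique_decoy_planted: int
    n_unique_decoy_as_nuc: int
    n_accessory_planted: int
    n_accessory_recovered: int     # single aHOG with planted occupancy
    planted_occupancy: dict[int, int]
    recovered_occupancy: dict[int, int]
    occupancy_chi2_pvalue: Optional[float]

    @property
    def core_recovery(self) -> float:
        return self.n_core_recovered / self.n_core_planted if self.n_core_planted else 1.0

    @property
    def unique_true_recovery(self) -> float:
        return (self.n_unique_true_as_tuc / self.n_unique_true_planted
                if self.n_unique_true_planted else 1.0)

    @property
    def unique_decoy_recovery(self) -> float:
        return (self.n_unique_decoy_as_nuc / self.n_unique_decoy_planted
                if self.n_unique_decoy_planted else 1.0)

    @property
    def accessory_recovery(self) -> float:
        return (self.n_accessory_recovered / self.n_accessory_planted
                if self.n_accessory_planted else 1.0)


def score_recovery(sim: SimulatedPangenome, result: PipelineResult) -> RecoveryReport:
    base_ids = set(sim.config.base_genome_ids)
    cluster_members = {h.cluster_id: frozenset(h.members) for h in result.hogs}
    members_to_cluster = {m: c for c, m in cluster_members.items()}
    occupancy = {h.cluster_id: h.occupancy for h in result.hogs}

    def find_cluster(fam) -> Optional[str]:
        planted = frozenset(
            (gid, pid) for gid, pids in fam.members.items()
            if gid in base_ids for pid in pids)
        return members_to_cluster.get(planted)

    core_kinds = ("core", "unique_true", "unique_decoy")
    n_core = n_core_ok = 0
    planted_occ: dict[int, int] = {}
    for fam in sim.truth.of_kind(*core_kinds, "accessory"):
        occ = sum(1 for gid in fam.members if gid in base_ids)
        planted_occ[occ] = planted_occ.get(occ, 0) + 1
    for fam in sim.truth.of_kind(*core_kinds):
        n_core += 1
        cid = find_cluster(fam)
        if (cid is not None and result.labels_final[cid].core
                and occupancy[cid] == len(base_ids)):
            n_core_ok += 1

    n_tu = n_tu_ok = 0
    for fam in sim.truth.of_kind("unique_true"):
        n_tu += 1
        cid = find_cluster(fam)
        if cid is not None and result.labels_final[cid].class_label == "tucHOG":
            n_tu_ok += 1
    n_de = n_de_ok = 0
    for fam in sim.truth.of_kind("unique_decoy"):
        n_de += 1
        cid = find_cluster(fam)
        if cid is not None and result.labels_final[cid].class_label == "nucHOG":
            n_de_ok += 1

    n_acc = n_acc_ok = 0
    for fam in sim.truth.of_kind("accessory"):
        n_acc += 1
        cid = find_cluster(fam)
        planted = sum(1 for gid in fam.members if gid in base_ids)
        if (cid is not None and not result.labels_final[cid].core
                and occupancy[cid] == planted):
            n_acc_ok += 1

    recovered_occ = dict(result.occupancy)
    pvalue = _occupancy_pvalue(planted_occ, recovered_occ)
    return RecoveryReport(
        n_core_planted=n_core, n_core_recovered=n_core_ok,
        n_unique_true_planted=n_tu, n_unique_true_as_tuc=n_tu_ok,
        n_unique_decoy_planted=n_de, n_unique_decoy_as_nuc=n_de_ok,
        n_accessory_planted=n_acc, n_accessory_recovered=n_acc_ok,
        planted_occupancy=dict(sorted(planted_occ.items())),
        recovered_occupancy=recovered_occ,
        occupancy_chi2_pvalue=pvalue)


def _occupancy_pvalue(planted: dict[int, int],
                      recovered: dict[int, int]) -> Optional[float]:
    """Goodness of fit of the recovered occupancy histogram to the planted
    one (cells with planted mass only; recovered mass outside them fails)."""
    support = [k for k, v in sorted(planted.items()) if v > 0]
    if not support:
        return None
    stray = sum(v for k, v in recovered.items() if k not in support and v > 0)
    if stray:
        return 0.0
    observed = [recovered.get(k, 0) for k in support]
    total_obs = sum(observed)
    if total_obs == 0:
        return 0.0
    expected = [planted[k] / sum(planted.values()) * total_obs for k in support]
    return float(chisquare(observed, f_exp=expected).pvalue)
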