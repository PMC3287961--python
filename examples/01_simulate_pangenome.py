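"""Generate a small synthetic pan-genome and inspect its planted structure.

The simulator plants core families (present in every genome), accessory
families (present in a subset, bimodal occupancy), clade-unique families
(absent from the outgroup; some are decoys with a planted outgroup homolog)
and per-genome singletons, and returns a truth table for scoring recovery.
"""

from panhog import SimulationConfig, simulate_pangenome

config = SimulationConfig(n_base_genomes=4, n_added_genomes=1,
                          n_core_families=10, n_accessory_families=6,
                          n_unique_true=2, n_unique_decoy=1,
                          n_singletons_per_genome=4, n_outgroup_random=30,
                          seed=1)
sim = simulate_pangenome(config)

print("base proteomes:", {p.genome_id: len(p) for p in sim.base})
print("added proteomes:", {p.genome_id: len(p) for p in sim.added})
print("outgroup database:", len(sim.outgroup.records), "proteins")
kinds = {}
for fam in sim.truth.families.values():
    kinds[fam.kind] = kinds.get(fam.kind, 0) + 1
print("planted families by kind:", dict(sorted(kinds.items())))
# each count is one planted gene family; 'unique_decoy' families carry a
# homolog in the outgroup database so the signature screen can reject them
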