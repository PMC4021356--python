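"""Extract a three-seed gene network from a simulated multi-species interactome.

Builds a five-species interactome with a planted triad (12 bivalent and 6
univalent interactors wired to the seeds CISD2/PPT1/CLN3), extracts the
seed neighborhood, and prints the valence summary and evidence mix.
"""

from seednet.interactome import count_valence, extract_seed_network, summarize_evidence
from seednet.synthetic import InteractomeSimConfig, PlantedTriad, interactome_objects

TRIAD = ("CISD2", "PPT1", "CLN3")

config = InteractomeSimConfig(
    genes_per_species=500,
    orthology_coverage=0.8,
    edge_prob_by_evidence={ev: 0.0005 for ev in (
        "coexpression", "genetic", "physical", "shared_domain", "colocalization")},
    planted_triad=PlantedTriad(TRIAD, n_bivalent=12, n_univalent=6),
    rng_seed=1,
)
db, orthology = interactome_objects(config)
network = extract_seed_network(db, TRIAD, orthology, k_augment=15)
valence = count_valence(network)

print(f"database edges: {len(db)}")
print(f"network members (seeds + interactors + connectors): {valence.n_total}")
print(f"genes interacting with >= 1 seed: {valence.n_interact_ge1}")
print(f"bivalent interactors (exactly 2 seeds): {valence.n_exactly2}")
print(f"trivalent interactors (all 3 seeds): {valence.n_exactly3}")
print("evidence fractions among retained edges:")
for ev, frac in summarize_evidence(network).items():
    print(f"  {ev:>13s}: {frac:.3f}")
print()
print("The bivalent count is the key multivalency statistic: the 12 planted")
print("bivalent genes are recovered exactly; extra >=1-seed genes come from")
print("random background edges.")
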