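"""Simulate the seven-population demonstration cohort.

Writes genotypes, population map and ground-truth autozygous tracts to
results/cohort/.  The designed FROH ordering mirrors a multi-breed goat
panel: cashmere IMC lowest, wild IBE extreme.
"""

from rohscan.cohorts import POPULATION_DESIGN, simulate_goatlike_cohort, write_cohort

SEED = 20_240_601 % (2**31 - 1)

gm, pop_map, tracts = simulate_goatlike_cohort(SEED)
geno, popmap, truth = write_cohort(gm, pop_map, tracts, "results/cohort")

print(f"cohort: {gm.n_samples} samples x {gm.n_variants} SNPs on {len(gm.chromosomes())} autosomes")
print(f"planted {len(tracts)} autozygous tracts")
print("designed FROH:", ", ".join(f"{p}={f}" for p, f in POPULATION_DESIGN.items()))
print(f"wrote {geno}, {popmap}, {truth}")
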