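"""Generate a synthetic bead-experiment measurement table and inspect it.

Two fluorescence-tagged E. coli strains are co-encapsulated at a 1:1 ratio
into 240 nL agarose beads at a mean inoculum of 2 cells/bead; every founder
grows one colony, sharing the bead's nutrient budget.
"""

import beadcolony as bc

config = bc.ExperimentConfig(n_beads=200, mean_inoculum=2.0, seed=7)
table = bc.generate_experiment(config)
bc.write_table(table, "scratch_table.csv")

n_colonies = table.groupby(["bead_id", "colony_id"]).ngroups
finals = table[table.time_h == 12.0]
print(f"{config.n_beads} beads -> {n_colonies} colonies, {len(table)} rows")
print(f"mean colony area at 12 h: {finals.area_um2.mean():.0f} um^2 "
      f"(B: {finals[finals.strain == 'B'].area_um2.mean():.0f}, "
      f"Y: {finals[finals.strain == 'Y'].area_um2.mean():.0f})")
# Y colonies end larger than B because strain Y grows faster and to a larger
# capacity; per-colony areas are thousands of um^2 at stationary phase.
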