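"""Enumerate the theoretical crosslink space of a grouped peptide library.

Builds a 43-peptide acidic-chemistry library, once split into reaction
groups and once pooled into a single vial, and counts the crosslink
combinations that could form in each setup.
"""

from xlfdr import SimulationConfig, enumerate_theoretical, generate_library

# grouped: peptides crosslinked in vials of 6-10, so only within-group pairs form
grouped_lib = generate_library(SimulationConfig(
    n_peptides=43, chemistry="acidic", seed=1))
grouped = enumerate_theoretical(grouped_lib, mode="grouped")

# pooled: all 43 peptides in one vial -> every unordered pair, self-pairs included
pooled_lib = generate_library(SimulationConfig(
    n_peptides=43, group_sizes=[43], chemistry="acidic", seed=1))
pooled = enumerate_theoretical(pooled_lib, mode="pooled")

print(f"grouped ({len(grouped_lib.groups)} groups): {len(grouped)} combinations")
print(f"pooled  (1 group):  {len(pooled)} combinations  "
      f"[= 43*44/2, counting homeotypic self-pairs]")
print(f"pooled link classes: {pooled.counts}")

# The pooled count is the maximum number of true links the library can
# produce; grouping trades combinations for the ability to flag any
# cross-group identification as a known false positive.
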