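"""Design a reduced representation library in silico.

Generates a small two-class genome, digests it with AluI, selects the
125-200 bp gel fraction and reports the genome fraction and the sequencing
depth a fixed number of read bases would achieve on it.
"""

from rrlchip.rrl_design import ALU_I, SizeWindow, digest, expected_depth, select_fraction
from rrlchip.synthetic_data import generate_genome

genome = generate_genome({"macro": [400_000], "micro": [40_000, 40_000]}, seed=1)
inventory = digest(genome, ALU_I)
window = SizeWindow(125, 200)
bed, selected_bp, fraction = select_fraction(inventory, window)

lengths = inventory.lengths()
print(f"genome: {genome.total_bp:,} bp in {len(genome.chromosomes)} chromosomes")
print(f"AluI fragments: {len(lengths):,} (mean length {sum(lengths)/len(lengths):.0f} bp)")
print(f"selected {len(bed):,} fragments of {window.min_bp}-{window.max_bp} bp")
print(f"selected fraction: {selected_bp:,} bp = {100*fraction:.2f}% of the genome")
print(f"depth from 15 Mb of sequence: {expected_depth(selected_bp, 15_000_000):.0f}x")
# The selected fraction is the part of the genome the pooled libraries
# sequence deeply; a few percent at tens-fold depth is the design point.
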