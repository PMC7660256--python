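"""Rebuild the recognition consensus from the packaged site sequences.

Tallies a 4 x 17 count matrix over the 27 printed site sequences,
reports per-position information content, and derives a majority-rule
degenerate consensus. The fully conserved core GGTnnnACC emerges even
though the outer arm positions degenerate.
"""

from regulonscan import build_matrix, derive_consensus, load_binding_sites

df = load_binding_sites()
seqs = [s.upper() for s in df.site_sequence.dropna()]
print(f"{len(seqs)} aligned 17-bp sites")

matrix = build_matrix(seqs)
consensus = derive_consensus(matrix, majority_threshold=0.75)
print(f"majority consensus (>=75 %): {consensus}")

ic = matrix.information_content
print("per-position information content (bits):")
print("  " + " ".join(f"{x:.2f}" for x in ic))
print(f"core positions 5-7:   {consensus[4:7]}")
print(f"core positions 11-13: {consensus[10:13]}")

# Positions with high information content cluster in the two trinucleotide
# half-sites; the spacer and outer positions carry little information.
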