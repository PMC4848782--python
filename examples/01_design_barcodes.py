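"""Design a cell-barcode set under the standard constraints.

Six-nucleotide barcodes, every pair at Hamming distance >= 2 (so one
sequencing error can never switch a read to another cell), GC between
33% and 67%, and no terminal T.
"""

from celseq2pipe import design_barcodes, gc_percent, hamming_distance

bset = design_barcodes(length=6, min_distance=2, gc_bounds=(33, 67), forbidden_last={"T"})
pairs = [(a, b) for i, a in enumerate(bset.barcodes) for b in bset.barcodes[i + 1 :]]

print(f"designed barcodes : {len(bset)}")
print(f"min pairwise dist : {min(hamming_distance(a, b) for a, b in pairs)}")
print(f"GC range          : {min(map(gc_percent, bset)):.1f}% - {max(map(gc_percent, bset)):.1f}%")
print(f"first five        : {', '.join(bset.barcodes[:5])}")
# Several hundred barcodes satisfy the constraints, far more than the 96
# or 168 wells of a typical plate layout; truncate with max_count=96.
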