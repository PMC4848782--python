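"""Count UMI-deduplicated molecules and correct for UMI collisions.

Reads are assigned to genes with strand-specific union semantics, then
collapsed to distinct UMIs per (cell, gene).  Because two molecules can
draw the same 6-nt UMI, distinct-UMI counts undershoot molecule counts;
the occupancy estimate ln(1 - k/K)/ln(1 - 1/K) with K = 4^6 undoes this.
"""

import tempfile
from pathlib import Path

from celseq2pipe import FeatureModel, SimConfig, count_run, simulate_run, umis_to_molecules

work = Path(tempfile.mkdtemp())
run = simulate_run(
    SimConfig(n_cells=3, n_genes=30, n_spikeins=5, capture_efficiency=1.0, seed=2),
    work / "sim",
)
model = FeatureModel.from_gtf(run.annotation_gtf)
matrix, report = count_run(run.alignments_sam, model)

print(f"reads assigned to genes  : {report.assigned} of {report.total}")
print(f"matrix shape             : {len(matrix.genes)} genes x {len(matrix.cells)} cells")
truth = run.truth.distinct_umis
got = matrix.umi_counts.reindex(index=run.truth.feature_ids, columns=run.truth.cell_barcodes)
print(f"matches simulated truth  : {got.equals(truth)}")
print(f"collision correction     : 2048 distinct UMIs of 4096 -> "
      f"{umis_to_molecules(2048, 4096):.1f} molecules")
# At half-full UMI space the corrected estimate is ~39% above the raw
# distinct count — the size of the error naive UMI counting would make.
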