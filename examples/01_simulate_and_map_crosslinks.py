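"""Simulate an iCLIP experiment and map crosslink sites.

Generates a toy genome with planted protein-RNA crosslink sites, emits
barcoded reads with PCR duplicates, then runs the read-processing half of
the pipeline: barcode extraction, demultiplexing, duplicate collapsing and
crosslink assignment.  The printed recovery rate compares assigned sites
with the simulator's ground truth.
"""

import iclipkit as ik

config = ik.SimulationConfig(n_genes=10, seed=42)
genome, annotation, truth = ik.simulate_genome(config)
reads, alignments = ik.simulate_iclip_reads(genome, truth, config)
print(f"simulated {len(truth.sites)} crosslink sites in {config.n_genes} genes, "
      f"{len(reads)} reads (with PCR duplicates)")

by_sample, summary = ik.preprocess_reads(reads, config.samples)
print(f"preprocessing: {summary.n_assigned} reads assigned, "
      f"{summary.n_unassigned} unassigned, {summary.n_too_short} too short")

unique = ik.filter_unique(alignments)
deduped, report = ik.collapse_pcr_duplicates(unique)
print(f"deduplication: {report.n_input} aligned tags -> "
      f"{report.n_output} molecules")

sites, skipped = ik.assign_crosslinks(deduped)
true_positions = truth.site_positions()
exact = sum((s.chrom, s.position, s.strand) in true_positions for s in sites)
print(f"crosslink assignment: {len(sites)} distinct sites, "
      f"{100 * exact / len(sites):.1f}% at a true crosslink position")
# A high recovery rate means the truncation/deletion crosslink rules invert
# the simulator's read model correctly on both strands.
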