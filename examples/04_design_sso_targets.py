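"""Select splice-switching oligonucleotide (SSO) targets.

Binding peaks 10-40 nt downstream of a repressed exon's 5' splice site are
good SSO targets: an antisense oligo over the silencer displaces the
repressor without blocking the donor.  This example plants peaks 11 nt and
70 nt downstream of a donor; only the proximal one is accepted, mirroring
the contrast between responsive targets (binding 11 nt downstream) and an
unresponsive one (70 nt downstream).
"""

import numpy as np

import iclipkit as ik
from iclipkit.intervals import GenomicInterval
from iclipkit.peaks import Peak

rng = np.random.default_rng(0)
sequence = list(rng.choice(list("ACGT"), size=4000))
exon = GenomicInterval("chr1", 1000, 1100, "+")  # repressed cassette exon
sequence[1110:1116] = "TAGGGA"  # silencer motif 11 nt into the intron
genome = {"chr1": "".join(sequence)}

matrix = ik.build_scoring_matrix(ik.build_frequency_matrix(["TAGGGA"] * 10))
peaks = [
    Peak(GenomicInterval("chr1", 1100 + d - 1, 1100 + d + 20, "+"),
         "geneA", height=8, total=16, p_value=0.001)
    for d in (11, 70)
]

candidates = ik.find_sso_candidates(peaks, [("exon3", exon)], genome, matrix)
print(f"{len(peaks)} peaks tested, {len(candidates)} accepted as SSO targets")
for cand in candidates:
    print(f"  peak {cand.distance_to_5ss} nt downstream of the donor: "
          f"rank score {cand.rank_score:.1f}")
    print(f"  proposed antisense oligo (5'->3' RNA): {cand.proposed_sso}")
# The 70-nt peak is rejected: blocking there does not improve inclusion.
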