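"""Delimit a physical interval from flanking genetic markers.

Builds a synthetic chromosome, plants two unique 60-bp markers, maps them
back (unique-placement filter: identity > 97%, HSP > 40 bp) and reports
the interval between their outer edges plus the genes inside it.
"""

import numpy as np

from petalsplit.locus_map import define_interval, genes_in_interval, map_markers
from petalsplit.seqio import GeneModel, GenomicInterval, SequenceRecord

rng = np.random.default_rng(0)
chrom = SequenceRecord("chr3", "".join(rng.choice(list("ACGT"), 100_000)))

markers = [
    SequenceRecord("flank_left", chrom.seq[20_000:20_060]),
    SequenceRecord("flank_right", chrom.seq[80_000:80_060]),
]
hits = map_markers(markers, [chrom])
retained = [h for h in hits if h.retained]
print(f"{len(retained)}/{len(markers)} markers retained (unique placement)")

interval = define_interval((retained[0], retained[1]))
print(f"interval: {interval.interval.contig}:{interval.interval.start}"
      f"-{interval.interval.end}  ({interval.length_bp:,} bp"
      f" = {interval.length_mb} Mb)")

# ten genes scattered on the chromosome; list those inside the interval
genes = [GeneModel(f"gene{i}", "chr3", "+",
                   (GenomicInterval("chr3", s, s + 2_000),))
         for i, s in enumerate(range(5_000, 100_000, 10_000))]
inside = genes_in_interval(interval, genes)
print(f"genes intersecting the interval: {len(inside)} of {len(genes)}")
# The interval spans marker outer edges; boundary-straddling genes count.
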