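"""Annotate an LTR retrotransposon and census its family in a genome.

Builds the 10,790-bp element of the insertion fixture, recovers its LTR
boundaries by terminal self-comparison, scores LTR identity (identical
repeats mean a recent insertion), finds the internal ORF, then plants a
small family in a background genome and counts complete copies vs
solo-LTRs.
"""

from petalsplit.simdata import SimParams, scatter_te_family, simulate_locus
from petalsplit.te import census_te_family, find_ltrs, find_orfs, ltr_identity

fx = simulate_locus(SimParams(), seed=1)            # full-size 10,790-bp TE
te_seq = fx.te.element.extract(fx.ins_haplotype.seq)
print(f"element length: {len(te_seq):,} bp")

pair = find_ltrs(te_seq, min_ltr_len=300)
print(f"5' LTR {pair.ltr5.start}-{pair.ltr5.end}, "
      f"3' LTR {pair.ltr3.start}-{pair.ltr3.end}")
ident = ltr_identity(pair.ltr5.extract(te_seq), pair.ltr3.extract(te_seq))
print(f"LTR identity: {ident:.1f}% (100% indicates a recent insertion)")

orfs = find_orfs(pair.internal.extract(te_seq), min_aa=500)
print(f"longest internal ORF: {3 * (orfs[0].aa_length + 1):,} bp "
      f"({orfs[0].aa_length} aa)")

params = SimParams(te_len=2000, ltr_len=300, n_complete=3, n_solo=5,
                   ltr_divergence=0.03)
family = scatter_te_family(40_000, params, seed=2)
census = census_te_family(family.genome, family.ltr, family.internal)
print(f"census of the planted family: {len(census.complete_copies)} complete "
      f"copies, {len(census.solo_ltrs)} solo-LTRs (truth: 3, 5)")
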