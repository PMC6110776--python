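"""Predict the splice consequence of the intron-8 TE insertion.

Finds the new acceptor inside the 5' LTR (AG after a polypyrimidine
tract), builds the chimeric mutant transcript, translates both alleles
and checks miR172 target-site retention.
"""

from petalsplit.simdata import SimParams, simulate_locus
from petalsplit.splicing import (
    build_transcript_pair,
    compare_mir_status,
    predict_new_acceptor,
    scan_mir_target,
)

fx = simulate_locus(SimParams(), seed=1)
acceptor = predict_new_acceptor(fx.ins_haplotype.seq, fx.te.ltr5)
print(f"new splice acceptor inside the 5' LTR at position {acceptor:,}")

tp = build_transcript_pair(fx)
print(f"wild-type protein: {tp.wt_protein_len} aa over {len(tp.wt_exons)} exons")
print(f"mutant protein:    {tp.mut_protein_len} aa "
      f"(premature stop: {tp.premature_stop}; lost exons {tp.lost_exons})")

status = compare_mir_status(tp, fx.mir_seq)
print(f"miR172 site on wild-type transcript: {status['wt_has_site']}")
print(f"miR172 site on mutant transcript:    {status['mut_has_site']}")
site = scan_mir_target(tp.wt_mrna, fx.mir_seq)[0]
print(f"wild-type site at mRNA position {site.position} "
      f"(penalty {site.score}; 0 = perfect complementarity)")
# Losing the site makes the truncated transcript miR172-resistant.
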