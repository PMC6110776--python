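"""Transcript-level consequence of the intron-8 TE insertion.

The inserted element's 5' LTR offers a new splice acceptor (an AG
dinucleotide preceded by a polypyrimidine stretch); splicing of exon 8's
donor onto it fuses exon 8 with LTR-derived sequence into a chimeric
exon, which introduces a premature stop codon, truncates the protein and
drops the two terminal exons — and with them the miR172 target site,
rendering the transcript miR172-resistant.  Target sites are scored with
an ungapped position-weighted penalty scheme (mismatch 1.0, G:U wobble
0.5, penalties doubled over the seed region, miRNA positions 2-13).
"""

from __future__ import annotations

from dataclasses import dataclass
from Bio.Seq import Seq

from .seqio import GenomicInterval, SequenceRecord
from .simdata import LocusFixture

__all__ = ["TranscriptPair", "MirTargetSite", "AcceptorConfig",
           "predict_new_acceptor", "build_transcript_pair",
           "scan_mir_target", "compare_mir_status", "MIR_CUTOFF"]

#: Maximum position-weighted penalty for a reported target site.
MIR_CUTOFF = 3.0


@dataclass(frozen=True)
class AcceptorConfig:
    """Minimal branch-free splice-acceptor model: an AG preceded by at
    least ``p_min`` pyrimidines in the preceding ``p_win`` bases."""

    p_min: int = 6
    p_win: int = 12


@dataclass(frozen=True)
class TranscriptPair:
    """The two allele transcripts and their predicted proteins."""

    wt_mrna: SequenceRecord
    mut_mrna: SequenceRecord
    wt_exons: tuple[GenomicInterval, ...]
    mut_exons: tuple[GenomicInterval, ...]
    wt_protein_len: int
    mut_protein_len: int
    premature_stop: bool
    lost_exons: tuple[int, ...]


@dataclass(frozen=True)
class MirTargetSite:
    """A reported miRNA target site on an mRNA (1-based start)."""

    position: int
    score: float
    pairing: str


def predict_new_acceptor(
    seq: SequenceRecord | str,
    ltr5: GenomicInterval,
    config: AcceptorConfig = AcceptorConfig(),
) -> int | None:
    """First qualifying splice acceptor inside the 5' LTR.

    ``seq`` is any sequence containing the inserted 5' LTR at the
    coordinates given by ``ltr5`` (1-based).  Returns the 1-based position
    of the AG's G — the chimeric exon starts at the next base — or None
    when no AG in the LTR passes the polypyrimidine filter.
    """
    s = (seq.seq if isinstance(seq, SequenceRecord) else seq).upper()
    for g in range(max(ltr5.start + 1, config.p_win + 2), ltr5.end + 1):
        if s[g - 2] == "A" and s[g - 1] == "G":
            window = s[g - 2 - config.p_win : g - 2]
            if sum(1 for c in window if c in "CT") >= config.p_min:
                return g
    return None


def build_transcript_pair(
    fixture: LocusFixture,
    acceptor: int | None = None,
    polya_boundary: int | None = None,
) -> TranscriptPair:
    """Assemble and translate the wild-type and mutant transcripts.

    The wild-type mRNA splices all ten exons.  The mutant mRNA splices
    exons 1-8 and then a chimeric exon running from the base after the
    acceptor AG to the polyadenylation boundary (a fixture parameter; 3'
    end prediction is out of model).  Both are translated from the
    annotated start codon to the first stop; ``premature_stop`` is set
    when the mutant stop precedes the wild-type stop and ``lost_exons``
    lists wild-type exon numbers absent from the mutant transcript.
    """
    if acceptor is None:
        acceptor = fixture.acceptor_pos
    if polya_boundary is None:
        polya_boundary = fixture.polya_boundary
    gm_wt, gm_ins = fixture.gene_model_wt, fixture.gene_model_ins
    wt_seq = fixture.wt_haplotype.seq
    ins_seq = fixture.ins_haplotype.seq

    donor_end = gm_ins.exons[7].end            # exon 8's 3' end (genomic)
    if acceptor <= donor_end:
        raise ValueError("acceptor must lie downstream of the exon-8 donor")

    wt_mrna = gm_wt.mrna(wt_seq)
    chimeric = GenomicInterval(gm_ins.contig, acceptor + 1, polya_boundary, "+")
    mut_exons = gm_ins.exons[:8] + (chimeric,)
    mut_mrna = "".join(e.extract(ins_seq) for e in mut_exons)

    cds_start_wt = gm_wt.genomic_to_mrna(gm_wt.cds_start)
    cds_start_mut = gm_ins.genomic_to_mrna(gm_ins.cds_start)
    wt_prot = _translate_to_stop(wt_mrna, cds_start_wt)
    mut_prot = _translate_to_stop(mut_mrna, cds_start_mut)

    # wild-type exons with no counterpart interval in the mutant transcript
    lost = []
    for i, e in enumerate(gm_wt.exons, start=1):
        shifted = gm_ins.exons[i - 1]
        if not any(shifted.overlaps(me) for me in mut_exons):
            lost.append(i)

    return TranscriptPair(
        wt_mrna=SequenceRecord(gm_wt.gene_id + ".mrna", wt_mrna),
        mut_mrna=SequenceRecord(gm_ins.gene_id + ".mrna", mut_mrna),
        wt_exons=gm_wt.exons,
        mut_exons=mut_exons,
        wt_protein_len=len(wt_prot),
        mut_protein_len=len(mut_prot),
        premature_stop=len(mut_prot) < len(wt_prot),
        lost_exons=tuple(lost),
    )


def _translate_to_stop(mrna: str, cds_start: int) -> str:
    """Translate from the annotated start codon to the first stop."""
    if mrna[cds_start - 1 : cds_start + 2] != "ATG":
        raise ValueError(f"no start codon at mRNA position {cds_start}")
    coding = mrna[cds_start - 1 :]
    coding = coding[: len(coding) - len(coding) % 3]
    return str(Seq(coding).translate(to_stop=True))


# ---------------------------------------------------------------------------
# miRNA target scanning
# ---------------------------------------------------------------------------

_SEED_LO, _SEED_HI = 2, 13     # miRNA positions with doubled penalties
_PENALTY_MISMATCH = 1.0
_PENALTY_WOBBLE = 0.5


def _pair_penalty(mir_base: str, target_base: str) -> tuple[float, str]:
    """Penalty and pairing symbol for one miRNA/target base pair."""
    complement = {"A": "T", "C": "G", "G": "C", "T": "A"}
    if complement.get(mir_base) == target_base:
        return 0.0, "|"
    if (mir_base == "G" and target_base == "T") or \
       (mir_base == "T" and target_base == "G"):
        return _PENALTY_WOBBLE, "o"
    return _PENALTY_MISMATCH, "."


def scan_mir_target(
    mrna: SequenceRecord | str,
    mir_seq: str,
    cutoff: float = MIR_CUTOFF,
) -> list[MirTargetSite]:
    """Slide the miRNA's reverse complement along the mRNA and score every
    position with the ungapped position-weighted penalty scheme.

    miRNA position 1 is its 5' end, which pairs with the 3' end of the
    site; penalties are doubled over positions 2-13.  Sites with total
    penalty <= ``cutoff`` are returned best-first.
    """
    seq = (mrna.seq if isinstance(mrna, SequenceRecord) else mrna).upper()
    mir = mir_seq.upper().replace("U", "T")
    if not 19 <= len(mir) <= 24:
        raise ValueError(f"miRNA length {len(mir)} outside 19-24 nt")
    L = len(mir)
    sites = []
    for s in range(len(seq) - L + 1):
        total, symbols = 0.0, []
        for i in range(1, L + 1):                  # miRNA position, 5'->3'
            t = seq[s + L - i]                     # pairs 3'->5' on the site
            pen, sym = _pair_penalty(mir[i - 1], t)
            if _SEED_LO <= i <= _SEED_HI:
                pen *= 2
            total += pen
            symbols.append(sym)
            if total > cutoff:
                break
        if total <= cutoff:
            # pairing string written 5'->3' along the target site
            sites.append(MirTargetSite(s + 1, total, "".join(symbols[::-1])))
    sites.sort(key=lambda x: (x.score, x.position))
    return sites


def compare_mir_status(
    pair: TranscriptPair,
    mir_seq: str,
    cutoff: float = MIR_CUTOFF,
) -> dict[str, bool]:
    """Whether each allele transcript retains a miRNA target site."""
    return {
        "wt_has_site": bool(scan_mir_target(pair.wt_mrna, mir_seq, cutoff)),
        "mut_has_site": bool(scan_mir_target(pair.mut_mrna, mir_seq, cutoff)),
    }
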