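"""Synthetic fixtures with known ground truth for every pipeline stage.

The generator emulates the structure of the rose double-flower locus: a
10-exon gene whose 8th intron carries (on one haplotype) a Gypsy-type LTR
retrotransposon with identical terminal repeats, a splice-acceptor motif
near the 3' end of its 5' LTR, and a long internal open reading frame.
The wild-type transcript carries exactly one miR172 target site spanning
the exon-9/exon-10 junction, so the truncation caused by the insertion
removes it.  Companion generators emit single-end genomic reads (diploid,
uniform, substitution errors only), paired-end RNA-seq fragments drawn
from two allele transcripts at a set mixture, and TE-family genomes with
planted complete copies and solo-LTRs.

Background sequence is i.i.d. uniform over ACGT: base composition is
irrelevant to the kernels under test.  All generators are deterministic
under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .seqio import GeneModel, GenomicInterval, SequenceRecord, revcomp

__all__ = [
    "MIR172", "MIR172_TARGET", "SimParams", "LocusFixture", "ReadPair",
    "TEFamilyFixture", "FixtureError", "CapacityError",
    "simulate_locus", "simulate_genomic_reads", "simulate_rnaseq_pairs",
    "scatter_te_family", "simulate_allele_pair",
]

#: Mature miR172 (DNA alphabet); its reverse complement is the planted
#: target site.  Chosen so the site contains no stop codon in any frame.
MIR172 = "AGAATCTTGATGATGCTGCAT"
MIR172_TARGET = revcomp(MIR172)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_STOPS = {"TAA", "TAG", "TGA"}


class FixtureError(ValueError):
    """The requested fixture geometry is infeasible."""


class CapacityError(ValueError):
    """Planted elements do not fit in the requested genome length."""


@dataclass(frozen=True)
class SimParams:
    """Generator settings.

    The sequencing geometry follows the resequencing data the genotyping
    procedure was designed for: 100-bp single-end genomic reads and
    paired-end RNA-seq.  ``te_len`` defaults to the 10,790-bp element of
    the focal insertion, with identical LTRs (``ltr_divergence=0``,
    i.e. a recent insertion).
    """

    coverage: float = 10.0
    read_len: int = 100
    error_rate: float = 0.01
    insert_mean: float = 300.0
    insert_sd: float = 30.0
    mixture: float = 0.5
    te_len: int = 10790
    ltr_len: int = 1500
    ltr_divergence: float = 0.0
    n_complete: int = 5
    n_solo: int = 10
    # locus geometry (desk-scale defaults; see docs/methods.md)
    flank_len: int = 600
    intron_len: int = 250
    intron8_len: int = 400

    def __post_init__(self) -> None:
        if self.coverage < 0:
            raise ValueError("coverage must be >= 0")
        if not 0 <= self.error_rate < 0.25:
            raise ValueError("error_rate must lie in [0, 0.25)")
        if not 0 <= self.mixture <= 1:
            raise ValueError("mixture must lie in [0, 1]")
        if self.ltr_len * 2 >= self.te_len:
            raise ValueError("ltr_len must be < te_len / 2")
        if not 0 <= self.ltr_divergence < 0.5:
            raise ValueError("ltr_divergence must lie in [0, 0.5)")
        if self.read_len <= 0 or self.te_len <= 0 or self.ltr_len < 60:
            raise ValueError("read_len/te_len positive; ltr_len >= 60 required")


@dataclass(frozen=True)
class ReadPair:
    """One simulated RNA-seq fragment: forward prefix + reverse-complement
    suffix of the fragment, plus its true transcript of origin (0 or 1)."""

    id: str
    r1: str
    r2: str
    origin: int


@dataclass(frozen=True)
class LocusFixture:
    """Diploid locus ground truth (see module docstring)."""

    wt_haplotype: SequenceRecord
    ins_haplotype: SequenceRecord
    gene_model_wt: GeneModel
    gene_model_ins: GeneModel
    te: "object"  # TEAnnotation (petalsplit.te); kept loose to avoid a cycle
    truth: str
    insertion_point: GenomicInterval
    mir_seq: str = MIR172
    acceptor_pos: int = 0          # ins-haplotype coordinate of the AG's G
    polya_boundary: int = 0        # ins-haplotype coordinate of mutant 3' end
    wt_protein_len: int = 0
    mut_protein_len: int = 0

    @property
    def haplotypes(self) -> tuple[SequenceRecord, SequenceRecord]:
        """Diploid haplotype pair implied by the truth label."""
        if self.truth == "hom_wt":
            return (self.wt_haplotype, self.wt_haplotype)
        if self.truth == "hom_ins":
            return (self.ins_haplotype, self.ins_haplotype)
        return (self.wt_haplotype, self.ins_haplotype)


@dataclass(frozen=True)
class TEFamilyFixture:
    """A background genome seeded with TE-family copies, plus truth."""

    genome: SequenceRecord
    element: SequenceRecord
    ltr: str
    internal: str
    truth: tuple[tuple[str, GenomicInterval], ...]


# ---------------------------------------------------------------------------
# low-level sequence builders
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode()


def _random_codons(rng: np.random.Generator, n: int) -> str:
    """n sense (non-stop) codons."""
    out = []
    while len(out) < n:
        c = _random_seq(rng, 3)
        if c not in _STOPS:
            out.append(c)
    return "".join(out)


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = np.nonzero(rng.random(arr.size) < rate)[0]
    for i in hit:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


def _suppress_acceptors(seq: str, p_min: int = 6, p_win: int = 12) -> str:
    """Remove every splice-acceptor-like motif (AG with >= p_min pyrimidines
    in the preceding p_win bases) by deterministically mutating pyrimidines
    to A.  Terminates because each edit lowers the pyrimidine count."""
    s = list(seq)
    changed = True
    while changed:
        changed = False
        for i in range(p_win, len(s) - 1):
            if s[i] == "A" and s[i + 1] == "G":
                ys = [j for j in range(i - p_win, i) if s[j] in "CT"]
                if len(ys) >= p_min:
                    s[ys[-1]] = "A"
                    changed = True
    return "".join(s)


_ACC_TAIL = 30      # LTR bases downstream of the planted acceptor AG
_CHIMERIC_CODONS = 40   # sense codons of the chimeric exon before its stop


def _build_ltr(rng: np.random.Generator, ltr_len: int) -> tuple[str, int]:
    """An LTR with exactly one qualifying splice acceptor near its 3' end.

    Returns (sequence, 1-based position of the AG's G within the LTR).
    The 30 bases after the AG are the in-frame start of the chimeric exon
    (first 10 sense codons), shared by both LTR copies.
    """
    if ltr_len < _ACC_TAIL + 16:
        raise FixtureError(f"ltr_len {ltr_len} too short for the acceptor motif")
    seq = _suppress_acceptors(_random_seq(rng, ltr_len))
    ag_g = ltr_len - _ACC_TAIL          # 1-based position of the G
    poly_y = "TCTTTCCTTCTT"             # 12 pyrimidines
    chimeric_head = _random_codons(rng, _ACC_TAIL // 3)
    # layout (1-based): Y*12 at ag_g-13..ag_g-2, then A G, then the 30-base
    # in-frame chimeric-exon head filling the rest of the LTR
    s = list(seq)
    s[ag_g - 14 : ag_g - 2] = poly_y
    s[ag_g - 2] = "A"
    s[ag_g - 1] = "G"
    s[ag_g : ag_g + _ACC_TAIL] = chimeric_head
    return "".join(s), ag_g


def _build_te(rng: np.random.Generator, params: SimParams) -> dict:
    """Full element: 5'LTR + internal (chimeric-exon start, poly(A) boundary,
    long ORF) + 3'LTR (mutated copy of the 5'LTR at ltr_divergence)."""
    ltr5, ag_g = _build_ltr(rng, params.ltr_len)
    internal_len = params.te_len - 2 * params.ltr_len
    tail_in_ltr = params.ltr_len - ag_g          # chimeric bases inside the LTR
    chim_remaining = 3 * (_CHIMERIC_CODONS + 1) - tail_in_ltr  # incl. stop codon
    polya_off = chim_remaining + 150             # internal offset of mutant 3' end
    orf_reserve = polya_off + 20
    if internal_len < orf_reserve + 120:
        raise FixtureError("internal region too short for chimeric exon + ORF")
    internal = list(_random_seq(rng, internal_len))
    chim = _random_codons(rng, _CHIMERIC_CODONS - _ACC_TAIL // 3) + "TAA"
    assert len(chim) == chim_remaining
    internal[:chim_remaining] = chim
    # plant the internal ORF (up to 5,535 bp as in a Gypsy pol ORF)
    orf_len = min(5535, 3 * ((internal_len - orf_reserve - 60) // 3))
    orf_start = orf_reserve + 30                 # 0-based offset in internal
    orf = "ATG" + _random_codons(rng, orf_len // 3 - 2) + "TGA"
    internal[orf_start : orf_start + orf_len] = orf
    # in-frame stop immediately upstream keeps the planted ORF maximal
    internal[orf_start - 3 : orf_start] = "TAA"
    internal = "".join(internal)
    ltr3 = _mutate(ltr5, params.ltr_divergence, rng)
    return {
        "seq": ltr5 + internal + ltr3,
        "ltr5": ltr5,
        "ltr3": ltr3,
        "internal": internal,
        "ag_g": ag_g,                            # 1-based within the 5' LTR
        "polya_internal_off": polya_off,         # 1-based within internal
        "orf": (orf_start + 1, orf_start + orf_len),  # 1-based within internal
    }


# ---------------------------------------------------------------------------
# locus fixture
# ---------------------------------------------------------------------------

# mRNA layout (bp): 60 UTR + 1,383 CDS (460 aa + stop) + 200 UTR, split into
# 10 exons such that exons 1-8 end on a codon boundary after 302 codons and
# the miR172 site straddles the exon-9/exon-10 junction in frame.
_UTR5, _UTR3 = 60, 200
_N_CODONS = 461                     # 460 aa + stop
_EXON_LENS = (150, 120, 110, 100, 130, 120, 118, 118, 181, 496)


def simulate_locus(params: SimParams, seed: int, truth: str = "het") -> LocusFixture:
    """Generate the diploid locus fixture.

    The wild-type haplotype carries a 10-exon gene encoding a 460-aa
    protein with a single miR172 target site spanning the exon-9/10
    junction.  The insertion haplotype is identical except for the TE
    inserted in the middle of intron 8; splicing onto the acceptor planted
    in the 5' LTR yields a chimeric exon whose in-frame stop truncates the
    protein to 342 aa.
    """
    if truth not in ("hom_wt", "het", "hom_ins"):
        raise ValueError(f"unknown truth label {truth!r}")
    min_intron_flank = 25
    if params.intron8_len < 2 * min_intron_flank:
        raise FixtureError("intron 8 too short to host an internal insertion point")
    rng = np.random.default_rng(seed)

    # transcript
    cds = "ATG" + _random_codons(rng, _N_CODONS - 2) + "TAA"
    mrna = list(_random_seq(rng, _UTR5) + cds + _random_seq(rng, _UTR3))
    site_start = sum(_EXON_LENS[:9]) - 10            # 0-based; 10 nt in exon 9
    assert (site_start - _UTR5) % 3 == 0
    mrna[site_start : site_start + len(MIR172_TARGET)] = MIR172_TARGET
    mrna = "".join(mrna)
    assert len(mrna) == sum(_EXON_LENS)

    # genomic structure
    intron_lens = [params.intron_len] * 9
    intron_lens[7] = params.intron8_len
    parts, exon_ivs = [], []
    pos = params.flank_len
    parts.append(_random_seq(rng, params.flank_len))
    m_off = 0
    for i, elen in enumerate(_EXON_LENS):
        parts.append(mrna[m_off : m_off + elen])
        exon_ivs.append(GenomicInterval("wt_hap", pos + 1, pos + elen, "+"))
        pos += elen
        m_off += elen
        if i < 9:
            intron = _random_seq(rng, intron_lens[i])
            # canonical splice dinucleotides, for realism
            intron = "GT" + intron[2:-2] + "AG"
            parts.append(intron)
            pos += intron_lens[i]
    parts.append(_random_seq(rng, params.flank_len))
    wt_seq = "".join(parts)

    # CDS genomic intervals (gene entirely on '+')
    cds_ivs = _project_to_exons(exon_ivs, _UTR5 + 1, _UTR5 + 3 * _N_CODONS)
    gm_wt = GeneModel("RcAP2L", "wt_hap", "+", tuple(exon_ivs), tuple(cds_ivs))

    # TE insertion in the middle of intron 8
    te = _build_te(rng, params)
    intron8 = gm_wt.introns[7]
    p = (intron8.start + intron8.end) // 2           # insert between p and p+1
    ins_seq = wt_seq[:p] + te["seq"] + wt_seq[p:]

    shift = params.te_len
    exon_ivs_ins = [
        GenomicInterval("ins_hap", e.start, e.end, "+") if e.end <= p
        else GenomicInterval("ins_hap", e.start + shift, e.end + shift, "+")
        for e in exon_ivs
    ]
    cds_ivs_ins = [
        GenomicInterval("ins_hap", c.start, c.end, "+") if c.end <= p
        else GenomicInterval("ins_hap", c.start + shift, c.end + shift, "+")
        for c in cds_ivs
    ]
    gm_ins = GeneModel("RcAP2L_d172", "ins_hap", "+",
                       tuple(exon_ivs_ins), tuple(cds_ivs_ins))

    from .te import Orf, TEAnnotation  # deferred: te module holds these types

    te_ann = TEAnnotation(
        element=GenomicInterval("ins_hap", p + 1, p + params.te_len, "+"),
        ltr5=GenomicInterval("ins_hap", p + 1, p + params.ltr_len, "+"),
        ltr3=GenomicInterval("ins_hap", p + params.te_len - params.ltr_len + 1,
                             p + params.te_len, "+"),
        internal=GenomicInterval("ins_hap", p + params.ltr_len + 1,
                                 p + params.te_len - params.ltr_len, "+"),
        ltr_identity=100.0 * (1 - params.ltr_divergence),
        orfs=(Orf(p + params.ltr_len + te["orf"][0],
                  p + params.ltr_len + te["orf"][1], "+", 0,
                  (te["orf"][1] - te["orf"][0] + 1) // 3 - 1),),
    )
    acceptor_pos = p + te["ag_g"]
    polya_boundary = p + params.ltr_len + te["polya_internal_off"]
    return LocusFixture(
        wt_haplotype=SequenceRecord("wt_hap", wt_seq),
        ins_haplotype=SequenceRecord("ins_hap", ins_seq),
        gene_model_wt=gm_wt,
        gene_model_ins=gm_ins,
        te=te_ann,
        truth=truth,
        insertion_point=GenomicInterval("wt_hap", p, p, "+"),
        acceptor_pos=acceptor_pos,
        polya_boundary=polya_boundary,
        wt_protein_len=_N_CODONS - 1,
        mut_protein_len=302 + _CHIMERIC_CODONS,
    )


def _project_to_exons(exons: Sequence[GenomicInterval], m_start: int,
                      m_end: int) -> list[GenomicInterval]:
    """Map an mRNA-coordinate interval onto genomic exon pieces ('+' genes)."""
    out, offset = [], 0
    for e in exons:
        lo = max(m_start, offset + 1)
        hi = min(m_end, offset + e.length)
        if lo <= hi:
            out.append(GenomicInterval(e.contig, e.start + (lo - offset - 1),
                                       e.start + (hi - offset - 1), e.strand))
        offset += e.length
    return out


# ---------------------------------------------------------------------------
# read simulators
# ---------------------------------------------------------------------------

def simulate_genomic_reads(
    haplotypes: Sequence[SequenceRecord], params: SimParams, seed: int,
) -> tuple[list[SequenceRecord], int]:
    """Single-end genomic reads drawn uniformly from each haplotype.

    Expected reads per haplotype = coverage * length / read_len (Poisson);
    per-base substitution errors at ``error_rate``; random strand.
    Returns (reads, library_size).
    """
    rng = np.random.default_rng(seed)
    reads: list[SequenceRecord] = []
    for h, hap in enumerate(haplotypes):
        if params.read_len > len(hap.seq):
            raise ValueError(f"read_len exceeds haplotype {hap.id} length")
        lam = params.coverage * len(hap.seq) / params.read_len
        n = int(rng.poisson(lam)) if lam > 0 else 0
        starts = rng.integers(0, len(hap.seq) - params.read_len + 1, size=n)
        strands = rng.random(n) < 0.5
        for i, (s, minus) in enumerate(zip(starts, strands)):
            frag = hap.seq[s : s + params.read_len]
            if minus:
                frag = revcomp(frag)
            frag = _mutate(frag, params.error_rate, rng)
            reads.append(SequenceRecord(f"{hap.id}:{h}:{i}", frag))
    return reads, len(reads)


def simulate_rnaseq_pairs(
    transcripts: tuple[SequenceRecord, SequenceRecord],
    params: SimParams, seed: int, n_pairs: int,
) -> list[ReadPair]:
    """Paired-end RNA-seq fragments from two allele transcripts.

    Each fragment originates from transcript 0 with probability
    ``params.mixture``; mate 1 is the fragment's forward prefix and mate 2
    the reverse complement of its suffix, both ``read_len`` long.
    """
    rng = np.random.default_rng(seed)
    for tx in transcripts:
        if len(tx.seq) <= params.insert_mean + 4 * params.insert_sd:
            raise ValueError(
                f"transcript {tx.id} shorter than insert_mean + 4*insert_sd")
    pairs: list[ReadPair] = []
    for i in range(n_pairs):
        origin = 0 if rng.random() < params.mixture else 1
        tx = transcripts[origin].seq
        frag_len = int(round(rng.normal(params.insert_mean, params.insert_sd)))
        frag_len = max(params.read_len, min(frag_len, len(tx)))
        start = int(rng.integers(0, len(tx) - frag_len + 1))
        frag = tx[start : start + frag_len]
        r1 = _mutate(frag[: params.read_len], params.error_rate, rng)
        r2 = _mutate(revcomp(frag)[: params.read_len], params.error_rate, rng)
        pairs.append(ReadPair(f"pair{i}", r1, r2, origin))
    return pairs


# ---------------------------------------------------------------------------
# TE family scatter
# ---------------------------------------------------------------------------

def scatter_te_family(genome_len: int, params: SimParams,
                      seed: int) -> TEFamilyFixture:
    """Plant ``n_complete`` full elements and ``n_solo`` lone LTRs in a
    random background, each copy independently mutated at
    ``params.ltr_divergence`` and placed on a random strand.

    Placements are pairwise disjoint by construction; the reference
    element (divergence 0) is returned alongside for use as the census
    query.  Raises :class:`CapacityError` when the genome is too small.
    """
    rng = np.random.default_rng(seed)
    te = _build_te(rng, params)
    pieces = [("complete", te["seq"])] * params.n_complete + \
             [("solo", te["ltr5"])] * params.n_solo
    order = rng.permutation(len(pieces))
    pieces = [pieces[i] for i in order]
    total = sum(len(s) for _, s in pieces)
    n_gaps = len(pieces) + 1
    min_gap = 50
    background = genome_len - total
    if background < n_gaps * min_gap:
        raise CapacityError(
            f"genome_len {genome_len} cannot host {params.n_complete} complete "
            f"copies and {params.n_solo} solo-LTRs")
    # random gap lengths >= min_gap summing to the background length
    cuts = np.sort(rng.integers(0, background - n_gaps * min_gap + 1,
                                size=n_gaps - 1))
    free = np.diff(np.concatenate([[0], cuts, [background - n_gaps * min_gap]]))
    gaps = (free + min_gap).tolist()

    chunks, truth = [], []
    pos = 0
    for gap, (kind, seq) in zip(gaps, pieces):
        chunks.append(_random_seq(rng, gap))
        pos += gap
        copy = _mutate(seq, params.ltr_divergence, rng)
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            copy = revcomp(copy)
        chunks.append(copy)
        truth.append((kind, GenomicInterval("sim_genome", pos + 1,
                                            pos + len(copy), strand)))
        pos += len(copy)
    chunks.append(_random_seq(rng, gaps[-1]))
    genome = "".join(chunks)
    return TEFamilyFixture(
        genome=SequenceRecord("sim_genome", genome),
        element=SequenceRecord("te_ref", te["seq"]),
        ltr=te["ltr5"],
        internal=te["internal"],
        truth=tuple(truth),
    )


# ---------------------------------------------------------------------------
# ASE allele-pair fixture
# ---------------------------------------------------------------------------

def simulate_allele_pair(
    seed: int,
    tx_len: int = 2000,
    snp_spacing: int = 150,
    identical_block: tuple[int, int] = (800, 1300),
    decoy_len: int = 1500,
) -> tuple[SequenceRecord, SequenceRecord, list[SequenceRecord]]:
    """Two equal-length allele transcripts plus one decoy.

    Allele B differs from allele A by one substitution every
    ``snp_spacing`` bp outside ``identical_block`` (1-based, inclusive);
    inside the block the alleles are identical, so fragments confined to
    it are ambiguous.  The decoy embeds a copy of the identical block, so
    those fragments also match elsewhere in the genome (category iv).
    """
    rng = np.random.default_rng(seed)
    a = _random_seq(rng, tx_len)
    b = list(a)
    lo, hi = identical_block
    for pos in range(snp_spacing, tx_len + 1, snp_spacing):
        if lo <= pos <= hi:
            continue
        i = pos - 1
        choices = [c for c in "ACGT" if c != b[i]]
        b[i] = choices[int(rng.integers(0, 3))]
    b = "".join(b)
    block_seq = a[lo - 1 : hi]
    pad = max(0, (decoy_len - len(block_seq)) // 2)
    decoy = _random_seq(rng, pad) + block_seq + _random_seq(rng, pad)
    return (
        SequenceRecord("alleleA", a),
        SequenceRecord("alleleB", b),
        [SequenceRecord("decoy1", decoy)],
    )
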