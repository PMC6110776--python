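"""LTR-retrotransposon structure annotation and family census.

``find_ltrs`` recovers the boundaries of the two long terminal repeats of
an extracted element by self-comparison of its termini; ``ltr_identity``
scores the two repeats with a global alignment (identical LTRs indicate a
recent insertion); ``find_orfs`` enumerates open reading frames in the
internal region; ``census_te_family`` searches a genome for complete
copies (two same-strand LTR matches flanking an internal-region match)
and solo-LTRs (stringent lone LTR matches), the classic footprint of
intra-element recombination.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from Bio import Align

from .align import LocalMatch, SeedExtendMatcher
from .config import DEFAULT_CONFIG, PipelineConfig
from .seqio import GenomicInterval, SequenceRecord, revcomp

__all__ = [
    "Orf", "LtrPair", "TEAnnotation", "FamilyCensus", "LtrNotFoundError",
    "find_ltrs", "ltr_identity", "find_orfs", "annotate_element",
    "census_te_family",
]


class LtrNotFoundError(ValueError):
    """The sequence has no qualifying pair of terminal repeats."""


@dataclass(frozen=True)
class Orf:
    """An open reading frame; coordinates are 1-based on the forward strand,
    ``aa_length`` excludes the stop codon."""

    start: int
    end: int
    strand: str
    frame: int
    aa_length: int


@dataclass(frozen=True)
class LtrPair:
    """Terminal-repeat boundaries within an element (element-local coords)."""

    ltr5: GenomicInterval
    ltr3: GenomicInterval
    internal: GenomicInterval
    identity: float


@dataclass(frozen=True)
class TEAnnotation:
    """Structural annotation of one LTR retrotransposon copy."""

    element: GenomicInterval
    ltr5: GenomicInterval
    ltr3: GenomicInterval
    internal: GenomicInterval
    ltr_identity: float
    orfs: tuple = ()

    def __post_init__(self) -> None:
        if not (self.ltr5.end < self.internal.start
                and self.internal.start <= self.internal.end
                and self.internal.end < self.ltr3.start):
            raise ValueError("LTR/internal intervals out of order")
        if abs(self.ltr5.length - self.ltr3.length) > 0.05 * max(
                self.ltr5.length, self.ltr3.length):
            raise ValueError("LTR lengths differ by more than 5%")


@dataclass(frozen=True)
class FamilyCensus:
    """Genome-wide census of one TE family."""

    complete_copies: tuple[TEAnnotation, ...]
    solo_ltrs: tuple[GenomicInterval, ...]
    config: PipelineConfig


# ---------------------------------------------------------------------------
# structure of a single element
# ---------------------------------------------------------------------------

_TERM_MATCH, _TERM_MISMATCH = 1, -3


def find_ltrs(te_seq: SequenceRecord | str, min_ltr_len: int = 100,
              min_identity: float = 0.90) -> LtrPair:
    """Locate the terminal repeats of an extracted element.

    The element's prefix and suffix are compared along the off-main
    diagonal: for every candidate repeat length L the prefix ``[1..L]``
    is scored against the suffix ``[n-L+1..n]`` (match +1, mismatch -3,
    substitution-only) and the best-scoring L is taken.  The pair must be
    at least ``min_ltr_len`` long at >= ``min_identity`` identity,
    otherwise :class:`LtrNotFoundError` is raised.
    """
    seq = te_seq.seq if isinstance(te_seq, SequenceRecord) else te_seq
    n = len(seq)
    if n <= 2 * min_ltr_len:
        raise LtrNotFoundError(f"sequence of {n} bp cannot hold two "
                               f">={min_ltr_len} bp terminal repeats")
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    max_l = n // 2
    best_l, best_score = 0, -1
    for L in range(min_ltr_len, max_l + 1):
        matches = int(np.count_nonzero(arr[:L] == arr[n - L : n]))
        score = _TERM_MATCH * matches + _TERM_MISMATCH * (L - matches)
        if score > best_score:
            best_score, best_l = score, L
    if best_l < min_ltr_len or best_score <= 0:
        raise LtrNotFoundError("no qualifying terminal repeat pair")
    matches = int(np.count_nonzero(arr[:best_l] == arr[n - best_l : n]))
    ident = matches / best_l
    if ident < min_identity:
        raise LtrNotFoundError(
            f"best terminal repeat ({best_l} bp) has identity {ident:.3f} "
            f"< {min_identity}")
    name = te_seq.id if isinstance(te_seq, SequenceRecord) else "element"
    return LtrPair(
        ltr5=GenomicInterval(name, 1, best_l, "+"),
        ltr3=GenomicInterval(name, n - best_l + 1, n, "+"),
        internal=GenomicInterval(name, best_l + 1, n - best_l, "+"),
        identity=100.0 * ident,
    )


def ltr_identity(ltr5_seq: str, ltr3_seq: str) -> float:
    """Global end-to-end percent identity between the two LTR sequences
    (unit mismatch and gap costs); 100.0 means identical repeats."""
    if not ltr5_seq or not ltr3_seq:
        raise ValueError("LTR sequences must be non-empty")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -1
    aligner.extend_gap_score = -1
    aln = aligner.align(ltr5_seq.upper(), ltr3_seq.upper())[0]
    a, b = aln[0], aln[1]
    matches = sum(1 for x, y in zip(a, b) if x == y and x != "-")
    return 100.0 * matches / len(a)


_STOPS = {"TAA", "TAG", "TGA"}


def find_orfs(seq: SequenceRecord | str, min_aa: int = 100) -> list[Orf]:
    """All ATG-to-stop open reading frames of >= ``min_aa`` amino acids on
    both strands (six frames, standard genetic code).  ORFs without an
    in-frame stop are not reported."""
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    s = (seq.seq if isinstance(seq, SequenceRecord) else seq).upper()
    n = len(s)
    out: list[Orf] = []
    for strand in ("+", "-"):
        work = s if strand == "+" else revcomp(s)
        for frame in range(3):
            i = frame
            open_starts: list[int] = []
            while i + 3 <= n:
                codon = work[i : i + 3]
                if codon == "ATG":
                    open_starts.append(i)
                elif codon in _STOPS and open_starts:
                    for st in open_starts:
                        aa = (i - st) // 3
                        if aa >= min_aa:
                            if strand == "+":
                                g0, g1 = st + 1, i + 3
                            else:
                                g0, g1 = n - (i + 3) + 1, n - st
                            out.append(Orf(g0, g1, strand, frame, aa))
                    open_starts = []
                i += 3
    out.sort(key=lambda o: (-o.aa_length, o.start))
    return out


def annotate_element(te_seq: SequenceRecord, min_ltr_len: int = 100,
                     min_orf_aa: int = 100) -> TEAnnotation:
    """Full structural annotation of one extracted element."""
    pair = find_ltrs(te_seq, min_ltr_len)
    seq = te_seq.seq
    ident = ltr_identity(pair.ltr5.extract(seq), pair.ltr3.extract(seq))
    internal_seq = pair.internal.extract(seq)
    orfs = tuple(
        Orf(o.start + pair.internal.start - 1, o.end + pair.internal.start - 1,
            o.strand, o.frame, o.aa_length)
        for o in find_orfs(internal_seq, min_orf_aa)
    )
    return TEAnnotation(
        element=GenomicInterval(te_seq.id, 1, len(seq), "+"),
        ltr5=pair.ltr5, ltr3=pair.ltr3, internal=pair.internal,
        ltr_identity=ident, orfs=orfs,
    )


# ---------------------------------------------------------------------------
# family census
# ---------------------------------------------------------------------------

def _covered_length(matches: Sequence[LocalMatch], lo: int, hi: int) -> int:
    """Summed non-overlapping genomic coverage of matches within [lo, hi]."""
    spans = sorted((max(m.g_start, lo), min(m.g_end, hi))
                   for m in matches if m.g_start <= hi and m.g_end >= lo)
    total, cur_lo, cur_hi = 0, None, None
    for s, e in spans:
        if s > e:
            continue
        if cur_hi is None or s > cur_hi + 1:
            if cur_hi is not None:
                total += cur_hi - cur_lo + 1
            cur_lo, cur_hi = s, e
        else:
            cur_hi = max(cur_hi, e)
    if cur_hi is not None:
        total += cur_hi - cur_lo + 1
    return total


def _pad_to_full_query(m: LocalMatch, query_len: int,
                       contig_len: int) -> LocalMatch:
    """Extend a match's genomic interval to the full query projection.

    Diverged copies yield trimmed local matches; padding restores the
    element-level boundaries so paired LTRs have comparable lengths.  The
    matched ``length``/``identity`` are kept for filtering.
    """
    if m.strand == "+":
        pad_l, pad_r = m.q_start - 1, query_len - m.q_end
    else:
        pad_l, pad_r = query_len - m.q_end, m.q_start - 1
    return LocalMatch(
        m.contig,
        max(1, m.g_start - pad_l),
        min(contig_len, m.g_end + pad_r),
        m.q_start, m.q_end, m.strand, m.length, m.identity,
    )


def census_te_family(
    genome: Sequence[SequenceRecord] | SequenceRecord,
    ltr_query: str,
    internal_query: str,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> FamilyCensus:
    """Census a genome for complete copies and solo-LTRs of one family.

    LTR matches must reach ``config.ltr_min_match`` bp (scaled to 0.8x the
    query when the query LTR is shorter) at >= 80% identity.  A complete
    copy is a pair of same-strand LTR matches whose span does not exceed
    1.5x the reference element length and whose inter-LTR gap is covered
    by internal-region matches over at least min(800, 0.8x internal) bp.
    A solo-LTR is a near-full-length (>= ``config.solo_ltr_min_match`` or
    0.9x query) LTR match at >= 90% identity not used by a complete copy.
    Complete copies and solo-LTRs are mutually exclusive.
    """
    contigs = [genome] if isinstance(genome, SequenceRecord) else list(genome)
    element_len = 2 * len(ltr_query) + len(internal_query)
    if not contigs or all(len(c.seq) < len(ltr_query) for c in contigs):
        return FamilyCensus((), (), config)
    matcher = SeedExtendMatcher(contigs)

    contig_len = {c.id: len(c.seq) for c in contigs}
    ltr_min = min(config.ltr_min_match, int(0.8 * len(ltr_query)))
    solo_min = min(config.solo_ltr_min_match, int(0.9 * len(ltr_query)))
    ltr_hits = [
        _pad_to_full_query(m, len(ltr_query), contig_len[m.contig])
        for m in matcher.search(ltr_query, min_len=ltr_min, min_identity=0.80)
    ]
    internal_hits = matcher.search(
        internal_query,
        min_len=min(300, int(0.3 * len(internal_query))),
        min_identity=0.80,
    )
    internal_cov_min = min(800, int(0.8 * len(internal_query)))
    max_span = int(1.5 * element_len)

    complete: list[TEAnnotation] = []
    used: set[int] = set()
    by_key = sorted(range(len(ltr_hits)),
                    key=lambda i: (ltr_hits[i].contig, ltr_hits[i].g_start))
    for ai_idx, ai in enumerate(by_key):
        if ai in used:
            continue
        a = ltr_hits[ai]
        for bi in by_key[ai_idx + 1 :]:
            if bi in used:
                continue
            b = ltr_hits[bi]
            if b.contig != a.contig or b.strand != a.strand:
                continue
            if b.g_start <= a.g_end:
                continue
            span = b.g_end - a.g_start + 1
            if span > max_span:
                break
            # the inter-LTR gap must look like one internal region: mostly
            # covered by internal matches and of comparable length (this
            # rejects pairings that straddle a neighbouring copy)
            gap_len = b.g_start - a.g_end - 1
            if not (0.5 * len(internal_query) <= gap_len
                    <= 1.3 * len(internal_query)):
                continue
            inner = [m for m in internal_hits
                     if m.contig == a.contig and m.strand == a.strand]
            cov = _covered_length(inner, a.g_end + 1, b.g_start - 1)
            if cov < internal_cov_min:
                continue
            complete.append(TEAnnotation(
                element=GenomicInterval(a.contig, a.g_start, b.g_end, a.strand),
                ltr5=GenomicInterval(a.contig, a.g_start, a.g_end, a.strand),
                ltr3=GenomicInterval(a.contig, b.g_start, b.g_end, a.strand),
                internal=GenomicInterval(a.contig, a.g_end + 1,
                                         b.g_start - 1, a.strand),
                ltr_identity=100.0 * min(a.identity, b.identity),
            ))
            used.update((ai, bi))
            break

    solo: list[GenomicInterval] = []
    for i, h in enumerate(ltr_hits):
        if i in used:
            continue
        if h.length < solo_min or h.identity < 0.90:
            continue
        iv = GenomicInterval(h.contig, h.g_start, h.g_end, h.strand)
        if any(c.element.overlaps(iv) for c in complete):
            continue
        solo.append(iv)
    return FamilyCensus(tuple(complete), tuple(solo), config)
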