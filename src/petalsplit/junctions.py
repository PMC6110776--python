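"""TE-insertion genotyping from junction-spanning reads.

Presence of the insertion is read off from reads that overlap the two
gene/TE junctions; absence from reads that overlap the intact position of
the wild-type allele.  Reads are trimmed to a homogeneous length, placed
end-to-end with at most two mismatches (substitution-only, both strands),
and counted for a target when a placement covers the focal position with
at least 15 bp on each side.  Counts are normalized to reads per 10^8
library reads and combined into a genotype call.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .align import EndToEndIndex, Placement, scan_end_to_end
from .config import DEFAULT_CONFIG, PipelineConfig
from .seqio import SequenceRecord
from .simdata import LocusFixture

__all__ = ["JunctionPanel", "GenotypeCall", "PanelError",
           "build_junction_panel", "trim_reads", "align_end_to_end",
           "count_junction_reads", "normalize_and_call", "genotype_sample",
           "DEFAULT_TAU"]

#: Call threshold in reads per 10^8: zero-vs-positive separation with a
#: guard against isolated chimeric reads at realistic library sizes.
DEFAULT_TAU = 1.0


class PanelError(ValueError):
    """The fixture cannot provide the requested flanking context."""


@dataclass(frozen=True)
class JunctionPanel:
    """The three diagnostic targets: intact site, 5' and 3' TE junctions.

    Each target is a ``2*flank_len + 1`` bp window whose central base
    (``focal = flank_len + 1``, 1-based) is the diagnostic position:
    the insertion-point base on the intact allele, the first TE base for
    the 5' junction and the last TE base for the 3' junction.
    """

    wt_target: SequenceRecord
    j5_target: SequenceRecord
    j3_target: SequenceRecord
    flank_len: int

    @property
    def focal(self) -> int:
        return self.flank_len + 1

    @property
    def targets(self) -> tuple[SequenceRecord, SequenceRecord, SequenceRecord]:
        return (self.wt_target, self.j5_target, self.j3_target)


@dataclass(frozen=True)
class GenotypeCall:
    """Raw and normalized junction counts plus the genotype call."""

    genotype_id: str
    raw_counts: tuple[int, int, int]
    library_size: int
    norm_counts: tuple[float, float, float]
    call: str


def build_junction_panel(fixture: LocusFixture,
                         flank_len: int = 200) -> JunctionPanel:
    """Extract the three diagnostic windows from a locus fixture."""
    wt = fixture.wt_haplotype.seq
    ins = fixture.ins_haplotype.seq
    p = fixture.insertion_point.start          # TE inserted between p and p+1
    te_start = fixture.te.element.start        # on the insertion haplotype
    te_end = fixture.te.element.end

    def window(seq: str, centre: int, name: str) -> SequenceRecord:
        lo, hi = centre - flank_len, centre + flank_len
        if lo < 1 or hi > len(seq):
            raise PanelError(
                f"{name}: focal position {centre} lacks {flank_len} bp of "
                f"context within its contig")
        return SequenceRecord(name, seq[lo - 1 : hi])

    return JunctionPanel(
        wt_target=window(wt, p, "wt_site"),
        j5_target=window(ins, te_start, "te_junction_5p"),
        j3_target=window(ins, te_end, "te_junction_3p"),
        flank_len=flank_len,
    )


def trim_reads(reads: Sequence[SequenceRecord],
               trim_len: int = DEFAULT_CONFIG.read_trim_len) -> list[SequenceRecord]:
    """Cut reads to a homogeneous length: longer reads are truncated from
    the 3' end, shorter reads discarded."""
    out = []
    for r in reads:
        if len(r.seq) >= trim_len:
            out.append(SequenceRecord(r.id, r.seq[:trim_len], r.description))
    return out


def align_end_to_end(read: str, target: str,
                     max_mm: int = DEFAULT_CONFIG.max_mismatches) -> list[Placement]:
    """Every end-to-end placement of the read on either strand of the
    target with at most ``max_mm`` mismatches (no indels)."""
    return scan_end_to_end(read, target, max_mm)


def count_junction_reads(
    reads: Sequence[SequenceRecord],
    panel: JunctionPanel,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> tuple[int, int, int]:
    """Count reads supporting each panel target.

    A read counts for a target when at least one placement covers the
    focal position with >= ``config.min_flank`` bases on each side; a read
    counts at most once per target but may count for several targets.
    """
    counts = []
    focal = panel.focal
    for target in panel.targets:
        idx_cache: dict[int, EndToEndIndex] = {}
        n = 0
        for read in reads:
            rl = len(read.seq)
            if rl > len(target.seq):
                continue
            if rl not in idx_cache:
                idx_cache[rl] = EndToEndIndex(target.seq, rl,
                                              config.max_mismatches)
            for p in idx_cache[rl].placements(read.seq):
                start, end = p.offset + 1, p.offset + rl
                if (start <= focal - config.min_flank
                        and end >= focal + config.min_flank):
                    n += 1
                    break
        counts.append(n)
    return tuple(counts)


def normalize_and_call(
    raw_counts: tuple[int, int, int],
    library_size: int,
    tau: float = DEFAULT_TAU,
    genotype_id: str = "sample",
    norm_denominator: float = DEFAULT_CONFIG.norm_denominator,
) -> GenotypeCall:
    """Normalize counts to reads per ``norm_denominator`` library reads and
    call the genotype.

    het: all three targets above tau; hom_ins: both junctions above tau and
    the intact site at or below; hom_wt: the intact site above tau and both
    junctions at or below; anything else: no_call.
    """
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    wt, j5, j3 = (c / library_size * norm_denominator for c in raw_counts)
    if wt > tau and j5 > tau and j3 > tau:
        call = "het"
    elif j5 > tau and j3 > tau and wt <= tau:
        call = "hom_ins"
    elif wt > tau and j5 <= tau and j3 <= tau:
        call = "hom_wt"
    else:
        call = "no_call"
    return GenotypeCall(genotype_id, tuple(raw_counts), library_size,
                        (wt, j5, j3), call)


def genotype_sample(
    reads: Sequence[SequenceRecord],
    panel: JunctionPanel,
    library_size: int,
    config: PipelineConfig = DEFAULT_CONFIG,
    tau: float = DEFAULT_TAU,
    genotype_id: str = "sample",
) -> GenotypeCall:
    """Trim, count and call one genotype in a single step."""
    trimmed = trim_reads(reads, config.read_trim_len)
    raw = count_junction_reads(trimmed, panel, config)
    return normalize_and_call(raw, library_size, tau, genotype_id,
                              config.norm_denominator)
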