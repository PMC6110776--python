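"""Physical-interval delimitation from genetic-map flanking markers.

Markers are placed on the genome with an ungapped seed-and-extend local
matcher; a placement passes when its identity strictly exceeds the
configured threshold (>97%) and its length exceeds 40 bp, and a marker is
retained only when exactly one placement passes genome-wide.  The mapped
interval spans from the leftmost to the rightmost retained flanking-marker
coordinate (outer edges), and annotated genes intersecting it are listed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .align import SeedExtendMatcher
from .config import DEFAULT_CONFIG, PipelineConfig
from .seqio import GeneModel, GenomicInterval, SequenceRecord

__all__ = ["MarkerHit", "MappedInterval", "MappingError",
           "map_markers", "define_interval", "genes_in_interval"]

_MARKER_SEED_K = 20


class MappingError(ValueError):
    """Raised when an interval cannot be defined from the given hits."""


@dataclass(frozen=True)
class MarkerHit:
    """Best passing placement of one marker, with its genome-wide
    placement count (retained markers have ``n_placements == 1``)."""

    marker_id: str
    target: GenomicInterval
    identity: float
    hsp_len: int
    n_placements: int

    @property
    def retained(self) -> bool:
        return self.n_placements == 1


@dataclass(frozen=True)
class MappedInterval:
    """The physical interval delimited by two flanking markers."""

    interval: GenomicInterval
    flanking_markers: tuple[MarkerHit, MarkerHit]
    genes: tuple[tuple[str, GenomicInterval], ...] = ()

    @property
    def length_bp(self) -> int:
        return self.interval.length

    @property
    def length_mb(self) -> float:
        return round(self.interval.length / 1e6, 1)


def map_markers(
    markers: Sequence[SequenceRecord],
    genome: Sequence[SequenceRecord],
    config: PipelineConfig = DEFAULT_CONFIG,
) -> list[MarkerHit]:
    """Place each marker on both strands of the genome.

    Returns one :class:`MarkerHit` per marker with at least one passing
    placement (identity > ``marker_min_identity`` and HSP length > 40 bp);
    the hit records the best placement and the number of passing
    placements.  Only hits with ``n_placements == 1`` should be used to
    delimit an interval.
    """
    if not genome:
        raise ValueError("empty genome")
    matcher = SeedExtendMatcher(genome, seed_k=_MARKER_SEED_K)
    hits: list[MarkerHit] = []
    for marker in markers:
        if len(marker.seq) < config.marker_min_hsp:
            continue
        matches = [
            m for m in matcher.search(marker.seq, min_len=config.marker_min_hsp,
                                      min_identity=config.marker_min_identity)
            if m.identity > config.marker_min_identity
            and m.length >= config.marker_min_hsp
        ]
        if not matches:
            continue
        best = max(matches, key=lambda m: (m.identity, m.length))
        hits.append(MarkerHit(
            marker_id=marker.id,
            target=GenomicInterval(best.contig, best.g_start, best.g_end,
                                   best.strand),
            identity=best.identity,
            hsp_len=best.length,
            n_placements=len(matches),
        ))
    return hits


def define_interval(hits: tuple[MarkerHit, MarkerHit]) -> MappedInterval:
    """Interval spanned by two flanking marker hits (outer edges).

    Symmetric in its arguments; both hits must be on the same contig.
    """
    a, b = hits
    if a.target.contig != b.target.contig:
        raise MappingError(
            f"flanking markers map to different contigs: "
            f"{a.target.contig} vs {b.target.contig}")
    start = min(a.target.start, b.target.start)
    end = max(a.target.end, b.target.end)
    return MappedInterval(
        interval=GenomicInterval(a.target.contig, start, end, "+"),
        flanking_markers=(a, b),
    )


def genes_in_interval(
    interval: GenomicInterval | MappedInterval,
    annotation: Sequence[GeneModel],
) -> list[tuple[str, GenomicInterval]]:
    """Genes whose span intersects the interval, sorted by start.

    Intersection (not containment) defines membership, so boundary-
    straddling genes are included.
    """
    iv = interval.interval if isinstance(interval, MappedInterval) else interval
    out = [(gm.gene_id, gm.span) for gm in annotation if gm.span.overlaps(iv)]
    out.sort(key=lambda t: t[1].start)
    return out
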