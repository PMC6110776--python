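"""k-mer occurrence profiling of a region within a read set.

Every 47-bp word of a region is counted in the read set (strand-collapsed
canonical counting, since reads are unstranded) and the counts are laid
out along the region as an occurrence track: high counts flag repeated
sequence, counts near the heterozygous single-copy mean flag
haplotype-specific sequence, and counts near the homozygous mean flag
shared single-copy sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .config import DEFAULT_CONFIG, PipelineConfig
from .seqio import GenomicInterval, SequenceRecord, parse_fastq, revcomp

__all__ = ["KmerTrack", "build_kmer_index", "occurrence_track",
           "classify_copy_number", "REPEAT_FACTOR"]

#: A position is "repeated" when its count exceeds this multiple of the
#: homozygous single-copy mean (midpoint between copy numbers 1 and 2).
REPEAT_FACTOR = 1.5

_ACGT = frozenset("ACGT")


@dataclass
class KmerTrack:
    """Occurrence counts per k-mer start position of a region.

    ``counts[i]`` is the read-set count of the canonical k-mer starting at
    1-based position ``i+1``; the track has ``region_length - k + 1``
    entries (empty when the region is shorter than k).  ``hom_mean`` and
    ``het_mean`` are the expected counts for homozygous and heterozygous
    single-copy sequence, supplied from control regions.
    """

    region: GenomicInterval | None
    k: int
    counts: np.ndarray
    hom_mean: float | None = None
    het_mean: float | None = None


def canonical(kmer: str) -> str:
    """Strand-collapsed representative: min(kmer, revcomp(kmer))."""
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def build_kmer_index(
    reads: Iterable[SequenceRecord | str] | str,
    k: int = DEFAULT_CONFIG.k,
) -> dict[str, int]:
    """Count canonical k-mers over a read set.

    ``reads`` may be a FASTQ path or an iterable of records/strings.
    k-mers containing non-ACGT characters are skipped; reads shorter than
    k contribute nothing.  Raises if a non-empty read set yields no k-mer.
    """
    if isinstance(reads, str):
        reads = parse_fastq(reads)
    counts: dict[str, int] = {}
    n_reads = 0
    for rec in reads:
        seq = rec.seq if isinstance(rec, SequenceRecord) else str(rec)
        n_reads += 1
        for i in range(len(seq) - k + 1):
            word = seq[i : i + k]
            if set(word) <= _ACGT:
                key = canonical(word)
                counts[key] = counts.get(key, 0) + 1
    if n_reads and not counts:
        raise ValueError(f"k={k} exceeds every read length; no k-mers counted")
    return counts


def occurrence_track(
    region_seq: SequenceRecord | str,
    index: dict[str, int],
    k: int = DEFAULT_CONFIG.k,
    region: GenomicInterval | None = None,
) -> KmerTrack:
    """Occurrence count of each k-mer of the region within the read set."""
    seq = region_seq.seq if isinstance(region_seq, SequenceRecord) else region_seq
    n = len(seq) - k + 1
    if n <= 0:
        return KmerTrack(region, k, np.zeros(0, dtype=np.int64))
    counts = np.zeros(n, dtype=np.int64)
    for i in range(n):
        word = seq[i : i + k]
        if set(word) <= _ACGT:
            counts[i] = index.get(canonical(word), 0)
    return KmerTrack(region, k, counts)


def classify_copy_number(
    track: KmerTrack,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> list[str]:
    """Label each track position as repeated / single_copy / haplotype_specific.

    A position is ``repeated`` when its count exceeds ``REPEAT_FACTOR *
    hom_mean``, ``haplotype_specific`` when it falls below the midpoint of
    the heterozygous and homozygous means, and ``single_copy`` otherwise.
    Labels are then smoothed by majority vote over a window of k positions
    (a single SNP perturbs k consecutive k-mers, so narrower windows
    over-fragment the labels).
    """
    if track.hom_mean is None or track.het_mean is None:
        raise ValueError("calibration means (hom_mean, het_mean) are required")
    if not track.hom_mean > track.het_mean > 0:
        raise ValueError("need hom_mean > het_mean > 0")
    labels = []
    hi = REPEAT_FACTOR * track.hom_mean
    lo = (track.het_mean + track.hom_mean) / 2.0
    for c in track.counts:
        if c > hi:
            labels.append("repeated")
        elif c < lo:
            labels.append("haplotype_specific")
        else:
            labels.append("single_copy")
    return _majority_smooth(labels, window=track.k)


def _majority_smooth(labels: Sequence[str], window: int) -> list[str]:
    half = window // 2
    n = len(labels)
    out = []
    for i in range(n):
        seg = labels[max(0, i - half) : min(n, i + half + 1)]
        out.append(max(set(seg), key=seg.count))
    return out
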