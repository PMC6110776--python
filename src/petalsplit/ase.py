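"""Allele-specific RNA-seq quantification for a two-allele locus.

Read pairs are placed end-to-end (substitution-bounded, no indels) on the
two allele transcripts and on a decoy set representing other loci, then
sorted into four categories: (i) specific to allele A, (ii) specific to
allele B, (iii) matching both alleles equally well with no decoy
placement as good, and (iv) matching a decoy at least as well as the
alleles (reads from repeated sequence).  Per-position coverage is
computed per category and normalized by library size; ambiguous coverage
(iii + iv) is then spread between the alleles according to the local
(i)/(ii) ratio on a sliding window, and per-allele expression is reported
as FPKM.

The apportionment operates on a common coordinate frame shared by the two
allele transcripts (equal-length transcripts differing by substitutions;
a shorter track is zero-padded).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .align import EndToEndIndex
from .config import DEFAULT_CONFIG, PipelineConfig
from .seqio import SequenceRecord
from .simdata import ReadPair

__all__ = ["ClassifiedPair", "CategorizedPairs", "AlleleCoverage",
           "classify_read_pairs", "coverage_tracks", "combine_tracks",
           "apportion_ambiguous", "expression_per_stage",
           "estimate_allele_fraction"]

_MAX_FRAGMENT = 1200   # concordance limit on implied fragment length (bp)


@dataclass(frozen=True)
class ClassifiedPair:
    """One categorized read pair with its coverage footprint.

    ``cov`` holds the two per-mate covered intervals (1-based, inclusive)
    on the coordinate frame given by ``frame`` ('A' or 'B').
    """

    pair_id: str
    category: str
    cov: tuple[tuple[int, int], tuple[int, int]]
    frame: str


@dataclass
class CategorizedPairs:
    """The four-way partition of pairs matching at least one allele."""

    cat_i: list[ClassifiedPair] = field(default_factory=list)
    cat_ii: list[ClassifiedPair] = field(default_factory=list)
    cat_iii: list[ClassifiedPair] = field(default_factory=list)
    cat_iv: list[ClassifiedPair] = field(default_factory=list)

    @property
    def total(self) -> int:
        return (len(self.cat_i) + len(self.cat_ii)
                + len(self.cat_iii) + len(self.cat_iv))


@dataclass
class AlleleCoverage:
    """Per-position normalized coverage on the common transcript frame."""

    cov_i: np.ndarray
    cov_ii: np.ndarray
    ambiguous: np.ndarray
    window: int = DEFAULT_CONFIG.ase_window
    assigned_a: np.ndarray | None = None
    assigned_b: np.ndarray | None = None


class _PairedAligner:
    """Concordant placement of a read pair against one reference."""

    def __init__(self, reference: SequenceRecord, max_mm: int) -> None:
        self.ref = reference
        self.max_mm = max_mm
        self._idx: dict[int, EndToEndIndex] = {}

    def _index(self, read_len: int) -> EndToEndIndex:
        if read_len not in self._idx:
            self._idx[read_len] = EndToEndIndex(self.ref.seq, read_len,
                                                self.max_mm)
        return self._idx[read_len]

    def best(self, r1: str, r2: str):
        """Best concordant placement: minimal summed mismatches.

        Concordant means opposite strands, the forward mate leftmost, and
        an implied fragment length of at most ``_MAX_FRAGMENT``.
        Returns (score, cov_intervals) or None.
        """
        if len(r1) > len(self.ref.seq) or len(r2) > len(self.ref.seq):
            return None
        p1 = self._index(len(r1)).placements(r1)
        p2 = self._index(len(r2)).placements(r2)
        best = None
        for a in p1:
            for b in p2:
                if a.strand == b.strand:
                    continue
                fwd, rev = (a, b) if a.strand == "+" else (b, a)
                fwd_len = len(r1) if fwd is a else len(r2)
                rev_len = len(r2) if fwd is a else len(r1)
                if fwd.offset > rev.offset:
                    continue
                frag = rev.offset + rev_len - fwd.offset
                if frag > _MAX_FRAGMENT:
                    continue
                score = a.mismatches + b.mismatches
                if best is None or score < best[0]:
                    cov = ((fwd.offset + 1, fwd.offset + fwd_len),
                           (rev.offset + 1, rev.offset + rev_len))
                    best = (score, cov)
        return best


def classify_read_pairs(
    pairs: Sequence[ReadPair],
    allele_a: SequenceRecord,
    allele_b: SequenceRecord,
    decoys: Sequence[SequenceRecord] = (),
    config: PipelineConfig = DEFAULT_CONFIG,
) -> CategorizedPairs:
    """Sort read pairs into the four allele-specificity categories.

    A pair lands in (i)/(ii) when its best concordant score on one allele
    is strictly better than on the other, in (iii) when the best scores
    tie and no decoy placement is as good, and in (iv) when any decoy
    placement ties or beats the best allele placement.  Pairs matching no
    allele are dropped (they carry no allelic information).
    """
    al_a = _PairedAligner(allele_a, config.max_mismatches)
    al_b = _PairedAligner(allele_b, config.max_mismatches)
    al_d = [_PairedAligner(d, config.max_mismatches) for d in decoys]
    out = CategorizedPairs()
    for pair in pairs:
        hit_a = al_a.best(pair.r1, pair.r2)
        hit_b = al_b.best(pair.r1, pair.r2)
        if hit_a is None and hit_b is None:
            continue
        d_scores = [h[0] for h in (al.best(pair.r1, pair.r2) for al in al_d)
                    if h is not None]
        d_best = min(d_scores) if d_scores else None
        sa = hit_a[0] if hit_a else None
        sb = hit_b[0] if hit_b else None
        allele_best = min(s for s in (sa, sb) if s is not None)
        frame, cov = ("A", hit_a[1]) if hit_a is not None else ("B", hit_b[1])
        if d_best is not None and d_best <= allele_best:
            out.cat_iv.append(ClassifiedPair(pair.id, "iv", cov, frame))
        elif sb is None or (sa is not None and sa < sb):
            out.cat_i.append(ClassifiedPair(pair.id, "i", hit_a[1], "A"))
        elif sa is None or sb < sa:
            out.cat_ii.append(ClassifiedPair(pair.id, "ii", hit_b[1], "B"))
        else:
            out.cat_iii.append(ClassifiedPair(pair.id, "iii", cov, frame))
    return out


def _add_coverage(track: np.ndarray, cp: ClassifiedPair, weight: float) -> None:
    for lo, hi in cp.cov:
        hi = min(hi, track.size)
        if lo <= hi:
            track[lo - 1 : hi] += weight


def coverage_tracks(
    cats: CategorizedPairs,
    tx_len_a: int,
    tx_len_b: int,
    library_size: int,
    window: int = DEFAULT_CONFIG.ase_window,
    scale: float = 1e6,
) -> AlleleCoverage:
    """Per-position fragment coverage per category for one library.

    Each pair adds coverage over its two mate intervals (the inner
    fragment gap is not covered); values are scaled by ``scale /
    library_size`` so tracks from different libraries can be summed.
    """
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    n = max(tx_len_a, tx_len_b)
    w = scale / library_size
    cov_i = np.zeros(n)
    cov_ii = np.zeros(n)
    amb = np.zeros(n)
    for cp in cats.cat_i:
        _add_coverage(cov_i, cp, w)
    for cp in cats.cat_ii:
        _add_coverage(cov_ii, cp, w)
    for cp in cats.cat_iii + cats.cat_iv:
        _add_coverage(amb, cp, w)
    return AlleleCoverage(cov_i, cov_ii, amb, window)


def combine_tracks(a: AlleleCoverage, b: AlleleCoverage) -> AlleleCoverage:
    """Sum two library-normalized coverage objects."""
    if a.window != b.window or a.cov_i.size != b.cov_i.size:
        raise ValueError("incompatible coverage tracks")
    return AlleleCoverage(a.cov_i + b.cov_i, a.cov_ii + b.cov_ii,
                          a.ambiguous + b.ambiguous, a.window)


def apportion_ambiguous(
    cov: AlleleCoverage,
    window: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Spread ambiguous coverage between the alleles.

    At each position the ratio r = sum_w(i) / (sum_w(i) + sum_w(ii)) is
    computed over a centred sliding window (truncated at the transcript
    ends; r = 0.5 where both window sums vanish), and the ambiguous
    coverage is split r : (1 - r).  Total coverage is conserved
    position-wise.
    """
    w = cov.window if window is None else window
    if w % 2 == 0:
        raise ValueError("apportionment window must be odd")
    kernel = np.ones(w)
    sum_i = np.convolve(cov.cov_i, kernel, mode="same")
    sum_ii = np.convolve(cov.cov_ii, kernel, mode="same")
    denom = sum_i + sum_ii
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, sum_i / np.where(denom > 0, denom, 1.0), 0.5)
    assigned_a = cov.cov_i + r * cov.ambiguous
    assigned_b = cov.cov_ii + (1.0 - r) * cov.ambiguous
    cov.assigned_a, cov.assigned_b = assigned_a, assigned_b
    return assigned_a, assigned_b


def expression_per_stage(
    stage_fragments: dict[str, tuple[float, float]],
    tx_len_a: int,
    tx_len_b: int,
    library_sizes: dict[str, int],
) -> pd.DataFrame:
    """FPKM per allele per developmental stage.

    ``stage_fragments[stage] = (fragments_A, fragments_B)``;
    FPKM = fragments / (transcript_kb * library_millions).  The returned
    frame also carries the per-stage allele-A fraction.
    """
    if tx_len_a <= 0 or tx_len_b <= 0:
        raise ValueError("transcript lengths must be positive")
    if not stage_fragments:
        raise ValueError("at least one stage is required")
    rows = []
    for stage, (fa, fb) in stage_fragments.items():
        lib_m = library_sizes[stage] / 1e6
        fpkm_a = fa / (tx_len_a / 1e3) / lib_m
        fpkm_b = fb / (tx_len_b / 1e3) / lib_m
        total = fa + fb
        rows.append({
            "stage": stage, "fragments_a": fa, "fragments_b": fb,
            "fpkm_a": fpkm_a, "fpkm_b": fpkm_b,
            "fraction_a": fa / total if total else np.nan,
        })
    return pd.DataFrame(rows)


def estimate_allele_fraction(
    pairs: Sequence[ReadPair],
    allele_a: SequenceRecord,
    allele_b: SequenceRecord,
    decoys: Sequence[SequenceRecord] = (),
    config: PipelineConfig = DEFAULT_CONFIG,
) -> tuple[float, AlleleCoverage]:
    """End-to-end allele-A expression fraction from raw pairs.

    Classifies, builds coverage, apportions ambiguous coverage and
    returns (assigned-A coverage fraction, coverage object).
    """
    cats = classify_read_pairs(pairs, allele_a, allele_b, decoys, config)
    cov = coverage_tracks(cats, len(allele_a.seq), len(allele_b.seq),
                          library_size=max(len(pairs), 1))
    a, b = apportion_ambiguous(cov)
    total = a.sum() + b.sum()
    return (float(a.sum() / total) if total else 0.5, cov)
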