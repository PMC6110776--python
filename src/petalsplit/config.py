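"""Shared pipeline configuration.

Every fixed parameter of the analysis lives here so that a run is fully
described by one object: the k-mer word size used for the repeat track,
the read-trimming length and mismatch budget of the end-to-end matcher,
the junction flank rule, the library-size normalization denominator, the
allele-apportionment window, the marker-retention filters, the LTR-family
match-length thresholds and the bootstrap replicate count.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class PipelineConfig:
    """Fixed parameters shared across pipeline stages.

    Attributes
    ----------
    k : int
        Word size for the k-mer occurrence track (bp).
    read_trim_len : int
        Genomic reads are cut to this homogeneous length before genotyping.
    max_mismatches : int
        Mismatch budget of the end-to-end (substitution-only) read matcher.
    min_flank : int
        A read counts for a junction only if its placement covers the focal
        position with at least this many bases on each side.
    norm_denominator : float
        Junction read counts are expressed per this many library reads
        (reads per 100 million by default).
    ase_window : int
        Width (bp, odd) of the sliding window used to apportion ambiguous
        RNA-seq coverage between the two alleles.
    marker_min_identity : float
        A marker placement passes only if identity strictly exceeds this.
    marker_min_hsp : int
        Minimum passing placement (HSP) length; placements must be > 40 bp,
        i.e. at least this value.
    ltr_min_match : int
        Minimum LTR match length for family-level census hits (bp); scaled
        to 0.8x the query LTR when the query is shorter.
    solo_ltr_min_match : int
        Stricter minimum match length for solo-LTR calls (bp); scaled to
        0.9x the query LTR when the query is shorter.
    bootstrap_reps : int
        Bootstrap replicates for phylogeny support values.
    rng_seed : int
        Seed for every stochastic stage.
    """

    k: int = 47
    read_trim_len: int = 100
    max_mismatches: int = 2
    min_flank: int = 15
    norm_denominator: float = 1e8
    ase_window: int = 241
    marker_min_identity: float = 0.97
    marker_min_hsp: int = 41
    ltr_min_match: int = 600
    solo_ltr_min_match: int = 900
    bootstrap_reps: int = 2000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("k", "read_trim_len", "min_flank", "ase_window",
                     "marker_min_hsp", "ltr_min_match", "solo_ltr_min_match",
                     "bootstrap_reps"):
            value = getattr(self, name)
            if not isinstance(value, int) or value <= 0:
                raise ValueError(f"{name} must be a positive integer, got {value!r}")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")
        if not 0.0 < self.marker_min_identity <= 1.0:
            raise ValueError("marker_min_identity must lie in (0, 1]")
        if self.ase_window % 2 == 0:
            raise ValueError("ase_window must be odd")
        if self.norm_denominator <= 0:
            raise ValueError("norm_denominator must be positive")


DEFAULT_CONFIG = PipelineConfig()
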