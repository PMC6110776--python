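# Methods

This note records the models, parameter choices and numerical decisions
behind `petalsplit`, and what the synthetic fixtures do and do not show.

## Coordinate and sequence conventions

All intervals are 1-based inclusive (`length = end − start + 1`,
implemented once in `GenomicInterval` and property-tested); conversion
to half-open slices happens only at internal array boundaries. Bases
outside {A,C,G,T} — including N — mismatch everything in every alignment
kernel, so an N can never help a placement. FASTQ qualities are parsed
and ignored: every kernel is substitution-count based.

## Read placement model

The genotyping and ASE stages share one placement contract: end-to-end,
substitution-only alignment with at most `max_mismatches` (default 2)
over the whole read, both strands, no indels. This is implemented
exactly, twice: an exhaustive Hamming scan (the reference), and a
pigeonhole-seeded index (the read is split into `max_mm + 1` segments;
any qualifying placement contains one exact segment, so exact segment
hits enumerate all candidates, each verified by Hamming count). The two
are equality-tested against each other. A Hamming scan implements the
stated contract exactly at panel scale, which is why no external aligner
is used; the price is that indel polymorphisms are invisible to the
whole pipeline (a known limitation of the model, not an approximation
bug).

Marker mapping and the TE census use a second, local matcher: exact
seed words (20 bp for near-identical markers, 12 bp for diverged family
copies) grouped per (contig, strand, diagonal), chained when gaps
≤ 150 bp, and extended with an X-drop rule (match +1, mismatch −3,
drop 15). Because simulated divergence is substitution-only, true
matches live on a single diagonal and the matcher is effectively exact
on fixtures; gapped copies would be fragmented. Statistical (e-value)
filtering is replaced throughout by the deterministic length and
identity thresholds the procedure actually prints (markers: identity
> 0.97 and HSP > 40 bp with genome-wide unique placement; census: match
length ≥ 600 bp family-level / ≥ 900 bp solo-stringent, scaled to
0.8×/0.9× the query LTR when the query is shorter, identities ≥ 80 % /
≥ 90 %): on desk-scale genomes these carry all the discriminative power.

## Junction genotyping

The three diagnostic targets are 401-bp windows (`flank_len = 200`)
whose central base is the insertion-point base of the intact allele, the
first TE base (5′ junction) and the last TE base (3′ junction). A read
supports a target when some placement covers the focal base with ≥ 15 bp
on each side; it counts once per target but may count for several
targets (the windows share flank sequence; the focal-coverage rule is
what disambiguates). Counts are normalized to reads per 10⁸ library
reads. The call threshold τ = 1 per 10⁸ separates zero from positive
signal while guarding against a single chimeric read at realistic
library sizes; any τ between 0 and the weakest true signal gives the
same calls. Expected counted reads per junction at coverage c are
c·(read_len − 2·min_flank + 1)/read_len ≈ 0.71·c per carrying haplotype,
so calls are Poisson-limited below ~5× per haplotype.

## k-mer repeat track

Counting is canonical (a word and its reverse complement share a key)
because reads are unstranded; words containing N are skipped. The
repeated/single-copy boundary is 1.5 × the homozygous single-copy mean —
the midpoint between copy numbers 1 and 2 — and the haplotype-specific
boundary is the midpoint of the heterozygous and homozygous means.
Calibration means must come from labelled control regions or the user;
the track itself never self-calibrates. Labels are majority-smoothed
over a window of k positions, since a single SNP perturbs k consecutive
words. Per-position counts at coverage c have mean ≈ 2c·(r−k+1)/r for
diploid single-copy sequence and Poisson-scale noise that is strongly
correlated over ~r−k neighbouring positions; per-position label accuracy
therefore needs deeper coverage (the label tests use 40×) than the
median-ratio statistic (robust at 10×).

## LTR element model

`find_ltrs` assumes the element was extracted to its boundaries, so the
two LTRs are terminal: it scores prefix-vs-suffix identity for every
candidate length (match +1, mismatch −3) and takes the best-scoring
length, requiring ≥ 90 % identity. The mismatch penalty makes the score
peak at the true boundary rather than drifting into random sequence
(+1/−3 means extension beyond the repeat loses ~2 per base in
expectation). LTR identity is a global Needleman–Wunsch with unit
costs; ORF finding is a plain six-frame ATG→stop enumeration (protein
domain annotation is out of scope). In the census, matched LTR hits are
padded to the full query projection before pairing, restoring
element-level boundaries for diverged copies; a complete copy requires
two same-strand LTR hits whose gap is 0.5–1.3 × the internal-query
length, covered ≥ min(800 bp, 0.8 × internal) by internal matches, with
total span ≤ 1.5 × the element (the gap conditions prevent pairings that
straddle a neighbouring copy). Solo-LTRs are near-full-length stringent
hits not consumed by a complete copy; the two sets are disjoint by
construction.

## Splice and miR172 model

The acceptor model is deliberately minimal and branch-point-free: the
first AG inside the 5′ LTR preceded by ≥ 6 pyrimidines in the preceding
12 bases (`p_min`, `p_win` configurable). The mutant transcript is
exons 1–8 plus a chimeric exon running from the base after that AG to a
polyadenylation boundary that is a *fixture parameter* — 3′-end
prediction is explicitly out of model. Both transcripts are translated
from the annotated start codon to the first stop.

miR172 sites are scored ungapped with Allen-style position weights:
mismatch 1.0, G:U wobble 0.5, penalties doubled over miRNA positions
2–13 (the functional seed of plant miRNA targeting), reported at total
penalty ≤ 3.0. miRNA position 1 is its 5′ end, pairing with the 3′ end
of the site. The weights are exposed as constants; the cutoff as an
argument.

## Allele-specific expression

Pair placement on the two allele transcripts and a decoy set replaces a
two-pass spliced-aligner workflow; at desk scale exhaustive placement is
affordable and the outcome is the same four-way partition: (i)/(ii)
strictly better best score on one allele; (iii) tied best on both
alleles with no decoy as good; (iv) any decoy placement tying or beating
the alleles (reads from repeated sequence, including those matching the
extracted alleles but belonging elsewhere). "Equally good" means equal
minimal mismatch count — score tie-breaking beyond mismatches is out of
model. Coverage is per-mate (the inner fragment gap is uncovered),
scaled by 1/library_size per library before summation. Ambiguous
(iii+iv) coverage is spread by r = Σw(i)/(Σw(i)+Σw(ii)) on a centred
241-bp window, truncated at transcript ends, r = 0.5 where both window
sums vanish; the window ratio uses coverage sums rather than pair counts
for positional smoothness. Apportionment conserves total coverage
position-wise to floating precision. It operates on a common coordinate
frame: the ASE fixtures use equal-length allele transcripts differing by
substitutions (a shorter track would be zero-padded); transcripts of
unequal structure are quantified correctly per category but share only
their common frame during apportionment. With zero divergence between
alleles the method is unidentifiable by design and returns 0.5.

## Phylogeny

Tajima–Nei (equal-input) distances: p is the proportion of differing
sites, gᵢ the base frequencies pooled over the pair, xᵢⱼ the frequencies
of unordered differing site patterns, h = Σᵢ<ⱼ xᵢⱼ²/(2gᵢgⱼ),
b = (1 − Σgᵢ² + p²/h)/2 and d = −b·ln(1 − p/b). Columns with a gap or
ambiguity in either sequence of a pair are excluded (pairwise deletion;
complete deletion available), implementing "indels not taken into
account". Saturated pairs (p ≥ b) and empty overlaps are flagged NaN,
never clamped — NJ refuses such matrices rather than silently repairing
them. A p-distance fallback covers amino-acid alignments. NJ is the
standard Saitou–Nei algorithm; Q-ties break to the lowest taxon-index
pair, and negative branch lengths are reported as computed so additive
matrices round-trip exactly. Bootstrap supports resample alignment
columns with replacement and count bipartition recovery; the default is
2,000 replicates, with tests and examples scaled to 100–200. Rooting
bisects the outgroup's pendant edge; supports stay attached to their
bipartitions across rooting.

## Synthetic fixtures: what they emulate, and what they do not

The locus generator builds a 10-exon gene (60-nt 5′ UTR, 1,383-nt CDS =
460 aa + stop, 200-nt 3′ UTR) over i.i.d.-uniform background, with the
miR172 target site planted in frame across the exon-9/exon-10 junction,
exons 1–8 ending on a codon boundary after 302 codons, and a TE inserted
mid-intron-8 whose 5′ LTR carries exactly one qualifying acceptor (all
chance acceptor motifs are deterministically suppressed) followed by an
in-frame chimeric segment of 40 sense codons and a stop — hence the
342-aa truncated protein. The element defaults to the focal insertion's
scale: 10,790 bp with 1,500-bp LTRs (an LTR length typical of plant
Gypsy elements; the internal region then accommodates the planted
5,535-bp ORF, kept maximal by an in-frame upstream stop), identical LTRs
by default (a recent insertion). Genomic reads are single-end 100 bp —
the geometry the genotyping procedure was designed for — drawn uniformly
per haplotype at Poisson depth with substitution errors only; RNA-seq is
paired-end with normal fragment sizes. The family-census fixture plants
complete copies and solo-LTRs, each independently mutated and randomly
stranded, at disjoint positions.

These fixtures deliberately omit: indels and structural noise, PCR
duplicates, quality-dependent errors, biological base composition,
target-site duplications at insertion points, nested/fragmented TE
copies, and spliced read alignment. Passing tests therefore demonstrate
the correctness of the decision rules and arithmetic under the stated
error model, not robustness to every artefact of real resequencing data.

## Problem sizes

The unit and acceptance suites run a compact variant of the locus
(2,000-bp element, 300-bp LTRs, ~5.2-kb wild-type haplotype) so that a
full genotyping replicate is a sub-second operation; census genomes are
40 kb with 3 complete + 5 solo planted copies; ASE uses 2-kb allele
transcripts with a SNP every 150 bp outside a 500-bp identical block
(~25 % ambiguous pairs) at 10,000 pairs per run; bootstrap checks use
100 replicates. The full-size element (10,790 bp / 1,500-bp LTRs) is
exercised in the TE-structure and splice stages, where a single fixture
suffices. Each simulated genotype replicate is driven by a single seed
(fixture and sequencing); the genotype-recovery check is
Poisson-limited, with roughly a 1-in-700 chance per heterozygote target
of drawing zero junction reads at 10×/1 % error.

## Known limitations

* No indel tolerance anywhere in read placement or local matching.
* `find_ltrs` requires terminal repeats (extracted elements), not
  elements embedded mid-contig.
* The census assumes substitution-level family divergence; gapped or
  nested copies fragment.
* The acceptor model ignores branch points and splicing strength; the
  mutant 3′ end is supplied, not predicted.
* Amino-acid phylogenies fall back to p-distance; the Tajima–Nei model
  is nucleotide-only.
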