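# petalsplit

Tools for the computational chain that links a transposable-element
insertion in a rose *AP2-like* gene to the double-flower phenotype.

In roses, double flowers (stamens homeotically converted to extra petals)
segregate with a dominant locus on chromosome 3. Within the mapped
interval lies a euAP2/TOE-family transcription factor whose heterozygous
mutant allele carries a ~10.8-kb Gypsy LTR retrotransposon in intron 8.
A splice acceptor inside the element's 5′ LTR creates a chimeric exon
with a premature stop codon: the truncated transcript loses its two
terminal exons and, with them, its miR172 binding site — making it
resistant to the microRNA that normally silences euAP2 genes in the
centre of the floral meristem. `petalsplit` re-implements every desk
step of that analysis as a tested Python library, for researchers who
want to run the same logic on their own locus or reads:

* **locus mapping** — place genetic markers (identity > 97 %, HSP > 40 bp,
  unique-placement filter) and delimit the physical interval between
  flanking markers; list annotated genes inside it;
* **k-mer repeat profiling** — count each 47-bp word of a region in a
  read set (canonical, strand-collapsed) and label positions repeated /
  single-copy / haplotype-specific against calibration means;
* **TE annotation & census** — recover LTR boundaries by terminal
  self-comparison, score LTR identity (identical LTRs ⇒ recent
  insertion), find internal ORFs, and census a genome for complete
  copies (LTR pair flanking an internal match) versus solo-LTRs;
* **junction genotyping** — trim reads to 100 bp, place them end-to-end
  with ≤ 2 mismatches, count reads covering the intact site or a gene/TE
  junction with ≥ 15 bp on each side, normalize to reads per 10⁸, and
  call hom/het/absent;
* **splice & miR172 consequence** — predict the LTR acceptor
  (AG after a polypyrimidine tract), assemble the chimeric transcript,
  translate both alleles, and score miR172 target sites with a
  position-weighted penalty scheme (mismatch 1, G:U 0.5, doubled over
  miRNA positions 2–13, cutoff 3);
* **allele-specific expression** — sort read pairs into four specificity
  categories, compute per-position coverage, spread ambiguous coverage
  by the local specific-coverage ratio on a 241-bp window, and report
  per-allele FPKM;
* **phylogeny** — Tajima–Nei distances
  (d = −b·ln(1 − p/b), b = (1 − Σgᵢ² + p²/h)/2, h = Σᵢ<ⱼ xᵢⱼ²/(2gᵢgⱼ),
  pairwise deletion), Neighbor-Joining, column-resampling bootstrap,
  outgroup rooting, Newick output;
* **synthetic data** — a first-class generator producing a diploid locus
  with/without the insertion, genomic reads, allele-mixed RNA-seq pairs
  and TE-seeded genomes, all with known ground truth.

## Worked example

Genotyping the insertion from simulated 100-bp reads at 10× per
haplotype with 1 % sequencing error (`examples/04_junction_genotyping.py`):

```
genotype         wt   5-prime TE   3-prime TE  call
hom_wt      1197605            0            0  hom_wt
het          417014       250209       667223  het
hom_ins           0      1122020       771388  hom_ins
```

Columns are reads per 10⁸ library reads supporting the intact wild-type
site and the two gene/TE junctions. A heterozygote shows all three
signals at comparable strength; homozygotes show exactly one side, and
zero junction reads exclude the insertion. The splice consequence on the
same fixture (`examples/05_splice_mir172.py`):

```
wild-type protein: 460 aa over 10 exons
mutant protein:    342 aa (premature stop: True; lost exons (9, 10))
miR172 site on wild-type transcript: True
miR172 site on mutant transcript:    False
```

The chimeric exon spliced from the 5′ LTR truncates the protein and
removes the miR172 site that sat across the exon-9/exon-10 junction.
Each script in `examples/` demonstrates one capability end to end.

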