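# probemap

Cross-species reuse of Infinium methylation BeadChip probes. Human
MethylationEPIC arrays carry ~850,000 fifty-mer probes designed against the
bisulfite-converted human genome; a useful minority of them hybridise well
enough to other genomes (mouse, rat, other laboratory species) to measure
DNA methylation there. `probemap` finds that minority for an arbitrary
reference genome and builds the annotation manifest needed to analyse array
data restricted to it.

The pipeline:

1. **prepare** — parse the Illumina-style probe manifest, reverse-complement
   each 50-mer (placing the probe's 3' end, which sits at the interrogated
   cytosine, at the query 5' end) and C→T convert it into the three-letter
   alphabet of bisulfite space.
2. **align** — convert the reference genome in silico on both strands
   (every C→T) and align each query ungapped with a 5'-seed mismatch
   allowance (defaults: seed length *l* = 28, *n* = 1 seed mismatch, total
   cap *n* + 1). A probe is kept only with a **unique best hit**: if two or
   more loci tie at the minimal mismatch count the probe is discarded as
   ambiguous. The reported MAPINFO is the 1-based coordinate of the target
   cytosine, derived from the design type (type II: the base flanking the
   aligned span; type I: its terminal base).
3. **mismatches** — compare the unconverted probe to the unconverted genome
   at its locus; differences explained by bisulfite chemistry (probe T over
   genomic C, and anything identical after collapsing C→T on both sides)
   are not mismatches. Remaining *true* mismatches at query positions 1–5 —
   the 3' probe end, where mismatches perturb hybridisation most — are
   flagged. The target-site dinucleotide (CpG / CpA / CpT / CpC / TpG /
   other) is read from the reference on the reported strand.
4. **annotate** — classify each retained site against gene models
   (priority TSS200 > TSS1500 > 5'UTR > 1st exon > body > 3'UTR > IGR when
   transcripts overlap), CpG-island context (island / shore ≤ 2 kb /
   shelf ≤ 4 kb / open sea) and enhancer intervals, and write the manifest
   TSV.
5. **qc** — filter a beta-value matrix (sex chromosomes → listed probe ids
   → detection *P* ≥ 0.01 in any sample), check the expected bimodal beta
   density (~0.1 and ~0.85 for valid signal; failed probes peak near 0.3),
   score replicate agreement as squared Pearson correlation, and cluster
   samples with Ward-variant (ward.D2) linkage on Euclidean distances.

A `synthetic` module generates every input format (genome FASTA, CGI and
enhancer BED, genePred gene models, probe CSV, beta/detection-P TSV) with
recorded ground truth, and contains a position-exhaustive brute-force
aligner used as the oracle for the seeded aligner.

## Worked example

Everything below runs on synthetic data; no downloads are needed.

```bash
probemap simulate probes --seed 31 --out sim --n-probes 60 --length 30000
probemap prepare --manifest sim/probes.csv --out probes.fa
probemap align --probes probes.fa --genome sim/genome.fa -l 28 -n 1 --out hits.tsv
probemap mismatches --hits hits.tsv --probes sim/probes.csv \
    --genome sim/genome.fa --out mm.tsv
probemap annotate --hits hits.tsv --genes sim/genes.genePred \
    --cgi sim/cgi.bed --enhancers sim/enhancers.bed --mm mm.tsv \
    --out manifest.tsv
```

prints

```
60 probes written to sim/probes.csv
60 queries written to probes.fa (0 of 60 rows skipped)
UM: 60/60  ME: 100.0%  (ambiguous: 0, unmapped: 0)
60 probes written to mm.tsv
60 manifest rows written to manifest.tsv
```

`UM` is the number of uniquely mapped probes and `ME` the mapping
efficiency (percent of input probes retained). All 60 planted probes map
uniquely because this simulation plants them without mutations or
duplicated loci. The manifest begins

```
probe_id  CHR   MAPINFO  Strand  Infinium_Design_Type  Gene_names  Gene_region  CGI_context
cgS00028  chr1  936      +       II                                IGR          OpenSea
cgS00031  chr1  1547     -       II                                IGR          OpenSea
cgS00002  chr1  3287     +       II                                IGR          Shelf
```

where MAPINFO is the 1-based position of the interrogated cytosine and the
remaining columns carry the gene-region, CpG-context, enhancer, target-site
and position-1–5 mismatch annotations. With array data in hand,
`probemap qc` then writes the filtered matrix, the density curve and modes,
replicate R², and a Newick dendrogram of the samples.

The same commands scale to real inputs: an Illumina manifest CSV, a genome
FASTA, a UCSC refGene table and CGI/enhancer BED files.

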