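# Methods

## The mapping model

Infinium methylation probes hybridise to bisulfite-converted DNA, in which
every unmethylated cytosine reads as thymine while methylated cytosines
remain cytosine. A probe sequence therefore cannot be compared with a raw
genome directly: both sides are first projected into three-letter space.
The reference is converted in silico on both strands — the forward sequence
with every C→T, and likewise the reverse complement — and the probe is
reverse-complemented and C→T converted, which puts the probe's 3' terminus
(the end at or adjacent to the interrogated cytosine) at the query's 5'
end. The degenerate base R, used in type II probes opposite internal CpG
cytosines, complements to Y (C/T) and converts deterministically to T; a
probe whose query retains any other degenerate code after conversion cannot
be represented as a single query and is dropped with a warning.

Alignment is ungapped Hamming matching with two constraints: at most *n*
mismatches within the 5'-most *l* bases (the seed; defaults *l* = 28,
*n* = 1) and at most *n* + 1 mismatches over the whole query (configurable
via `total_mismatch_cap`). Positions over ambiguous reference bases (N)
always count as mismatches. The original short-read stacks this emulates
add a base-quality sum cutoff; probe FASTA queries carry no qualities, so a
plain total-mismatch cap is used instead and exposed as a parameter.
Full-scale unique-hit counts from quality-aware aligners are therefore
expected to be approximated, not reproduced bit-for-bit.

A probe is assigned a locus only under the **unique-best rule**: among all
hits satisfying the caps, the minimum mismatch count must be attained by
exactly one locus. Ties are never broken — two equally good loci mean the
array signal could come from either, so the probe is discarded as
ambiguous. Probes with no admissible hit are unmapped. Mapping efficiency
is the percentage of input probes with a unique best hit, reported to one
decimal.

### Seeding

Candidate loci are found by pigeonhole seeding: the seed is split into
*n* + 1 equal blocks, at least one of which must match exactly in any
admissible hit; the first min(block, 14) bases of each block are looked up
in a k-mer index over both converted strands, and every candidate is then
verified against both constraints by direct comparison. This is an
implementation detail behind the `align_probe` contract; a
position-exhaustive brute-force scan in the `synthetic` module provides the
independent check that the candidate generation loses nothing (verified
over the grid *l* ∈ {20, 28, 50} × *n* ∈ {0, 1, 2}).

### Coordinates

Internally all coordinates are 0-based half-open on the forward strand,
including for hits whose query matched the converted reverse strand.
Emitted MAPINFO is the 1-based position of the target cytosine: for type II
probes the base immediately 5'-flanking the aligned span in query
orientation (forward hits: `start`; reverse hits: `start + 50 + 1`,
1-based), for type I the terminal aligned base. A target falling outside
the chromosome (alignment at a contig edge) drops the probe with a warning
rather than emitting an invalid coordinate.

## True mismatches and target sites

Mismatch analysis returns to unconverted space: the raw probe (reverse-
complemented into query orientation) is compared to the raw reference over
the aligned span, read on the matched strand. A position is a *true*
mismatch iff the bases still differ after collapsing C→T on both sides
(with Y collapsing to T). This single rule removes exactly the differences
bisulfite chemistry can produce — probe T over genomic C (conversion of an
unmethylated cytosine) and probe C over genomic C (retained methylated
cytosine) — and is equivalent, for ungapped alignments, to reconciling an
aligner's mismatch (MD) tags with its methylation-call tags, without
depending on any tag dialect. Consequently every true mismatch is also a
converted-space mismatch, which the tests assert. Positions are reported
1-based from the query 5' end, and a flag marks mismatches at positions
1–5, the probe's 3' terminus where single-base changes most affect
hybridisation and single-base extension.

The target-site dinucleotide is read from the raw reference starting at
MAPINFO on the reported strand and classified as CpG, CpA, CpT, CpC, TpG or
other; TpG at a nominal CpG position is the signature of a C→T transition
by deamination of 5-methylcytosine.

## Annotation

Gene models are UCSC genePred/refGene rows validated against the layout
invariants (txStart ≤ cdsStart ≤ cdsEnd ≤ txEnd; sorted, non-overlapping
exons). The promoter extension is applied strand-aware at classification
time rather than baked into stored coordinates, so a site can never be
counted both as promoter of an extended transcript and body of the same
unextended one. Per transcript a site is classified as TSS200 (1–200 bp
upstream of the TSS, which is txStart on '+' and txEnd − 1 on '−'), TSS1500
(201–1500 bp upstream), 5'UTR (exonic, transcript-5' of the CDS), 1st exon,
3'UTR (exonic, transcript-3' of the CDS), or body (anywhere else inside the
transcript, introns included — the Illumina-manifest convention of
exonic-only UTRs). Non-coding transcripts (cdsStart == cdsEnd) take no UTR
classes. When several transcripts overlap, the classes are resolved by the
fixed priority TSS200 > TSS1500 > 5'UTR > 1st exon > body > 3'UTR > IGR;
the same order resolves multiple classes within one transcript, which makes
the classifier equal to an enumerate-everything-take-max oracle. Gene names
reported for a site are those of the transcripts attaining the winning
class, deduplicated case-insensitively.

CpG-island context uses distance from the nearest island boundary: 0 inside
an island, shore for 1–2000 bp, shelf for 2001–4000 bp, open sea beyond.
The 2 kb / 4 kb widths are the annotatr/Illumina convention and are
configurable. Enhancer overlap defaults to the 1-bp target site; a
probe-span mode is available, since interval-intersection analyses are
sometimes run over the full 50-mer footprint.

The manifest inner-joins mapping, mismatch, target-site and annotation
records over uniquely mapped probes, sorts by (chromosome, MAPINFO) with
natural chromosome ordering, and round-trips losslessly through TSV. The
validation column is NA until array data supplies it.

## Array QC

The QC stage consumes *normalised* beta values; within-array normalisation
(SWAN/BMIQ and relatives) is upstream and out of scope. Filtering removes,
in a fixed and separately counted order: probes absent from the manifest
(with a warning), probes on dropped chromosomes (default X and Y, for
mixed-sex designs), explicitly listed probe ids (e.g. probes known to
target non-CpG sites in the design species), and probes failing detection.
The detection rule is configurable as a maximum failing-sample fraction;
the default 0.0 removes a probe with detection *P* ≥ 0.01 in any sample,
the strictest common convention. Filtering is idempotent.

Beta densities use a Gaussian KDE with Silverman bandwidth on a 512-point
grid over [0, 1]; modes are local maxima sorted by height. Valid
methylation signal is bimodal (lowly and highly methylated probes); a
unimodal peak near 0.3 is the classic failed-hybridisation signature.
Replicate agreement is the squared Pearson correlation over probes observed
in both samples. Sample clustering is agglomerative with Ward-variant
linkage in which squared Euclidean distances drive the Lance–Williams
update (scipy's `ward`, equivalent to R's `ward.D2` on Euclidean input);
missing values are an error unless the pairwise-complete fallback is
requested, because silent NA handling changes distances. The dendrogram is
exported both as the merge table and as Newick with branch lengths equal to
merge-height differences.

## The synthetic generator

The generator exists so that every stage can be tested against recorded
truth with no downloads. Genomes are i.i.d. bases at a configurable GC
content (default 0.42, a mammalian-like value) with planted CpG-rich
islands, enhancer intervals and random multi-exon transcripts at recorded
coordinates. Probes are synthesised the way the array chemistry defines
them: a CpG is chosen (either strand), the target-strand window is
bisulfite-converted with each cytosine retained with probability 0.3
(mimicking methylated positions; retention is irrelevant to alignment and
recorded for the mismatch tests) and reverse-complemented into probe
orientation. Planted substitutions are drawn per base (default rates 0–3%
in the tests), capped at two per probe with at most one inside the default
seed so the locus remains recoverable under default parameters, and are
chosen to remain mismatches after C→T collapse; duplicated probes have
their aligned span copied verbatim to a second recorded location, making
them ambiguous by construction. Beta matrices draw valid probes from the
mixture 0.5·Beta(2, 18) + 0.5·Beta(17, 3) (component means ≈ 0.1 and 0.85),
re-draw 20% of probes per sample type to create between-type structure, add
clipped Gaussian replicate noise (sd 0.02), and give a designated 10% of
probes a unimodal Beta(6, 14) signal (peak ≈ 0.3) with detection *P* above
the cutoff in every sample. Default problem sizes — two 50 kb chromosomes,
60–600 probes, 10,000-probe beta matrices over a 3-cell-type × 2-replicate
design — keep every test and the verification script fast while leaving
all rates and counts large enough to be informative.

What the generator does *not* emulate: repeat structure and segmental
duplication (ambiguity beyond exact planted duplicates), SNP-driven
mismatch hotspots, probe-intensity chemistry and detection-P computation
from raw intensities, and normalisation artefacts. Passing tests therefore
demonstrate algorithmic correctness of mapping, classification, annotation
and QC arithmetic on faithful miniatures — not the biological hit rate of
any particular species pair, which depends on real sequence homology.

## Numerical and degenerate-input choices

- Score ties in hit classification are never broken; ambiguity is the
  point of the unique-best rule.
- Softmasked (lowercase) genome sequence is uppercased and used; N never
  matches anything, in seeding or verification.
- Chromosomes shorter than the query contribute no hits.
- Manifest rows sort chromosomes naturally (chr2 before chr10), then by
  coordinate, then probe id, so output is deterministic.
- `filter_probes` reports removals per rule in the fixed order
  sex-chromosome → listed → detection-P; counts are additive.
- KDE requires ≥ 2 finite values; replicate R² requires ≥ 3 shared probes;
  clustering requires ≥ 2 samples. Each raises a descriptive error below
  its minimum.
- All generators are pure functions of (seed, parameters); fixtures are
  regenerated at test time rather than stored.
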