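"""Three-letter alignment of probe queries to a bisulfite-converted genome.

The reference is converted in silico on both strands (every C of the forward
sequence becomes T, and likewise on the reverse complement), so that a fully
converted query can match regardless of the methylation state of the locus.
Queries are aligned ungapped with a 5'-seed mismatch allowance and a total
mismatch cap, and a probe is kept only when exactly one locus attains the
best (minimum-mismatch) score: ties mean the probe cannot be assigned a
unique target and it is discarded as ambiguous.

Coordinates: alignment hits store the 0-based leftmost position of the
aligned span *on the forward strand* regardless of which converted strand
matched; emitted manifest coordinates (MAPINFO) are 1-based positions of the
target cytosine, following Illumina convention.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .probe_io import ProbeRecord
from .seq import QUERY_ALPHABET, SequenceError, bisulfite_convert, revcomp

log = logging.getLogger(__name__)

#: k-mer width used for seed lookup; seeds shorter than this (after the
#: pigeonhole split) use their own length.
DEFAULT_INDEX_K = 14

UNIQUE_BEST = "unique_best"
AMBIGUOUS = "ambiguous"
UNMAPPED = "unmapped"


@dataclass(frozen=True)
class AlignParams:
    """Alignment parameters: 5' seed length, seed mismatch allowance and
    total mismatch cap (defaults to allowance + 1)."""

    seed_length: int = 28
    seed_mismatches: int = 1
    total_mismatch_cap: Optional[int] = None

    def __post_init__(self) -> None:
        if self.seed_length < 1:
            raise ValueError("seed_length must be >= 1")
        if not 0 <= self.seed_mismatches <= 3:
            raise ValueError("seed_mismatches must be in [0, 3]")
        if self.total_mismatch_cap is not None and self.total_mismatch_cap < self.seed_mismatches:
            raise ValueError("total_mismatch_cap must be >= seed_mismatches")

    @property
    def cap(self) -> int:
        return (
            self.total_mismatch_cap
            if self.total_mismatch_cap is not None
            else self.seed_mismatches + 1
        )


@dataclass(frozen=True)
class AlignmentHit:
    """One candidate locus for a probe query.

    ``start`` is 0-based on the forward strand; ``strand`` records which
    converted genome ('+' forward, '-' reverse complement) matched.
    """

    probe_id: str
    chrom: str
    start: int
    strand: str
    query_length: int
    mismatches_seed: int
    mismatches_total: int

    @property
    def score(self) -> int:
        return self.mismatches_total


@dataclass
class MappingResult:
    """Per-probe outcome of unique-best-hit classification."""

    probe_id: str
    status: str
    best_hit: Optional[AlignmentHit] = None
    n_best: int = 0
    chrom: Optional[str] = None
    mapinfo: Optional[int] = None  # 1-based target-cytosine coordinate
    strand: Optional[str] = None


@dataclass
class MappingStats:
    total_probes: int = 0
    uniquely_mapped: int = 0
    ambiguous: int = 0
    unmapped: int = 0
    edge_dropped: int = 0
    per_chrom_unique: Counter = field(default_factory=Counter)

    @property
    def mapping_efficiency(self) -> float:
        """Percent of probes with a unique best hit, to one decimal."""
        if self.total_probes == 0:
            return 0.0
        return round(100.0 * self.uniquely_mapped / self.total_probes, 1)


class ConvertedGenome:
    """A reference genome with both in-silico bisulfite-converted strands.

    Holds the raw (uppercased) sequence, the C->T conversion of the forward
    strand, the C->T conversion of the reverse complement, and lazily built
    k-mer indexes over both converted strands.  Soft-masked lowercase input
    is uppercased; ambiguous bases are preserved and never indexed, so they
    can only ever count as mismatches.
    """

    def __init__(self, seqs: dict[str, str], source: str = "<memory>"):
        if not seqs:
            raise ValueError(f"no sequences in {source}")
        self.source = source
        self.raw: dict[str, str] = {name: s.upper() for name, s in seqs.items()}
        self.chrom_lengths: dict[str, int] = {name: len(s) for name, s in self.raw.items()}
        self.ct_forward: dict[str, str] = {
            name: bisulfite_convert(s) for name, s in self.raw.items()
        }
        self.ct_reverse: dict[str, str] = {
            name: bisulfite_convert(revcomp(s)) for name, s in self.raw.items()
        }
        self._indexes: dict[int, dict[str, list[tuple[str, str, int]]]] = {}

    @classmethod
    def from_fasta(cls, path: str | Path) -> "ConvertedGenome":
        from pyfaidx import Fasta

        fasta = Fasta(str(path), read_long_names=False, rebuild=True)
        seqs = {name: str(fasta[name][:]) for name in fasta.keys()}
        if not seqs:
            raise ValueError(f"empty FASTA {path}")
        return cls(seqs, source=str(path))

    def strand_seq(self, chrom: str, strand: str) -> str:
        return self.ct_forward[chrom] if strand == "+" else self.ct_reverse[chrom]

    def kmer_index(self, k: int) -> dict[str, list[tuple[str, str, int]]]:
        """Positions of every unambiguous k-mer across both converted strands."""
        if k not in self._indexes:
            index: dict[str, list[tuple[str, str, int]]] = defaultdict(list)
            for chrom in self.raw:
                for strand in "+-":
                    seq = self.strand_seq(chrom, strand)
                    for i in range(len(seq) - k + 1):
                        kmer = seq[i : i + k]
                        if set(kmer) <= QUERY_ALPHABET:
                            index[kmer].append((chrom, strand, i))
            self._indexes[k] = dict(index)
        return self._indexes[k]


def convert_genome(fasta_path: str | Path) -> ConvertedGenome:
    """Load a FASTA and prepare both bisulfite-converted strands."""
    return ConvertedGenome.from_fasta(fasta_path)


def _count_mismatches(query: str, ref: str, seed_length: int) -> tuple[int, int]:
    seed = 0
    total = 0
    for j, (q, r) in enumerate(zip(query, ref)):
        if q != r or r not in QUERY_ALPHABET:
            total += 1
            if j < seed_length:
                seed += 1
    return seed, total


def align_probe(
    query: str, genome: ConvertedGenome, params: AlignParams = AlignParams()
) -> list[AlignmentHit]:
    """All ungapped alignments of a converted query on both converted strands.

    A hit must have at most ``seed_mismatches`` Hamming mismatches within the
    5' ``seed_length`` bases and at most ``cap`` over the whole query; any
    position over an ambiguous reference base counts as a mismatch.

    Candidate loci are found by pigeonhole seeding: the seed is split into
    ``n + 1`` blocks, at least one of which must match exactly, and the
    k-prefix of each block is looked up in the genome k-mer index before
    verifying the full query.
    """
    query = query.upper()
    if "C" in query:
        raise SequenceError("query contains 'C'; convert it before aligning")
    if set(query) - QUERY_ALPHABET:
        raise SequenceError(f"query contains non-A/G/T characters: {set(query) - QUERY_ALPHABET}")
    m = len(query)
    l = params.seed_length
    if m < l:
        raise ValueError(f"query length {m} is shorter than seed length {l}")

    n_blocks = params.seed_mismatches + 1
    block = l // n_blocks
    if block < 1:
        raise ValueError("seed_length must be at least seed_mismatches + 1")
    k = min(block, DEFAULT_INDEX_K)
    index = genome.kmer_index(k)
    offsets = [i * block for i in range(n_blocks)]

    candidates: set[tuple[str, str, int]] = set()
    for off in offsets:
        for chrom, strand, pos in index.get(query[off : off + k], ()):
            start = pos - off
            if start >= 0:
                candidates.add((chrom, strand, start))

    hits: dict[tuple[str, int, str], AlignmentHit] = {}
    for chrom, strand, start in candidates:
        length = genome.chrom_lengths[chrom]
        if length < m:
            continue
        if start + m > length:
            continue
        ref = genome.strand_seq(chrom, strand)[start : start + m]
        seed_mm, total_mm = _count_mismatches(query, ref, l)
        if seed_mm > params.seed_mismatches or total_mm > params.cap:
            continue
        fwd_start = start if strand == "+" else length - start - m
        key = (chrom, fwd_start, strand)
        if key not in hits:
            hits[key] = AlignmentHit(
                probe_id="",
                chrom=chrom,
                start=fwd_start,
                strand=strand,
                query_length=m,
                mismatches_seed=seed_mm,
                mismatches_total=total_mm,
            )
    return sorted(hits.values(), key=lambda h: (h.chrom, h.start, h.strand))


def classify_hits(hits: Sequence[AlignmentHit], probe_id: str = "") -> MappingResult:
    """Unique-best-hit rule: a probe is kept only when exactly one locus
    attains the minimum mismatch score; score ties make it ambiguous."""
    if not probe_id and hits:
        probe_id = hits[0].probe_id
    if not hits:
        return MappingResult(probe_id=probe_id, status=UNMAPPED, n_best=0)
    best_score = min(h.score for h in hits)
    best = [h for h in hits if h.score == best_score]
    if len(best) == 1:
        return MappingResult(
            probe_id=probe_id, status=UNIQUE_BEST, best_hit=best[0], n_best=1
        )
    return MappingResult(probe_id=probe_id, status=AMBIGUOUS, n_best=len(best))


def derive_mapinfo(
    hit: AlignmentHit, design_type: str, genome: ConvertedGenome
) -> Optional[tuple[str, int, str]]:
    """1-based coordinate of the target cytosine for a unique best hit.

    The query's 5' end corresponds to the probe's 3' end, which sits at the
    target site.  For type II probes the target cytosine is the base
    immediately 5'-flanking the aligned span in query orientation; for type I
    it is the terminal aligned base itself.  Returns None (with a warning)
    when the target falls outside the chromosome.
    """
    length = genome.chrom_lengths[hit.chrom]
    if design_type == "II":
        target0 = hit.start - 1 if hit.strand == "+" else hit.start + hit.query_length
    elif design_type == "I":
        target0 = hit.start if hit.strand == "+" else hit.start + hit.query_length - 1
    else:
        raise ValueError(f"unknown design type {design_type!r}")
    if not 0 <= target0 < length:
        log.warning(
            "probe %s: target position %d outside %s (length %d); dropped",
            hit.probe_id, target0, hit.chrom, length,
        )
        return None
    return hit.chrom, target0 + 1, hit.strand


def run_mapping(
    probes: Iterable[ProbeRecord],
    genome: ConvertedGenome,
    params: AlignParams = AlignParams(),
) -> tuple[list[MappingResult], MappingStats]:
    """Align every probe, classify hits and derive manifest coordinates.

    Returns one :class:`MappingResult` per probe plus summary statistics
    (uniquely mapped count, mapping efficiency in percent, per-chromosome
    unique-hit counts)."""
    results: list[MappingResult] = []
    stats = MappingStats()
    for probe in probes:
        stats.total_probes += 1
        hits = align_probe(probe.query_seq, genome, params)
        result = classify_hits(hits, probe_id=probe.probe_id)
        if result.status == UNIQUE_BEST:
            located = derive_mapinfo(result.best_hit, probe.design_type, genome)
            if located is None:
                stats.edge_dropped += 1
                result = MappingResult(probe_id=probe.probe_id, status=UNMAPPED, n_best=0)
            else:
                result.chrom, result.mapinfo, result.strand = located
                result.best_hit = AlignmentHit(
                    probe_id=probe.probe_id,
                    chrom=result.best_hit.chrom,
                    start=result.best_hit.start,
                    strand=result.best_hit.strand,
                    query_length=result.best_hit.query_length,
                    mismatches_seed=result.best_hit.mismatches_seed,
                    mismatches_total=result.best_hit.mismatches_total,
                )
        if result.status == UNIQUE_BEST:
            stats.uniquely_mapped += 1
            stats.per_chrom_unique[result.chrom] += 1
        elif result.status == AMBIGUOUS:
            stats.ambiguous += 1
        else:
            stats.unmapped += 1
        results.append(result)
    return results, stats


# ---------------------------------------------------------------------------
# Tabular I/O

HITS_COLUMNS = [
    "probe_id", "status", "chrom", "mapinfo", "strand",
    "start", "query_length", "design_type", "mm_seed", "mm_total",
]


def write_hits_tsv(
    results: Sequence[MappingResult],
    path: str | Path,
    design_types: Optional[dict[str, str]] = None,
) -> None:
    """Write per-probe mapping results as TSV (one row per probe)."""
    import pandas as pd

    rows = []
    for r in results:
        hit = r.best_hit
        rows.append(
            {
                "probe_id": r.probe_id,
                "status": r.status,
                "chrom": r.chrom or "",
                "mapinfo": r.mapinfo if r.mapinfo is not None else "",
                "strand": r.strand or "",
                "start": hit.start if hit else "",
                "query_length": hit.query_length if hit else "",
                "design_type": (design_types or {}).get(r.probe_id, ""),
                "mm_seed": hit.mismatches_seed if hit else "",
                "mm_total": hit.mismatches_total if hit else "",
            }
        )
    pd.DataFrame(rows, columns=HITS_COLUMNS).to_csv(path, sep="\t", index=False)


def read_hits_tsv(path: str | Path) -> list[MappingResult]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chrom": str})
    results = []
    for row in df.itertuples(index=False):
        result = MappingResult(probe_id=row.probe_id, status=row.status)
        if row.status == UNIQUE_BEST:
            result.chrom = str(row.chrom)
            result.mapinfo = int(row.mapinfo)
            result.strand = row.strand
            result.n_best = 1
            result.best_hit = AlignmentHit(
                probe_id=row.probe_id,
                chrom=str(row.chrom),
                start=int(row.start),
                strand=row.strand,
                query_length=int(row.query_length),
                mismatches_seed=int(row.mm_seed),
                mismatches_total=int(row.mm_total),
            )
        results.append(result)
    return results


def write_sam(
    results: Sequence[MappingResult],
    queries: dict[str, str],
    genome: ConvertedGenome,
    path: str | Path,
) -> None:
    """Minimal SAM of retained (unique-best) hits in converted space.

    Reverse-strand hits are stored reverse-complemented with flag 16, per SAM
    convention; the NM tag carries the converted-space mismatch count.
    """
    with open(path, "w") as handle:
        handle.write("@HD\tVN:1.6\tSO:unknown\n")
        for chrom, length in genome.chrom_lengths.items():
            handle.write(f"@SQ\tSN:{chrom}\tLN:{length}\n")
        handle.write("@PG\tID:probemap\tPN:probemap\n")
        for r in results:
            if r.status != UNIQUE_BEST or r.best_hit is None:
                continue
            hit = r.best_hit
            seq = queries[r.probe_id]
            flag = 0 if hit.strand == "+" else 16
            if hit.strand == "-":
                seq = revcomp(seq)
            handle.write(
                f"{r.probe_id}\t{flag}\t{hit.chrom}\t{hit.start + 1}\t255\t"
                f"{hit.query_length}M\t*\t0\t0\t{seq}\t*\tNM:i:{hit.mismatches_total}\n"
            )
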