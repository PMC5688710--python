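"""Synthetic fixtures with known ground truth, plus the brute-force oracle.

Everything the pipeline consumes — genome FASTA, CpG-island and enhancer
BED, genePred gene models, probe manifest CSV, beta/detection-P matrices —
can be generated here as a pure function of a seed, with the planted truth
recorded alongside.  Probes are synthesised the way the array chemistry
produces them: the target-strand window is bisulfite-converted with a
recorded subset of cytosines retained ("methylated"), reverse-complemented
into probe orientation, and optionally mutated at recorded positions.  The
brute-force aligner scans every genome position on both converted strands
with no indexing shortcuts and serves as the oracle for the seeded aligner.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .annotation import GeneModel
from .array_qc import BetaMatrix
from .bisulfite_align import AlignmentHit, AlignParams, ConvertedGenome
from .probe_io import PROBE_LENGTH, ProbeRecord
from .seq import bisulfite_convert, revcomp

BRUTE_FORCE_GUARD = 1_000_000  # total genome bp the oracle will scan


# ---------------------------------------------------------------------------
# Genome generation


@dataclass
class SyntheticGenome:
    """An i.i.d. random genome with recorded CGI, enhancer and gene features."""

    seqs: dict[str, str]
    cgi: list[tuple[str, int, int]]
    enhancers: list[tuple[str, int, int]]
    genes: list[GeneModel]
    gc_content: float
    seed: int

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.seqs.values())

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write FASTA + BED + genePred files; returns the paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "genome.fa",
            "cgi": outdir / "cgi.bed",
            "enhancers": outdir / "enhancers.bed",
            "genes": outdir / "genes.genePred",
        }
        with open(paths["fasta"], "w") as fh:
            for name, seq in self.seqs.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")
        _write_bed(self.cgi, paths["cgi"])
        _write_bed(self.enhancers, paths["enhancers"])
        with open(paths["genes"], "w") as fh:
            for g in self.genes:
                fh.write(
                    "\t".join(
                        [
                            g.transcript_id, g.chrom, g.strand,
                            str(g.tx_start), str(g.tx_end),
                            str(g.cds_start), str(g.cds_end),
                            str(len(g.exon_starts)),
                            ",".join(map(str, g.exon_starts)) + ",",
                            ",".join(map(str, g.exon_ends)) + ",",
                            "0", g.gene_name,
                        ]
                    )
                    + "\n"
                )
        return paths


def _write_bed(intervals: Iterable[tuple[str, int, int]], path: Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=probs))


def generate_genome(
    n_chrom: int = 2,
    length: int = 50_000,
    gc_content: float = 0.42,
    seed: int = 0,
    n_cgi_per_chrom: int = 3,
    n_enhancers_per_chrom: int = 3,
    n_genes_per_chrom: int = 3,
) -> SyntheticGenome:
    """Generate a random genome with planted CpG islands, enhancers and
    multi-exon transcripts at recorded coordinates.

    Bases are i.i.d. at the stated GC content except inside planted CpG
    islands, which are rewritten CpG-rich so the island annotation has the
    sequence character it labels.  Deterministic for a fixed seed.
    """
    if length < 1000:
        raise ValueError("chromosome length must be >= 1000")
    if not 0 < gc_content < 1:
        raise ValueError("gc_content must be in (0, 1)")
    rng = np.random.default_rng(seed)
    seqs: dict[str, str] = {}
    cgi: list[tuple[str, int, int]] = []
    enhancers: list[tuple[str, int, int]] = []
    genes: list[GeneModel] = []
    for c in range(n_chrom):
        chrom = f"chr{c + 1}"
        seq = list(_random_seq(rng, length, gc_content))
        # plant CpG-rich islands at recorded, non-overlapping coordinates
        occupied: list[tuple[int, int]] = []
        for _ in range(n_cgi_per_chrom):
            span = int(rng.integers(300, 800))
            start = _free_position(rng, length, span, occupied)
            if start is None:
                continue
            occupied.append((start, start + span))
            island = []
            while len(island) < span:
                island.append("CG" if rng.random() < 0.35 else rng.choice(list("ACGT")))
            text = "".join(island)[:span]
            seq[start : start + span] = list(text)
            cgi.append((chrom, start, start + span))
        seqs[chrom] = "".join(seq)
        for _ in range(n_enhancers_per_chrom):
            span = int(rng.integers(200, 400))
            start = int(rng.integers(0, length - span))
            enhancers.append((chrom, start, start + span))
        for g in range(n_genes_per_chrom):
            genes.append(_random_transcript(rng, chrom, length, f"NM_{c:02d}{g:04d}", f"Gene{c}_{g}"))
    cgi.sort()
    enhancers.sort()
    return SyntheticGenome(
        seqs=seqs, cgi=cgi, enhancers=enhancers, genes=genes,
        gc_content=gc_content, seed=seed,
    )


def _free_position(
    rng: np.random.Generator, length: int, span: int, occupied: list[tuple[int, int]],
    margin: int = 100, tries: int = 50,
) -> Optional[int]:
    for _ in range(tries):
        start = int(rng.integers(margin, length - span - margin))
        if all(start + span + margin <= s or start >= e + margin for s, e in occupied):
            return start
    return None


def _random_transcript(
    rng: np.random.Generator, chrom: str, chrom_len: int, tx_id: str, gene: str
) -> GeneModel:
    tx_len = int(rng.integers(2000, 8000))
    if chrom_len < tx_len + 3400:
        tx_len = max(300, chrom_len // 3)
    margin = min(1600, (chrom_len - tx_len) // 2)
    tx_start = int(rng.integers(margin, chrom_len - tx_len - margin + 1))
    tx_end = tx_start + tx_len
    n_exons = int(rng.integers(2, 6))
    # cut the transcript into alternating exon/intron blocks
    cuts = np.sort(rng.choice(np.arange(1, tx_len), size=2 * n_exons - 2, replace=False))
    bounds = [0, *cuts.tolist(), tx_len]
    exon_starts = [tx_start + bounds[i] for i in range(0, 2 * n_exons - 1, 2)]
    exon_ends = [tx_start + bounds[i + 1] for i in range(0, 2 * n_exons - 1, 2)]
    coding = rng.random() < 0.8
    if coding:
        cds_start = int(rng.integers(exon_starts[0], exon_ends[0]))
        cds_end = int(rng.integers(exon_starts[-1], exon_ends[-1]))
        if cds_end <= cds_start:
            cds_start, cds_end = exon_starts[0], exon_ends[-1]
    else:
        cds_start = cds_end = tx_start
    return GeneModel(
        transcript_id=tx_id,
        gene_name=gene,
        chrom=chrom,
        strand="+" if rng.random() < 0.5 else "-",
        tx_start=tx_start,
        tx_end=tx_end,
        cds_start=cds_start,
        cds_end=cds_end,
        exon_starts=exon_starts,
        exon_ends=exon_ends,
    )


# ---------------------------------------------------------------------------
# Probe planting


@dataclass
class ProbeTruth:
    """Ground truth for one planted probe."""

    probe_id: str
    chrom: str
    cytosine_pos: int  # 0-based position of the target cytosine (forward strand)
    strand: str
    design_type: str
    window_start: int  # 0-based forward-strand start of the aligned span
    mutations: list[tuple[int, str, str]]  # (1-based query pos, from, to)
    converted_positions: list[int]  # 1-based query positions bisulfite-converted
    multiplicity: int = 1


@dataclass
class PlantedProbeSet:
    """Planted probes, their truth and the (possibly edited) genome."""

    probes: list[ProbeRecord]
    truth: dict[str, ProbeTruth]
    genome: SyntheticGenome
    seed: int

    def write_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "IlmnID": [p.probe_id for p in self.probes],
                "AlleleA_ProbeSeq": [p.probe_seq for p in self.probes],
                "Infinium_Design_Type": [p.design_type for p in self.probes],
            }
        ).to_csv(path, index=False)

    def write_truth(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({pid: asdict(t) for pid, t in self.truth.items()}, fh, indent=1)

    @staticmethod
    def read_truth(path: str | Path) -> dict[str, ProbeTruth]:
        with open(path) as fh:
            raw = json.load(fh)
        return {
            pid: ProbeTruth(
                **{
                    **rec,
                    "mutations": [tuple(mut) for mut in rec["mutations"]],
                }
            )
            for pid, rec in raw.items()
        }


def _probe_window(
    pos: int, strand: str, design_type: str, m: int = PROBE_LENGTH
) -> int:
    """Forward-strand 0-based start of the aligned span for a probe whose
    target cytosine sits at forward position ``pos``.

    Derived from the coordinate conventions of the aligner: the query's 5'
    end carries the probe's 3' end, which is at (type I) or adjacent to
    (type II) the target.
    """
    if design_type == "II":
        return pos + 1 if strand == "+" else pos - m
    return pos if strand == "+" else pos - m + 1


def plant_probes(
    genome: SyntheticGenome,
    n_probes: int = 100,
    mutation_rate: float = 0.0,
    duplicate_fraction: float = 0.0,
    seed: int = 0,
    retention_prob: float = 0.3,
    type_ii_fraction: float = 0.84,
    max_mutations: int = 2,
) -> PlantedProbeSet:
    """Synthesise probes targeting CpG sites of the genome, with recorded
    mutations, bisulfite-conversion positions and planted duplicate loci.

    For each probe a CpG is chosen (forward-strand C for '+' probes, the
    complementary C for '-'), the target-strand window is bisulfite
    converted — each cytosine retained with ``retention_prob``, mimicking a
    methylated position, and converted otherwise — then reverse-complemented
    into probe orientation.  ``mutation_rate`` is the per-base substitution
    probability; at most ``max_mutations`` are planted per probe and at most
    one inside the first 28 query bases, so the default alignment settings
    still recover the locus.  A ``duplicate_fraction`` of probes have their
    aligned span copied verbatim to a second, recorded location, which makes
    them ambiguous by construction.  Duplicate copies overwrite genome
    sequence, so the genome carried by the returned set supersedes the
    input.
    """
    rng = np.random.default_rng(seed)
    m = PROBE_LENGTH
    margin = m + 5
    seqs = {c: list(s) for c, s in genome.seqs.items()}

    candidates: list[tuple[str, int]] = []
    for chrom, s in genome.seqs.items():
        start = margin
        while True:
            i = s.find("CG", start)
            if i == -1 or i >= len(s) - margin:
                break
            candidates.append((chrom, i))
            start = i + 2
    if len(candidates) < n_probes:
        raise ValueError(
            f"genome has only {len(candidates)} usable CpG sites; need {n_probes}"
        )
    order = rng.permutation(len(candidates))

    reserved: dict[str, list[tuple[int, int]]] = {c: [] for c in genome.seqs}
    chosen: list[tuple[str, int, str, str, int]] = []  # chrom, cyt pos, strand, type, start
    for idx in order:
        if len(chosen) == n_probes:
            break
        chrom, cpg = candidates[idx]
        strand = "+" if rng.random() < 0.5 else "-"
        design = "II" if rng.random() < type_ii_fraction else "I"
        # '-' probes target the C on the reverse strand, i.e. the G of the CpG
        pos = cpg if strand == "+" else cpg + 1
        start = _probe_window(pos, strand, design, m)
        if start < 0 or start + m > len(genome.seqs[chrom]):
            continue
        if any(start < e and s < start + m for s, e in reserved[chrom]):
            continue
        reserved[chrom].append((start, start + m))
        chosen.append((chrom, pos, strand, design, start))
    if len(chosen) < n_probes:
        raise ValueError("could not place the requested number of probes")

    n_dup = int(round(duplicate_fraction * n_probes))
    dup_indices = set(rng.choice(n_probes, size=n_dup, replace=False).tolist()) if n_dup else set()

    probes: list[ProbeRecord] = []
    truth: dict[str, ProbeTruth] = {}
    for i, (chrom, pos, strand, design, start) in enumerate(chosen):
        probe_id = f"cgS{i:05d}"
        window = genome.seqs[chrom][start : start + m]
        target_strand_seq = window if strand == "+" else revcomp(window)
        # bisulfite conversion of the target strand with recorded retention
        converted_positions: list[int] = []
        bs = []
        for j, base in enumerate(target_strand_seq):
            if base == "C" and rng.random() >= retention_prob:
                bs.append("T")
                converted_positions.append(j + 1)
            else:
                bs.append(base)
        query_raw = "".join(bs)  # unconverted probe in query orientation

        mutations: list[tuple[int, str, str]] = []
        n_mut = min(int(rng.binomial(m, mutation_rate)), max_mutations)
        if n_mut:
            positions = rng.choice(m, size=n_mut, replace=False)
            in_seed = 0
            for j in sorted(int(p) for p in positions):
                if j < 28:
                    if in_seed >= 1:
                        continue
                    in_seed += 1
                old = query_raw[j]
                new = _mutant_base(rng, old, target_strand_seq[j])
                query_raw = query_raw[:j] + new + query_raw[j + 1 :]
                mutations.append((j + 1, old, new))

        probe_seq = revcomp(query_raw)
        multiplicity = 1
        if i in dup_indices:
            dest = _duplicate_destination(rng, genome, reserved, m)
            if dest is not None:
                dchrom, dstart = dest
                seqs[dchrom][dstart : dstart + m] = list(window)
                reserved[dchrom].append((dstart, dstart + m))
                multiplicity = 2
        probes.append(
            ProbeRecord(
                probe_id=probe_id, design_type=design, probe_seq=probe_seq,
                query_seq=bisulfite_convert(query_raw),
            )
        )
        truth[probe_id] = ProbeTruth(
            probe_id=probe_id,
            chrom=chrom,
            cytosine_pos=pos,
            strand=strand,
            design_type=design,
            window_start=start,
            mutations=mutations,
            converted_positions=converted_positions,
            multiplicity=multiplicity,
        )

    edited = SyntheticGenome(
        seqs={c: "".join(s) for c, s in seqs.items()},
        cgi=genome.cgi,
        enhancers=genome.enhancers,
        genes=genome.genes,
        gc_content=genome.gc_content,
        seed=genome.seed,
    )
    return PlantedProbeSet(probes=probes, truth=truth, genome=edited, seed=seed)


def _mutant_base(rng: np.random.Generator, old: str, genome_base: str) -> str:
    """A substitution that is a true mismatch: it must differ from the old
    base and stay distinguishable from the genome base after C->T collapse."""
    collapse = {"C": "T"}
    g = collapse.get(genome_base, genome_base)
    options = [b for b in "ACGT" if b != old and collapse.get(b, b) != g]
    return str(rng.choice(options))


def _duplicate_destination(
    rng: np.random.Generator,
    genome: SyntheticGenome,
    reserved: dict[str, list[tuple[int, int]]],
    m: int,
    tries: int = 100,
) -> Optional[tuple[str, int]]:
    chroms = list(genome.seqs)
    for _ in range(tries):
        chrom = chroms[int(rng.integers(len(chroms)))]
        length = len(genome.seqs[chrom])
        if length < 3 * m:
            continue
        start = int(rng.integers(m, length - 2 * m))
        if all(start + m <= s or start >= e for s, e in reserved[chrom]):
            return chrom, start
    return None


# ---------------------------------------------------------------------------
# Brute-force oracle


def brute_force_align(
    query: str,
    genome_raw: SyntheticGenome | ConvertedGenome | dict,
    params: AlignParams = AlignParams(),
) -> list[AlignmentHit]:
    """Position-exhaustive oracle for the seeded aligner.

    Converts the genome on the fly and tests every start position on both
    converted strands against the seed and total mismatch caps — no index,
    no candidate pruning.  Guarded to genomes of at most 1 Mb.
    """
    grid = brute_force_align_grid(query, genome_raw, [params])
    return grid[0]


def brute_force_align_grid(
    query: str,
    genome_raw: SyntheticGenome | ConvertedGenome | dict,
    params_list: Sequence[AlignParams],
) -> list[list[AlignmentHit]]:
    """Run the brute-force scan once and read off hits for several parameter
    settings (the per-position mismatch prefix sums are shared)."""
    seqs = _genome_seqs(genome_raw)
    total = sum(len(s) for s in seqs.values())
    if total > BRUTE_FORCE_GUARD:
        raise ValueError(f"genome of {total} bp exceeds brute-force guard ({BRUTE_FORCE_GUARD})")
    query = query.upper()
    if "C" in query or (set(query) - set("AGT")):
        raise ValueError("query must be converted (A/G/T only)")
    m = len(query)
    for p in params_list:
        if p.seed_length > m:
            raise ValueError("seed length exceeds query length")

    boundaries = sorted({p.seed_length for p in params_list} | {m})
    qbytes = np.frombuffer(query.encode(), dtype=np.uint8)
    out: list[dict[tuple[str, int, str], AlignmentHit]] = [{} for _ in params_list]
    for chrom, seq in seqs.items():
        length = len(seq)
        if length < m:
            continue
        for strand in "+-":
            text = bisulfite_convert(seq.upper() if strand == "+" else revcomp(seq.upper()))
            sbytes = np.frombuffer(text.encode(), dtype=np.uint8)
            npos = length - m + 1
            # prefix mismatch counts at each boundary, every start position
            prefix: dict[int, np.ndarray] = {}
            acc = np.zeros(npos, dtype=np.int32)
            j = 0
            for b in boundaries:
                while j < b:
                    acc += sbytes[j : j + npos] != qbytes[j]
                    j += 1
                prefix[b] = acc.copy()
            for pi, p in enumerate(params_list):
                ok = (prefix[p.seed_length] <= p.seed_mismatches) & (prefix[m] <= p.cap)
                for start in np.flatnonzero(ok):
                    start = int(start)
                    fwd = start if strand == "+" else length - start - m
                    out[pi][(chrom, fwd, strand)] = AlignmentHit(
                        probe_id="",
                        chrom=chrom,
                        start=fwd,
                        strand=strand,
                        query_length=m,
                        mismatches_seed=int(prefix[p.seed_length][start]),
                        mismatches_total=int(prefix[m][start]),
                    )
    return [
        sorted(hits.values(), key=lambda h: (h.chrom, h.start, h.strand))
        for hits in out
    ]


def _genome_seqs(genome) -> dict[str, str]:
    if isinstance(genome, SyntheticGenome):
        return genome.seqs
    if isinstance(genome, ConvertedGenome):
        return genome.raw
    return dict(genome)


# ---------------------------------------------------------------------------
# Beta-matrix simulation


@dataclass
class BetaTruth:
    """Ground truth of a simulated array experiment."""

    failed_probe_ids: list[str]
    replicate_pairs: list[tuple[str, str]]
    sample_types: dict[str, str]


def simulate_beta_matrix(
    n_probes: int = 10_000,
    samples_spec: Sequence[tuple[str, int]] = (("type1", 2), ("type2", 2), ("type3", 2)),
    failed_fraction: float = 0.1,
    noise_sd: float = 0.02,
    type_shift_fraction: float = 0.2,
    detection_p_cutoff: float = 0.01,
    seed: int = 0,
) -> tuple[BetaMatrix, BetaTruth]:
    """Simulate a probes x samples beta matrix with detection P values.

    Valid probes draw a per-probe baseline from the bimodal mixture
    0.5 Beta(2, 18) + 0.5 Beta(17, 3) (low ~0.1 and high ~0.85 methylation);
    per sample type a recorded fraction of probes is re-drawn, creating
    between-type structure; replicates add clipped Gaussian noise.  A
    ``failed_fraction`` of probes instead draws from a unimodal Beta peaked
    near 0.3 with detection P at or above the cutoff in every sample,
    mimicking non-hybridising probes.
    """
    rng = np.random.default_rng(seed)
    probe_ids = [f"cgB{i:06d}" for i in range(n_probes)]
    n_failed = int(round(failed_fraction * n_probes))
    failed = set(rng.choice(n_probes, size=n_failed, replace=False).tolist())

    def mixture(size: int) -> np.ndarray:
        low = rng.beta(2, 18, size=size)
        high = rng.beta(17, 3, size=size)
        return np.where(rng.random(size) < 0.5, low, high)

    base = mixture(n_probes)
    columns: dict[str, np.ndarray] = {}
    detp: dict[str, np.ndarray] = {}
    sample_types: dict[str, str] = {}
    pairs: list[tuple[str, str]] = []
    for type_name, n_reps in samples_spec:
        type_base = base.copy()
        shifted = rng.random(n_probes) < type_shift_fraction
        type_base[shifted] = mixture(int(shifted.sum()))
        rep_ids = []
        for r in range(n_reps):
            sample_id = f"{type_name}_rep{r + 1}"
            values = np.clip(type_base + rng.normal(0.0, noise_sd, size=n_probes), 0.0, 1.0)
            p = rng.uniform(0.0, detection_p_cutoff / 10.0, size=n_probes)
            columns[sample_id] = values
            detp[sample_id] = p
            sample_types[sample_id] = type_name
            rep_ids.append(sample_id)
        pairs.extend((rep_ids[i], rep_ids[i + 1]) for i in range(len(rep_ids) - 1))

    failed_idx = sorted(failed)
    for sample_id in columns:
        columns[sample_id][failed_idx] = rng.beta(6, 14, size=len(failed_idx))
        detp[sample_id][failed_idx] = rng.uniform(detection_p_cutoff, 0.5, size=len(failed_idx))

    beta = pd.DataFrame(columns, index=probe_ids)
    detection_p = pd.DataFrame(detp, index=probe_ids)
    truth = BetaTruth(
        failed_probe_ids=[probe_ids[i] for i in failed_idx],
        replicate_pairs=pairs,
        sample_types=sample_types,
    )
    return BetaMatrix(beta=beta, detection_p=detection_p), truth
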