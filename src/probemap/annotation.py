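"""Genomic annotation of mapped probes and manifest assembly.

Each uniquely mapped probe is annotated with a gene-region class (with the
Illumina-style priority TSS200 > TSS1500 > 5'UTR > 1st exon > body > 3'UTR >
intergenic when several transcripts overlap the site), a CpG-island context
(island / shore / shelf / open sea by distance bands from the nearest
island), an enhancer overlap flag, the target-site dinucleotide and the
position-1-5 mismatch flag; the rows are assembled into a manifest TSV.
"""

from __future__ import annotations

import logging
import re
from bisect import bisect_left
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .bisulfite_align import UNIQUE_BEST, MappingResult
from .mismatch import MismatchReport, TargetSiteClass

log = logging.getLogger(__name__)

# Gene-region classes in priority order (highest first).
TSS200 = "TSS200"
TSS1500 = "TSS1500"
UTR5 = "5'UTR"
FIRST_EXON = "1stExon"
BODY = "Body"
UTR3 = "3'UTR"
IGR = "IGR"

REGION_PRIORITY = (TSS200, TSS1500, UTR5, FIRST_EXON, BODY, UTR3, IGR)
_PRIORITY_RANK = {name: i for i, name in enumerate(REGION_PRIORITY)}

# CpG-island context bands.
ISLAND = "Island"
SHORE = "Shore"
SHELF = "Shelf"
OPEN_SEA = "OpenSea"

DEFAULT_SHORE_BP = 2000
DEFAULT_SHELF_BP = 4000

PROMOTER_BP = 1500  # upstream extension considered part of the promoter


class GeneModelError(ValueError):
    """A gene-model row violates the genePred invariants."""


@dataclass
class GeneModel:
    """One transcript in UCSC genePred coordinates (0-based half-open).

    The TSS is ``tx_start`` on '+' and ``tx_end - 1`` on '-'; promoter
    windows are applied strand-aware at classification time, not baked into
    the stored coordinates.
    """

    transcript_id: str
    gene_name: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    cds_start: int
    cds_end: int
    exon_starts: list[int]
    exon_ends: list[int]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise GeneModelError(f"{self.transcript_id}: bad strand {self.strand!r}")
        if len(self.exon_starts) != len(self.exon_ends):
            raise GeneModelError(
                f"{self.transcript_id}: exonStarts/exonEnds length mismatch"
            )
        if not (self.tx_start <= self.cds_start <= self.cds_end <= self.tx_end):
            raise GeneModelError(
                f"{self.transcript_id}: txStart <= cdsStart <= cdsEnd <= txEnd violated"
            )
        prev_end = self.tx_start
        for s, e in zip(self.exon_starts, self.exon_ends):
            if s >= e or s < prev_end or e > self.tx_end:
                raise GeneModelError(
                    f"{self.transcript_id}: exons must be sorted, non-overlapping "
                    f"and within the transcript"
                )
            prev_end = e

    @property
    def is_coding(self) -> bool:
        return self.cds_start < self.cds_end

    @property
    def tss(self) -> int:
        """0-based position of the first transcribed base."""
        return self.tx_start if self.strand == "+" else self.tx_end - 1

    @property
    def exons(self) -> list[tuple[int, int]]:
        return list(zip(self.exon_starts, self.exon_ends))


def load_gene_models(path: str | Path) -> list[GeneModel]:
    """Read transcripts from a UCSC genePred / refGene table.

    Both the bare 10+-column genePred layout (name first) and the refGene
    dump with a leading integer ``bin`` column are accepted; a ``name2``
    column, when present, supplies the gene symbol.
    """
    models: list[GeneModel] = []
    with open(path) as handle:
        for line_no, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            offset = 1 if re.fullmatch(r"\d+", fields[0]) else 0
            if len(fields) < offset + 10:
                raise GeneModelError(f"{path}:{line_no}: fewer than 10 genePred columns")
            name = fields[offset]
            try:
                model = GeneModel(
                    transcript_id=name,
                    gene_name=fields[offset + 11] if len(fields) > offset + 11 else name,
                    chrom=fields[offset + 1],
                    strand=fields[offset + 2],
                    tx_start=int(fields[offset + 3]),
                    tx_end=int(fields[offset + 4]),
                    cds_start=int(fields[offset + 5]),
                    cds_end=int(fields[offset + 6]),
                    exon_starts=_int_list(fields[offset + 8]),
                    exon_ends=_int_list(fields[offset + 9]),
                )
            except (ValueError, GeneModelError) as exc:
                raise GeneModelError(f"{path}:{line_no} ({name}): {exc}") from exc
            if len(model.exon_starts) != int(fields[offset + 7]):
                raise GeneModelError(
                    f"{path}:{line_no} ({name}): exonCount disagrees with exon lists"
                )
            models.append(model)
    return models


def _int_list(text: str) -> list[int]:
    return [int(tok) for tok in text.strip(",").split(",") if tok]


def transcript_region(pos0: int, model: GeneModel) -> Optional[str]:
    """Class of a 0-based site with respect to one transcript, or None when
    the site is neither inside the transcript nor within 1500 bp upstream.

    Within a transcript the same priority order used across transcripts
    resolves overlapping definitions (e.g. a first exon that is also 5'UTR).
    """
    if model.strand == "+":
        upstream = model.tss - pos0
    else:
        upstream = pos0 - model.tss
    if 1 <= upstream <= 200:
        return TSS200
    if 200 < upstream <= PROMOTER_BP:
        return TSS1500
    if not model.tx_start <= pos0 < model.tx_end:
        return None

    exonic = any(s <= pos0 < e for s, e in model.exons)
    candidates: list[str] = []
    if model.is_coding and exonic:
        if model.strand == "+":
            if pos0 < model.cds_start:
                candidates.append(UTR5)
            elif pos0 >= model.cds_end:
                candidates.append(UTR3)
        else:
            if pos0 >= model.cds_end:
                candidates.append(UTR5)
            elif pos0 < model.cds_start:
                candidates.append(UTR3)
    first = model.exons[0] if model.strand == "+" else model.exons[-1]
    if first[0] <= pos0 < first[1]:
        candidates.append(FIRST_EXON)
    candidates.append(BODY)
    return min(candidates, key=_PRIORITY_RANK.__getitem__)


class GeneRegionIndex:
    """Interval index over transcripts (promoter windows included) for bulk
    site classification."""

    def __init__(self, models: Sequence[GeneModel]):
        self._trees: dict[str, IntervalTree] = {}
        for model in models:
            lo = model.tx_start - (PROMOTER_BP if model.strand == "+" else 0)
            hi = model.tx_end + (PROMOTER_BP if model.strand == "-" else 0)
            self._trees.setdefault(model.chrom, IntervalTree()).addi(lo, hi, model)

    def classify(self, chrom: str, mapinfo: int) -> tuple[str, list[str]]:
        """Priority-resolved gene-region class and overlapping gene names.

        ``mapinfo`` is 1-based.  Gene names are those of transcripts that
        attain the winning class, deduplicated case-insensitively in order
        of transcript position.
        """
        pos0 = mapinfo - 1
        tree = self._trees.get(chrom)
        hits: list[tuple[str, GeneModel]] = []
        if tree is not None:
            for iv in sorted(tree[pos0], key=lambda iv: (iv.begin, iv.data.transcript_id)):
                region = transcript_region(pos0, iv.data)
                if region is not None:
                    hits.append((region, iv.data))
        if not hits:
            return IGR, []
        best = min((region for region, _ in hits), key=_PRIORITY_RANK.__getitem__)
        names: list[str] = []
        seen: set[str] = set()
        for region, model in hits:
            if region == best and model.gene_name.upper() not in seen:
                seen.add(model.gene_name.upper())
                names.append(model.gene_name)
        return best, names


def classify_gene_region(
    site: tuple[str, int], models: Sequence[GeneModel] | GeneRegionIndex
) -> tuple[str, list[str]]:
    """Classify one (chrom, 1-based mapinfo) site; see :class:`GeneRegionIndex`."""
    index = models if isinstance(models, GeneRegionIndex) else GeneRegionIndex(models)
    return index.classify(*site)


class CgiIndex:
    """Sorted CpG-island intervals per chromosome with distance queries."""

    def __init__(
        self,
        islands: Iterable[tuple[str, int, int]],
        shore_bp: int = DEFAULT_SHORE_BP,
        shelf_bp: int = DEFAULT_SHELF_BP,
    ):
        if not 0 < shore_bp < shelf_bp:
            raise ValueError("need 0 < shore_bp < shelf_bp")
        self.shore_bp = shore_bp
        self.shelf_bp = shelf_bp
        per_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in islands:
            if start >= end:
                raise ValueError(f"empty island interval {chrom}:{start}-{end}")
            per_chrom.setdefault(chrom, []).append((start, end))
        self._starts: dict[str, list[int]] = {}
        self._ends: dict[str, list[int]] = {}
        for chrom, ivs in per_chrom.items():
            ivs.sort()
            self._starts[chrom] = [s for s, _ in ivs]
            self._ends[chrom] = [e for _, e in ivs]

    def distance(self, chrom: str, mapinfo: int) -> Optional[int]:
        """Base-pair distance from a 1-based site to the nearest island
        boundary; 0 inside an island, None when the chromosome has none."""
        starts = self._starts.get(chrom)
        if not starts:
            return None
        ends = self._ends[chrom]
        pos0 = mapinfo - 1
        i = bisect_left(starts, pos0 + 1)  # islands with start <= pos0
        best: Optional[int] = None
        if i > 0:
            if pos0 < ends[i - 1]:
                return 0
            best = pos0 - (ends[i - 1] - 1)
        if i < len(starts):
            d = starts[i] - pos0
            best = d if best is None else min(best, d)
        return best

    def classify(self, chrom: str, mapinfo: int) -> str:
        d = self.distance(chrom, mapinfo)
        if d is None:
            return OPEN_SEA
        if d == 0:
            return ISLAND
        if d <= self.shore_bp:
            return SHORE
        if d <= self.shelf_bp:
            return SHELF
        return OPEN_SEA


def classify_cgi_context(
    site: tuple[str, int],
    islands: Iterable[tuple[str, int, int]] | CgiIndex,
    shore_bp: int = DEFAULT_SHORE_BP,
    shelf_bp: int = DEFAULT_SHELF_BP,
) -> str:
    """Island / Shore / Shelf / OpenSea for one (chrom, 1-based mapinfo) site."""
    index = (
        islands
        if isinstance(islands, CgiIndex)
        else CgiIndex(islands, shore_bp=shore_bp, shelf_bp=shelf_bp)
    )
    return index.classify(*site)


class EnhancerIndex:
    """Interval overlap index for enhancer BED intervals (0-based half-open)."""

    def __init__(self, intervals: Iterable[tuple[str, int, int]]):
        self._trees: dict[str, IntervalTree] = {}
        for chrom, start, end in intervals:
            if start < end:
                self._trees.setdefault(chrom, IntervalTree()).addi(start, end)

    def overlaps(self, chrom: str, start0: int, end0: int) -> bool:
        tree = self._trees.get(chrom)
        return bool(tree is not None and tree.overlap(start0, end0))


def flag_enhancer(
    site: tuple[str, int],
    enhancers: Iterable[tuple[str, int, int]] | EnhancerIndex,
    span: Optional[tuple[int, int]] = None,
) -> bool:
    """True iff the target site (or, when given, the probe span as a 1-based
    inclusive interval) intersects an enhancer interval."""
    index = enhancers if isinstance(enhancers, EnhancerIndex) else EnhancerIndex(enhancers)
    chrom, mapinfo = site
    if span is None:
        return index.overlaps(chrom, mapinfo - 1, mapinfo)
    lo, hi = span
    return index.overlaps(chrom, lo - 1, hi)


def read_bed(path: str | Path) -> list[tuple[str, int, int]]:
    """Minimal BED3 reader (0-based half-open intervals)."""
    intervals: list[tuple[str, int, int]] = []
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split("\t")[:3]
            intervals.append((chrom, int(start), int(end)))
    return intervals


# ---------------------------------------------------------------------------
# Manifest assembly


@dataclass
class ManifestRow:
    """One record of the output manifest (Illumina-flavoured columns)."""

    probe_id: str
    chrom: str
    mapinfo: int
    strand: str
    design_type: str
    gene_names: str  # semicolon-joined, deduplicated
    gene_region: str
    cgi_context: str
    fantom5_enhancer: bool
    target_site: str
    mismatches_pos1_5: bool
    validation_0_01: Optional[bool] = None


MANIFEST_COLUMNS = [
    "probe_id", "CHR", "MAPINFO", "Strand", "Infinium_Design_Type",
    "Gene_names", "Gene_region", "CGI_context", "FANTOM5_enhancer",
    "Target_site", "Mismatches_Pos1_5", "Validation_0.01",
]


@dataclass
class ProbeAnnotation:
    """Annotation bundle for one probe prior to manifest assembly."""

    gene_region: str
    gene_names: list[str]
    cgi_context: str
    fantom5_enhancer: bool


def annotate_sites(
    mapping: Sequence[MappingResult],
    gene_index: GeneRegionIndex,
    cgi_index: CgiIndex,
    enhancer_index: EnhancerIndex,
) -> dict[str, ProbeAnnotation]:
    """Annotate every uniquely mapped probe with gene region, CGI context
    and enhancer overlap."""
    annotations: dict[str, ProbeAnnotation] = {}
    for result in mapping:
        if result.status != UNIQUE_BEST:
            continue
        site = (result.chrom, result.mapinfo)
        region, names = gene_index.classify(*site)
        annotations[result.probe_id] = ProbeAnnotation(
            gene_region=region,
            gene_names=names,
            cgi_context=cgi_index.classify(*site),
            fantom5_enhancer=flag_enhancer(site, enhancer_index),
        )
    return annotations


def _chrom_sort_key(chrom: str) -> tuple:
    m = re.fullmatch(r"(?:chr)?(\d+)", chrom)
    return (0, int(m.group(1)), "") if m else (1, 0, chrom)


def assemble_manifest(
    mapping: Sequence[MappingResult],
    mismatch_reports: Mapping[str, MismatchReport],
    annotations: Mapping[str, ProbeAnnotation],
    design_types: Mapping[str, str],
    target_sites: Mapping[str, TargetSiteClass],
    validation: Optional[Mapping[str, bool]] = None,
) -> list[ManifestRow]:
    """Inner-join all per-probe information over uniquely mapped probes into
    manifest rows, deterministically sorted by (chromosome, coordinate).

    A probe that appears in ``annotations`` but not among the uniquely
    mapped probes is a consistency error.
    """
    unique = {r.probe_id: r for r in mapping if r.status == UNIQUE_BEST}
    stray = set(annotations) - set(unique)
    if stray:
        raise ValueError(
            f"annotations reference probes absent from mapping: {sorted(stray)[:5]}"
        )
    rows: list[ManifestRow] = []
    for probe_id, result in unique.items():
        if probe_id not in annotations or probe_id not in mismatch_reports:
            continue
        ann = annotations[probe_id]
        mm = mismatch_reports[probe_id]
        ts = target_sites[probe_id]
        rows.append(
            ManifestRow(
                probe_id=probe_id,
                chrom=result.chrom,
                mapinfo=result.mapinfo,
                strand=result.strand,
                design_type=design_types.get(probe_id, "II"),
                gene_names=";".join(ann.gene_names),
                gene_region=ann.gene_region,
                cgi_context=ann.cgi_context,
                fantom5_enhancer=ann.fantom5_enhancer,
                target_site=ts.dinucleotide,
                mismatches_pos1_5=mm.has_mismatch_pos1_5,
                validation_0_01=None if validation is None else validation.get(probe_id),
            )
        )
    rows.sort(key=lambda r: (_chrom_sort_key(r.chrom), r.mapinfo, r.probe_id))
    return rows


def write_manifest(rows: Sequence[ManifestRow], path: str | Path) -> None:
    """Write manifest rows as TSV; the validation column reads NA when no
    array data was supplied."""
    records = []
    for r in rows:
        records.append(
            {
                "probe_id": r.probe_id,
                "CHR": r.chrom,
                "MAPINFO": r.mapinfo,
                "Strand": r.strand,
                "Infinium_Design_Type": r.design_type,
                "Gene_names": r.gene_names,
                "Gene_region": r.gene_region,
                "CGI_context": r.cgi_context,
                "FANTOM5_enhancer": int(r.fantom5_enhancer),
                "Target_site": r.target_site,
                "Mismatches_Pos1_5": int(r.mismatches_pos1_5),
                "Validation_0.01": "NA" if r.validation_0_01 is None else int(r.validation_0_01),
            }
        )
    pd.DataFrame(records, columns=MANIFEST_COLUMNS).to_csv(path, sep="\t", index=False)


def read_manifest(path: str | Path) -> list[ManifestRow]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    rows: list[ManifestRow] = []
    for rec in df.to_dict("records"):
        validation = rec["Validation_0.01"]
        rows.append(
            ManifestRow(
                probe_id=rec["probe_id"],
                chrom=rec["CHR"],
                mapinfo=int(rec["MAPINFO"]),
                strand=rec["Strand"],
                design_type=rec["Infinium_Design_Type"],
                gene_names=rec["Gene_names"],
                gene_region=rec["Gene_region"],
                cgi_context=rec["CGI_context"],
                fantom5_enhancer=bool(int(rec["FANTOM5_enhancer"])),
                target_site=rec["Target_site"],
                mismatches_pos1_5=bool(int(rec["Mismatches_Pos1_5"])),
                validation_0_01=None if validation == "NA" else bool(int(validation)),
            )
        )
    return rows


def probes_per_gene(
    rows: Sequence[ManifestRow], bins: Optional[Sequence[int]] = None
) -> tuple[dict[str, int], tuple[list[int], list[float]]]:
    """Count distinct probes per gene and histogram the per-gene counts.

    A probe annotated to several genes counts once for each; returns the
    per-gene counts and a (histogram, bin_edges) pair.
    """
    import numpy as np

    counts: dict[str, set[str]] = {}
    for row in rows:
        if not row.gene_names:
            continue
        for gene in row.gene_names.split(";"):
            counts.setdefault(gene, set()).add(row.probe_id)
    per_gene = {gene: len(ids) for gene, ids in counts.items()}
    if not per_gene:
        return {}, ([], [])
    values = list(per_gene.values())
    if bins is None:
        bins = list(range(1, max(values) + 2))
    hist, edges = np.histogram(values, bins=bins)
    return per_gene, (hist.tolist(), edges.tolist())
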