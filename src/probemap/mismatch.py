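"""True-mismatch extraction and target-site dinucleotide classification.

After mapping, the interesting differences between a probe and its locus are
the ones that bisulfite chemistry cannot explain: a probe T over a genomic C
is exactly what conversion of an unmethylated cytosine produces and is not a
mismatch, and a probe C over a genomic C (methylated, retained) is a plain
match.  Everything else that still differs after collapsing C into T on both
sides is a *true* mismatch.  Mismatches within the first five bases of the
reverse/complemented query (the probe's 3' end, nearest the target site) are
flagged separately because they are the ones known to perturb hybridisation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from .bisulfite_align import AlignmentHit, ConvertedGenome
from .probe_io import ProbeRecord
from .seq import ct_collapse, revcomp

log = logging.getLogger(__name__)

TARGET_CATEGORIES = ("CpG", "CpA", "CpT", "CpC", "TpG", "other")

_DINUCLEOTIDE_TO_CATEGORY = {
    "CG": "CpG",
    "CA": "CpA",
    "CT": "CpT",
    "CC": "CpC",
    "TG": "TpG",
}


@dataclass
class MismatchReport:
    """Positions (1-based, query 5'->3') of non-bisulfite probe/genome
    differences at the mapped locus."""

    probe_id: str
    positions: list[int]
    n_true_mismatches: int
    has_mismatch_pos1_5: bool


@dataclass
class TargetSiteClass:
    """Strand-oriented dinucleotide at the target coordinate and its class."""

    dinucleotide: str
    category: str


def _raw_seqs(genome) -> Mapping[str, str]:
    if isinstance(genome, ConvertedGenome):
        return genome.raw
    return genome


def extract_true_mismatches(
    probe: ProbeRecord, hit: AlignmentHit, genome_raw
) -> MismatchReport:
    """Compare the unconverted probe to the unconverted reference at its
    mapped locus, in query orientation on the matched strand.

    A position is a true mismatch iff the bases still differ after both are
    collapsed into post-bisulfite space (C and the degenerate Y read as T);
    this removes probe-T-over-genome-C conversion events and keeps every
    difference that conversion cannot produce.  Ambiguous reference bases
    (N) always count as mismatches.
    """
    seqs = _raw_seqs(genome_raw)
    chrom_seq = seqs[hit.chrom]
    m = hit.query_length
    if hit.start < 0 or hit.start + m > len(chrom_seq):
        raise ValueError(
            f"{hit.probe_id}: aligned span [{hit.start}, {hit.start + m}) "
            f"outside {hit.chrom}"
        )
    # unconverted probe in query orientation, truncated like the query was
    probe_query = revcomp(probe.probe_seq.upper())[:m]
    ref = chrom_seq[hit.start : hit.start + m].upper()
    if hit.strand == "-":
        ref = revcomp(ref)
    positions = [
        i + 1
        for i, (p, g) in enumerate(zip(probe_query, ref))
        if ct_collapse(p) != ct_collapse(g)
    ]
    return MismatchReport(
        probe_id=probe.probe_id or hit.probe_id,
        positions=positions,
        n_true_mismatches=len(positions),
        has_mismatch_pos1_5=any(p <= 5 for p in positions),
    )


def classify_target_site(
    chrom: str, mapinfo: int, strand: str, genome_raw
) -> TargetSiteClass:
    """Read the dinucleotide starting at the target coordinate on the
    reported strand and classify it (CpG / CpA / CpT / CpC / TpG / other)."""
    seqs = _raw_seqs(genome_raw)
    chrom_seq = seqs[chrom]
    pos0 = mapinfo - 1
    if not 0 <= pos0 < len(chrom_seq):
        raise ValueError(f"mapinfo {mapinfo} outside {chrom}")
    if strand == "+":
        if pos0 + 1 >= len(chrom_seq):
            log.warning("target at final base of %s; no downstream base", chrom)
            return TargetSiteClass(dinucleotide=chrom_seq[pos0].upper(), category="other")
        din = chrom_seq[pos0 : pos0 + 2].upper()
    else:
        if pos0 - 1 < 0:
            log.warning("target at first base of %s; no downstream base on '-'", chrom)
            return TargetSiteClass(
                dinucleotide=revcomp(chrom_seq[pos0].upper()), category="other"
            )
        din = revcomp(chrom_seq[pos0 - 1 : pos0 + 1].upper())
    return TargetSiteClass(
        dinucleotide=din, category=_DINUCLEOTIDE_TO_CATEGORY.get(din, "other")
    )


def summarize_target_sites(
    records: Iterable[TargetSiteClass],
) -> dict[str, tuple[int, float]]:
    """Category -> (count, percent of records)."""
    counts: dict[str, int] = {}
    total = 0
    for rec in records:
        counts[rec.category] = counts.get(rec.category, 0) + 1
        total += 1
    if total == 0:
        return {}
    return {cat: (n, 100.0 * n / total) for cat, n in counts.items()}
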