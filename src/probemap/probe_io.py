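"""Reading Illumina-style probe manifests and deriving alignment queries.

An Infinium methylation probe is a 50-mer whose 3' end sits at (type I) or
immediately next to (type II) the interrogated cytosine.  Because the probe
hybridises to bisulfite-converted DNA, the sequence that should be aligned
against a bisulfite-converted reference is the reverse complement of the
probe, C->T converted.  This module parses the manifest CSV, derives those
query sequences and round-trips them through FASTA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from Bio import SeqIO

from .seq import PROBE_ALPHABET, QUERY_ALPHABET, SequenceError, bisulfite_convert, revcomp

log = logging.getLogger(__name__)

PROBE_LENGTH = 50

#: Column names used when none are supplied; these match the Illumina
#: MethylationEPIC manifest header.
DEFAULT_ID_COLUMN = "IlmnID"
DEFAULT_SEQUENCE_COLUMN = "AlleleA_ProbeSeq"
DEFAULT_TYPE_COLUMN = "Infinium_Design_Type"


class ManifestError(ValueError):
    """Configuration-level problem with a probe manifest (e.g. missing column)."""


class ProbeSequenceError(SequenceError):
    """Record-level problem with one probe's sequence; carries the probe id."""

    def __init__(self, probe_id: str, message: str):
        super().__init__(f"{probe_id}: {message}")
        self.probe_id = probe_id


@dataclass
class ProbeRecord:
    """One array probe and its derived alignment query.

    ``probe_seq`` is the AlleleA probe sequence as printed in the manifest
    (5'->3', 3' end at/adjacent to the target site).  ``query_seq`` is the
    reverse complement after C->T conversion, i.e. the string actually
    aligned against a converted genome; it contains only A/G/T.
    """

    probe_id: str
    design_type: str  # "I" or "II"
    probe_seq: str
    query_seq: str = ""

    def __post_init__(self) -> None:
        if self.design_type not in ("I", "II"):
            raise ManifestError(
                f"{self.probe_id}: design type must be 'I' or 'II', got {self.design_type!r}"
            )


@dataclass
class LoadReport:
    """Bookkeeping for a manifest parse: rows_in == len(records) + skipped."""

    total_rows: int = 0
    loaded: int = 0
    skipped_empty: int = 0
    skipped_length: int = 0
    dropped_degenerate: int = 0

    @property
    def skipped(self) -> int:
        return self.skipped_empty + self.skipped_length + self.dropped_degenerate


def make_query_sequence(probe: ProbeRecord, truncate_to: Optional[int] = None) -> str:
    """Derive the alignment query for one probe.

    The probe is reverse-complemented (placing the target-site end at the
    query 5' end, which seeds the alignment), optionally truncated to its
    5'-most ``truncate_to`` bases, then C->T converted.  Degenerate Y in the
    reverse complement (R in the probe) converts to T; a residual R cannot
    be resolved to a single base and raises :class:`ProbeSequenceError`.
    """
    bad = set(probe.probe_seq.upper()) - PROBE_ALPHABET
    if bad:
        raise ProbeSequenceError(probe.probe_id, f"non-IUPAC probe base(s) {sorted(bad)}")
    query = revcomp(probe.probe_seq.upper())
    if truncate_to is not None:
        if not 1 <= truncate_to <= len(query):
            raise ManifestError(f"truncate_to must be in [1, {len(query)}], got {truncate_to}")
        query = query[:truncate_to]
    query = bisulfite_convert(query).replace("Y", "T")
    residual = set(query) - QUERY_ALPHABET
    if residual:
        raise ProbeSequenceError(
            probe.probe_id, f"unresolvable degenerate base(s) {sorted(residual)} in query"
        )
    return query


def parse_probe_manifest(
    path: str | Path,
    sequence_column: str = DEFAULT_SEQUENCE_COLUMN,
    id_column: str = DEFAULT_ID_COLUMN,
    type_column: str = DEFAULT_TYPE_COLUMN,
    truncate_to: Optional[int] = None,
    probe_length: int = PROBE_LENGTH,
) -> tuple[list[ProbeRecord], LoadReport]:
    """Parse a probe manifest CSV into :class:`ProbeRecord` objects.

    Rows with an empty or wrong-length sequence are skipped and counted;
    probes whose query cannot be derived (unresolvable degenerate code) are
    dropped with a warning.  A sequence containing a non-IUPAC character is
    a hard error naming the probe, as is a missing column or duplicate id.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in (id_column, sequence_column, type_column):
        if col not in df.columns:
            raise ManifestError(f"manifest {path} is missing required column {col!r}")

    report = LoadReport(total_rows=len(df))
    records: list[ProbeRecord] = []
    seen: set[str] = set()
    for probe_id, seqtext, design_raw in zip(
        df[id_column], df[sequence_column], df[type_column]
    ):
        seqtext = seqtext.strip().upper()
        if not seqtext:
            report.skipped_empty += 1
            continue
        if len(seqtext) != probe_length:
            report.skipped_length += 1
            continue
        design = _normalise_design_type(design_raw)
        record = ProbeRecord(probe_id=probe_id, design_type=design, probe_seq=seqtext)
        if record.probe_id in seen:
            raise ManifestError(f"duplicate probe id {record.probe_id!r} in manifest")
        try:
            record.query_seq = make_query_sequence(record, truncate_to=truncate_to)
        except ProbeSequenceError as exc:
            if "non-IUPAC" in str(exc):
                raise
            log.warning("dropping probe %s: %s", record.probe_id, exc)
            report.dropped_degenerate += 1
            continue
        seen.add(record.probe_id)
        records.append(record)
    report.loaded = len(records)
    if report.skipped:
        log.info(
            "parsed %s: %d rows, %d loaded, %d skipped (%d empty, %d length, %d degenerate)",
            path, report.total_rows, report.loaded, report.skipped,
            report.skipped_empty, report.skipped_length, report.dropped_degenerate,
        )
    return records, report


def _normalise_design_type(value: str) -> str:
    value = value.strip().upper()
    if value in ("I", "1"):
        return "I"
    if value in ("II", "2", ""):
        return "II"
    raise ManifestError(f"unrecognised Infinium design type {value!r}")


def write_probe_fasta(
    probes: Iterable[ProbeRecord], path: str | Path, line_width: Optional[int] = None
) -> None:
    """Write query sequences to FASTA, one record per probe.

    The header is ``>probe_id design_type`` so that design type survives a
    round trip.  Default layout is single-line sequences; pass ``line_width``
    to wrap.
    """
    with open(path, "w") as handle:
        for probe in probes:
            seq = probe.query_seq or make_query_sequence(probe)
            handle.write(f">{probe.probe_id} {probe.design_type}\n")
            if line_width:
                for i in range(0, len(seq), line_width):
                    handle.write(seq[i : i + line_width] + "\n")
            else:
                handle.write(seq + "\n")


def read_probe_fasta(path: str | Path) -> list[ProbeRecord]:
    """Read a query FASTA back into :class:`ProbeRecord` objects.

    The original 50-mer probe sequence is not recoverable from the query, so
    ``probe_seq`` is left empty.  Duplicate ids are an error.
    """
    records: list[ProbeRecord] = []
    seen: dict[str, int] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seen[rec.id] = seen.get(rec.id, 0) + 1
        design = "II"
        parts = rec.description.split()
        if len(parts) > 1 and parts[1] in ("I", "II"):
            design = parts[1]
        records.append(
            ProbeRecord(probe_id=rec.id, design_type=design, probe_seq="", query_seq=str(rec.seq).upper())
        )
    duplicates = sorted(pid for pid, n in seen.items() if n > 1)
    if duplicates:
        raise ManifestError(f"duplicate probe ids in {path}: {duplicates}")
    return records
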