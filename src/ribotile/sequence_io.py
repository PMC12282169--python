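"""Readers and writers for the formats the toolkit touches.

FASTA/FASTQ parsing is delegated to Biopython; SAM ingestion to pysam.
FASTQ qualities are Phred+33 only — a heuristic rejects files that look
Phred+64 encoded rather than silently mis-decoding them.

Probe tables are written in four flavours: FASTA, a full TSV (round-trippable),
an order-sheet style two-column CSV (name, sequence) suitable for submitting
an oligo pool for synthesis, and BED for genome-browser inspection.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path
from typing import Iterable, List, Union

from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .records import (
    AlignmentRecord,
    FormatError,
    ProbeRecord,
    ReadRecord,
    ReferenceSeq,
    ValidationError,
)

logger = logging.getLogger(__name__)

PROBE_TSV_COLUMNS = ["probe_id", "ref_id", "target_start", "target_end", "sequence"]
ALIGNMENT_TSV_COLUMNS = ["read_id", "ref_id", "ref_start", "ref_end", "strand"]

PHRED_OFFSET = 33


def read_sequences(path, format: str):
    """Parse a FASTA or FASTQ file.

    Returns a list of :class:`ReferenceSeq` (fasta) or :class:`ReadRecord`
    (fastq, qualities decoded from Phred+33). Identifiers are the first
    whitespace-delimited token of each header and must be unique.
    """
    path = Path(path)
    if format == "fasta":
        return _read_fasta(path)
    if format == "fastq":
        return _read_fastq(path)
    raise ValueError(f"unknown sequence format {format!r}")


def _read_fasta(path: Path) -> List[ReferenceSeq]:
    records: List[ReferenceSeq] = []
    seen = set()
    with open(path) as handle:
        for title, seq in SimpleFastaParser(handle):
            ref_id = title.split()[0] if title.split() else ""
            taxon = title.split(maxsplit=1)[1] if len(title.split(maxsplit=1)) > 1 else None
            if ref_id in seen:
                raise FormatError(f"{path}: duplicate sequence id {ref_id!r}")
            seen.add(ref_id)
            if not seq:
                raise FormatError(f"{path}: record {ref_id!r} has an empty sequence")
            records.append(ReferenceSeq(ref_id=ref_id, sequence=seq.upper(), taxon=taxon))
    return records


def _read_fastq(path: Path) -> List[ReadRecord]:
    records: List[ReadRecord] = []
    seen = set()
    n = 0
    with open(path) as handle:
        iterator = FastqGeneralIterator(handle)
        while True:
            try:
                title, seq, qual = next(iterator)
            except StopIteration:
                break
            except ValueError as exc:
                # 4 lines per record; the failing record starts right after
                # the last complete one.
                raise FormatError(f"{path}: near line {4 * n + 1}: {exc}") from exc
            n += 1
            read_id = title.split()[0]
            if read_id in seen:
                raise FormatError(f"{path}: near line {4 * n - 3}: duplicate read id {read_id!r}")
            seen.add(read_id)
            if len(seq) != len(qual):
                raise FormatError(
                    f"{path}: near line {4 * n - 3}: read {read_id!r} "
                    f"sequence/quality length mismatch"
                )
            qualities = [ord(c) - PHRED_OFFSET for c in qual]
            records.append(ReadRecord(read_id=read_id, sequence=seq.upper(), qualities=qualities))
    _check_phred33(path, records)
    return records


def _check_phred33(path: Path, records: List[ReadRecord]) -> None:
    """Reject files whose quality distribution only makes sense as Phred+64."""
    lo, hi = 1000, -1
    for rec in records:
        for q in rec.qualities:
            if q < 0:
                raise FormatError(f"{path}: quality character below '!' in read {rec.read_id!r}")
            lo = min(lo, q)
            hi = max(hi, q)
    if records and lo >= 26 and hi > 45:
        raise FormatError(
            f"{path}: quality scores in [{lo}, {hi}] suggest Phred+64 encoding; "
            "only Phred+33 input is supported"
        )


def write_sequences(records: Iterable[Union[ReadRecord, ReferenceSeq]], path, format: str) -> None:
    """Write records as FASTA or FASTQ (Phred+33)."""
    path = Path(path)
    with open(path, "w") as handle:
        if format == "fasta":
            for rec in records:
                name = rec.ref_id if isinstance(rec, ReferenceSeq) else rec.read_id
                handle.write(f">{name}\n{rec.sequence}\n")
        elif format == "fastq":
            for rec in records:
                qual = "".join(chr(q + PHRED_OFFSET) for q in rec.qualities)
                handle.write(f"@{rec.read_id}\n{rec.sequence}\n+\n{qual}\n")
        else:
            raise ValueError(f"unknown sequence format {format!r}")


def read_alignments(path, format: str = "tsv") -> List[AlignmentRecord]:
    """Read alignment records from a TSV table or a SAM file.

    TSV columns: read_id, ref_id, ref_start, ref_end, strand (0-based
    half-open; a header row is recognised and skipped). SAM records are
    converted from 1-based inclusive coordinates; unmapped, secondary and
    supplementary records are skipped with a logged count.
    """
    path = Path(path)
    if format == "tsv":
        return _read_alignment_tsv(path)
    if format == "sam":
        return _read_alignment_sam(path)
    raise ValueError(f"unknown alignment format {format!r}")


def _read_alignment_tsv(path: Path) -> List[AlignmentRecord]:
    records: List[AlignmentRecord] = []
    with open(path) as handle:
        reader = csv.reader(handle, delimiter="\t")
        for lineno, row in enumerate(reader, start=1):
            if not row or row[0].startswith("#"):
                continue
            if lineno == 1 and row[0] == "read_id":
                continue
            if len(row) < 5:
                raise FormatError(f"{path}: line {lineno}: expected 5 columns, got {len(row)}")
            read_id, ref_id, start_s, end_s, strand = row[:5]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: non-integer coordinate") from exc
            if end <= start:
                raise FormatError(
                    f"{path}: line {lineno}: empty or inverted interval [{start}, {end})"
                )
            records.append(AlignmentRecord(read_id, ref_id, start, end, strand))
    return records


def _read_alignment_sam(path: Path) -> List[AlignmentRecord]:
    import pysam

    records: List[AlignmentRecord] = []
    skipped = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                skipped += 1
                continue
            if aln.reference_end is None:
                skipped += 1
                continue
            records.append(
                AlignmentRecord(
                    read_id=aln.query_name,
                    ref_id=aln.reference_name,
                    ref_start=aln.reference_start,
                    ref_end=aln.reference_end,
                    strand="-" if aln.is_reverse else "+",
                )
            )
    if skipped:
        logger.info("%s: skipped %d unmapped/secondary/supplementary records", path, skipped)
    return records


def write_alignments(alignments: Iterable[AlignmentRecord], path) -> None:
    """Write alignments as the TSV flavour `read_alignments` accepts."""
    with open(path, "w") as handle:
        handle.write("\t".join(ALIGNMENT_TSV_COLUMNS) + "\n")
        for aln in alignments:
            handle.write(
                f"{aln.read_id}\t{aln.ref_id}\t{aln.ref_start}\t{aln.ref_end}\t{aln.strand}\n"
            )


def _probe_list(probes) -> List[ProbeRecord]:
    if hasattr(probes, "probes"):
        probes = probes.probes
    probes = list(probes)
    seen = set()
    for p in probes:
        if p.probe_id in seen:
            raise ValidationError(f"duplicate probe_id {p.probe_id!r}")
        seen.add(p.probe_id)
    return probes


def write_probe_set(probes, path, format: str = "tsv") -> None:
    """Write a probe pool.

    ``fasta``: one record per probe. ``tsv``: full table (round-trippable via
    :func:`read_probe_table`). ``opools_csv``: headerless name,sequence pairs
    as an oligo-pool order sheet. ``bed``: target intervals, 0-based half-open.
    """
    probe_list = _probe_list(probes)
    if not probe_list:
        logger.warning("writing empty probe set to %s", path)
    path = Path(path)
    with open(path, "w", newline="") as handle:
        if format == "fasta":
            for p in probe_list:
                handle.write(f">{p.probe_id}\n{p.sequence}\n")
        elif format == "tsv":
            handle.write("\t".join(PROBE_TSV_COLUMNS) + "\n")
            for p in probe_list:
                handle.write(
                    f"{p.probe_id}\t{p.ref_id}\t{p.target_start}\t{p.target_end}\t{p.sequence}\n"
                )
        elif format == "opools_csv":
            writer = csv.writer(handle)
            for p in probe_list:
                writer.writerow([p.probe_id, p.sequence])
        elif format == "bed":
            for p in probe_list:
                handle.write(f"{p.ref_id}\t{p.target_start}\t{p.target_end}\t{p.probe_id}\n")
        else:
            raise ValueError(f"unknown probe format {format!r}")


def read_probe_table(path) -> List[ProbeRecord]:
    """Read back the TSV flavour written by :func:`write_probe_set`."""
    probes: List[ProbeRecord] = []
    seen = set()
    with open(path) as handle:
        reader = csv.reader(handle, delimiter="\t")
        header = next(reader, None)
        if header != PROBE_TSV_COLUMNS:
            raise FormatError(f"{path}: unexpected probe table header {header}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            probe_id, ref_id, start_s, end_s, seq = row
            if probe_id in seen:
                raise FormatError(f"{path}: line {lineno}: duplicate probe_id {probe_id!r}")
            seen.add(probe_id)
            probes.append(ProbeRecord(probe_id, ref_id, int(start_s), int(end_s), seq))
    return probes
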