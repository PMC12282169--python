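"""Core record types shared across the toolkit.

All genomic intervals in ribotile are 0-based, half-open (BED convention).
SAM input is converted at the parser boundary; nothing downstream ever sees
1-based coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

__all__ = [
    "ReadRecord",
    "ReferenceSeq",
    "AlignmentRecord",
    "ProbeRecord",
    "reverse_complement",
    "canonical_kmer",
    "FormatError",
    "ValidationError",
]


class FormatError(ValueError):
    """A file violated its declared format."""


class ValidationError(ValueError):
    """A record or record set violated an invariant."""


_RC_TABLE = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N, case preserved)."""
    return seq.translate(_RC_TABLE)[::-1]


def canonical_kmer(kmer: str) -> str:
    """The lexicographically smaller of a k-mer and its reverse complement."""
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc


@dataclass
class ReadRecord:
    """A sequencing read with per-base Phred qualities (already decoded)."""

    read_id: str
    sequence: str
    qualities: Sequence[int]

    def __post_init__(self) -> None:
        if not self.read_id:
            raise ValidationError("read_id must be nonempty")
        if len(self.sequence) != len(self.qualities):
            raise ValidationError(
                f"read {self.read_id!r}: sequence length {len(self.sequence)} "
                f"!= quality length {len(self.qualities)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def mean_quality(self) -> float:
        n = len(self.qualities)
        if n == 0:
            return 0.0
        return sum(self.qualities) / n


@dataclass
class ReferenceSeq:
    """A reference sequence (e.g., an rRNA transcript) with an optional taxon label."""

    ref_id: str
    sequence: str
    taxon: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.ref_id:
            raise ValidationError("ref_id must be nonempty")
        if not self.sequence:
            raise ValidationError(f"reference {self.ref_id!r} has an empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class AlignmentRecord:
    """A read-to-reference alignment span, 0-based half-open."""

    read_id: str
    ref_id: str
    ref_start: int
    ref_end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (0 <= self.ref_start < self.ref_end):
            raise FormatError(
                f"alignment {self.read_id!r}: invalid interval "
                f"[{self.ref_start}, {self.ref_end})"
            )

    @property
    def span(self) -> int:
        return self.ref_end - self.ref_start


@dataclass
class ProbeRecord:
    """A fixed-length antisense oligo and the sense-strand window it targets.

    The probe sequence is the reverse complement of
    ``reference[target_start:target_end]``.
    """

    probe_id: str
    ref_id: str
    target_start: int
    target_end: int
    sequence: str

    def __post_init__(self) -> None:
        if not (0 <= self.target_start < self.target_end):
            raise ValidationError(
                f"probe {self.probe_id!r}: invalid target interval "
                f"[{self.target_start}, {self.target_end})"
            )
        if len(self.sequence) != self.target_end - self.target_start:
            raise ValidationError(
                f"probe {self.probe_id!r}: sequence length {len(self.sequence)} "
                f"!= target span {self.target_end - self.target_start}"
            )

    @property
    def length(self) -> int:
        return self.target_end - self.target_start


def default_probe_id(ref_id: str, start: int, end: int) -> str:
    """Deterministic probe naming: ``<ref_id>:<start>-<end>``."""
    return f"{ref_id}:{start}-{end}"
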