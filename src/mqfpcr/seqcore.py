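"""Sequence and interval primitives shared by every MQF-PCR stage.

Conventions
-----------
* Genomic coordinates are externally 1-based inclusive (``GenomicInterval``);
  any 0-based arithmetic is confined to function internals.
* BED input is standard 0-based half-open and is converted on read.
* Sequences are stored uppercase over the IUPAC nucleotide alphabet;
  soft-masked (lowercase) input is accepted and uppercased with no masking
  semantics attached.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, TextIO, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

#: Expansion set of every IUPAC nucleotide symbol.
IUPAC_EXPAND: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

IUPAC_ALPHABET = frozenset(IUPAC_EXPAND)
CONCRETE_BASES = frozenset("ACGT")

IUPAC_COMPLEMENT: dict[str, str] = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}

#: Reverse lookup: expansion set -> IUPAC code (used to build degenerate consensi).
_SET_TO_CODE: dict[frozenset[str], str] = {v: k for k, v in IUPAC_EXPAND.items()}


def validate_seq(seq: str, *, context: str = "sequence") -> str:
    """Uppercase ``seq`` and verify it is IUPAC DNA.

    Raises ``ValueError`` naming the (1-based) position of the first
    offending character.
    """
    s = seq.upper()
    if not s:
        raise ValueError(f"empty {context}")
    for i, c in enumerate(s):
        if c not in IUPAC_ALPHABET:
            raise ValueError(
                f"non-IUPAC character {c!r} at position {i + 1} in {context}"
            )
    return s


def ambiguity_code(bases: Iterable[str]) -> str:
    """IUPAC code whose expansion is exactly the union of ``bases``' expansions."""
    expanded: set[str] = set()
    for b in bases:
        expanded |= IUPAC_EXPAND[b.upper()]
    return _SET_TO_CODE[frozenset(expanded)]


def revcomp(seq: str) -> str:
    """IUPAC-aware reverse complement (an involution)."""
    s = validate_seq(seq)
    return "".join(IUPAC_COMPLEMENT[c] for c in reversed(s))


def iupac_match(a: str, b: str) -> bool:
    """True iff concrete base ``b`` lies in the expansion set of IUPAC symbol ``a``.

    ``b`` must be concrete: templates are real genomic sequence, only the
    primer side may be degenerate.
    """
    a = a.upper()
    b = b.upper()
    if a not in IUPAC_ALPHABET:
        raise ValueError(f"invalid IUPAC symbol {a!r}")
    if b not in CONCRETE_BASES:
        raise ValueError(f"template base must be concrete (A/C/G/T), got {b!r}")
    return b in IUPAC_EXPAND[a]


def expand_degenerate(seq: str) -> list[str]:
    """All concrete sequences in the expansion of a degenerate sequence."""
    out = [""]
    for c in validate_seq(seq):
        out = [p + b for p in out for b in sorted(IUPAC_EXPAND[c])]
    return out


@dataclass(frozen=True)
class SeqRecord:
    """A named DNA sequence over the IUPAC alphabet (stored uppercase)."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", validate_seq(self.seq, context=f"record {self.id!r}"))

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class GenomicInterval:
    """1-based inclusive genomic span, optionally stranded."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 1 <= start <= end)"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and self.end >= other.start
        )

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}({self.strand})"


def span_length(iv: GenomicInterval) -> int:
    """Inclusive span length in bp (end - start + 1)."""
    return iv.length


@dataclass(frozen=True)
class Primer:
    """A PCR primer: template-binding ``core`` plus optional universal 5' ``tail``.

    The synthesised oligo is ``tail + core`` (5'->3').
    """

    name: str
    core: str
    tail: str = ""
    role: str = "forward"

    def __post_init__(self) -> None:
        object.__setattr__(self, "core", validate_seq(self.core, context=f"primer {self.name!r} core"))
        if self.tail:
            object.__setattr__(self, "tail", validate_seq(self.tail, context=f"primer {self.name!r} tail"))
        if len(self.core) < 15:
            raise ValueError(f"primer {self.name!r}: core shorter than 15 nt")
        if self.role not in ("forward", "reverse"):
            raise ValueError(f"primer role must be forward/reverse, got {self.role!r}")

    @property
    def full(self) -> str:
        return self.tail + self.core


# --------------------------------------------------------------------------
# FASTA / BED I/O
# --------------------------------------------------------------------------

def parse_fasta(source: Union[str, TextIO]) -> list[SeqRecord]:
    """Parse FASTA text (string or file handle) into validated records.

    Sequence is uppercased; record order preserved. Errors on empty input,
    on sequence lines appearing before any header, and on non-IUPAC
    characters (with position).
    """
    if isinstance(source, str):
        text = source
    else:
        text = source.read()
    nonblank = [ln for ln in text.splitlines() if ln.strip()]
    if not nonblank:
        raise ValueError("empty FASTA input")
    if not nonblank[0].startswith(">"):
        raise ValueError("FASTA input has sequence data before any '>' header")
    records = []
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        records.append(SeqRecord(id=rec.id, seq=str(rec.seq), description=desc))
    return records


def write_fasta(records: Iterable[SeqRecord], handle: TextIO, width: int = 60) -> None:
    """Write records as wrapped FASTA."""
    bio = [
        _BioSeqRecord(Seq(r.seq), id=r.id, description=r.description)
        for r in records
    ]
    writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
    writer.write_file(bio)


def fasta_to_string(records: Iterable[SeqRecord], width: int = 60) -> str:
    buf = io.StringIO()
    write_fasta(records, buf, width=width)
    return buf.getvalue()


def read_fasta_path(path: Union[str, Path]) -> list[SeqRecord]:
    """Read a FASTA file, transparently handling ``.gz``."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:  # type: ignore[operator]
        return parse_fasta(fh)


def parse_bed(source: Union[str, TextIO]) -> list[GenomicInterval]:
    """Read BED3+ (0-based half-open) into 1-based inclusive intervals."""
    text = source if isinstance(source, str) else source.read()
    out = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) < 3:
            raise ValueError(f"BED line {lineno}: fewer than 3 columns")
        chrom, start0, end0 = parts[0], int(parts[1]), int(parts[2])
        if end0 <= start0:
            raise ValueError(f"BED line {lineno}: end <= start")
        out.append(GenomicInterval(chrom=chrom, start=start0 + 1, end=end0))
    return out


def read_bed_path(path: Union[str, Path]) -> list[GenomicInterval]:
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:  # type: ignore[operator]
        return parse_bed(fh)
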