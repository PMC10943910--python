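"""Sequence I/O and six-frame translation.

Reads FASTA/FASTQ into validated :class:`SequenceRecord` objects and bridges
DNA reads to peptide space by six-frame translation with stop-codon splitting.
Coordinates are 0-based half-open on the forward strand of the read; frames
are numbered +1..+3 (forward) and -1..-3 (reverse complement) following the
common six-frame convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

from Bio import SeqIO as _BioSeqIO
from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

PROTEIN_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_PROTEIN_SET = frozenset(PROTEIN_ALPHABET)
_DNA_SET = frozenset("ACGTN")

# Standard genetic code (translation table 1)
_TABLE1 = unambiguous_dna_by_id[1]
_CODON_TO_AA = dict(_TABLE1.forward_table)
_STOP_CODONS = frozenset(_TABLE1.stop_codons)


class InvalidSequenceError(ValueError):
    """A sequence contains letters outside its declared alphabet."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named sequence with a declared alphabet (``dna`` or ``protein``)."""

    id: str
    sequence: str
    alphabet: Literal["dna", "protein"]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise InvalidSequenceError(f"record {self.id!r}: empty sequence")
        if any(c.isspace() for c in self.id) or not self.id:
            raise ValueError(f"record id must be a non-empty token, got {self.id!r}")
        allowed = _DNA_SET if self.alphabet == "dna" else _PROTEIN_SET
        bad = set(self.sequence) - allowed
        if bad:
            raise InvalidSequenceError(
                f"record {self.id!r}: invalid {self.alphabet} letters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TranslatedFragment:
    """A stop-free peptide stretch translated from one frame of a read.

    ``nt_start``/``nt_end`` are 0-based half-open coordinates on the forward
    strand of the source read, regardless of frame sign.
    """

    read_id: str
    frame: int  # one of +1,+2,+3,-1,-2,-3
    nt_start: int
    nt_end: int
    peptide: str

    def __post_init__(self) -> None:
        if self.frame not in (1, 2, 3, -1, -2, -3):
            raise ValueError(f"invalid frame {self.frame}")
        if self.nt_end - self.nt_start != 3 * len(self.peptide):
            raise ValueError("fragment span does not equal 3 x peptide length")
        if not self.peptide:
            raise ValueError("empty fragment")


def validate_peptide(sequence: str) -> str:
    """Upper-case and validate a peptide over the 20 canonical letters."""
    seq = sequence.upper()
    bad = set(seq) - _PROTEIN_SET
    if bad or not seq:
        raise InvalidSequenceError(f"invalid peptide letters {sorted(bad)}" if bad else "empty peptide")
    return seq


def read_fasta(
    path: str | Path,
    alphabet: Literal["dna", "protein"],
    invalid_policy: Literal["reject", "error"] = "reject",
) -> list[SequenceRecord]:
    """Parse a FASTA file into validated records.

    Records containing letters outside the alphabet are rejected with a
    logged warning under the default policy (``reject``), or raise under
    ``error``. Returns records in file order. The number of rejected records
    is available via :func:`read_fasta_with_stats`.
    """
    records, _ = read_fasta_with_stats(path, alphabet, invalid_policy)
    return records


def read_fasta_with_stats(
    path: str | Path,
    alphabet: Literal["dna", "protein"],
    invalid_policy: Literal["reject", "error"] = "reject",
) -> tuple[list[SequenceRecord], int]:
    """As :func:`read_fasta`, also returning the rejected-record count."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    if not text.strip():
        raise ValueError(f"{path}: empty FASTA file")
    first = next(line for line in text.splitlines() if line.strip())
    if not first.startswith(">"):
        raise ValueError(f"{path}: first non-blank line is not a '>' header")

    records: list[SequenceRecord] = []
    n_rejected = 0
    for rec in _BioSeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().strip()
        desc = rec.description[len(rec.id):].strip() if rec.description.startswith(rec.id) else rec.description
        try:
            records.append(SequenceRecord(id=rec.id, sequence=seq, alphabet=alphabet, description=desc))
        except InvalidSequenceError as exc:
            if invalid_policy == "error":
                raise
            n_rejected += 1
            logger.warning("rejected record: %s", exc)
    if n_rejected:
        logger.warning("%d record(s) rejected while reading %s", n_rejected, path)
    return records, n_rejected


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    """Write records as FASTA with 60-column-wrapped sequence lines."""
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            header = f">{rec.id}" + (f" {rec.description}" if rec.description else "")
            fh.write(header + "\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def read_fastq(path: str | Path) -> list[SequenceRecord]:
    """Parse Phred+33 FASTQ into DNA records; qualities are checked and discarded.

    No quality filtering is performed: upstream read QC is assumed done.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[SequenceRecord] = []
    with path.open() as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    # strip trailing blank lines
    while lines and not lines[-1].strip():
        lines.pop()
    if len(lines) % 4 != 0:
        raise ValueError(f"{path}: truncated FASTQ (line count {len(lines)} not a multiple of 4)")
    for i in range(0, len(lines), 4):
        head, seq, plus, qual = lines[i : i + 4]
        if not head.startswith("@"):
            raise ValueError(f"{path}: record at line {i + 1} does not start with '@'")
        if not plus.startswith("+"):
            raise ValueError(f"{path}: record at line {i + 1} missing '+' separator")
        rid = head[1:].split()[0]
        if len(qual) != len(seq):
            raise ValueError(
                f"{path}: record {rid!r}: quality length {len(qual)} != sequence length {len(seq)}"
            )
        records.append(SequenceRecord(id=rid, sequence=seq.upper(), alphabet="dna"))
    return records


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _translate_frame(seq: str, offset: int) -> list[tuple[int, int, str]]:
    """Translate one frame of ``seq`` starting at ``offset``.

    Returns stop-free fragments as (start, end, peptide) in frame-local
    (i.e. ``seq``) coordinates. Fragments are split at stop codons and at any
    codon containing N.
    """
    fragments: list[tuple[int, int, str]] = []
    chars: list[str] = []
    frag_start = offset
    pos = offset
    while pos + 3 <= len(seq):
        codon = seq[pos : pos + 3]
        if codon in _STOP_CODONS or "N" in codon:
            if chars:
                fragments.append((frag_start, pos, "".join(chars)))
                chars = []
            frag_start = pos + 3
        else:
            chars.append(_CODON_TO_AA[codon])
        pos += 3
    if chars:
        fragments.append((frag_start, pos, "".join(chars)))
    return fragments


def six_frame_translate(record: SequenceRecord, min_len: int = 1) -> list[TranslatedFragment]:
    """Translate a DNA read in all six frames under the standard genetic code.

    Fragments are split at stop codons and at codons containing N; only
    fragments of length >= ``min_len`` are returned, with coordinates mapped
    to the forward strand. A read shorter than 3 nt yields an empty list.
    """
    if record.alphabet != "dna":
        raise ValueError("six_frame_translate requires a dna record")
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    seq = record.sequence
    L = len(seq)
    out: list[TranslatedFragment] = []
    for k in (1, 2, 3):
        for start, end, pep in _translate_frame(seq, k - 1):
            if len(pep) >= min_len:
                out.append(TranslatedFragment(record.id, k, start, end, pep))
    rc = reverse_complement(seq)
    for k in (1, 2, 3):
        for start, end, pep in _translate_frame(rc, k - 1):
            if len(pep) >= min_len:
                # map reverse-complement coordinates back to the forward strand
                out.append(TranslatedFragment(record.id, -k, L - end, L - start, pep))
    return out


def extract_fragment_peptide(read_seq: str, frame: int, nt_start: int, nt_end: int) -> str:
    """Re-derive a fragment's peptide from its read and coordinates (audit helper)."""
    sub = read_seq[nt_start:nt_end]
    if frame < 0:
        sub = reverse_complement(sub)
    return "".join(_CODON_TO_AA[sub[i : i + 3]] for i in range(0, len(sub), 3))
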