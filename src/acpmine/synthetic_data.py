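"""Seeded synthetic data: labelled peptide classes and reads with planted ORFs.

Two generators make every pipeline stage testable without external
downloads:

* :func:`sample_peptides` draws peptides i.i.d. from a residue-frequency
  class profile (lengths uniform on 5..50), emulating curated ACP-like and
  background peptide sets. The default ACP-like profile is enriched in
  K, R, W, F and L and depleted in D and E — the cationic, hydrophobic
  character typical of anticancer peptides — and ships as a data file.

* :func:`generate_reads` reverse-translates known peptides with uniform
  codon choice, embeds each in a random-base DNA read flanked by stop
  codons on a random strand and offset, adds random background reads, and
  emits a ground-truth manifest from which every planted peptide is
  recoverable by six-frame translation.

All outputs are pure functions of (configuration, seed).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import unambiguous_dna_by_id

from . import _tables
from .seqio import PROTEIN_ALPHABET, SequenceRecord, reverse_complement

_TABLE1 = unambiguous_dna_by_id[1]
_BACK_TABLE: dict[str, list[str]] = {}
for codon, aa in _TABLE1.forward_table.items():
    _BACK_TABLE.setdefault(aa, []).append(codon)
for aa in _BACK_TABLE:
    _BACK_TABLE[aa].sort()
_STOP = "TAA"

MIN_PEPTIDE_LEN = 5
MAX_PEPTIDE_LEN = 50


@dataclass(frozen=True)
class ClassProfile:
    """Residue-frequency profile of one peptide class.

    ``transitions`` optionally holds a 20x20 first-order chain (rows sum to
    1); when present, residue i+1 is drawn from the row of residue i, which
    is how dipeptide-frequency shifts are planted.
    """

    name: str
    freqs: dict[str, float]
    length_range: tuple[int, int] = (MIN_PEPTIDE_LEN, MAX_PEPTIDE_LEN)
    transitions: np.ndarray | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if set(self.freqs) != set(PROTEIN_ALPHABET):
            raise ValueError("profile must cover exactly the 20 canonical residues")
        total = sum(self.freqs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"frequencies sum to {total}, not 1")
        if any(f < 0 for f in self.freqs.values()):
            raise ValueError("negative frequency")
        lo, hi = self.length_range
        if lo < MIN_PEPTIDE_LEN or hi > MAX_PEPTIDE_LEN or lo > hi:
            raise ValueError(f"length range must satisfy {MIN_PEPTIDE_LEN} <= lo <= hi <= {MAX_PEPTIDE_LEN}")

    def freq_vector(self) -> np.ndarray:
        return np.array([self.freqs[aa] for aa in PROTEIN_ALPHABET])


def default_profile(which: str) -> ClassProfile:
    """Bundled profiles: ``acp`` (cationic/hydrophobic) or ``background`` (uniform)."""
    return ClassProfile(name=which, freqs=_tables.load_profile(which))


def plant_feature_shift(profile: ClassProfile, feature: str, delta: float) -> ClassProfile:
    """Raise one mono- or dipeptide frequency by ``delta``; renormalize the rest.

    For a single residue the target frequency becomes f+delta and the
    remaining mass is rescaled proportionally. For a dipeptide ``XY`` a
    first-order chain is built from the (possibly already shifted) residue
    frequencies and the X->Y transition probability is boosted by ``delta``
    with the rest of row X rescaled.
    """
    if len(feature) == 1:
        if feature not in profile.freqs:
            raise ValueError(f"unknown residue {feature!r}")
        new_target = profile.freqs[feature] + delta
        if not 0.0 <= new_target <= 1.0:
            raise ValueError(f"shift pushes {feature} frequency to {new_target}, outside [0,1]")
        rest = 1.0 - profile.freqs[feature]
        scale = (1.0 - new_target) / rest if rest > 0 else 0.0
        freqs = {aa: (new_target if aa == feature else f * scale)
                 for aa, f in profile.freqs.items()}
        return ClassProfile(name=f"{profile.name}+{feature}{delta:+g}", freqs=freqs,
                            length_range=profile.length_range)
    if len(feature) == 2 and all(c in profile.freqs for c in feature):
        x, y = feature
        base = profile.freq_vector()
        trans = np.tile(base, (20, 1)) if profile.transitions is None else profile.transitions.copy()
        xi, yi = PROTEIN_ALPHABET.index(x), PROTEIN_ALPHABET.index(y)
        row = trans[xi].copy()
        new_target = row[yi] + delta
        if not 0.0 <= new_target <= 1.0:
            raise ValueError(f"shift pushes P({y}|{x}) to {new_target}, outside [0,1]")
        rest = 1.0 - row[yi]
        scale = (1.0 - new_target) / rest if rest > 0 else 0.0
        row *= scale
        row[yi] = new_target
        trans[xi] = row
        return ClassProfile(name=f"{profile.name}+{feature}{delta:+g}",
                            freqs=profile.freqs, length_range=profile.length_range,
                            transitions=trans)
    raise ValueError(f"feature must be a residue or dipeptide token, got {feature!r}")


def sample_peptides(profile: ClassProfile, n: int, seed: int,
                    id_prefix: str | None = None) -> list[SequenceRecord]:
    """Draw ``n`` peptides from the profile; bit-reproducible for a seed.

    Residues are i.i.d. from the frequency vector (or follow the first-order
    chain when transitions are planted); lengths are uniform on the profile's
    length range. Records are labelled via the description field.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    alphabet = np.array(list(PROTEIN_ALPHABET))
    lo, hi = profile.length_range
    prefix = id_prefix or profile.name
    records = []
    for i in range(n):
        length = int(rng.integers(lo, hi + 1))
        if profile.transitions is None:
            idx = rng.choice(20, size=length, p=profile.freq_vector())
        else:
            idx = np.empty(length, dtype=int)
            idx[0] = rng.choice(20, p=profile.freq_vector())
            for j in range(1, length):
                idx[j] = rng.choice(20, p=profile.transitions[idx[j - 1]])
        seq = "".join(alphabet[idx])
        records.append(SequenceRecord(id=f"{prefix}_{i:05d}", sequence=seq,
                                      alphabet="protein", description=f"label={profile.name}"))
    return records


def reverse_translate(peptide: str, rng: np.random.Generator) -> str:
    """Encode a peptide as DNA with uniform random codon choice per residue."""
    return "".join(_BACK_TABLE[aa][rng.integers(0, len(_BACK_TABLE[aa]))] for aa in peptide)


def _random_bases(n: int, rng: np.random.Generator) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


@dataclass(frozen=True)
class GroundTruthManifest:
    """Planted-peptide provenance plus the generator seed and config hash."""

    entries: pd.DataFrame  # peptide, read_id, frame, nt_start, nt_end
    seed: int
    config_hash: str

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# seed={self.seed}\tconfig_hash={self.config_hash}\n")
            self.entries.to_csv(fh, sep="\t", index=False)


def generate_reads(planted_peptides: list[str], n_background: int,
                   read_length: int = 300, seed: int = 0
                   ) -> tuple[list[SequenceRecord], GroundTruthManifest]:
    """Emit DNA reads with one planted ORF each, plus random background reads.

    Each planted peptide is reverse-translated, flanked by stop codons,
    embedded at a random offset on a random strand within a random-base read
    of ``read_length``. The manifest records the peptide, read, frame and
    forward-strand nucleotide interval of the coding region; every entry is
    recoverable verbatim by six-frame translation.
    """
    rng = np.random.default_rng(seed)
    config = {"n_planted": len(planted_peptides), "n_background": n_background,
              "read_length": read_length, "peptides": planted_peptides}
    config_hash = hashlib.sha256(json.dumps(config, sort_keys=True).encode()).hexdigest()[:16]

    reads: list[SequenceRecord] = []
    entries = []
    for i, pep in enumerate(planted_peptides):
        insert = _STOP + reverse_translate(pep, rng) + _STOP
        if read_length < len(insert):
            raise ValueError(
                f"read_length {read_length} too short for planted peptide of length {len(pep)}")
        offset = int(rng.integers(0, read_length - len(insert) + 1))
        strand = int(rng.integers(0, 2))  # 0 forward, 1 reverse
        left = _random_bases(offset, rng)
        right = _random_bases(read_length - offset - len(insert), rng)
        forward_insert = insert if strand == 0 else reverse_complement(insert)
        read_seq = left + forward_insert + right
        read_id = f"planted_{i:05d}"
        # coding-region coordinates on the forward strand (excluding flanks)
        if strand == 0:
            nt_start = offset + 3
            nt_end = offset + len(insert) - 3
            frame = (nt_start % 3) + 1
        else:
            nt_start = offset + 3
            nt_end = offset + len(insert) - 3
            frame = -(((read_length - nt_end) % 3) + 1)
        reads.append(SequenceRecord(id=read_id, sequence=read_seq, alphabet="dna"))
        entries.append({"peptide": pep, "read_id": read_id, "frame": frame,
                        "nt_start": nt_start, "nt_end": nt_end})
    for i in range(n_background):
        reads.append(SequenceRecord(id=f"background_{i:05d}",
                                    sequence=_random_bases(read_length, rng),
                                    alphabet="dna"))
    manifest = GroundTruthManifest(
        entries=pd.DataFrame(entries, columns=["peptide", "read_id", "frame",
                                               "nt_start", "nt_end"]),
        seed=seed, config_hash=config_hash)
    return reads, manifest


def write_fastq(reads: list[SequenceRecord], path) -> None:
    """Write reads as Phred+33 FASTQ with constant 'I' qualities."""
    with open(path, "w") as fh:
        for rec in reads:
            fh.write(f"@{rec.id}\n{rec.sequence}\n+\n{'I' * len(rec.sequence)}\n")
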