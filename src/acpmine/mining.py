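"""Sliding-window candidate mining and domain-annotation adapter.

Translated fragments are expanded into every contiguous window in a length
range (minimum 5 residues), deduplicated while preserving provenance,
scored by the trained classifier, and ranked. Domain annotations come from
externally produced profile-HMM search output (``--domtblout`` per-domain
tables) — the adapter parses, never scores, HMMs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd

from .classifier import ACPClassifier, ACP
from .seqio import SequenceRecord, TranslatedFragment, six_frame_translate

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Provenance:
    read_id: str
    frame: int
    offset: int  # peptide-space start offset within the translated fragment
    length: int
    frag_nt_start: int = 0  # forward-strand start of the source fragment


@dataclass
class WindowCandidate:
    peptide: str
    provenance: list[Provenance] = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(self.peptide)


@dataclass(frozen=True)
class MiningConfig:
    min_len: int = 5
    max_len: int = 50
    translate_min_len: int = 5


def enumerate_windows(fragment: str, min_len: int = 5,
                      max_len: int | None = None) -> Iterator[tuple[int, str]]:
    """Yield (offset, window) for every contiguous substring with length in
    [min_len, max_len], in (length ascending, offset ascending) order.

    The emitted count obeys the closed form sum over lengths L of
    (len(fragment) - L + 1).
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    if max_len is None:
        max_len = len(fragment)
    if max_len < min_len:
        raise ValueError("max_len must be >= min_len")
    top = min(max_len, len(fragment))
    for L in range(min_len, top + 1):
        for off in range(len(fragment) - L + 1):
            yield off, fragment[off : off + L]


def window_count(fragment_len: int, min_len: int, max_len: int) -> int:
    """Closed-form window count: sum over L in [min_len, min(max_len, n)] of n-L+1."""
    top = min(max_len, fragment_len)
    return sum(fragment_len - L + 1 for L in range(min_len, top + 1))


def deduplicate(candidates: Iterable[tuple[str, Provenance]]) -> list[WindowCandidate]:
    """Merge identical window peptides; provenance entries are conserved."""
    by_pep: dict[str, WindowCandidate] = {}
    for pep, prov in candidates:
        if pep not in by_pep:
            by_pep[pep] = WindowCandidate(pep)
        by_pep[pep].provenance.append(prov)
    return list(by_pep.values())


def windows_from_fragments(fragments: Sequence[TranslatedFragment],
                           config: MiningConfig) -> list[WindowCandidate]:
    raw = ((pep, Provenance(f.read_id, f.frame, off, len(pep), f.nt_start))
           for f in fragments
           for off, pep in enumerate_windows(f.peptide, config.min_len, config.max_len))
    return deduplicate(raw)


def mine_reads(reads: Sequence[SequenceRecord], model: ACPClassifier,
               config: MiningConfig = MiningConfig()) -> tuple[pd.DataFrame, dict[str, int]]:
    """Full mining pass: translate, window, deduplicate, score, rank.

    Returns the ranked candidate report (score descending, ties broken by
    shorter length then lexicographic peptide) and per-stage counts. Protein
    records bypass translation and are windowed directly.
    """
    if not reads:
        raise ValueError("empty read set")
    fragments: list[TranslatedFragment] = []
    for rec in reads:
        if rec.alphabet == "dna":
            fragments.extend(six_frame_translate(rec, min_len=config.translate_min_len))
        else:
            fragments.append(TranslatedFragment(rec.id, 1, 0, 3 * len(rec.sequence), rec.sequence))
    candidates = windows_from_fragments(fragments, config)
    n_windows = sum(len(c.provenance) for c in candidates)

    peptides = [c.peptide for c in candidates]
    scores = model.score_peptides(peptides) if candidates else []
    report = pd.DataFrame({
        "peptide": peptides,
        "length": [c.length for c in candidates],
        "score": scores,
        "label": [ACP if s > model.threshold else "nonACP" for s in scores],
        "n_sources": [len(c.provenance) for c in candidates],
    }, columns=["peptide", "length", "score", "label", "n_sources"])
    if len(report):
        report = report.sort_values(
            by=["score", "length", "peptide"], ascending=[False, True, True]
        ).reset_index(drop=True)
    counts = {
        "reads": len(reads),
        "fragments": len(fragments),
        "windows": n_windows,
        "candidates": len(candidates),
        "predicted_acp": int((report["label"] == ACP).sum()) if len(report) else 0,
    }
    for stage, n in counts.items():
        logger.info("mining stage %-14s %d", stage, n)
    return report, counts


# -- domain-annotation adapter --------------------------------------------

@dataclass(frozen=True)
class DomainHit:
    candidate_id: str
    domain_name: str
    accession: str
    e_value: float
    ali_start: int  # 0-based half-open on the candidate
    ali_end: int

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise ValueError("e-value must be >= 0")
        if self.ali_end <= self.ali_start or self.ali_start < 0:
            raise ValueError("invalid alignment coordinates")


def parse_domtblout(path: str | Path) -> list[DomainHit]:
    """Parse a per-domain tabular (``--domtblout``) profile-HMM search table.

    Assumes the hmmscan orientation: the query is the candidate peptide and
    the target the domain model. The per-domain independent e-value is kept,
    and 1-based inclusive alignment coordinates are converted to 0-based
    half-open.
    """
    hits: list[DomainHit] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split()
        if len(cols) < 23:
            raise ValueError(f"{path}:{lineno}: expected >= 23 columns, got {len(cols)}")
        target, t_acc, query = cols[0], cols[1], cols[3]
        i_evalue = float(cols[12])
        ali_from, ali_to = int(cols[17]), int(cols[18])
        hits.append(DomainHit(candidate_id=query, domain_name=target, accession=t_acc,
                              e_value=i_evalue, ali_start=ali_from - 1, ali_end=ali_to))
    return hits


def annotate_candidates(report: pd.DataFrame, hits: Sequence[DomainHit],
                        e_max: float = 0.01,
                        id_column: str = "peptide") -> pd.DataFrame:
    """Attach domain annotations (e-value <= e_max) to the candidate report.

    Scores and ranking are untouched; candidates without an accepted hit get
    an empty ``domains`` field. Hits naming unknown candidates are skipped
    with a warning.
    """
    known = set(report[id_column])
    domains: dict[str, list[str]] = {}
    for hit in hits:
        if hit.candidate_id not in known:
            logger.warning("domain hit for unknown candidate %r skipped", hit.candidate_id)
            continue
        if hit.e_value <= e_max:
            domains.setdefault(hit.candidate_id, []).append(
                f"{hit.domain_name}({hit.accession})")
    out = report.copy()
    out["domains"] = [";".join(domains.get(c, [])) for c in out[id_column]]
    return out
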