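"""Windowed antimicrobial-propensity scanning.

Slides a fixed-size window (default 5 residues) along the peptide, scores
each window as the mean residue propensity under a chosen scale, flags every
residue covered by at least one window whose score strictly exceeds the
threshold (default 0.25), merges flagged residues into maximal regions, and
reports the percentage of the peptide they cover.

Region coordinates are 1-based inclusive residue intervals, so a single
above-threshold window starting at residue 1 with window 5 gives the region
(1, 5) and two consecutive ones merge into (1, 6).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _tables
from .seqio import validate_peptide


@dataclass(frozen=True)
class PropensityProfile:
    peptide: str
    window: int
    threshold: float
    scores: tuple[float, ...]          # indexed by 1-based window start
    regions: tuple[tuple[int, int], ...]  # 1-based inclusive residue intervals
    coverage_percent: float

    @property
    def coverage_percent_rounded(self) -> int:
        return int(round(self.coverage_percent))


def window_scores(peptide: str, scale: str = "amp_synthetic", window: int = 5) -> np.ndarray:
    """Mean residue propensity of each window; length len(peptide)-window+1."""
    pep = validate_peptide(peptide)
    if window < 1:
        raise ValueError("window must be >= 1")
    if len(pep) < window:
        raise ValueError(f"peptide length {len(pep)} shorter than window {window}")
    s = _tables.load_scale(scale)
    vals = np.array([s[aa] for aa in pep])
    kernel = np.ones(window) / window
    return np.convolve(vals, kernel, mode="valid")


def flag_regions(scores: np.ndarray, threshold: float = 0.25,
                 window: int = 5) -> list[tuple[int, int]]:
    """Maximal runs of residues covered by any window scoring above threshold.

    Strict inequality at the threshold. Returns sorted, disjoint 1-based
    inclusive intervals.
    """
    scores = np.asarray(scores, dtype=float)
    length = len(scores) + window - 1
    flagged = np.zeros(length, dtype=bool)
    for i in np.flatnonzero(scores > threshold):
        flagged[i : i + window] = True
    regions: list[tuple[int, int]] = []
    start = None
    for i, on in enumerate(flagged):
        if on and start is None:
            start = i
        elif not on and start is not None:
            regions.append((start + 1, i))
            start = None
    if start is not None:
        regions.append((start + 1, length))
    return regions


def coverage_percent(regions: list[tuple[int, int]], length: int) -> float:
    """Percentage of residues inside the (disjoint, in-range) region union."""
    covered = 0
    prev_end = 0
    for start, end in sorted(regions):
        if start < 1 or end > length or end < start:
            raise ValueError(f"region ({start},{end}) out of range for length {length}")
        if start <= prev_end:
            raise ValueError(f"overlapping regions at ({start},{end})")
        covered += end - start + 1
        prev_end = end
    return 100.0 * covered / length


def scan(peptide: str, scale: str = "amp_synthetic", window: int = 5,
         threshold: float = 0.25) -> PropensityProfile:
    """Full propensity scan: window scores, flagged regions and coverage."""
    pep = validate_peptide(peptide)
    scores = window_scores(pep, scale, window)
    regions = flag_regions(scores, threshold, window)
    return PropensityProfile(
        peptide=pep, window=window, threshold=threshold,
        scores=tuple(float(s) for s in scores),
        regions=tuple(regions),
        coverage_percent=coverage_percent(regions, len(pep)),
    )


def profile_to_text(profile: PropensityProfile) -> str:
    """Delimited-text serialization: per-window scores then a region summary."""
    lines = ["window_start\tscore"]
    lines += [f"{i + 1}\t{s:.6f}" for i, s in enumerate(profile.scores)]
    lines.append("# regions (1-based inclusive residue intervals)")
    for start, end in profile.regions:
        lines.append(f"# region\t{start}\t{end}")
    lines.append(f"# coverage_percent\t{profile.coverage_percent:.4f}")
    lines.append(f"# coverage_percent_rounded\t{profile.coverage_percent_rounded}")
    return "\n".join(lines) + "\n"
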