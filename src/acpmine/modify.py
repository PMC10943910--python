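"""Rational terminal extension of a base peptide.

Generalizes the hand-designed four-residue N-terminal addition (the AAEK
step that turned the mined 30-mer homeodomain core into the final 34-mer)
into a scored search: every candidate extension is evaluated by the change
it induces in integer net charge, GRAVY and hydrophobic moment per residue,
combined linearly with configurable weights, optionally under a
classifier-retention constraint (the modified peptide must still score
above the ACP decision threshold).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterator, Literal

from .classifier import ACPClassifier
from .properties import (PropertyReport, gravy, hydrophobic_moment,
                         net_charge_integer, property_report)
from .seqio import PROTEIN_ALPHABET, validate_peptide

Terminus = Literal["N", "C"]


@dataclass(frozen=True)
class ObjectiveWeights:
    charge: float = 1.0
    gravy: float = 1.0
    moment_per_residue: float = 1.0


@dataclass(frozen=True)
class ExtensionCandidate:
    extension: str
    terminus: Terminus
    modified: str
    delta_charge_integer: int
    delta_gravy: float
    delta_moment_per_residue: float
    objective_value: float
    classifier_score: float | None = None


def attach(base: str, extension: str, terminus: Terminus = "N") -> str:
    """The modified peptide: extension ++ base (N) or base ++ extension (C)."""
    base = validate_peptide(base)
    extension = validate_peptide(extension)
    return extension + base if terminus == "N" else base + extension


def score_extension(base: str, extension: str, terminus: Terminus = "N",
                    weights: ObjectiveWeights = ObjectiveWeights(),
                    model: ACPClassifier | None = None) -> ExtensionCandidate:
    """Score one terminal extension by its physicochemical deltas.

    objective = w_charge * d(charge) + w_gravy * d(GRAVY)
              + w_moment * d(moment/residue); all deltas are
    modified-minus-base, recomputed from scratch on the full sequences.
    """
    base = validate_peptide(base)
    modified = attach(base, extension, terminus)
    d_charge = net_charge_integer(modified) - net_charge_integer(base)
    d_gravy = gravy(modified) - gravy(base)
    d_moment = (hydrophobic_moment(modified) / len(modified)
                - hydrophobic_moment(base) / len(base))
    objective = (weights.charge * d_charge + weights.gravy * d_gravy
                 + weights.moment_per_residue * d_moment)
    score = model.score_peptide(modified) if model is not None else None
    return ExtensionCandidate(
        extension=validate_peptide(extension), terminus=terminus, modified=modified,
        delta_charge_integer=d_charge, delta_gravy=d_gravy,
        delta_moment_per_residue=d_moment, objective_value=objective,
        classifier_score=score,
    )


def _enumerate_extensions(length: int) -> Iterator[str]:
    for combo in itertools.product(PROTEIN_ALPHABET, repeat=length):
        yield "".join(combo)


def search_extensions(base: str, length: int = 4, terminus: Terminus = "N",
                      weights: ObjectiveWeights = ObjectiveWeights(),
                      model: ACPClassifier | None = None,
                      top_n: int = 10) -> tuple[list[ExtensionCandidate], dict[str, int]]:
    """Rank terminal extensions of a given length by the linear objective.

    Exhaustive enumeration (20^length candidates) for length <= 4; longer
    extensions are built greedily one residue at a time, keeping the best
    single-residue addition at each step (a documented approximation).
    Candidates whose classifier score falls below the model threshold are
    excluded and counted. Ties rank lexicographically.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    base = validate_peptide(base)

    if length <= 4:
        extensions: Iterator[str] = _enumerate_extensions(length)
    else:
        prefix = ""
        for _ in range(length - 4):
            # ties resolved toward the lexicographically smaller extension
            best = max((score_extension(base, prefix + aa, terminus, weights)
                        for aa in PROTEIN_ALPHABET),
                       key=lambda c: (c.objective_value,
                                      [-ord(x) for x in c.extension]))
            prefix = best.extension
        extensions = (prefix + tail for tail in _enumerate_extensions(4))

    scored: list[ExtensionCandidate] = []
    n_total = 0
    n_excluded = 0
    for ext in extensions:
        n_total += 1
        cand = score_extension(base, ext, terminus, weights, model)
        if model is not None and cand.classifier_score is not None \
                and cand.classifier_score < model.threshold:
            n_excluded += 1
            continue
        scored.append(cand)
    scored.sort(key=lambda c: (-c.objective_value, c.extension))
    counts = {"enumerated": n_total, "excluded_by_classifier": n_excluded,
              "retained": len(scored)}
    return scored[:top_n], counts


def apply_extension(base: str, extension: str, terminus: Terminus = "N"
                    ) -> tuple[str, PropertyReport, PropertyReport]:
    """Attach an extension and return (modified, before-report, after-report)."""
    if not extension:
        raise ValueError("empty extension")
    modified = attach(base, extension, terminus)
    return modified, property_report(base), property_report(modified)
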