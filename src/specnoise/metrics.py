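"""Evaluation metrics for de novo peptide sequencing.

An amino acid at position i of a prediction is *matched* when its residue
mass (modifications included) is within 0.1 Da of the true residue mass at
the same position, and the cumulative mass of the preceding i−1 residues
agrees with the true prefix to within 0.5 Da.  The mass-based rule means
isobaric or near-isobaric residues (Leu/Ile exactly; Lys/Gln at Δ0.036 Da)
count as matched — a documented property, not a bug.

Amino-acid precision = matched / predicted residues; amino-acid recall =
matched / true residues; peptide recall = fully correct peptides / spectra.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .chemistry import Peptide
from .matching import Spectrum

RESIDUE_MASS_TOL = 0.1
PREFIX_MASS_TOL = 0.5


@dataclass(frozen=True)
class Prediction:
    """A de novo sequence prediction for one spectrum."""

    spectrum_id: str
    peptide: Peptide


@dataclass(frozen=True)
class MetricsResult:
    aa_recall: float
    aa_precision: float
    peptide_recall: float
    matched_aa: int
    predicted_aa: int
    actual_aa: int
    correct_peptides: int
    total_spectra: int
    precision_defined: bool = True


def match_amino_acids(predicted: Peptide, actual: Peptide) -> int:
    """Count positionally matched residues under the mass + prefix-mass gates."""
    pm = predicted.residue_masses()
    am = actual.residue_masses()
    matched = 0
    prefix_pred = 0.0
    prefix_act = 0.0
    for i in range(min(len(pm), len(am))):
        if (abs(pm[i] - am[i]) < RESIDUE_MASS_TOL
                and abs(prefix_pred - prefix_act) < PREFIX_MASS_TOL):
            matched += 1
        prefix_pred += pm[i]
        prefix_act += am[i]
    return matched


def is_correct_peptide(predicted: Peptide, actual: Peptide) -> bool:
    """Strict reading: equal length and every position matched."""
    return (len(predicted) == len(actual)
            and match_amino_acids(predicted, actual) == len(actual))


def evaluate(
    predictions: Sequence[Prediction], corpus: Sequence[Spectrum]
) -> MetricsResult:
    """Aggregate de novo metrics over a labelled corpus.

    Spectra without a prediction contribute their true residues to the
    recall denominator but nothing else.  With zero predicted residues the
    precision is reported as 0 with ``precision_defined=False``.
    """
    by_title = {s.title: s for s in corpus}
    matched_aa = predicted_aa = actual_aa = correct = 0
    seen: set[str] = set()
    for pred in predictions:
        spec = by_title.get(pred.spectrum_id)
        if spec is None:
            raise KeyError(f"prediction references unknown spectrum {pred.spectrum_id!r}")
        if spec.peptide is None:
            raise ValueError(f"spectrum {pred.spectrum_id!r} has no peptide label")
        if pred.spectrum_id in seen:
            raise ValueError(f"duplicate prediction for {pred.spectrum_id!r}")
        seen.add(pred.spectrum_id)
        matched_aa += match_amino_acids(pred.peptide, spec.peptide)
        predicted_aa += len(pred.peptide)
        if is_correct_peptide(pred.peptide, spec.peptide):
            correct += 1
    for spec in corpus:
        if spec.peptide is not None:
            actual_aa += len(spec.peptide)
    total = len(corpus)
    precision_defined = predicted_aa > 0
    return MetricsResult(
        aa_recall=matched_aa / actual_aa if actual_aa else 0.0,
        aa_precision=matched_aa / predicted_aa if precision_defined else 0.0,
        peptide_recall=correct / total if total else 0.0,
        matched_aa=matched_aa,
        predicted_aa=predicted_aa,
        actual_aa=actual_aa,
        correct_peptides=correct,
        total_spectra=total,
        precision_defined=precision_defined,
    )
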