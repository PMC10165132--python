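"""Random-peptide null model for estimating spurious fragment matches.

For each labelled spectrum a random tryptic peptide of the same length is
drawn, with residues sampled from an amino-acid frequency model and the
final residue forced to arginine or lysine — whichever the assigned
peptide does *not* end in, which guarantees every y ion mass differs and
minimises accidental fragment-mass overlap.  Matching the random peptide's
theoretical ions against the observed peaks estimates how many of the real
matches arise by chance.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .chemistry import Peptide, enumerate_backbone_ions, enumerate_internal_fragments
from .matching import (
    DEFAULT_TOLERANCE,
    MatchConfig,
    Spectrum,
    annotate_spectrum,
    match_ions,
)

# Average amino-acid composition of proteins (Swiss-Prot release statistics),
# used as the default sampling model when no corpus-derived model is given.
SWISSPROT_AA_FREQUENCIES: dict[str, float] = {
    "A": 0.0825, "R": 0.0553, "N": 0.0406, "D": 0.0545, "C": 0.0138,
    "Q": 0.0393, "E": 0.0675, "G": 0.0707, "H": 0.0227, "I": 0.0596,
    "L": 0.0966, "K": 0.0584, "M": 0.0242, "F": 0.0386, "P": 0.0470,
    "S": 0.0656, "T": 0.0534, "W": 0.0108, "Y": 0.0292, "V": 0.0687,
}


@dataclass(frozen=True)
class AAFrequencyModel:
    """Sampling probabilities over the 20 standard one-letter residue codes."""

    probabilities: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.probabilities.values())
        if any(p < 0 for p in self.probabilities.values()):
            raise ValueError("probabilities must be non-negative")
        if abs(total - 1.0) > 1e-6:
            # normalise silently only when close; reject garbage
            if not 0.5 < total < 2.0:
                raise ValueError(f"probabilities sum to {total}, not 1")
        norm = {aa: p / total for aa, p in self.probabilities.items()}
        object.__setattr__(self, "probabilities", norm)

    @property
    def alphabet(self) -> list[str]:
        return sorted(self.probabilities)

    def as_arrays(self) -> tuple[list[str], np.ndarray]:
        aas = self.alphabet
        return aas, np.array([self.probabilities[a] for a in aas])


DEFAULT_AA_MODEL = AAFrequencyModel(SWISSPROT_AA_FREQUENCIES)


def estimate_aa_frequencies(corpus: Sequence[Spectrum]) -> AAFrequencyModel:
    """Empirical residue frequencies over the assigned peptides of a corpus."""
    counts = dict.fromkeys(SWISSPROT_AA_FREQUENCIES, 0)
    total = 0
    for spec in corpus:
        if spec.peptide is None:
            continue
        for aa in spec.peptide.sequence:
            counts[aa] += 1
            total += 1
    if total == 0:
        raise ValueError("corpus contains no labelled spectra")
    return AAFrequencyModel({aa: c / total for aa, c in counts.items()})


def sample_random_peptide(
    length: int,
    freqs: AAFrequencyModel = DEFAULT_AA_MODEL,
    original_last: str = "K",
    rng: np.random.Generator | int | None = None,
) -> Peptide:
    """Draw a random tryptic peptide of a given length.

    Non-terminal positions are i.i.d. from ``freqs``; the final residue is
    R if the original peptide ended in K, K if it ended in R, and a fair
    coin flip between the two for non-tryptic originals.
    """
    if length < 2:
        raise ValueError("random peptide length must be >= 2")
    rng = np.random.default_rng(rng)
    aas, probs = freqs.as_arrays()
    body = rng.choice(aas, size=length - 1, p=probs)
    if original_last == "K":
        last = "R"
    elif original_last == "R":
        last = "K"
    else:
        last = "R" if rng.random() < 0.5 else "K"
    return Peptide("".join(body) + last)


def estimate_spurious_matches(
    corpus: Sequence[Spectrum],
    freqs: AAFrequencyModel = DEFAULT_AA_MODEL,
    config: MatchConfig | None = None,
    seed: int = 0,
    replicates: int = 1,
) -> dict[str, float]:
    """Per-ion-type counts of matches achieved by random decoy peptides.

    One decoy is drawn per spectrum (per replicate); its backbone ions and
    internal fragments are matched against the observed peaks with the same
    tolerance used for the real accounting.  Each spectrum's decoy stream
    is seeded from (seed, hash of its title and peptide), so the totals do
    not depend on the order of spectra in the corpus.  With
    ``replicates > 1`` the mean count per replicate is returned, allowing
    variance estimation of the null externally.
    """
    config = config or MatchConfig()
    totals: dict[str, float] = {}
    for spec in corpus:
        if spec.peptide is None:
            raise ValueError("every spectrum must carry a peptide label")
    for rep in range(replicates):
        for spec in corpus:
            pep = spec.peptide
            key = zlib.crc32(f"{spec.title}|{pep.sequence}".encode())
            rng = np.random.default_rng([int(seed), key, rep])
            decoy = sample_random_peptide(
                len(pep), freqs, pep.sequence[-1], rng
            )
            ions: list = list(enumerate_backbone_ions(decoy))
            if len(decoy) >= config.internal_min_len + 2:
                ions += enumerate_internal_fragments(decoy, config.internal_min_len)
            for rec in match_ions(spec, ions, config.tolerance):
                totals[rec.ion_type] = totals.get(rec.ion_type, 0) + 1
    if replicates > 1:
        totals = {t: n / replicates for t, n in totals.items()}
    return totals


def spurious_ratio(
    real_matched: dict[str, int], random_matched: dict[str, float]
) -> dict[str, float]:
    """Per-type random/matched ratio; NaN where the real count is zero."""
    out: dict[str, float] = {}
    for t, n in real_matched.items():
        out[t] = random_matched.get(t, 0) / n if n else float("nan")
    return out
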