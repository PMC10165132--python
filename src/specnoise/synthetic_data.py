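"""Synthetic labelled corpora: clean predicted spectra and noisy twins.

The generator emulates the statistical structure of database-labelled
tryptic HCD data: peptides of bounded length with a configurable residue
frequency model and an R/K C-terminus, a deterministic b/y intensity
predictor standing in for a learned spectrum predictor, and "real-like"
twins produced by the parameterised noise stack (peak removal, unknown
peaks, m/z jitter, optional extra ion types).

The intensity predictor here is NOT a re-implementation of any learned
model: it is a smooth deterministic surrogate whose only job is to supply
a reproducible, normalised b/y peak list so every transform and accounting
routine can be exercised.  Conclusions about real predictors must not be
drawn from it.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from pyteomics import mgf as _mgf

from .chemistry import (
    MOD_OXIDATION,
    PROTON,
    Peptide,
    enumerate_backbone_ions,
    peptide_neutral_mass,
)
from .decoy_null import DEFAULT_AA_MODEL, AAFrequencyModel
from .matching import Peak, Spectrum
from .noise_models import NoiseConfig
from .transform import augment_predicted

MAX_PEPTIDE_LENGTH = 30

_MOD_RE = re.compile(r"\(([+-]\d+(?:\.\d+)?)\)")


@dataclass
class CorpusConfig:
    """Parameters of the synthetic corpus generator.

    Lengths follow a geometric distribution truncated to
    [length_min, length_max] with its median at ``length_median`` —
    short tryptic peptides dominate real digests.  Charges are drawn from
    ``charge_probs``.  ``ox_probability`` is the per-methionine chance of
    an oxidation modification.
    """

    n_spectra: int = 100
    length_min: int = 7
    length_max: int = 25
    length_median: int = 10
    aa_model: AAFrequencyModel = field(default_factory=lambda: DEFAULT_AA_MODEL)
    charge_probs: dict[int, float] = field(default_factory=lambda: {2: 0.65, 3: 0.35})
    ox_probability: float = 0.05
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_spectra < 1:
            raise ValueError("n_spectra must be >= 1")
        if not 2 <= self.length_min <= self.length_median <= self.length_max:
            raise ValueError("need 2 <= length_min <= length_median <= length_max")
        if self.length_max > MAX_PEPTIDE_LENGTH:
            raise ValueError(f"length_max must be <= {MAX_PEPTIDE_LENGTH}")
        total = sum(self.charge_probs.values())
        self.charge_probs = {z: p / total for z, p in self.charge_probs.items()}


def _frac(x: float) -> float:
    return x - math.floor(x)


def _flank_factor(left_mass: float, right_mass: float) -> float:
    # smooth deterministic variation with the residues flanking the cleavage
    return 0.6 + 0.4 * _frac(left_mass * 0.7 + right_mass * 1.3)


def predict_spectrum(peptide: Peptide) -> Spectrum:
    """Deterministic b/y-only spectrum prediction (toy surrogate).

    Emits b and y ions at charges 1+ and 2+ with intensities that are a
    fixed smooth function of the series, the relative cleavage position
    and the residues flanking the cleavage, normalised so the most intense
    fragment is 1.  Identical input gives byte-identical output.
    """
    L = len(peptide)
    if not 2 <= L <= MAX_PEPTIDE_LENGTH:
        raise ValueError(f"peptide length {L} outside [2, {MAX_PEPTIDE_LENGTH}]")
    for _pos, delta in peptide.mods:
        if abs(delta - MOD_OXIDATION) > 1e-3:
            raise ValueError(f"unsupported modification delta {delta}")
    res = peptide.residue_masses()
    peaks: list[Peak] = []
    for ion in enumerate_backbone_ions(peptide, charges=(1, 2), losses=("none",)):
        if ion.series == "a":
            continue
        i = ion.index
        x = i / L
        if ion.series == "y":
            base = math.exp(-1.2 * x)           # y1 strongest, decaying
            left, right = res[L - i - 1], res[L - i]
        else:
            base = 2.2 * x * math.exp(-2.5 * x)  # b1 weak, peak near b2-b3
            left, right = res[i - 1], res[i]
        intensity = base * _flank_factor(left, right)
        if ion.charge == 2:
            intensity *= 0.25
        peaks.append(Peak(ion.mz, intensity))
    top = max(p.intensity for p in peaks)
    peaks = [Peak(p.mz, p.intensity / top) for p in peaks]
    mz = (peptide_neutral_mass(peptide) + peptide.precursor_charge * PROTON) \
        / peptide.precursor_charge
    title = f"synth|{peptide.sequence}|{peptide.precursor_charge}+"
    return Spectrum(title, mz, peptide.precursor_charge, peaks, peptide)


def sample_peptide(config: CorpusConfig, rng: np.random.Generator) -> Peptide:
    """Draw one tryptic peptide under the configured length/residue model."""
    # truncated geometric with median at length_median
    p = 1.0 - 0.5 ** (1.0 / (config.length_median - config.length_min + 1))
    span = config.length_max - config.length_min + 1
    probs = np.array([p * (1 - p) ** j for j in range(span)])
    probs /= probs.sum()
    length = config.length_min + int(rng.choice(span, p=probs))

    aas, aa_probs = config.aa_model.as_arrays()
    body = rng.choice(aas, size=length - 1, p=aa_probs)
    last = "K" if rng.random() < 0.5 else "R"
    seq = "".join(body) + last
    mods = tuple(
        (i + 1, MOD_OXIDATION)
        for i, aa in enumerate(seq)
        if aa == "M" and rng.random() < config.ox_probability
    )
    charges = sorted(config.charge_probs)
    z = int(rng.choice(charges, p=[config.charge_probs[c] for c in charges]))
    return Peptide(seq, mods, precursor_charge=z)


def _inject_extra_ions(
    spectrum: Spectrum, rate: float, rng: np.random.Generator
) -> Spectrum:
    """Add a-ions and neutral-loss peaks, each with probability ``rate``."""
    if rate <= 0:
        return spectrum
    peptide = spectrum.peptide
    extra: list[Peak] = []
    for ion in enumerate_backbone_ions(peptide):
        is_extra = ion.series == "a" or ion.loss != "none"
        if is_extra and rng.random() < rate:
            extra.append(Peak(ion.mz, float(rng.lognormal(-3.0, 1.0))))
    if not extra:
        return spectrum
    return spectrum.with_peaks(list(spectrum.peaks) + extra)


def generate_corpus(config: CorpusConfig) -> tuple[list[Spectrum], list[Spectrum]]:
    """Generate paired predicted and realified corpora.

    Both corpora share titles and peptide labels; the realified corpus is
    the predicted one passed through the noise stack plus optional extra
    ion types injected at ``config.noise.extra_ion_rate``.  Peptide
    sampling and noise consume independent seed streams, so the same seed
    yields the same peptides whatever the noise settings — corpora
    differing only in one noise toggle stay label-paired.
    """
    ss_peptide, ss_noise = np.random.SeedSequence(config.seed).spawn(2)
    rng = np.random.default_rng(ss_peptide)
    rng_noise = np.random.default_rng(ss_noise)
    predicted: list[Spectrum] = []
    realified: list[Spectrum] = []
    for i in range(config.n_spectra):
        peptide = sample_peptide(config, rng)
        pred = predict_spectrum(peptide)
        pred = replace(pred, title=f"synth|{i:06d}|{peptide.sequence}")
        real = _inject_extra_ions(pred, config.noise.extra_ion_rate, rng_noise)
        real = augment_predicted(real, config.noise, rng_noise, freqs=config.aa_model)
        predicted.append(pred)
        realified.append(real)
    return predicted, realified


def is_compatible(peptide: Peptide) -> bool:
    """Length <= 30 and no modification beyond M oxidation (C fixed mod is implicit)."""
    if len(peptide) > MAX_PEPTIDE_LENGTH:
        return False
    for pos, delta in peptide.mods:
        if peptide.sequence[pos - 1] != "M" or abs(delta - MOD_OXIDATION) > 1e-3:
            return False
    return True


def filter_compatible(corpus: Sequence[Spectrum]) -> list[Spectrum]:
    """Drop spectra whose label a b/y-only predictor could not reproduce."""
    kept = [s for s in corpus if s.peptide is not None and is_compatible(s.peptide)]
    removed = len(corpus) - len(kept)
    if removed:
        warnings.warn(f"filter_compatible removed {removed} spectra", stacklevel=2)
    return kept


# --- MGF I/O ---------------------------------------------------------------

def _encode_peptide(peptide: Peptide) -> str:
    out = []
    mods = dict(peptide.mods)
    for i, aa in enumerate(peptide.sequence, start=1):
        out.append(aa)
        if i in mods:
            out.append(f"({mods[i]:+.2f})")
    return "".join(out)


def _decode_peptide(text: str, charge: int) -> Peptide:
    mods: list[tuple[int, float]] = []
    seq: list[str] = []
    pos = 0
    while pos < len(text):
        ch = text[pos]
        if ch == "(":
            m = _MOD_RE.match(text, pos)
            if m is None:
                raise ValueError(f"malformed modification in SEQ {text!r}")
            delta = float(m.group(1))
            # snap near-oxidation deltas to the canonical value
            if abs(delta - MOD_OXIDATION) < 0.02:
                delta = MOD_OXIDATION
            mods.append((len(seq), delta))
            pos = m.end()
        else:
            seq.append(ch)
            pos += 1
    return Peptide("".join(seq), tuple(mods), precursor_charge=charge)


def write_mgf(corpus: Sequence[Spectrum], path) -> None:
    """Write a corpus as MGF; peptide labels go on a SEQ= header line."""
    entries = []
    for spec in corpus:
        params = {
            "title": spec.title,
            "pepmass": spec.precursor_mz,
            "charge": spec.precursor_charge,
        }
        if spec.peptide is not None:
            params["seq"] = _encode_peptide(spec.peptide)
        entries.append({
            "m/z array": np.array([p.mz for p in spec.peaks]),
            "intensity array": np.array([p.intensity for p in spec.peaks]),
            "params": params,
        })
    _mgf.write(entries, str(path), file_mode="w")


def read_mgf(path) -> list[Spectrum]:
    """Read an MGF file into a corpus; a missing CHARGE defaults to 2+."""
    corpus: list[Spectrum] = []
    try:
        with _mgf.read(str(path)) as reader:
            for idx, entry in enumerate(reader):
                params = entry["params"]
                title = str(params.get("title", f"spectrum_{idx}"))
                pepmass = params.get("pepmass", (0.0,))
                precursor_mz = float(pepmass[0]) if pepmass else 0.0
                charge_field = params.get("charge")
                if charge_field:
                    charge = int(charge_field[0])
                else:
                    warnings.warn(
                        f"{path}: spectrum {title!r} has no CHARGE; assuming 2+",
                        stacklevel=2,
                    )
                    charge = 2
                peaks = [
                    Peak(float(m), float(i))
                    for m, i in zip(entry["m/z array"], entry["intensity array"])
                ]
                peptide = None
                if "seq" in params:
                    peptide = _decode_peptide(str(params["seq"]), charge)
                corpus.append(Spectrum(title, precursor_mz, charge, peaks, peptide))
    except (ValueError, KeyError) as exc:
        if isinstance(exc, ValueError) and "malformed" in str(exc):
            raise
        raise ValueError(f"malformed MGF file {path}: {exc}") from exc
    return corpus
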