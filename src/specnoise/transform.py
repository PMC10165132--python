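"""Composite spectrum transforms: noise removal, replacement and augmentation.

Removal transforms operate on labelled "real-like" spectra (snap m/z to
theoretical values, replace intensities with predicted ones, strip or
shuffle non-backbone peaks, insert predicted-but-absent peaks).  The
augmentation pipeline goes the other way, degrading a clean predicted
spectrum with the parameterised noise stack.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .chemistry import Peptide, TheoreticalIon, enumerate_backbone_ions
from .matching import (
    MatchConfig,
    Peak,
    Spectrum,
    classify_spectrum,
    match_ions,
)
from .noise_models import (
    NoiseConfig,
    generate_unknown_peaks,
    missing_peak_count,
    remove_low_intensity_peaks,
    sample_jitter,
)


def _require_label(spectrum: Spectrum) -> Peptide:
    if spectrum.peptide is None:
        raise ValueError("this transform requires a peptide-labelled spectrum")
    return spectrum.peptide


def _require_same_peptide(a: Spectrum, b: Spectrum) -> Peptide:
    pa, pb = _require_label(a), _require_label(b)
    if pa.sequence != pb.sequence or pa.mods != pb.mods:
        raise ValueError(
            f"peptide labels differ: {pa.sequence!r} vs {pb.sequence!r}"
        )
    return pa


def snap_mz(spectrum: Spectrum, config: MatchConfig | None = None) -> Spectrum:
    """Reset each matched peak's m/z to its theoretical value.

    Every theoretical ion of the label (backbone and internal) is matched;
    the closest peak within tolerance takes the exact theoretical m/z.
    Unmatched peaks are unchanged.  When one peak serves several ions the
    smallest-|delta| assignment wins.
    """
    peptide = _require_label(spectrum)
    config = config or MatchConfig()
    from .chemistry import enumerate_internal_fragments

    ions: list = list(enumerate_backbone_ions(peptide))
    if len(peptide) >= config.internal_min_len + 2:
        ions += enumerate_internal_fragments(peptide, config.internal_min_len)
    records = match_ions(spectrum, ions, config.tolerance)
    # smallest |delta| per peak wins the snap
    best: dict[int, float] = {}
    for rec in sorted(records, key=lambda r: abs(r.delta)):
        best.setdefault(
            rec.peak_index,
            rec.ion.mz if isinstance(rec.ion, TheoreticalIon) else rec.ion.mass,
        )
    peaks = [
        Peak(best.get(i, p.mz), p.intensity)
        for i, p in enumerate(spectrum.peaks)
    ]
    return spectrum.with_peaks(peaks)


def _fragment_key(ion: TheoreticalIon) -> tuple[str, int, int, str]:
    return (ion.series, ion.index, ion.charge, ion.loss)


def replace_intensity(
    spectrum: Spectrum,
    predicted: Spectrum,
    config: MatchConfig | None = None,
) -> Spectrum:
    """Swap matched fragment intensities for their predicted counterparts.

    Matched peaks whose (series, index, charge) has no predicted peak keep
    their observed intensity, as do unmatched peaks.
    """
    peptide = _require_same_peptide(spectrum, predicted)
    config = config or MatchConfig()
    ions = enumerate_backbone_ions(peptide)
    predicted_intensity = {
        _fragment_key(rec.ion): predicted.peaks[rec.peak_index].intensity
        for rec in match_ions(predicted, ions, config.tolerance)
        if isinstance(rec.ion, TheoreticalIon)
    }
    new_intensity: dict[int, float] = {}
    for rec in sorted(match_ions(spectrum, ions, config.tolerance),
                      key=lambda r: abs(r.delta)):
        key = _fragment_key(rec.ion)
        if key in predicted_intensity:
            new_intensity.setdefault(rec.peak_index, predicted_intensity[key])
    peaks = [
        Peak(p.mz, new_intensity.get(i, p.intensity))
        for i, p in enumerate(spectrum.peaks)
    ]
    return spectrum.with_peaks(peaks)


def remove_non_backbone(
    spectrum: Spectrum, config: MatchConfig | None = None
) -> Spectrum:
    """Keep only peaks classified as backbone ions (1+ or 2+)."""
    _require_label(spectrum)
    summary = classify_spectrum(spectrum, config)
    keep = {
        rec.peak_index
        for cat in ("backbone_1plus", "backbone_2plus")
        for rec in summary.records[cat]
    }
    peaks = [p for i, p in enumerate(spectrum.peaks) if i in keep]
    return spectrum.with_peaks(peaks)


def _split_backbone(spectrum: Spectrum, config: MatchConfig | None):
    summary = classify_spectrum(spectrum, config)
    backbone_idx = {
        rec.peak_index
        for cat in ("backbone_1plus", "backbone_2plus")
        for rec in summary.records[cat]
    }
    backbone = [p for i, p in enumerate(spectrum.peaks) if i in backbone_idx]
    other = [p for i, p in enumerate(spectrum.peaks) if i not in backbone_idx]
    return backbone, other


def shuffle_non_backbone(
    corpus: Sequence[Spectrum],
    n_bins: int = 100,
    rng: np.random.Generator | int | None = None,
    config: MatchConfig | None = None,
) -> list[Spectrum]:
    """Permute non-backbone peak sets among spectra of similar parent mass.

    Spectra are grouped into ``n_bins`` equal-width bins over the corpus's
    precursor neutral-mass range; within each bin the non-backbone peak
    sets are permuted whole among spectra while backbone peaks stay put.
    Singleton bins are left untouched.
    """
    rng = np.random.default_rng(rng)
    masses = np.array([s.precursor_neutral_mass() for s in corpus])
    lo, hi = masses.min(), masses.max()
    width = (hi - lo) / n_bins or 1.0
    bins = np.minimum(((masses - lo) / width).astype(int), n_bins - 1)

    split = [_split_backbone(s, config) for s in corpus]
    out: list[Optional[Spectrum]] = [None] * len(corpus)
    for b in range(n_bins):
        members = np.flatnonzero(bins == b)
        if len(members) == 0:
            continue
        perm = rng.permutation(len(members)) if len(members) > 1 else [0]
        for slot, src in zip(members, members[perm]):
            backbone, _ = split[slot]
            _, other = split[src]
            out[slot] = corpus[slot].with_peaks(backbone + other)
    return [s for s in out if s is not None]


def add_predicted_missing_peaks(
    spectrum: Spectrum,
    predicted: Spectrum,
    config: MatchConfig | None = None,
) -> Spectrum:
    """Insert predicted fragment peaks that have no matched counterpart."""
    peptide = _require_same_peptide(spectrum, predicted)
    config = config or MatchConfig()
    ions = enumerate_backbone_ions(peptide)
    observed_keys = {
        _fragment_key(rec.ion)
        for rec in match_ions(spectrum, ions, config.tolerance)
        if isinstance(rec.ion, TheoreticalIon)
    }
    extra = []
    for rec in match_ions(predicted, ions, config.tolerance):
        if not isinstance(rec.ion, TheoreticalIon):
            continue
        if _fragment_key(rec.ion) not in observed_keys:
            extra.append(Peak(rec.ion.mz, predicted.peaks[rec.peak_index].intensity))
            observed_keys.add(_fragment_key(rec.ion))
    if not extra:
        return spectrum.with_peaks(spectrum.peaks)
    return spectrum.with_peaks(list(spectrum.peaks) + extra)


def apply_jitter(
    spectrum: Spectrum, model, rng: np.random.Generator | int | None = None
) -> Spectrum:
    """Add i.i.d. m/z offsets from a jitter model to every peak."""
    rng = np.random.default_rng(rng)
    offsets = sample_jitter(model, len(spectrum.peaks), rng)
    peaks = [Peak(p.mz + d, p.intensity) for p, d in zip(spectrum.peaks, offsets)]
    return spectrum.with_peaks(peaks)


def augment_predicted(
    spectrum: Spectrum,
    config: NoiseConfig,
    rng: np.random.Generator | int | None = None,
    unknown_count: Optional[int] = None,
    freqs=None,
) -> Spectrum:
    """Degrade a clean predicted spectrum with the configured noise stack.

    Steps run in order: (1) remove the ``max(l − 5, 0)`` lowest-intensity
    peaks, (2) insert unknown peaks, (3) jitter every peak — so unknown
    peaks are jittered too, as they are in observed data.  With every
    flag off this is the identity map.
    """
    peptide = _require_label(spectrum)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    else:
        rng = np.random.default_rng(rng)
    out = spectrum.with_peaks(spectrum.peaks)
    if config.missing_peaks:
        out = remove_low_intensity_peaks(out, missing_peak_count(len(peptide)))
    if config.unknown is not None:
        if unknown_count is not None:
            count = unknown_count
        elif config.unknown_count_mode == "per_spectrum":
            count = int(rng.poisson(config.unknown_count))
        else:
            count = config.unknown_count
        kwargs = {} if freqs is None else {"freqs": freqs}
        extra = generate_unknown_peaks(config.unknown, count, peptide, rng=rng, **kwargs)
        out = out.with_peaks(list(out.peaks) + extra)
    if config.jitter is not None:
        out = apply_jitter(out, config.jitter, rng)
    return out
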