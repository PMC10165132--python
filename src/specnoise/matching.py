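"""Peak-to-ion matching, per-spectrum peak classification and corpus tables.

An observed peak matches a theoretical ion when it lies within a fixed m/z
tolerance (default 0.05 Da); among several candidates the peak with the
smallest absolute mass difference wins.  Classification assigns each
observed peak to exactly one category using the priority order

    backbone 1+  >  backbone 2+  >  neutral loss  >  internal  >  unknown

so that a peak consumed by a higher-priority match is unavailable to lower
priorities and category counts partition the peak list.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .chemistry import (
    BACKBONE_ION_TYPES,
    INTERNAL_ION_TYPES,
    InternalFragment,
    Peptide,
    TheoreticalIon,
    enumerate_backbone_ions,
    enumerate_internal_fragments,
)

DEFAULT_TOLERANCE = 0.05

CATEGORIES = (
    "backbone_1plus",
    "backbone_2plus",
    "neutral_loss",
    "internal_b",
    "internal_a",
    "unknown",
)


@dataclass(frozen=True)
class Peak:
    mz: float
    intensity: float

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError("peak m/z must be positive")
        if self.intensity < 0:
            raise ValueError("peak intensity must be non-negative")


@dataclass
class Spectrum:
    """Precursor metadata plus a peak list sorted ascending by m/z."""

    title: str
    precursor_mz: float
    precursor_charge: int
    peaks: list[Peak] = field(default_factory=list)
    peptide: Optional[Peptide] = None

    def __post_init__(self) -> None:
        dedup: dict[float, Peak] = {}
        for p in sorted(self.peaks, key=lambda p: p.mz):
            dedup[p.mz] = p  # exact m/z ties collapse, last wins
        self.peaks = list(dedup.values())

    @property
    def mz_array(self) -> np.ndarray:
        return np.array([p.mz for p in self.peaks])

    @property
    def intensity_array(self) -> np.ndarray:
        return np.array([p.intensity for p in self.peaks])

    def precursor_neutral_mass(self) -> float:
        from .chemistry import PROTON

        z = self.precursor_charge
        return self.precursor_mz * z - z * PROTON

    def with_peaks(self, peaks: Iterable[Peak]) -> "Spectrum":
        return Spectrum(self.title, self.precursor_mz, self.precursor_charge,
                        list(peaks), self.peptide)


@dataclass(frozen=True)
class MatchRecord:
    """Pairing of a theoretical ion with an observed peak."""

    ion: Union[TheoreticalIon, InternalFragment]
    peak_index: int
    delta: float  # observed − theoretical, Da

    @property
    def ion_type(self) -> str:
        if isinstance(self.ion, TheoreticalIon):
            return self.ion.ion_type
        return self.ion.type_label


@dataclass
class MatchConfig:
    """Knobs shared by the classification and accounting routines."""

    tolerance: float = DEFAULT_TOLERANCE
    internal_min_len: int = 1

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")


@dataclass
class ClassificationSummary:
    """Per-category peak counts for one spectrum (or totals over a corpus)."""

    category_counts: dict[str, int]
    total_peaks: int
    records: dict[str, list[MatchRecord]] = field(default_factory=dict)

    @property
    def fractions(self) -> dict[str, float]:
        if self.total_peaks == 0:
            return {c: 0.0 for c in self.category_counts}
        return {c: n / self.total_peaks for c, n in self.category_counts.items()}


def _ion_mz(ion: Union[TheoreticalIon, InternalFragment]) -> float:
    return ion.mz if isinstance(ion, TheoreticalIon) else ion.mass


def match_ions(
    spectrum: Spectrum,
    ions: Sequence[Union[TheoreticalIon, InternalFragment]],
    tolerance: float = DEFAULT_TOLERANCE,
) -> list[MatchRecord]:
    """Match each theoretical ion to its closest observed peak within tolerance.

    Each ion yields at most one record; ions with no peak within the
    tolerance yield none.  A single observed peak may serve several ions
    here — exclusive consumption is the classifier's job.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    mzs = [p.mz for p in spectrum.peaks]
    records: list[MatchRecord] = []
    for ion in ions:
        target = _ion_mz(ion)
        j = bisect.bisect_left(mzs, target)
        best = None
        for k in (j - 1, j):
            if 0 <= k < len(mzs):
                d = mzs[k] - target
                if abs(d) <= tolerance and (best is None or abs(d) < abs(best[1])):
                    best = (k, d)
        if best is not None:
            records.append(MatchRecord(ion, best[0], best[1]))
    return records


def _greedy_consume(
    records: list[MatchRecord], available: set[int]
) -> list[MatchRecord]:
    """Resolve one-peak-to-many-ions conflicts greedily by ascending |delta|."""
    kept: list[MatchRecord] = []
    for rec in sorted(records, key=lambda r: abs(r.delta)):
        if rec.peak_index in available:
            available.discard(rec.peak_index)
            kept.append(rec)
    return kept


def _category_ions(peptide: Peptide, internal_min_len: int):
    backbone = enumerate_backbone_ions(peptide)
    by_cat: dict[str, list] = {c: [] for c in CATEGORIES[:-1]}
    for ion in backbone:
        if ion.charge == 1 and ion.loss == "none":
            by_cat["backbone_1plus"].append(ion)
        elif ion.charge == 2:
            by_cat["backbone_2plus"].append(ion)
        else:
            by_cat["neutral_loss"].append(ion)
    if len(peptide) >= internal_min_len + 2:
        for frag in enumerate_internal_fragments(peptide, internal_min_len):
            cat = "internal_b" if frag.ion_type == "b" else "internal_a"
            by_cat[cat].append(frag)
    return by_cat


def classify_spectrum(
    spectrum: Spectrum, config: MatchConfig | None = None
) -> ClassificationSummary:
    """Assign every observed peak to exactly one ion category.

    Categories are matched in priority order; each pass may only consume
    peaks not already claimed by a higher-priority pass.
    """
    if spectrum.peptide is None:
        raise ValueError("classify_spectrum requires a peptide-labelled spectrum")
    config = config or MatchConfig()
    by_cat = _category_ions(spectrum.peptide, config.internal_min_len)

    available = set(range(len(spectrum.peaks)))
    counts: dict[str, int] = {}
    kept_records: dict[str, list[MatchRecord]] = {}
    for cat in CATEGORIES[:-1]:
        recs = match_ions(spectrum, by_cat[cat], config.tolerance)
        recs = [r for r in recs if r.peak_index in available]
        recs = _greedy_consume(recs, available)
        counts[cat] = len(recs)
        kept_records[cat] = recs
    counts["unknown"] = len(available)
    kept_records["unknown"] = []
    return ClassificationSummary(counts, len(spectrum.peaks), kept_records)


def presence_profile(
    corpus: Sequence[Spectrum],
    peptide_length: int,
    config: MatchConfig | None = None,
) -> pd.DataFrame:
    """Fraction of length-L spectra in which each backbone ion matched a peak.

    Returns a DataFrame indexed by ion number 1..L−1 with one column per
    backbone ion type.
    """
    config = config or MatchConfig()
    subset = [s for s in corpus
              if s.peptide is not None and len(s.peptide) == peptide_length]
    if not subset:
        raise ValueError(f"no labelled spectra of peptide length {peptide_length}")
    L = peptide_length
    hits = pd.DataFrame(
        0.0, index=range(1, L), columns=list(BACKBONE_ION_TYPES)
    )
    for spec in subset:
        ions = enumerate_backbone_ions(spec.peptide)
        for rec in match_ions(spec, ions, config.tolerance):
            hits.loc[rec.ion.index, rec.ion_type] += 1
    hits /= len(subset)
    hits.index.name = "ion_number"
    return hits


def _count_by_type(records: Iterable[MatchRecord]) -> dict[str, int]:
    out: dict[str, int] = {}
    for rec in records:
        out[rec.ion_type] = out.get(rec.ion_type, 0) + 1
    return out


def annotate_spectrum(
    spectrum: Spectrum, config: MatchConfig | None = None
) -> tuple[dict[str, int], dict[str, int]]:
    """Per-ion-type (possible, matched) counts for one labelled spectrum.

    Types are counted independently (an observed peak may serve several
    types), mirroring per-type accounting rather than the exclusive
    classification scheme.
    """
    if spectrum.peptide is None:
        raise ValueError("annotate_spectrum requires a peptide-labelled spectrum")
    config = config or MatchConfig()
    ions: list = list(enumerate_backbone_ions(spectrum.peptide))
    if len(spectrum.peptide) >= config.internal_min_len + 2:
        ions += enumerate_internal_fragments(spectrum.peptide, config.internal_min_len)
    possible: dict[str, int] = {}
    for ion in ions:
        t = ion.ion_type if isinstance(ion, TheoreticalIon) else ion.type_label
        possible[t] = possible.get(t, 0) + 1
    matched = _count_by_type(match_ions(spectrum, ions, config.tolerance))
    return possible, matched


def summarize_corpus(
    corpus: Sequence[Spectrum],
    random_matches: dict[str, int] | None = None,
    config: MatchConfig | None = None,
) -> pd.DataFrame:
    """Corpus-level per-ion-type accounting table.

    Columns: possible, matched, fraction_matched, random_matched and
    random_over_matched (NaN where matched is zero).  ``random_matches``
    is typically the output of :func:`specnoise.decoy_null.estimate_spurious_matches`
    computed with the same tolerance.
    """
    config = config or MatchConfig()
    all_types = list(BACKBONE_ION_TYPES) + list(INTERNAL_ION_TYPES)
    possible = dict.fromkeys(all_types, 0)
    matched = dict.fromkeys(all_types, 0)
    for spec in corpus:
        p, m = annotate_spectrum(spec, config)
        for t, n in p.items():
            possible[t] += n
        for t, n in m.items():
            matched[t] += n
    random_matches = random_matches or {}
    rows = []
    for t in all_types:
        n_pos, n_match = possible[t], matched[t]
        n_rand = random_matches.get(t, 0)
        rows.append({
            "ion_type": t,
            "possible": n_pos,
            "matched": n_match,
            "fraction_matched": n_match / n_pos if n_pos else np.nan,
            "random_matched": n_rand,
            "random_over_matched": n_rand / n_match if n_match else np.nan,
        })
    return pd.DataFrame(rows).set_index("ion_type")
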