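"""Parametric models for the four noise types seen in real tandem-MS spectra.

* m/z jitter — measurement error around the theoretical fragment m/z,
  modelled either as a 1:1 mixture of two zero-mean normals (sd 1e-2 and
  1e-3) or as a 12:1 mixture of a Laplace (scale 2.5e-3) and a uniform on
  [−0.05, 0.05].
* missing peaks — the n lowest-intensity predicted peaks are removed,
  with n = max(l − 5, 0) for a length-l peptide.
* unknown peaks — extra singly charged peaks whose m/z comes either from
  random amino-acid combinations, from the assigned peptide's internal
  fragments, or a mixture of both.
* unknown-peak intensity — log-normal with ln-mean −4.4 and ln-sd 1.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .chemistry import Peptide, enumerate_internal_fragments
from .decoy_null import DEFAULT_AA_MODEL, AAFrequencyModel
from .matching import Peak, Spectrum


@dataclass(frozen=True)
class JitterModel:
    """Mixture model for m/z measurement error.

    Method 1: equal-weight mixture of Normal(0, 1e-2) and Normal(0, 1e-3).
    Method 2: Laplace(0, 2.5e-3) and Uniform(−0.05, 0.05) mixed 12:1.
    """

    method: int = 2
    normal_sds: tuple[float, float] = (1e-2, 1e-3)
    normal_weights: tuple[float, float] = (1.0, 1.0)
    laplace_scale: float = 2.5e-3
    uniform_bound: float = 0.05
    laplace_uniform_weights: tuple[float, float] = (12.0, 1.0)

    def __post_init__(self) -> None:
        if self.method not in (1, 2):
            raise ValueError("jitter method must be 1 or 2")
        for w in (*self.normal_weights, *self.laplace_uniform_weights):
            if w <= 0:
                raise ValueError("mixture weights must be positive")

    def variance(self) -> float:
        """Closed-form variance of the configured mixture."""
        if self.method == 1:
            w = np.asarray(self.normal_weights, dtype=float)
            w = w / w.sum()
            sds = np.asarray(self.normal_sds)
            return float(np.sum(w * sds**2))
        w = np.asarray(self.laplace_uniform_weights, dtype=float)
        w = w / w.sum()
        var_laplace = 2 * self.laplace_scale**2
        var_uniform = (2 * self.uniform_bound) ** 2 / 12
        return float(w[0] * var_laplace + w[1] * var_uniform)


def sample_jitter(
    model: JitterModel, n: int, rng: np.random.Generator | int | None = None
) -> np.ndarray:
    """Draw n i.i.d. m/z offsets (Da) from the configured mixture."""
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(rng)
    if n == 0:
        return np.empty(0)
    if model.method == 1:
        w = np.asarray(model.normal_weights, dtype=float)
        w = w / w.sum()
        comp = rng.choice(2, size=n, p=w)
        sds = np.asarray(model.normal_sds)
        return rng.normal(0.0, 1.0, size=n) * sds[comp]
    w = np.asarray(model.laplace_uniform_weights, dtype=float)
    w = w / w.sum()
    comp = rng.choice(2, size=n, p=w)
    out = np.where(
        comp == 0,
        rng.laplace(0.0, model.laplace_scale, size=n),
        rng.uniform(-model.uniform_bound, model.uniform_bound, size=n),
    )
    return out


def missing_peak_count(peptide_length: int) -> int:
    """Number of low-intensity peaks to remove: n = max(l − 5, 0)."""
    if peptide_length < 1:
        raise ValueError("peptide length must be >= 1")
    return max(peptide_length - 5, 0)


def remove_low_intensity_peaks(spectrum: Spectrum, n: int) -> Spectrum:
    """Delete the n lowest-intensity peaks (ties broken by lower m/z first)."""
    if n < 0:
        raise ValueError("n must be >= 0")
    if n == 0:
        return spectrum.with_peaks(spectrum.peaks)
    order = sorted(range(len(spectrum.peaks)),
                   key=lambda i: (spectrum.peaks[i].intensity, spectrum.peaks[i].mz))
    drop = set(order[:n])
    kept = [p for i, p in enumerate(spectrum.peaks) if i not in drop]
    return spectrum.with_peaks(kept)


@dataclass(frozen=True)
class UnknownPeakModel:
    """Generator of extra singly charged peaks of non-fragment origin.

    m/z values are neutral masses taken directly as m/z (no protonation),
    matching how chemical-background ions were modelled.  Intensities are
    log-normal: ln(I) ~ Normal(−4.4, 1.5).
    """

    method: str = "combined"            # random_aa | internal_fragments | combined
    log_mean: float = -4.4
    log_sd: float = 1.5
    internal_fraction: float = 0.27     # share of internal-fragment peaks in 'combined'
    random_aa_min: int = 2              # residues per random combination
    random_aa_max: int = 9
    internal_min_len: int = 1

    def __post_init__(self) -> None:
        if self.method not in ("random_aa", "internal_fragments", "combined"):
            raise ValueError(f"unknown-peak method {self.method!r}")
        if not 0 <= self.internal_fraction <= 1:
            raise ValueError("internal_fraction must be in [0, 1]")
        if not 1 <= self.random_aa_min <= self.random_aa_max:
            raise ValueError("need 1 <= random_aa_min <= random_aa_max")


def sample_unknown_intensities(
    model: UnknownPeakModel, n: int, rng: np.random.Generator | int | None = None
) -> np.ndarray:
    """Draw n log-normal intensities: ln(I) ~ Normal(log_mean, log_sd)."""
    rng = np.random.default_rng(rng)
    return rng.lognormal(model.log_mean, model.log_sd, size=n)


def _random_aa_masses(
    count: int,
    model: UnknownPeakModel,
    freqs: AAFrequencyModel,
    rng: np.random.Generator,
) -> np.ndarray:
    from .chemistry import RESIDUE_MASSES

    aas, probs = freqs.as_arrays()
    masses = np.array([RESIDUE_MASSES[a] for a in aas])
    sizes = rng.integers(model.random_aa_min, model.random_aa_max + 1, size=count)
    out = np.empty(count)
    for i, k in enumerate(sizes):
        out[i] = masses[rng.choice(len(aas), size=k, p=probs)].sum()
    return out


def _internal_masses(
    count: int, model: UnknownPeakModel, peptide: Peptide, rng: np.random.Generator
) -> np.ndarray:
    pool = np.array([
        f.mass for f in enumerate_internal_fragments(peptide, model.internal_min_len)
    ])
    if count <= len(pool):
        return rng.choice(pool, size=count, replace=False)
    return rng.choice(pool, size=count, replace=True)


def generate_unknown_peaks(
    model: UnknownPeakModel,
    count: int,
    peptide: Optional[Peptide] = None,
    freqs: AAFrequencyModel = DEFAULT_AA_MODEL,
    rng: np.random.Generator | int | None = None,
) -> list[Peak]:
    """Generate ``count`` unknown peaks per the configured method.

    ``internal_fragments`` and ``combined`` need a labelled peptide of
    length >= internal_min_len + 2 to provide the internal-fragment pool.
    """
    if count < 0:
        raise ValueError("count must be >= 0")
    if count == 0:
        return []
    rng = np.random.default_rng(rng)
    needs_internal = model.method in ("internal_fragments", "combined")
    if needs_internal:
        if peptide is None:
            raise ValueError(f"method {model.method!r} requires a peptide")
        if len(peptide) < model.internal_min_len + 2:
            raise ValueError(
                f"peptide of length {len(peptide)} has no internal fragments "
                f"of length >= {model.internal_min_len}"
            )
    if model.method == "random_aa":
        mzs = _random_aa_masses(count, model, freqs, rng)
    elif model.method == "internal_fragments":
        mzs = _internal_masses(count, model, peptide, rng)
    else:
        n_internal = int(round(model.internal_fraction * count))
        mzs = np.concatenate([
            _internal_masses(n_internal, model, peptide, rng),
            _random_aa_masses(count - n_internal, model, freqs, rng),
        ])
    intensities = sample_unknown_intensities(model, count, rng)
    return [Peak(float(m), float(i)) for m, i in zip(mzs, intensities)]


@dataclass
class NoiseConfig:
    """Full parameterisation of the noise stack applied to predicted spectra.

    ``unknown_count_mode`` is one of 'fixed' (always ``unknown_count``
    peaks), 'per_spectrum' (Poisson around ``unknown_count``) or
    'matched_to_real' (caller supplies the count explicitly, as when a
    paired real spectrum defines it).
    """

    jitter: Optional[JitterModel] = None
    missing_peaks: bool = False
    unknown: Optional[UnknownPeakModel] = None
    unknown_count: int = 0
    unknown_count_mode: str = "fixed"
    extra_ion_rate: float = 0.0   # rate of injecting a-ions / neutral losses
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.unknown_count_mode not in ("fixed", "per_spectrum", "matched_to_real"):
            raise ValueError(f"unknown_count_mode {self.unknown_count_mode!r}")
        if self.unknown_count < 0:
            raise ValueError("unknown_count must be >= 0")
        if not 0 <= self.extra_ion_rate <= 1:
            raise ValueError("extra_ion_rate must be in [0, 1]")

    @classmethod
    def from_dict(cls, d: dict) -> "NoiseConfig":
        """Build from a (TOML/YAML-style) nested mapping; unknown keys error."""
        d = dict(d)
        bad = set(d) - {"jitter", "missing", "unknown", "extra_ion_rate", "seed"}
        if bad:
            raise ValueError(f"unknown noise-config keys: {sorted(bad)}")
        jitter = None
        if "jitter" in d and d["jitter"].get("enabled", True):
            jd = {k: v for k, v in d["jitter"].items() if k != "enabled"}
            jitter = JitterModel(**jd)
        missing = bool(d.get("missing", {}).get("enabled", False))
        unknown = None
        count = 0
        mode = "fixed"
        if "unknown" in d and d["unknown"].get("enabled", True):
            ud = dict(d["unknown"])
            ud.pop("enabled", None)
            count = ud.pop("count", 0)
            mode = ud.pop("count_mode", "fixed")
            unknown = UnknownPeakModel(**ud)
        return cls(jitter=jitter, missing_peaks=missing, unknown=unknown,
                   unknown_count=count, unknown_count_mode=mode,
                   extra_ion_rate=float(d.get("extra_ion_rate", 0.0)),
                   seed=d.get("seed"))

    @classmethod
    def all_off(cls) -> "NoiseConfig":
        return cls()
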