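"""Error-distribution statistics and mass-defect analysis of unknown peaks.

The mass-defect tools exploit the fact that biomolecular ions sit close to
integer multiples of an element-composition-specific mass per nucleon: for
peptide-like material (mostly H, C, N, O, S in their typical residue
ratios) that constant is ~1.0005 Da per nucleon, so plotting m/z against
m/z modulo 1 shows unknown chemical-background peaks collapsing onto
streaks of that slope — the signature of co-eluting peptide fragments
rather than electrical noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize

from .matching import DEFAULT_TOLERANCE, MatchRecord

# Monoisotopic masses and nucleon (mass) numbers of the biologically
# dominant elements.
ELEMENT_MASSES = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.99491461956,
    "S": 31.972071,
}
ELEMENT_NUCLEONS = {"H": 1, "C": 12, "N": 14, "O": 16, "S": 32}


@dataclass(frozen=True)
class ElementRatios:
    """Mean atom counts per residue for H, C, N, O, S."""

    H: float
    C: float
    N: float
    O: float
    S: float

    def __post_init__(self) -> None:
        vals = (self.H, self.C, self.N, self.O, self.S)
        if any(v < 0 for v in vals):
            raise ValueError("element ratios must be non-negative")
        if not any(v > 0 for v in vals):
            raise ValueError("at least one element ratio must be positive")

    def as_dict(self) -> dict[str, float]:
        return {"H": self.H, "C": self.C, "N": self.N, "O": self.O, "S": self.S}


#: Averagine-style mean elemental composition of a peptide residue.  An
#: approximation to dataset-derived ratios, adequate for the mass-per-
#: nucleon constant to four decimals.
AVERAGINE_RATIOS = ElementRatios(H=7.7583, C=4.9384, N=1.3577, O=1.4773, S=0.0417)


def error_stats(
    records: Sequence[MatchRecord] | Sequence[float],
    tolerance: float = DEFAULT_TOLERANCE,
    bins: int = 50,
) -> dict:
    """Mean squared error, signed mean and histogram of match m/z deltas.

    Accepts MatchRecords or raw delta values.  The histogram spans
    [−tolerance, +tolerance] with fixed-width bins.
    """
    if len(records) == 0:
        raise ValueError("error_stats requires at least one match record")
    deltas = np.array([
        r.delta if isinstance(r, MatchRecord) else float(r) for r in records
    ])
    counts, edges = np.histogram(deltas, bins=bins, range=(-tolerance, tolerance))
    return {
        "mse": float(np.mean(deltas**2)),
        "mean": float(np.mean(deltas)),
        "n": len(deltas),
        "histogram": (counts, edges),
    }


def mod1_coordinates(mzs: Sequence[float]) -> list[tuple[float, float]]:
    """Pairs (m/z, m/z mod 1); the second coordinate lies in [0, 1)."""
    arr = np.asarray(mzs, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("m/z values must be positive")
    return [(float(m), float(m % 1.0)) for m in arr]


def mass_per_nucleon(ratios: ElementRatios = AVERAGINE_RATIOS) -> float:
    """Average monoisotopic mass per nucleon of the given composition.

    Σ(ratio·element mass) / Σ(ratio·element nucleon count); scale-invariant
    in the ratios.  Peptide-like compositions give ~1.0005 Da/nucleon.
    """
    d = ratios.as_dict()
    mass = sum(r * ELEMENT_MASSES[e] for e, r in d.items())
    nucleons = sum(r * ELEMENT_NUCLEONS[e] for e, r in d.items())
    return mass / nucleons


def fit_defect_slope(
    mzs: Sequence[float], charge: int = 1, init_slope: float = 1.0005
) -> float:
    """Estimate the Da-per-nucleon slope of one mass-defect streak.

    Each m/z is unwrapped to an integer nucleon count
    ``k = round(z·mz / s)``; the slope minimising Σ(z·mz − s·k)² is then
    ``s = Σ(z·mz·k)/Σk²``.  Because a slope error Δs misrounds k once
    ``Δs·k > 0.5``, unwrapping proceeds progressively: the fit starts on
    the low-mass points (where k is unambiguous for any plausible initial
    slope), then doubles the mass cutoff and refits until all points are
    included, with a final fixed-point refinement.  Points must come from
    a single charge streak.
    """
    arr = np.sort(np.asarray(mzs, dtype=float)) * charge
    if arr.size < 10:
        raise ValueError("need at least 10 points to fit a streak slope")
    if np.ptp(arr) == 0:
        raise ValueError("degenerate input: all m/z values identical")

    def refit(subset: np.ndarray, s: float) -> float:
        k = np.round(subset / s)
        k[k == 0] = 1  # guard: sub-dalton m/z cannot define a count
        return float(np.sum(subset * k) / np.sum(k**2))

    slope = init_slope
    cutoff = max(arr[0] * 2, 400.0)
    while True:
        subset = arr[arr <= cutoff]
        if subset.size >= 10:
            slope = refit(subset, slope)
        if cutoff >= arr[-1]:
            break
        cutoff *= 2
    for _ in range(3):
        slope = refit(arr, slope)
    return slope


def fit_jitter_mixture(
    deltas: Sequence[float],
    uniform_bound: float = 0.05,
    init_scale: float = 2.5e-3,
) -> dict[str, float]:
    """MLE of the Laplace+uniform jitter mixture from matched m/z errors.

    Fits ``w·Laplace(0, b) + (1−w)·Uniform(−u, u)`` by maximising the
    log-likelihood over (b, w) with the uniform bound fixed.  The plain
    mean-|x| estimator is biased upward by the uniform component, so the
    mixture fit is needed to recover the Laplace scale from matched peaks.
    """
    x = np.abs(np.asarray(deltas, dtype=float))

    def nll(params):
        log_b, logit_w = params
        b = np.exp(log_b)
        w = 1.0 / (1.0 + np.exp(-logit_w))
        lik = w * np.exp(-x / b) / (2 * b) + (1 - w) / (2 * uniform_bound)
        return -np.sum(np.log(lik))

    res = optimize.minimize(
        nll, x0=[np.log(init_scale), np.log(12.0)], method="Nelder-Mead"
    )
    b = float(np.exp(res.x[0]))
    w = float(1.0 / (1.0 + np.exp(-res.x[1])))
    return {"laplace_scale": b, "laplace_weight": w, "converged": bool(res.success)}
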