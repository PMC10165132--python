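# Methods

## Scope and model

The package treats a labelled MS/MS spectrum as a peak list plus an
assigned peptide and asks, peak by peak, what the peptide can account for
and what statistical structure the remainder carries. Everything is built
around four parametric noise models that map between clean predicted
spectra (b/y ions only, exact m/z, deterministic intensities) and
real-looking spectra, together with the accounting machinery needed to
measure each noise type on labelled data.

## Mass arithmetic and fragment enumeration

Monoisotopic masses throughout, taken from the pyteomics tables: proton
1.007276 Da, H atom 1.007825 Da, H₂O 18.010565 Da, NH₃ 17.026549 Da, CO
27.994915 Da. The high-resolution setting (0.05 Da matching tolerance)
makes average masses inappropriate.

Backbone fragments: for cleavage ordinal i ∈ [1, L−1], b_i is the
N-terminal prefix (neutral mass = residue sum), y_i the C-terminal suffix
(+ H₂O), a_i = b_i − CO; m/z = (neutral + z·proton)/z for z ∈ {1, 2}.
Twelve ion types are enumerated: a/b/y at 1+, their −H₂O and −NH₃
variants at 1+, and a/b/y at 2+. Water loss is emitted only for y ions
(which contain the C-terminus) or fragments containing D/E/S/T; ammonia
loss only for fragments containing R/K/Q/N. b₁ ions are enumerated — they
are rare in spectra but belong in the possible-ion accounting — and
doubly charged fragments are enumerated regardless of precursor charge.

Internal fragments are the contiguous spans of positions 2..L−1.
b-type internal mass = residue sum + one H **atom** (not a proton), taken
directly as the singly charged m/z; a-type = b-type − CO. The per-type
count for length L and minimum span k is the triangular number
T(L−1−k) = (L−1−k)(L−k)/2 — 28 for L = 10, k = 2, against 9 backbone
fragments per ion type at the same length. The default minimum span is 1
(single-residue internal fragments are real and frequent); the
28-counting convention uses 2. Both are exposed as a parameter.

Modifications: carbamidomethylation (+57.02146 Da) is fixed and applied
implicitly to every cysteine; oxidation of methionine (+15.99491 Da) is
the only variable modification, carried per position. The compatibility
filter drops peptides longer than 30 residues or carrying anything else,
matching what b/y intensity predictors accept.

## Matching and classification

An observed peak matches a theoretical ion when |observed − theoretical|
≤ 0.05 Da (the default; the loosest fragment tolerance across the
instruments this kind of data comes from), and among candidates the
smallest |Δ| wins. The converse conflict — one observed peak wanted by
several ions — is resolved greedily in ascending |Δ| within each
category pass, so each peak is consumed once and category counts
partition the peak list. The category priority (backbone 1+ > backbone
2+ > neutral loss > internal b > internal a > unknown) reflects the
relative reliability of each assignment; it is a convention, and the
per-ion-type accounting table deliberately does *not* use it (types are
counted independently there, so one peak may serve several types — both
views are useful and both are provided).

## Random-peptide null

For each spectrum one decoy tryptic peptide of the same length is drawn:
non-terminal residues i.i.d. from an amino-acid frequency model, final
residue R if the true peptide ends in K and vice versa (uniform over
{R, K} for non-tryptic labels). The terminus swap guarantees every y-ion
mass differs from the true ladder. Matching the decoy's full theoretical
ion set against the observed peaks estimates the chance-match count per
ion type. Decoy draws are seeded per spectrum from a hash of its title
and sequence, so the null is invariant to corpus order. The default
frequency model is the Swiss-Prot average protein composition;
`estimate_aa_frequencies` derives a corpus-specific model when the decoys
should mirror a particular dataset.

## Noise models

* **Jitter.** Method 1: 1:1 mixture of N(0, 1e-2²) and N(0, 1e-3²)
  (mixture variance 5.05e-5 Da²). Method 2: 12:1 mixture of
  Laplace(0, 2.5e-3) and Uniform(−0.05, 0.05). Both are symmetric about
  zero. Jitter is additive on the theoretical m/z.
* **Missing peaks.** n = max(l − 5, 0) peaks removed, lowest intensity
  first; intensity ties break toward lower m/z (a choice the data cannot
  dictate — removal order among equal intensities is unobservable).
* **Unknown peaks.** Singly charged, m/z equal to the neutral mass.
  `random_aa` sums 2–9 residues drawn from the frequency model (the
  span covers the observed fragment m/z range; configurable);
  `internal_fragments` samples without replacement from the label's
  internal-fragment masses (with replacement once the pool is
  exhausted); `combined` mixes the two with a default internal fraction
  of 0.27, an estimate of the internal share of non-backbone peaks and
  explicitly configurable.
* **Unknown-peak intensity.** ln(I) ~ N(−4.4, 1.5²).

The augmentation pipeline applies, per config flag: removal → unknown
peaks → jitter. The order matters only for jitter, which is applied last
so that injected unknown peaks are jittered too — in real data they are
observed peaks like any other. The order is configurable by composing
the individual transforms directly. With every flag off the pipeline is
the identity map.

## Removal transforms

`snap_mz` resets each matched peak to its theoretical m/z (smallest-|Δ|
ion per peak); `replace_intensity` swaps matched fragment intensities
for their predicted counterparts, keeping the observed value where no
prediction exists; `remove_non_backbone` keeps only backbone-classified
peaks; `add_predicted_missing_peaks` inserts predicted fragments absent
from the observed spectrum; `shuffle_non_backbone` permutes whole
non-backbone peak sets among spectra within 100 equal-width precursor-
neutral-mass bins (the bin *count* is the stated constant; the ~25 Da
width reported for one corpus is a property of that corpus's mass range).

## Mass-defect diagnostics

Biomolecules are built from few elements, so their monoisotopic mass is
close to (mass-per-nucleon)·(nucleon count). For the mean peptide-residue
composition (averagine-style H 7.7583, C 4.9384, N 1.3577, O 1.4773,
S 0.0417) the constant is Σ(rᵢmᵢ)/Σ(rᵢAᵢ) = 1.0005 Da per nucleon —
scale-invariant in the ratios, and an approximation: the exact value for
a given corpus depends on its residue composition, but agrees to four
decimals for protein-like material. Unknown peaks that fall on streaks of
this slope in the m/z vs (m/z mod 1) plane are therefore peptide-derived
chemical background, not electrical noise.

The streak slope estimator unwraps each m/z to an integer nucleon count
k = round(z·mz/s) and solves the least-squares slope s = Σ(z·mz·k)/Σk².
Because a slope error Δs misrounds k once Δs·k > 0.5, fitting starts on
the low-mass points, doubles the mass cutoff while refitting, and
finishes with a fixed-point refinement — this recovers slopes anywhere
near 1 (e.g. exactly 1.0) from the default initial guess of 1.0005,
which a single global rounding pass cannot.

The Laplace jitter scale is recovered from matched-peak errors by
maximum likelihood on the two-component mixture (Laplace + uniform with
the bound fixed at the matching tolerance), because the naive mean-|Δ|
estimator is biased upward by the uniform component (~0.0042 vs 0.0025
at the 12:1 weights).

## De novo metrics

Prediction and truth are compared position by position: residue i is
matched iff its residue mass (modifications included) is within 0.1 Da
of the true residue's and the preceding i−1 residues' cumulative masses
agree within 0.5 Da. Leu/Ile (identical mass) and Lys/Gln (Δ 0.036 Da)
therefore count as matched — a property of the mass-based rule, kept
deliberately. Positional alignment with the i−1 prefix gate is the
literal reading of the metric; lineage implementations that align by
prefix-mass proximity can differ on pathological cases. A peptide is
"correct" iff lengths are equal and every position matches — the
strictest reading consistent with the per-residue rule. Amino-acid
precision = matched/predicted, recall = matched/actual, peptide recall =
correct/total spectra; with no predictions the precision is reported as
0 with an explicit `precision_defined=False` flag.

## Synthetic corpus generator

Defaults: lengths 7–25 drawn from a truncated geometric with median 10
(short tryptic peptides dominate real digests; 30 is the hard cap),
residues from the Swiss-Prot average composition with a forced R/K
C-terminus, precursor charges {2: 0.65, 3: 0.35}, oxidation probability
0.05 per methionine. The intensity predictor is a smooth deterministic
function of series, relative cleavage position and the flanking residues
(y decays from y₁, b rises from a weak b₁ to a maximum near b₂–b₃ then
decays; 2+ ions at a quarter of the 1+ intensity; maximum normalised
to 1). **It is a surrogate, not a model of fragmentation chemistry**: it
exists so that every transform, accounting table and metric can be
exercised on data with known ground truth. Peptide sampling and noise
consume independent seed streams, so corpora generated with the same
seed but different noise settings are label-paired — the basis for the
toggle-one-noise-type comparisons in the tests.

What passing tests show: the accounting, null-model, transform and
diagnostic machinery is self-consistent on data whose generating process
is known exactly. What they do not show: that the noise parameters fit
any particular instrument, that the surrogate intensities resemble a
learned predictor's, or that conclusions about model training transfer —
real spectra carry correlated noise structure (co-elution, isotope
envelopes, charge-state crosstalk) that the generator deliberately
omits.

## Numerical and design choices

* Exact m/z ties within a spectrum are deduplicated on construction;
  peaks are always kept sorted ascending.
* Matching uses bisection on the sorted peak list; tolerance boundaries
  are inclusive.
* `fit_defect_slope` requires ≥ 10 points and a non-degenerate spread;
  all-equal inputs are rejected rather than returning a spurious slope.
* Accounting ratios with a zero denominator are reported as NaN, never
  raised.
* MGF dialect: `SEQ=` carries the label, mods inline as `M(+15.99)`
  (snapped to the canonical oxidation delta on read), `CHARGE=2+`;
  a missing CHARGE defaults to 2+ with a warning.
* Test problem sizes: property suites run on corpora of 30–1000 spectra
  and Monte Carlo checks at 10⁵–10⁶ draws, sizes at which the checked
  statistics are comfortably inside their asymptotic regimes.

## Known limitations

* The unknown-peak count in real data equals the count observed per
  spectrum; without paired real data it must come from configuration
  (fixed or Poisson per spectrum), which flattens the count's true
  dependence on precursor mass and abundance.
* The internal fraction (0.27) of the combined unknown-peak model is an
  estimate, not a measured constant.
* Charge ≥ 3 fragments, isotope envelopes, immonium ions and c/x/z ions
  are out of scope; the classifier files such peaks under "unknown".
* The element-ratio default is averagine-style; corpus-specific ratios
  shift the mass-per-nucleon constant in the fifth decimal.
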