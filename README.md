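# specnoise

Tools for dissecting what separates **real HCD peptide tandem-MS spectra**
from the clean, deterministic spectra produced by fragment-intensity
predictors — aimed at people building or evaluating de novo peptide
sequencing models who need realistic artificial training and test data.

A labelled spectrum (a PSM) is a peak list `{(m/z, intensity)}` plus the
peptide assigned to it. Predicted spectra contain only b/y backbone ions at
exact theoretical positions; real spectra differ in four ways, each of
which this package models, measures, removes and re-introduces:

* **m/z jitter** — measurement error around the theoretical fragment m/z.
  Two parametric models: a 1:1 mixture of N(0, 1e-2²) and N(0, 1e-3²), or a
  12:1 mixture of Laplace(0, 2.5e-3) and Uniform(−0.05, 0.05).
* **Missing peaks** — for a length-*l* peptide, the *n* = max(*l* − 5, 0)
  lowest-intensity predicted peaks are absent.
* **Unknown peaks** — the majority of real peaks match no fragment of the
  assigned peptide. They are modelled as singly charged residue-mass sums:
  random amino-acid combinations, internal fragments of the assigned
  peptide, or a mixture.
* **Unknown-peak intensity** — log-normal, ln(I) ~ N(−4.4, 1.5²).

Around these sit the supporting machinery: enumeration of the 12 backbone
ion types (a/b/y, ±H₂O, ±NH₃, 1+/2+) and a/b internal fragments with the
standard eligibility rules; peak matching at 0.05 Da with exclusive
priority classification (backbone 1+ > backbone 2+ > neutral loss >
internal > unknown); a random-tryptic-peptide null that estimates how many
matches arise by chance; mass-defect diagnostics (peptide-like ions fall on
streaks of slope ≈ 1.0005 Da per nucleon in an m/z vs m/z mod 1 plot);
mass-gated amino-acid precision/recall and peptide recall for de novo
output; and a synthetic corpus generator that pairs each clean predicted
spectrum with a noise-degraded twin.

## Worked example

```python
from specnoise import (CorpusConfig, JitterModel, NoiseConfig, UnknownPeakModel,
                       classify_spectrum, generate_corpus)
from specnoise.decoy_null import estimate_aa_frequencies, estimate_spurious_matches
from specnoise.matching import summarize_corpus

noise = NoiseConfig(jitter=JitterModel(method=2), missing_peaks=True,
                    unknown=UnknownPeakModel(method="combined"), unknown_count=20)
predicted, realified = generate_corpus(CorpusConfig(n_spectra=200, seed=42, noise=noise))

print(classify_spectrum(realified[0]).fractions)
# {'backbone_1plus': 0.462, 'backbone_2plus': 0.282, 'neutral_loss': 0.0,
#  'internal_b': 0.051, 'internal_a': 0.013, 'unknown': 0.192}

freqs = estimate_aa_frequencies(realified)
random_counts = estimate_spurious_matches(realified, freqs, seed=17)
table = summarize_corpus(realified, random_counts)
print(table.loc[["b", "y", "Int-b"],
                ["possible", "matched", "fraction_matched", "random_matched"]])
#           possible  matched  fraction_matched  random_matched
# ion_type
# b             2169     2161          0.996312              87
# y             2169     2169          1.000000              34
# Int-b        12892     1312          0.101769             634
```

The first line classifies every peak of one noisy spectrum into exclusive
categories: ~74% of peaks are still backbone ions of the label, ~6% alias
internal-fragment masses, and 19% are unknown (the injected noise peaks).
The table gives corpus-level accounting per ion type: the generator emits
complete b/y ladders, so nearly all possible b/y ions are matched, while
the `random_matched` column — matches achieved by a random tryptic decoy
peptide per spectrum — estimates how many matches of each type are chance
alignments (nearly half of the internal-fragment matches here).

The same operations are available from the shell:

```bash
specnoise simulate --config corpus.toml --out-predicted pred.mgf --out-real real.mgf
specnoise annotate --mgf real.mgf --out table.tsv
specnoise null --mgf real.mgf --seed 17 --out null.tsv
specnoise denoise --in real.mgf --drop jitter --out snapped.mgf
specnoise augment --in pred.mgf --config corpus.toml --seed 3 --out noisy.mgf
specnoise diagnose --mgf real.mgf --out defect.tsv
specnoise evaluate --predictions preds.tsv --mgf real.mgf --out metrics.json
```

Spectra are read and written as MGF (`BEGIN IONS`/`END IONS` blocks with
`TITLE`, `PEPMASS`, `CHARGE` and a `SEQ=` line carrying the peptide label;
oxidised methionine is encoded inline as `M(+15.99)`).

## Documentation

See `docs/methods.md` for the models, their assumptions and parameters,
what the synthetic generator does and does not emulate, and the numerical
choices behind the estimators.
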