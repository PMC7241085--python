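# iterdda

In-silico comparison of MS² data-dependent acquisition (DDA) strategies for
untargeted LC–MS metabolomics, together with the QA/QC feature screening,
inclusion-list construction and spectral annotation machinery the comparison
is measured with.

## The problem

Untargeted LC–MS metabolomics identifies thousands of features (m/z, RT
peaks), but annotating them requires MS² spectra, and an instrument can only
fragment a handful of precursors per survey-scan cycle. Which precursors to
pick is therefore a sampling-strategy problem. This package implements and
compares four automated strategies that fit inside a standard QA/QC batch
(blanks and pooled-QC injections around the study samples):

* **dda** — untargeted top-N selection over the full 70–1500 m/z range, one
  QC injection;
* **idda** — untargeted iterated DDA, one QC injection per m/z band
  ([70–200], [200–400], … [1250–1500] Da, seven runs);
* **xcms** — targeted *dynamic* iterated DDA from an inclusion list of
  "informative" features: min QC intensity / max blank intensity > 6 in the
  conditioning batch (2 blanks + 3 QCs), ¹³C isotopologues excluded;
* **hmdb** — targeted dynamic iterated DDA from an inclusion list of
  features absent from blanks that pre-annotate as one of 17 ESI⁺ adducts of
  a database metabolite within 20 ppm.

In the dynamic modes the inclusion list is pruned between consecutive QC
injections, so each run only chases what is still missing.

Because real raw data cannot be re-acquired at a desk, the package ships a
scan-level simulator: a synthetic metabolite library, Gaussian
chromatographic peaks with adduct/isotopologue pseudospectrum structure,
blank/QC/sample batches with a realistic noise-feature fraction, and a
cycle-accurate acquisition engine (5 Hz, 5 precursors per cycle, ±2 Da
isolation, dynamic exclusion of 0.15 min after two consecutive selections).
Every synthetic feature carries ground truth, so coverage and annotation
claims are testable.

## Spectral annotation

A fragmented precursor is pre-annotated against the database via adduct
mass calculus, then each candidate's reference spectrum is scored with a
weighted spectral cosine:

    dp = (Σ A_exp · A_ref)² / (Σ A_exp² · Σ A_ref²),   A = I^m · (m/z)^n

with m = 1.2, n = 0.9. `dp` runs over the union of ions (experimental-only
ions have their intensity halved to damp co-fragmentation artefacts); the
reverse dot product `rdp` is restricted to ions present in both spectra.
Matches need ≥ 4 shared ions above the intensity floors (500 AU, 0.01% of
base peak) and a geometric-mean score √(dp·rdp) ≥ 0.25; the geometric mean
never exceeds the arithmetic mean (equality iff dp = rdp), which makes it
the stricter ranking statistic.

## Worked example

```python
from iterdda import BatchDesign
from iterdda.benchmark_report import run_benchmark, strategy_summary, informative_coverage

bench = run_benchmark(BatchDesign(seed=1))
df = strategy_summary(bench.outcomes)
print(df[["strategy", "runs", "total_spectra", "informative", "noise", "pct_noise"]].to_string(index=False))
print({k: round(v, 2) for k, v in informative_coverage(bench).items()})
```

prints

```
strategy  runs  total_spectra  informative  noise  pct_noise
     dda     1            736          132    345         47
    idda     7           2364          412    823         35
    xcms     6            385          354      0          0
    hmdb     6            385          354      0          0
{'dda': 0.33, 'idda': 0.87, 'xcms': 0.89, 'hmdb': 0.89}
```

Reading: single-run DDA spends about half its 736 spectra on noise and
reaches only 33% of the informative (monoisotopic, metabolite-derived)
features. Iterating over seven m/z bands buys coverage (87%) at the price of
2364 spectra, still mostly off-target. The targeted dynamic modes reach the
highest coverage (89%) with ~6× fewer spectra than i-DDA and essentially
none wasted on noise — the inclusion lists were built from nothing more than
the 2 blanks + 3 QCs of system conditioning.

A command-line interface mirrors the library
(`iterdda simulate-batch | screen | build-list | acquire | annotate | compare`);
see `iterdda --help`.

## Scope

The package consumes peak tables (CSV), MS² spectra (MGF) and spectral
libraries (MSP); raw vendor data, peak detection (centWave), retention-time
correction, full CAMERA deconvolution and lipidomics-specific annotation are
out of scope. See `docs/methods.md` for the model details, parameter
defaults and known limitations.
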