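# Methods

## Acquisition model

An LC–MS injection is modelled at scan level. Each ion elutes as a Gaussian:
height(t) = apex_height · exp(−(t − apex_rt)² / 2σ²), with per-feature σ
drawn from 1.5–6 s (base widths of roughly 5–25 s). A survey scan at time t
reports one centroid (m/z, height(t)) per eluting ion inside the 70–1500 m/z
working range. The instrument clock mimics a QTOF at 5 Hz: every cycle costs
one survey scan plus one scan per MS² event, i.e. (1 + k)/5 s for k
fragmentations, so heavier MS² load slows the survey sampling — the central
trade-off the strategy comparison is about.

Precursor selection per cycle: candidates are the survey ions inside the
active m/z range (the whole range for dda, the current band for idda, the
inclusion-list matches for the targeted modes — 20 ppm and an RT window of
±0.1 min per entry), above the minimum precursor intensity, and not on
dynamic exclusion; the top 5 by intensity are fragmented (ties by ascending
m/z). Dynamic exclusion bans a precursor (20 ppm identity) for 0.15 min
after it has been selected in two consecutive cycles; a skipped cycle resets
the consecutive count. Exclusion windows take effect at the end of the cycle
that triggered them, and consecutive selections are counted across cycles
(whether a real instrument counts within-cycle repeats is not observable
from the outside; the audit replays the same convention).

Isolation is ±2.0 Da (a symmetric reading of a "medium, ~4 amu" window):
every ion eluting inside the window co-fragments, and the spectrum is the
union of the contributors' reference fragment spectra scaled by their
elution heights at selection time. Chimeric spectra record all contributors
in `truth_sources`.

Defaults (all on `MethodConfig`): scan_hz 5, top_n_per_cycle 5,
isolation_halfwidth 2.0 Da, exclusion_after_n_consecutive 2,
exclusion_minutes 0.15, min_precursor_intensity 3000 AU (mirroring the
3000-count prefilter typical of peak detection settings), i-DDA bands
[70–200], [200–400], [400–600], [600–800], [800–1000], [1000–1250],
[1250–1500] Da.

## Feature screening

The blank-ratio rule labels a feature informative iff min(QC intensities) /
max(blank intensities) > 6, with two conventions for zeros: blank-absent
(max = 0) with all QCs positive → informative; missing from any QC (min = 0)
→ noise. Intensity 0 always encodes "not detected". The same rule is applied
to both batches; no additional carry-over criteria are modelled.

Cross-batch alignment is greedy nearest within 7.5 mDa / 0.1 min: candidate
pairs are consumed in ascending combined distance |Δmz|/tol_mz + |Δrt|/tol_rt,
each feature used at most once. Greedy was chosen over optimal assignment
because it is deterministic, O(n log n) in the candidate pairs, and testable
against a brute-force oracle on small instances.

Pseudospectrum grouping is a deliberately simple stand-in for full
deconvolution: connected components of the graph linking features with
|ΔRT| ≤ 0.05 min and Pearson correlation of log-intensities across non-blank
samples ≥ 0.75. Peak-shape analysis is not modelled; synthetic batches are
pre-aligned. ¹³C isotopologues are flagged inside pseudospectra: a partner
at mz − 1.003355/z (z ∈ {1, 2}) within 20 ppm whose intensity dominates the
feature in every QC marks the feature as an isotopologue.

## Adduct calculus and inclusion lists

m/z = (n_M · M + shift − z·m_e) / z over the 17 ESI⁺ forms ([M+H]⁺ …
[2M+Na+CH3CN]⁺, [M+H−H2O]⁺), with monoisotopic atomic masses and the
electron mass included — at m/z 100 the electron is a ~5 ppm effect, material
at the 20 ppm matching tolerance. Pre-annotation scans all (metabolite ×
adduct) pairs and returns hits sorted by |ppm error|.

The informative-mode list contains every blank-ratio-informative,
monoisotopic feature of the conditioning batch; the preannotated-mode list
contains features with zero intensity in **every** blank ("not detected in
blanks" is the only definable convention without raw-data reintegration)
and ≥ 1 database hit. Pruning removes an entry as soon as one acquired
spectrum falls within 20 ppm and the entry's RT window — one spectrum per
entry maximises per-run coverage gain and reproduces the sharply decaying
per-run spectra counts characteristic of dynamic targeted acquisition.

## Annotation scoring

A = I^m · (m/z)^n with m = 1.2 (intensity), n = 0.9 (m/z), both exponents
applied identically in dp and rdp. dp uses the union-vector construction:
matched ions contribute cross terms; experimental-only ions enter the
experimental norm with intensity × 0.5 (the penalty multiplies the raw
intensity, before exponentiation); reference-only ions enter the reference
norm. rdp restricts all sums to matched ions. Both are scale-free in either
spectrum's intensities and bounded in [0, 1]. Experimental peaks must clear
an absolute floor of 500 AU and a relative floor of 0.01% of the base peak
(the floors sentence pairs "absolute and relative" the other way round in
places; 500 AU as absolute and 0.01% as relative is the only physically
coherent reading). Accepted matches need ≥ 4 matched ions and geometric mean
≥ 0.25; the best (top 1) candidate is reported, ties broken by precursor ppm
error. Spectra whose precursor feature is a flagged isotopologue are skipped
with an empty result rather than an error. Ion pairing is greedy
nearest-ppm, one-to-one.

## Synthetic data: what it emulates, what it does not

The generator reproduces the structural features the strategy comparison
depends on: a conditioning batch (2 blanks + 3 QCs) and a sample batch (42
samples, 13 interleaved QCs, 3 blanks); ~65% noise/background features
(present in blanks at QC-comparable intensity, enforced min QC / max blank
≤ 6); metabolite pseudospectra (always [M+H]⁺ plus 0–4 further adducts at
2–50% relative abundance, co-eluting within 0.05 min) and ¹³C isotopologues
(probability 0.5 per adduct feature, exact 2–30% of the parent in every
sample, at +1.003355/z Da); lognormal metabolite abundances (ln-scale μ
11.5, σ 2.6, clipped to [2·10³, 10⁹] AU) spanning > 4 orders of magnitude;
QC replicate variation with ln-σ 0.15 and study-sample variation 0.5
(typical untargeted dispersions; noise features use 0.2); co-elution
clusters of ~4 metabolites sharing an RT neighbourhood. Between batches,
feature m/z and RT are re-detected with ≤ 1 mDa / ≤ 0.02 min jitter so that
cross-batch alignment is non-trivial but recoverable.

Desk-scale sizes were fixed once: 60 metabolites (~225 metabolite-derived
features after adducts and isotopologues, ~420 noise features) over a 3-min
gradient with seven QC acquisition runs. This preserves the regime that
drives the published comparisons — more selectable features per unit time
than the 5 Hz / top-5 duty cycle can fragment in one run — while keeping a
full four-strategy benchmark under ~10 s.

Not emulated: ionization/suppression physics, gradient and drift effects,
mass-calibration drift, carry-over decay (carry-over features are tagged in
truth but behave like background), peak asymmetry, and detector noise in
MS² spectra (fragment intensities are exact scalings of the reference
pattern). Passing tests therefore demonstrate the *logic* of screening,
acquisition and annotation under controlled truth — not robustness to the
full messiness of real chromatography.

## Comparison metrics

Informative-feature coverage is the fraction of **monoisotopic**
metabolite-derived features fragmented. Isotopologues are excluded from the
denominator because the targeted modes exclude them from inclusion lists on
purpose (their spectra duplicate the parent's); counting them would penalise
exactly that design. Selection bias is summarised as the ratio of median
(over features) median non-blank intensity, fragmented vs unfragmented,
restricted to informative features, with co-elution counted within
±0.05 min. Overlap sets across strategies use tolerance clustering (20 ppm,
0.1 min) of the pooled fragmented features; reported percentages round half
away from zero to integers. Ordering claims (targeted > i-DDA > DDA
coverage; bias reduction by targeting) are asserted across ≥ 10 seeds, bias
medians across seeds, since single batches can invert close ratios.

## Numerical choices and degenerate inputs

ppm errors are always computed against the reference (second) argument.
Survey centroids below 1 AU are dropped (the Gaussian never truly reaches
zero). Zero-tolerance alignment degenerates gracefully (distance
denominators guarded). Pearson correlation of a constant intensity vector is
defined as 0. Empty spectra or empty reference lists score (0, 0). An empty
inclusion list yields zero runs and zero spectra. CSV round-trips use
round-trip float parsing so tables survive write/read bit-exactly.

## Known limitations

* The exclusion bookkeeping merges real distinct ions closer than 20 ppm
  into one record, as a real instrument's exclusion list would.
* Pseudospectrum grouping by connected components can chain features that
  are pairwise below the correlation threshold through intermediates.
* With a complete database the two targeted modes build near-identical
  inclusion lists and behave identically; `run_benchmark(...,
  database_coverage=<1)` withholds part of the library to study the
  incomplete-database regime.
* The simulator's MS² fragment intensities are noise-free, so annotation
  scores on un-chimeric spectra are near-perfect by construction; chimeric
  contamination is the only score-degrading mechanism modelled.
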