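"""MS2 spectral annotation: adduct pre-annotation plus weighted dot-product matching.

A fragmented precursor is first pre-annotated against a metabolite database
(does its m/z match any of the 17 ESI+ adduct forms of some metabolite
within 20 ppm?).  Each candidate's reference spectrum is then compared with
the experimental spectrum via a weighted cosine similarity

    dp = (sum A_exp * A_ref)^2 / (sum A_exp^2 * sum A_ref^2),
    A  = intensity^m * (m/z)^n,

with m = 1.2 and n = 0.9.  ``dp`` runs over the union of ions (experimental
ions with no reference counterpart first have their raw intensity halved to
damp co-fragmentation artefacts; reference-only ions contribute to the
reference norm); the reverse dot product ``rdp`` is the same expression
restricted to ions present in both spectra.  Candidates need at least 4
matching ions above the intensity floors (500 AU absolute, 0.01% of the base
peak relative) and a geometric-mean score sqrt(dp*rdp) of at least 0.25; the
best candidate (top 1) is reported.  The geometric mean never exceeds the
arithmetic mean, with equality exactly when dp = rdp, which is what makes it
the stricter ranking statistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .model_io import FragmentPeak, LibraryEntry, MS2Spectrum, PeakTable
from .precursor_targets import Adduct, _AdductIndex, preannotate

__all__ = [
    "MatchParameters",
    "AnnotationResult",
    "filter_peaks",
    "match_ions",
    "IonPairing",
    "dot_products",
    "mean_score",
    "annotate_spectrum",
    "label_fragments",
]


@dataclass(frozen=True)
class MatchParameters:
    """Scoring parameters for spectral library matching."""

    m: float = 1.2  # intensity exponent
    n: float = 0.9  # m/z exponent
    ppm_tol: float = 20.0
    min_matched_ions: int = 4
    abs_intensity_floor: float = 500.0  # AU
    rel_intensity_floor: float = 0.0001  # fraction of base peak (0.01%)
    unmatched_penalty: float = 0.5
    min_mean_dp: float = 0.25
    top_n: int = 1

    def __post_init__(self) -> None:
        if self.m <= 0 or self.n <= 0:
            raise ValueError("exponents must be > 0")
        if not 0 < self.unmatched_penalty <= 1:
            raise ValueError("unmatched_penalty must be in (0, 1]")
        if self.abs_intensity_floor < 0 or self.rel_intensity_floor < 0:
            raise ValueError("intensity floors must be >= 0")


@dataclass
class AnnotationResult:
    """A scored library match for one spectrum."""

    spectrum: MS2Spectrum
    metabolite_id: str
    adduct: str
    dp: float
    rdp: float
    gmean: float
    matched_ions: int
    precursor_ppm_error: float = 0.0
    labeled_fragment_features: list[str] = field(default_factory=list)


def filter_peaks(spec: MS2Spectrum, params: MatchParameters = MatchParameters()) -> list[FragmentPeak]:
    """Keep fragments above both the absolute and the relative intensity floor."""
    base = spec.base_peak_intensity
    floor = max(params.abs_intensity_floor, params.rel_intensity_floor * base)
    return [p for p in spec.fragments if p.intensity >= floor]


@dataclass
class IonPairing:
    """Outcome of greedy ion matching between two peak lists."""

    pairs: list[tuple[int, int]]  # (exp index, ref index)
    exp_only: list[int]
    ref_only: list[int]


def match_ions(
    exp_peaks: list[FragmentPeak],
    ref_peaks: list[FragmentPeak],
    ppm_tol: float = 20.0,
) -> IonPairing:
    """Greedy nearest-ppm one-to-one pairing of experimental and reference ions.

    Candidate pairs within tolerance are consumed in ascending |ppm error|;
    each ion is used at most once.
    """
    cands: list[tuple[float, int, int]] = []
    for i, e in enumerate(exp_peaks):
        for j, r in enumerate(ref_peaks):
            ppm = abs(1e6 * (e.mz - r.mz) / r.mz)
            if ppm <= ppm_tol:
                cands.append((ppm, i, j))
    cands.sort()
    used_e: set[int] = set()
    used_r: set[int] = set()
    pairs = []
    for _, i, j in cands:
        if i in used_e or j in used_r:
            continue
        used_e.add(i)
        used_r.add(j)
        pairs.append((i, j))
    pairs.sort()
    return IonPairing(
        pairs=pairs,
        exp_only=[i for i in range(len(exp_peaks)) if i not in used_e],
        ref_only=[j for j in range(len(ref_peaks)) if j not in used_r],
    )


def dot_products(
    pairing: IonPairing,
    exp_peaks: list[FragmentPeak],
    ref_peaks: list[FragmentPeak],
    params: MatchParameters = MatchParameters(),
) -> tuple[float, float]:
    """(dp, rdp) of an ion pairing under the weighted-cosine formula.

    ``dp`` uses the union of ions: matched pairs contribute the cross term,
    experimental-only ions enter the experimental norm with their raw
    intensity multiplied by ``unmatched_penalty`` before exponentiation, and
    reference-only ions enter the reference norm.  ``rdp`` restricts every
    sum to the matched pairs.  Empty inputs give (0, 0); both values are
    scale-invariant in either spectrum's intensities and lie in [0, 1].
    """
    if not exp_peaks or not ref_peaks:
        return 0.0, 0.0
    m, n = params.m, params.n

    def weight(intensity: float, mz: float) -> float:
        return intensity**m * mz**n

    cross = exp_sq = ref_sq = 0.0
    r_cross = r_exp_sq = r_ref_sq = 0.0
    for i, j in pairing.pairs:
        ae = weight(exp_peaks[i].intensity, exp_peaks[i].mz)
        ar = weight(ref_peaks[j].intensity, ref_peaks[j].mz)
        cross += ae * ar
        exp_sq += ae**2
        ref_sq += ar**2
        r_cross += ae * ar
        r_exp_sq += ae**2
        r_ref_sq += ar**2
    for i in pairing.exp_only:
        ae = weight(exp_peaks[i].intensity * params.unmatched_penalty, exp_peaks[i].mz)
        exp_sq += ae**2
    for j in pairing.ref_only:
        ar = weight(ref_peaks[j].intensity, ref_peaks[j].mz)
        ref_sq += ar**2
    dp = cross**2 / (exp_sq * ref_sq) if cross > 0 else 0.0
    rdp = r_cross**2 / (r_exp_sq * r_ref_sq) if r_cross > 0 else 0.0
    return dp, rdp


def mean_score(dp: float, rdp: float) -> float:
    """Geometric mean sqrt(dp*rdp); <= arithmetic mean, equal iff dp = rdp."""
    return math.sqrt(dp * rdp)


def annotate_spectrum(
    spec: MS2Spectrum,
    library: list[LibraryEntry],
    adducts: dict[str, Adduct] | None = None,
    params: MatchParameters = MatchParameters(),
    precursor_feature_isotope_flag: str = "monoisotopic",
    _index: _AdductIndex | None = None,
) -> list[AnnotationResult]:
    """Annotate one spectrum against a library; returns up to ``top_n`` results.

    Candidates come from adduct pre-annotation of the precursor m/z; each is
    scored with dp/rdp on the floor-filtered experimental spectrum and kept
    only with >= ``min_matched_ions`` matching ions and geometric mean >=
    ``min_mean_dp``.  Ranking is by geometric mean, ties broken by absolute
    precursor ppm error.  A spectrum whose precursor feature is a flagged
    13C isotopologue is skipped (empty result, by convention not an error).
    """
    if precursor_feature_isotope_flag == "c13_isotopologue":
        return []
    by_id = {e.metabolite_id: e for e in library}
    hits = preannotate(spec.precursor_mz, library, adducts, params.ppm_tol, _index=_index)
    exp = filter_peaks(spec, params)
    results = []
    for met_id, adduct_name, ppm_err in hits:
        entry = by_id[met_id]
        pairing = match_ions(exp, entry.reference_spectrum, params.ppm_tol)
        if len(pairing.pairs) < params.min_matched_ions:
            continue
        dp, rdp = dot_products(pairing, exp, entry.reference_spectrum, params)
        g = mean_score(dp, rdp)
        if g < params.min_mean_dp:
            continue
        results.append(
            AnnotationResult(
                spectrum=spec,
                metabolite_id=met_id,
                adduct=adduct_name,
                dp=dp,
                rdp=rdp,
                gmean=g,
                matched_ions=len(pairing.pairs),
                precursor_ppm_error=ppm_err,
            )
        )
    results.sort(key=lambda r: (-r.gmean, abs(r.precursor_ppm_error)))
    return results[: params.top_n]


def label_fragments(
    result: AnnotationResult,
    table: PeakTable,
    feature_id: str,
    ref_spectrum: list[FragmentPeak],
    params: MatchParameters = MatchParameters(),
) -> AnnotationResult:
    """Label same-pseudospectrum features that are fragments of the annotated metabolite.

    A pcgroup partner of the annotated feature is labeled when its m/z
    matches (within ``ppm_tol``) an ion present in *both* the floor-filtered
    experimental spectrum and the reference spectrum.
    """
    feature = table.feature(feature_id)
    if feature.pcgroup is None:
        return result
    exp = filter_peaks(result.spectrum, params)
    pairing = match_ions(exp, ref_spectrum, params.ppm_tol)
    shared_mz = [exp[i].mz for i, _ in pairing.pairs]
    labeled = []
    for f in table.features:
        if f.pcgroup != feature.pcgroup or f.feature_id == feature_id:
            continue
        for mz in shared_mz:
            if abs(1e6 * (f.mz - mz) / mz) <= params.ppm_tol:
                labeled.append(f.feature_id)
                break
    result.labeled_fragment_features = labeled
    return result
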