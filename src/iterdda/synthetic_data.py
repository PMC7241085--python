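"""Synthetic metabolite libraries, LC-MS run models and blank/QC/sample batches.

The generator emulates the structure of an untargeted ESI+ LC-MS
metabolomics experiment run under a standard QA/QC design: a small
conditioning batch (blanks then pooled QCs) followed by a sample batch in
which QCs are interleaved among study samples.  Metabolites elute as
Gaussian chromatographic peaks, each appearing as a small pseudospectrum of
co-eluting adduct features (always [M+H]+, sometimes further adducts and a
13C isotopologue), while background/noise features are present in blanks at
intensities comparable to QCs so that the blank-ratio rule separates the two
populations.  Feature intensities span several orders of magnitude, which is
what makes intensity-ranked precursor selection a biased sampler.

Everything is driven by one seed: fixed seed, bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .model_io import (
    Feature,
    FragmentPeak,
    LibraryEntry,
    PeakTable,
    SampleInfo,
)
from .precursor_targets import ADDUCTS, adduct_mz

__all__ = [
    "ChromPeakModel",
    "RunModel",
    "BatchDesign",
    "FeatureTruth",
    "GroundTruth",
    "generate_library",
    "generate_batch",
]

C13_C12_DELTA = 1.003355

#: adducts the generator may attach beyond the always-present [M+H]+
_EXTRA_ADDUCTS = [
    "[M+Na]+",
    "[M+NH4]+",
    "[M+K]+",
    "[M+H-H2O]+",
    "[2M+H]+",
    "[2M+Na]+",
    "[M+H+Na]2+",
    "[M+H+CH3CN]+",
]

_CLASS_NAMES = [
    "Triacylglycerols",
    "Diacylglycerols",
    "Glycerophosphocholines",
    "Fatty acids and conjugates",
    "Carbohydrates and conjugates",
    "Monoacylglycerols",
    "Fatty alcohols",
    "Monoterpenoids",
    "Amino acids and derivatives",
    "Flavonoid glycosides",
]


@dataclass
class ChromPeakModel:
    """A Gaussian elution profile for one ion in one run."""

    feature_id: str
    mz: float
    apex_rt: float
    sigma: float  # minutes
    apex_height: float
    source: str  # 'metabolite-adduct' | 'noise' | 'carryover'
    source_metabolite: str | None = None
    source_adduct: str | None = None

    def height(self, t: float) -> float:
        return self.apex_height * math.exp(-((t - self.apex_rt) ** 2) / (2 * self.sigma**2))


@dataclass
class RunModel:
    """Scan-level model of one LC-MS injection."""

    sample: SampleInfo
    scan_interval: float  # seconds, from the 5 Hz scan frequency
    gradient_length: float  # minutes
    peaks: list[ChromPeakModel]
    fragment_truth: dict[str, list[FragmentPeak]]

    def __post_init__(self) -> None:
        for p in self.peaks:
            if not 0 <= p.apex_rt <= self.gradient_length:
                raise ValueError(f"peak {p.feature_id} elutes outside the gradient")


@dataclass
class BatchDesign:
    """Knobs of the synthetic experiment; defaults mirror the QA/QC batch layout
    (2 blanks + 3 QCs conditioning, then 42 samples / 13 QCs / 3 blanks)."""

    n_blanks_initial: int = 2
    n_qc_initial: int = 3
    n_samples: int = 42
    n_qc_sample_batch: int = 13
    n_blanks_sample_batch: int = 3
    n_metabolites: int = 60
    n_noise_features: int | None = None  # None: derived from noise_fraction_target
    noise_fraction_target: float = 0.65
    intensity_lognormal: tuple[float, float] = (11.5, 2.6)  # (mu, sigma) of ln(intensity)
    co_elution_cluster_mean: float = 4.0
    qc_cv: float = 0.15
    sample_cv: float = 0.5
    gradient_length: float = 3.0  # minutes
    scan_hz: float = 5.0
    p_isotopologue: float = 0.5
    extra_adduct_mean: float = 1.5
    initial_noise_fraction_present: float = 0.8
    n_acquisition_runs: int = 7
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_blanks_initial,
            self.n_qc_initial,
            self.n_samples,
            self.n_qc_sample_batch,
            self.n_blanks_sample_batch,
            self.n_metabolites,
        )
        if any(c < 0 for c in counts):
            raise ValueError("design counts must be >= 0")
        if not 0 <= self.noise_fraction_target < 1:
            raise ValueError("noise_fraction_target must be in [0, 1)")


@dataclass(frozen=True)
class FeatureTruth:
    """What a generated feature really is."""

    source: str  # 'metabolite-adduct' | 'noise' | 'carryover'
    metabolite_id: str | None
    adduct: str | None
    is_isotopologue: bool


@dataclass
class GroundTruth:
    """Generator-side truth: per-feature provenance and per-metabolite adduct sets."""

    feature_truth: dict[str, FeatureTruth]
    metabolite_features: dict[str, list[str]] = field(default_factory=dict)

    @property
    def informative_ids(self) -> set[str]:
        return {
            fid for fid, t in self.feature_truth.items() if t.source == "metabolite-adduct"
        }

    @property
    def noise_ids(self) -> set[str]:
        return {
            fid
            for fid, t in self.feature_truth.items()
            if t.source in ("noise", "carryover")
        }


# ---------------------------------------------------------------------------
# library generation
# ---------------------------------------------------------------------------

def generate_library(
    n_metabolites: int = 60,
    n_classes: int = 8,
    fragments_per_spectrum_range: tuple[int, int] = (3, 20),
    mass_range: tuple[float, float] = (120.0, 700.0),
    seed: int = 0,
    min_separation_ppm: float = 40.0,
) -> list[LibraryEntry]:
    """Random metabolite database with reference MS2 spectra.

    Neutral masses are unique at > ``min_separation_ppm`` mutual separation
    and constrained so that every one of the 17 adduct forms falls inside the
    70-1500 m/z acquisition range.  Reference spectra have 3-20 fragments
    normalised to base peak 100.
    """
    lo, hi = mass_range
    all_mz = [adduct_mz(m, a) for m in (lo, hi) for a in ADDUCTS.values()]
    if min(all_mz) < 70.0 or max(all_mz) > 1500.0:
        raise ValueError(
            "mass_range must keep every adduct m/z inside [70, 1500]; "
            f"got adduct m/z range [{min(all_mz):.1f}, {max(all_mz):.1f}]"
        )
    # feasibility of the mutual-separation constraint
    n_slots = math.log(hi / lo) / (min_separation_ppm * 1e-6)
    if n_metabolites > 0.25 * n_slots:
        raise ValueError("mass separation infeasible for requested n_metabolites")
    rng = np.random.default_rng(seed)
    masses: list[float] = []
    while len(masses) < n_metabolites:
        m = float(rng.uniform(lo, hi))
        if all(abs(1e6 * (m - x) / x) > min_separation_ppm for x in masses):
            masses.append(m)
    f_lo, f_hi = fragments_per_spectrum_range
    entries = []
    for i, mass in enumerate(masses):
        n_frag = int(rng.integers(f_lo, f_hi + 1))
        frag_hi = max(60.0, mass - 5.0)
        mzs: list[float] = []
        while len(mzs) < n_frag:
            fm = float(rng.uniform(50.0, frag_hi))
            if all(abs(fm - x) > 0.5 for x in mzs):
                mzs.append(fm)
        mzs.sort()
        heights = rng.uniform(1.0, 100.0, size=n_frag)
        heights = heights / heights.max() * 100.0
        entries.append(
            LibraryEntry(
                metabolite_id=f"MET_{i:04d}",
                name=f"synthetic metabolite {i}",
                neutral_mass=mass,
                compound_class=_CLASS_NAMES[i % n_classes],
                reference_spectrum=[
                    FragmentPeak(m, float(h)) for m, h in zip(mzs, heights)
                ],
                reference_adduct="[M+H]+",
            )
        )
    return entries


# ---------------------------------------------------------------------------
# batch generation
# ---------------------------------------------------------------------------

def _lognormal_factor(rng: np.random.Generator, cv: float, size: int | None = None):
    """Multiplicative replicate noise with ln-sigma = cv (cv ~ relative SD for small cv)."""
    return np.exp(rng.normal(0.0, cv, size=size))


@dataclass
class _ProtoFeature:
    feature_id: str
    mz: float
    rt: float
    sigma: float
    base: float  # typical QC-level intensity
    truth: FeatureTruth
    parent: str | None = None  # isotopologue parent feature
    iso_ratio: float = 1.0
    in_initial: bool = True


def generate_batch(
    design: BatchDesign,
    library: list[LibraryEntry] | None = None,
) -> tuple[PeakTable, PeakTable, list[RunModel], GroundTruth]:
    """Generate (initial_batch, sample_batch, acquisition RunModels, ground truth).

    Contracts honoured by construction: informative features are absent from
    blanks; noise/carryover features satisfy min(QC)/max(blank) <= 6; adduct
    and isotopologue features of one metabolite co-elute within 0.05 min;
    isotopologue intensities are an exact fixed fraction (2-30%) of the
    monoisotopic partner in every sample.
    """
    rng = np.random.default_rng(design.seed)
    if library is None:
        library = generate_library(design.n_metabolites, seed=design.seed)
    library = library[: design.n_metabolites]
    mu, sig = design.intensity_lognormal

    elute_lo, elute_hi = 0.12 * design.gradient_length, 0.88 * design.gradient_length
    n_clusters = max(1, round(len(library) / design.co_elution_cluster_mean))
    centers = rng.uniform(elute_lo, elute_hi, size=n_clusters)
    cluster_of = rng.integers(0, n_clusters, size=len(library))

    protos: list[_ProtoFeature] = []
    truth = GroundTruth(feature_truth={})
    fid_counter = 0

    def new_fid() -> str:
        nonlocal fid_counter
        fid_counter += 1
        return f"F{fid_counter:05d}"

    # --- metabolite-derived features -------------------------------------
    for k, entry in enumerate(library):
        met_apex = float(
            np.clip(
                centers[cluster_of[k]] + rng.normal(0.0, 0.012),
                elute_lo - 0.02,
                elute_hi + 0.02,
            )
        )
        base_abund = float(np.clip(rng.lognormal(mu, sig), 2e3, 1e9))
        n_extra = min(int(rng.poisson(design.extra_adduct_mean)), len(_EXTRA_ADDUCTS))
        adduct_names = ["[M+H]+"] + list(
            rng.choice(_EXTRA_ADDUCTS, size=n_extra, replace=False)
        )
        met_fids = []
        for a_name in adduct_names:
            add = ADDUCTS[a_name]
            factor = 1.0 if a_name == "[M+H]+" else float(rng.uniform(0.02, 0.5))
            fid = new_fid()
            sigma_min = float(rng.uniform(1.5, 6.0)) / 60.0
            apex = met_apex + float(rng.uniform(-0.01, 0.01))
            protos.append(
                _ProtoFeature(
                    feature_id=fid,
                    mz=adduct_mz(entry.neutral_mass, add),
                    rt=apex,
                    sigma=sigma_min,
                    base=base_abund * factor,
                    truth=FeatureTruth("metabolite-adduct", entry.metabolite_id, a_name, False),
                )
            )
            met_fids.append(fid)
            if rng.random() < design.p_isotopologue:
                iso_fid = new_fid()
                protos.append(
                    _ProtoFeature(
                        feature_id=iso_fid,
                        mz=protos[-1].mz + C13_C12_DELTA / add.charge,
                        rt=apex,
                        sigma=sigma_min,
                        base=0.0,  # derived from parent
                        truth=FeatureTruth(
                            "metabolite-adduct", entry.metabolite_id, a_name, True
                        ),
                        parent=fid,
                        iso_ratio=float(rng.uniform(0.02, 0.30)),
                    )
                )
                met_fids.append(iso_fid)
        truth.metabolite_features[entry.metabolite_id] = met_fids

    n_informative = len(protos)

    # --- noise / background features -------------------------------------
    t = design.noise_fraction_target
    n_noise = (
        design.n_noise_features
        if design.n_noise_features is not None
        else round(n_informative * t / (1.0 - t))
    )
    noise_fragments: dict[str, list[FragmentPeak]] = {}
    for j in range(n_noise):
        fid = new_fid()
        source = "carryover" if rng.random() < 0.1 else "noise"
        nmz = float(rng.uniform(70.0, 1490.0))
        protos.append(
            _ProtoFeature(
                feature_id=fid,
                mz=nmz,
                rt=float(rng.uniform(0.05 * design.gradient_length, 0.95 * design.gradient_length)),
                sigma=float(rng.uniform(1.5, 6.0)) / 60.0,
                base=float(np.clip(rng.lognormal(mu - 1.0, sig), 2e3, 1e9)),
                truth=FeatureTruth(source, None, None, False),
                in_initial=bool(rng.random() < design.initial_noise_fraction_present),
            )
        )
        nid = f"NOISE_{j:04d}"
        n_frag = int(rng.integers(3, 9))
        fmzs: list[float] = []
        while len(fmzs) < n_frag:
            fm = float(rng.uniform(50.0, max(60.0, nmz)))
            if all(abs(fm - x) > 0.5 for x in fmzs):
                fmzs.append(fm)
        heights = rng.uniform(1.0, 100.0, size=n_frag)
        heights = heights / heights.max() * 100.0
        noise_fragments[nid] = [
            FragmentPeak(m, float(h)) for m, h in zip(sorted(fmzs), heights)
        ]
        protos[-1].truth = FeatureTruth(source, nid, None, False)

    for p in protos:
        truth.feature_truth[p.feature_id] = p.truth

    by_id = {p.feature_id: p for p in protos}

    # --- sample layouts ---------------------------------------------------
    initial_samples: list[SampleInfo] = []
    order = 1
    for i in range(design.n_blanks_initial):
        initial_samples.append(SampleInfo(f"iblank_{i+1}", "blank", order))
        order += 1
    for i in range(design.n_qc_initial):
        initial_samples.append(SampleInfo(f"iqc_{i+1}", "qc", order))
        order += 1

    sample_samples: list[SampleInfo] = []
    order = 1
    qc_left, smp_left = design.n_qc_sample_batch, design.n_samples
    qc_i = smp_i = 0
    spacing = max(1, design.n_samples // max(1, design.n_qc_sample_batch - 1))
    while qc_left or smp_left:
        if qc_left and (smp_i % spacing == 0 or not smp_left):
            qc_i += 1
            sample_samples.append(SampleInfo(f"qc_{qc_i}", "qc", order))
            qc_left -= 1
        elif smp_left:
            smp_i += 1
            sample_samples.append(SampleInfo(f"sample_{smp_i}", "sample", order))
            smp_left -= 1
        else:
            smp_i += 1  # pragma: no cover
        order += 1
    for i in range(design.n_blanks_sample_batch):
        sample_samples.append(SampleInfo(f"sblank_{i+1}", "blank", order))
        order += 1

    # --- per-sample intensities ------------------------------------------
    def draw_intensities(samples: list[SampleInfo]) -> dict[str, dict[str, float]]:
        values: dict[str, dict[str, float]] = {p.feature_id: {} for p in protos}
        for p in protos:
            if p.parent is not None:
                continue
            row = values[p.feature_id]
            if p.truth.source == "metabolite-adduct":
                for s in samples:
                    if s.cls == "blank":
                        row[s.sample_id] = 0.0
                    elif s.cls == "qc":
                        row[s.sample_id] = p.base * float(_lognormal_factor(rng, design.qc_cv))
                    else:
                        row[s.sample_id] = p.base * float(
                            _lognormal_factor(rng, design.sample_cv)
                        )
            else:
                for s in samples:
                    row[s.sample_id] = p.base * float(_lognormal_factor(rng, 0.2))
                qcs = [s.sample_id for s in samples if s.cls == "qc"]
                blanks = [s.sample_id for s in samples if s.cls == "blank"]
                if qcs and blanks:
                    qmin = min(row[s] for s in qcs)
                    bmax = max(row[s] for s in blanks)
                    if bmax > 0 and qmin / bmax > 6.0:
                        scale = (qmin / bmax) / 3.0
                        for s in blanks:
                            row[s] *= scale
        for p in protos:  # isotopologues: exact fraction of the parent
            if p.parent is not None:
                values[p.feature_id] = {
                    s: v * p.iso_ratio for s, v in values[p.parent].items()
                }
        return values

    initial_values = draw_intensities(initial_samples)
    sample_values = draw_intensities(sample_samples)

    def build_table(
        samples: list[SampleInfo],
        values: dict[str, dict[str, float]],
        jitter: bool,
    ) -> PeakTable:
        feats = []
        for p in protos:
            if jitter:  # independent re-detection in the second batch
                mz = p.mz + float(np.clip(rng.normal(0.0, 0.0004), -0.001, 0.001))
                rt = p.rt + float(np.clip(rng.normal(0.0, 0.008), -0.02, 0.02))
            else:
                mz, rt = p.mz, p.rt
            feats.append(
                Feature(
                    feature_id=p.feature_id,
                    mz=mz,
                    rt=max(rt, 0.0),
                    intensity=values[p.feature_id],
                )
            )
        return PeakTable(samples=samples, features=feats)

    initial_table = PeakTable(
        samples=initial_samples,
        features=[
            f
            for f in build_table(initial_samples, initial_values, jitter=False).features
            if by_id[f.feature_id].in_initial
        ],
    )
    sample_table = build_table(sample_samples, sample_values, jitter=True)

    # --- acquisition run models (QC injections) ---------------------------
    fragment_truth: dict[str, list[FragmentPeak]] = dict(noise_fragments)
    for entry in library:
        fragment_truth[entry.metabolite_id] = list(entry.reference_spectrum)

    runs: list[RunModel] = []
    for r in range(design.n_acquisition_runs):
        heights: dict[str, float] = {}
        for p in protos:
            if p.parent is None:
                cv = design.qc_cv if p.truth.source == "metabolite-adduct" else 0.2
                heights[p.feature_id] = p.base * float(_lognormal_factor(rng, cv))
        for p in protos:
            if p.parent is not None:
                heights[p.feature_id] = heights[p.parent] * p.iso_ratio
        peaks = [
            ChromPeakModel(
                feature_id=p.feature_id,
                mz=p.mz,
                apex_rt=min(max(p.rt, 0.0), design.gradient_length),
                sigma=p.sigma,
                apex_height=heights[p.feature_id],
                source=p.truth.source,
                source_metabolite=p.truth.metabolite_id,
                source_adduct=p.truth.adduct,
            )
            for p in protos
        ]
        runs.append(
            RunModel(
                sample=SampleInfo(f"acqqc_{r+1}", "qc", r + 1),
                scan_interval=1.0 / design.scan_hz,
                gradient_length=design.gradient_length,
                peaks=peaks,
                fragment_truth=fragment_truth,
            )
        )

    return initial_table, sample_table, runs, truth
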