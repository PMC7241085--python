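"""Domain types and file I/O for LC-MS peak tables, MS2 spectra and spectral libraries.

The central objects are :class:`PeakTable` (aligned LC-MS features with
per-sample intensities), :class:`MS2Spectrum` (a fragment spectrum with its
precursor coordinates) and :class:`LibraryEntry` (a metabolite with a
reference MS2 spectrum).  All retention times are minutes internally; MGF
``RTINSECONDS`` values are converted at the boundary.  Intensity 0 encodes
"not detected", which the blank-filtering rules rely on.

Peak tables are stored as two CSV files: a feature sheet
(``feature_id, mz, rt, pcgroup, isotope_flag, label`` plus one intensity
column per sample) and a sample sheet (``sample_id, cls, injection_order``)
found at ``<stem>.samples.csv`` next to the feature sheet.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from matchms.importing import load_from_msp
from pyteomics import mgf as _mgf

__all__ = [
    "FormatError",
    "SampleInfo",
    "Feature",
    "PeakTable",
    "FragmentPeak",
    "MS2Spectrum",
    "LibraryEntry",
    "ToleranceSpec",
    "ppm_error",
    "mz_match",
    "read_peak_table",
    "write_peak_table",
    "read_msp",
    "write_msp",
    "read_mgf",
    "write_mgf",
]

SAMPLE_CLASSES = ("blank", "qc", "sample")
ISOTOPE_FLAGS = ("monoisotopic", "c13_isotopologue", "unknown")
LABELS = ("informative", "noise", "unlabeled")


class FormatError(ValueError):
    """A file violated the documented peak-table / MGF / MSP schema."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SampleInfo:
    """One injection in a batch: blank, pooled QC, or study sample."""

    sample_id: str
    cls: str
    injection_order: int

    def __post_init__(self) -> None:
        if self.cls not in SAMPLE_CLASSES:
            raise FormatError(f"unknown sample class {self.cls!r}")
        if self.injection_order < 1:
            raise ValueError("injection_order must be a positive integer")


@dataclass
class Feature:
    """One aligned LC-MS feature: (m/z, RT) with per-sample intensities."""

    feature_id: str
    mz: float
    rt: float
    intensity: dict[str, float]
    pcgroup: int | None = None
    isotope_flag: str = "unknown"
    label: str = "unlabeled"

    def __post_init__(self) -> None:
        if not self.mz > 0:
            raise ValueError(f"feature {self.feature_id}: mz must be > 0")
        if self.rt < 0:
            raise ValueError(f"feature {self.feature_id}: rt must be >= 0")
        if self.isotope_flag not in ISOTOPE_FLAGS:
            raise ValueError(f"unknown isotope flag {self.isotope_flag!r}")
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")


@dataclass
class PeakTable:
    """A batch: sample metadata plus the features detected across it."""

    samples: list[SampleInfo]
    features: list[Feature]

    def __post_init__(self) -> None:
        ids = [f.feature_id for f in self.features]
        if len(ids) != len(set(ids)):
            raise FormatError("duplicate feature_id in peak table")
        sids = [s.sample_id for s in self.samples]
        if len(sids) != len(set(sids)):
            raise FormatError("duplicate sample_id in peak table")
        known = set(sids)
        for f in self.features:
            extra = set(f.intensity) - known
            if extra:
                raise FormatError(
                    f"feature {f.feature_id} has intensities for unknown samples {sorted(extra)}"
                )

    def sample_ids(self, cls: str | None = None) -> list[str]:
        return [s.sample_id for s in self.samples if cls is None or s.cls == cls]

    def feature(self, feature_id: str) -> Feature:
        for f in self.features:
            if f.feature_id == feature_id:
                return f
        raise KeyError(feature_id)

    def intensity_matrix(self, sample_ids: Sequence[str] | None = None) -> np.ndarray:
        """(n_features, n_samples) array; missing entries are 0."""
        cols = list(sample_ids) if sample_ids is not None else self.sample_ids()
        out = np.zeros((len(self.features), len(cols)))
        for i, f in enumerate(self.features):
            for j, s in enumerate(cols):
                out[i, j] = f.intensity.get(s, 0.0)
        return out

    def mz_array(self) -> np.ndarray:
        return np.array([f.mz for f in self.features])

    def rt_array(self) -> np.ndarray:
        return np.array([f.rt for f in self.features])


@dataclass(frozen=True, order=True)
class FragmentPeak:
    """A single centroided fragment ion."""

    mz: float
    intensity: float

    def __post_init__(self) -> None:
        if not self.mz > 0:
            raise ValueError("fragment mz must be > 0")


@dataclass
class MS2Spectrum:
    """A fragment spectrum with precursor coordinates and acquisition context.

    ``truth_sources`` is only populated by the simulator and lists the
    ground-truth contributors (chimeric spectra carry more than one).
    """

    precursor_mz: float
    precursor_rt: float
    run_id: str
    cycle_index: int = 0
    fragments: list[FragmentPeak] = field(default_factory=list)
    truth_sources: list[str] | None = None

    def __post_init__(self) -> None:
        mzs = [p.mz for p in self.fragments]
        if mzs != sorted(mzs):
            self.fragments = sorted(self.fragments, key=lambda p: p.mz)
            mzs = sorted(mzs)
        if len(set(mzs)) != len(mzs):
            raise ValueError("duplicate fragment m/z in spectrum")

    @property
    def base_peak_intensity(self) -> float:
        return max((p.intensity for p in self.fragments), default=0.0)


@dataclass
class LibraryEntry:
    """A database metabolite with neutral mass, class and reference MS2 spectrum."""

    metabolite_id: str
    name: str
    neutral_mass: float
    compound_class: str
    reference_spectrum: list[FragmentPeak]
    reference_adduct: str = "[M+H]+"

    def __post_init__(self) -> None:
        if not self.neutral_mass > 0:
            raise ValueError("neutral_mass must be > 0")
        if not self.reference_spectrum:
            raise ValueError("reference_spectrum must be non-empty")
        self.reference_spectrum = sorted(self.reference_spectrum, key=lambda p: p.mz)


@dataclass(frozen=True)
class ToleranceSpec:
    """Matching tolerances: ppm for m/z lookups, absolute m/z and RT for alignment.

    Defaults are 20 ppm, 7.5 mDa and 0.1 min.
    """

    ppm: float = 20.0
    mz_abs: float = 0.0075
    rt: float = 0.1

    def __post_init__(self) -> None:
        if self.ppm < 0 or self.mz_abs < 0 or self.rt < 0:
            raise ValueError("tolerances must be >= 0")


# ---------------------------------------------------------------------------
# tolerance arithmetic
# ---------------------------------------------------------------------------

def ppm_error(mz_obs: float, mz_theo: float) -> float:
    """Signed relative mass error in parts per million.

    The second argument is the reference (theoretical) mass, matching
    database-lookup usage: ``1e6 * (mz_obs - mz_theo) / mz_theo``.
    """
    if not mz_theo > 0:
        raise ValueError("reference mass must be > 0")
    return 1e6 * (mz_obs - mz_theo) / mz_theo


def mz_match(mz_a: float, mz_b: float, tol: ToleranceSpec, mode: str = "ppm") -> bool:
    """Do two m/z values agree within tolerance?

    ``mode='ppm'`` compares ``|ppm_error(mz_a, mz_b)|`` against ``tol.ppm``
    (second argument is the reference); ``mode='absolute'`` compares
    ``|mz_a - mz_b|`` against ``tol.mz_abs`` and is symmetric.
    """
    if mode == "ppm":
        return abs(ppm_error(mz_a, mz_b)) <= tol.ppm
    if mode == "absolute":
        return abs(mz_a - mz_b) <= tol.mz_abs
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# peak-table CSV
# ---------------------------------------------------------------------------

_FEATURE_COLS = ["feature_id", "mz", "rt", "pcgroup", "isotope_flag", "label"]


def _samples_path(path: Path) -> Path:
    return path.with_name(path.stem + ".samples.csv")


def write_peak_table(table: PeakTable, path: str | Path) -> None:
    """Write feature and sample sheets (CSV, schema in the module docstring)."""
    path = Path(path)
    sample_ids = table.sample_ids()
    rows = []
    for f in table.features:
        row = {
            "feature_id": f.feature_id,
            "mz": f.mz,
            "rt": f.rt,
            "pcgroup": "" if f.pcgroup is None else f.pcgroup,
            "isotope_flag": f.isotope_flag,
            "label": f.label,
        }
        for s in sample_ids:
            row[s] = f.intensity.get(s, 0.0)
        rows.append(row)
    pd.DataFrame(rows, columns=_FEATURE_COLS + sample_ids).to_csv(path, index=False)
    meta = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "cls": [s.cls for s in table.samples],
            "injection_order": [s.injection_order for s in table.samples],
        }
    )
    meta.to_csv(_samples_path(path), index=False)


def read_peak_table(path: str | Path, samples_path: str | Path | None = None) -> PeakTable:
    """Read a peak table written by :func:`write_peak_table`.

    Empty intensity cells read as 0 (not detected).  Duplicate feature ids or
    an unknown sample class raise :class:`FormatError`.
    """
    path = Path(path)
    samples_path = Path(samples_path) if samples_path else _samples_path(path)
    meta = pd.read_csv(samples_path)
    samples = [
        SampleInfo(str(r.sample_id), str(r.cls), int(r.injection_order))
        for r in meta.itertuples()
    ]
    df = pd.read_csv(path, dtype={"feature_id": str}, float_precision="round_trip")
    if df["feature_id"].duplicated().any():
        raise FormatError(f"duplicate feature_id in {path}")
    sample_ids = [s.sample_id for s in samples]
    missing = [s for s in sample_ids if s not in df.columns]
    if missing:
        raise FormatError(f"intensity columns missing for samples {missing}")
    # itertuples mangles arbitrary sample-id column names; index positionally
    features = []
    col_idx = {c: i for i, c in enumerate(df.columns)}
    for row in df.itertuples(index=False, name=None):
        pcg = row[col_idx["pcgroup"]]
        pcgroup = None if (pcg is None or (isinstance(pcg, float) and math.isnan(pcg)) or pcg == "") else int(pcg)
        inten = {}
        for s in sample_ids:
            v = row[col_idx[s]]
            inten[s] = 0.0 if (v is None or (isinstance(v, float) and math.isnan(v))) else float(v)
        features.append(
            Feature(
                feature_id=str(row[col_idx["feature_id"]]),
                mz=float(row[col_idx["mz"]]),
                rt=float(row[col_idx["rt"]]),
                intensity=inten,
                pcgroup=pcgroup,
                isotope_flag=str(row[col_idx["isotope_flag"]]),
                label=str(row[col_idx["label"]]),
            )
        )
    return PeakTable(samples=samples, features=features)


# ---------------------------------------------------------------------------
# MSP spectral libraries
# ---------------------------------------------------------------------------

def _validate_msp_peak_counts(path: Path) -> None:
    """Check that every record's peak lines agree with its Num Peaks header."""
    declared: int | None = None
    counted = 0
    record = 0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                if declared is not None and counted != declared:
                    raise FormatError(
                        f"record {record}: Num Peaks {declared} != {counted} peak lines"
                    )
                if declared is not None:
                    record += 1
                declared, counted = None, 0
            elif line.lower().startswith("num peaks"):
                declared = int(line.split(":", 1)[1])
            elif declared is not None:
                counted += 1
    if declared is not None and counted != declared:
        raise FormatError(f"record {record}: Num Peaks {declared} != {counted} peak lines")


def read_msp(path: str | Path) -> list[LibraryEntry]:
    """Read a NIST-style MSP library into :class:`LibraryEntry` records.

    Required per record: ``NAME``, ``NEUTRALMASS`` (or ``PRECURSORMZ`` with a
    known ``ADDUCT``), ``Num Peaks`` and that many peak lines.  Optional:
    ``METABOLITEID``, ``COMPOUNDCLASS``.
    """
    from .precursor_targets import ADDUCTS, neutral_from_adduct_mz  # cyclic at import time otherwise

    _validate_msp_peak_counts(Path(path))
    entries = []
    for i, spec in enumerate(load_from_msp(str(path), metadata_harmonization=False)):
        md = {k.lower(): v for k, v in spec.metadata.items()}
        n_declared = md.get("num_peaks")
        if n_declared is not None and int(n_declared) != len(spec.peaks.mz):
            raise FormatError(
                f"record {i}: Num Peaks {n_declared} != {len(spec.peaks.mz)} peak lines"
            )
        adduct = md.get("adduct", "[M+H]+")
        if "neutralmass" in md:
            neutral = float(md["neutralmass"])
        elif "precursor_mz" in md or "precursormz" in md:
            pmz = float(md.get("precursor_mz", md.get("precursormz")))
            if adduct not in ADDUCTS:
                raise FormatError(f"record {i}: unknown adduct {adduct!r}")
            neutral = neutral_from_adduct_mz(pmz, ADDUCTS[adduct])
        else:
            raise FormatError(f"record {i}: neither NEUTRALMASS nor PRECURSORMZ given")
        name = md.get("compound_name", md.get("name", f"entry_{i}"))
        frags = [
            FragmentPeak(float(m), float(h))
            for m, h in zip(spec.peaks.mz, spec.peaks.intensities)
        ]
        entries.append(
            LibraryEntry(
                metabolite_id=str(md.get("metaboliteid", name)),
                name=str(name),
                neutral_mass=neutral,
                compound_class=str(md.get("compoundclass", "unknown")),
                reference_spectrum=frags,
                reference_adduct=adduct,
            )
        )
    return entries


def write_msp(entries: Iterable[LibraryEntry], path: str | Path) -> None:
    """Write library entries as NIST-style MSP, round-trippable by :func:`read_msp`."""
    from .precursor_targets import ADDUCTS, adduct_mz

    with open(path, "w") as fh:
        for e in entries:
            fh.write(f"NAME: {e.name}\n")
            fh.write(f"METABOLITEID: {e.metabolite_id}\n")
            fh.write(f"NEUTRALMASS: {e.neutral_mass:.6f}\n")
            if e.reference_adduct in ADDUCTS:
                fh.write(
                    f"PRECURSORMZ: {adduct_mz(e.neutral_mass, ADDUCTS[e.reference_adduct]):.6f}\n"
                )
            fh.write(f"ADDUCT: {e.reference_adduct}\n")
            fh.write(f"COMPOUNDCLASS: {e.compound_class}\n")
            fh.write(f"Num Peaks: {len(e.reference_spectrum)}\n")
            for p in e.reference_spectrum:
                fh.write(f"{p.mz:.6f} {p.intensity:.6g}\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# MGF MS2 spectra
# ---------------------------------------------------------------------------

def read_mgf(path: str | Path) -> list[MS2Spectrum]:
    """Read MGF; RTINSECONDS is converted to minutes."""
    spectra = []
    with _mgf.MGF(str(path)) as reader:
        for rec in reader:
            params = rec["params"]
            pep = params.get("pepmass")
            pmz = float(pep[0] if isinstance(pep, (tuple, list)) else pep)
            rt_s = float(params.get("rtinseconds", 0.0))
            truth = params.get("truthsources")
            frags = [
                FragmentPeak(float(m), float(h))
                for m, h in zip(rec["m/z array"], rec["intensity array"])
            ]
            spectra.append(
                MS2Spectrum(
                    precursor_mz=pmz,
                    precursor_rt=rt_s / 60.0,
                    run_id=str(params.get("runid", "")),
                    cycle_index=int(params.get("cycle", 0)),
                    fragments=frags,
                    truth_sources=str(truth).split(";") if truth else None,
                )
            )
    return spectra


def write_mgf(spectra: Iterable[MS2Spectrum], path: str | Path) -> None:
    """Write spectra as MGF (RT emitted as RTINSECONDS)."""
    records = []
    for s in spectra:
        params = {
            "pepmass": s.precursor_mz,
            "rtinseconds": s.precursor_rt * 60.0,
            "runid": s.run_id,
            "cycle": s.cycle_index,
        }
        if s.truth_sources:
            params["truthsources"] = ";".join(s.truth_sources)
        records.append(
            {
                "m/z array": np.array([p.mz for p in s.fragments]),
                "intensity array": np.array([p.intensity for p in s.fragments]),
                "params": params,
            }
        )
    _mgf.write(records, str(path), file_mode="w")
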