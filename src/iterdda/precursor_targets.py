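"""Adduct mass calculus, database pre-annotation and inclusion-list construction.

Positive-mode electrospray adducts are modelled as
``m/z = (n_m * M + shift - z * m_e) / z`` where ``M`` is the neutral
monoisotopic mass, ``n_m`` the metabolite multiplicity (1 or 2), ``shift``
the summed monoisotopic masses of the added/removed atoms and ``m_e`` the
electron mass.  The built-in table holds the 17 singly- and doubly-charged
forms commonly observed in ESI+ metabolomics ([M+H]+ through
[2M+Na+CH3CN]+ and the water loss [M+H-H2O]+).

Two inclusion-list builders implement the targeted acquisition modes:

* *informative* — features passing the blank-ratio rule (min QC / max blank
  intensity > 6) in the conditioning batch, excluding 13C isotopologues;
* *preannotated* — features absent from all blanks whose m/z matches an
  adduct of at least one database metabolite within 20 ppm.

``prune_inclusion`` removes entries already covered by acquired MS2 spectra,
which is what makes the targeted modes *dynamic*: the list shrinks between
consecutive QC injections.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model_io import LibraryEntry, MS2Spectrum, PeakTable, ToleranceSpec

__all__ = [
    "Adduct",
    "ADDUCTS",
    "ATOMIC_MASS",
    "ELECTRON_MASS",
    "InclusionEntry",
    "adduct_mz",
    "neutral_from_adduct_mz",
    "preannotate",
    "build_inclusion_informative",
    "build_inclusion_preannotated",
    "prune_inclusion",
]

ELECTRON_MASS = 0.00054858

ATOMIC_MASS = {
    "H": 1.0078250319,
    "C": 12.0,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "Na": 22.98976928,
    "K": 38.9637064864,
}

_H = ATOMIC_MASS["H"]
_NA = ATOMIC_MASS["Na"]
_K = ATOMIC_MASS["K"]
_NH4 = ATOMIC_MASS["N"] + 4 * _H
_ACN = 2 * ATOMIC_MASS["C"] + 3 * _H + ATOMIC_MASS["N"]  # acetonitrile CH3CN
_H2O = 2 * _H + ATOMIC_MASS["O"]


@dataclass(frozen=True)
class Adduct:
    """A positive-mode adduct form: multiplicity, charge and mass shift."""

    name: str
    n_m: int
    charge: int
    shift_mass: float

    def __post_init__(self) -> None:
        if self.n_m not in (1, 2) or self.charge not in (1, 2):
            raise ValueError("only 1M/2M and charge 1/2 adducts are supported")


_ADDUCT_SPECS = [
    ("[M+H]+", 1, 1, _H),
    ("[M+Na]+", 1, 1, _NA),
    ("[M+NH4]+", 1, 1, _NH4),
    ("[M+H+Na]2+", 1, 2, _H + _NA),
    ("[M+K]+", 1, 1, _K),
    ("[M+H+K]2+", 1, 2, _H + _K),
    ("[M+H+CH3CN]+", 1, 1, _H + _ACN),
    ("[M+H+2CH3CN]+", 1, 1, _H + 2 * _ACN),
    ("[M+Na+CH3CN]+", 1, 1, _NA + _ACN),
    ("[M+2Na-H]+", 1, 1, 2 * _NA - _H),
    ("[2M+H]+", 2, 1, _H),
    ("[2M+Na]+", 2, 1, _NA),
    ("[2M+K]+", 2, 1, _K),
    ("[2M+NH4]+", 2, 1, _NH4),
    ("[2M+H+CH3CN]+", 2, 1, _H + _ACN),
    ("[2M+Na+CH3CN]+", 2, 1, _NA + _ACN),
    ("[M+H-H2O]+", 1, 1, _H - _H2O),
]

#: The 17 built-in ESI+ adduct forms, keyed by name.
ADDUCTS: dict[str, Adduct] = {
    name: Adduct(name, n_m, z, shift) for name, n_m, z, shift in _ADDUCT_SPECS
}


def adduct_mz(neutral_mass: float, adduct: Adduct | str) -> float:
    """Observed m/z of ``adduct`` for a metabolite of the given neutral mass."""
    if isinstance(adduct, str):
        try:
            adduct = ADDUCTS[adduct]
        except KeyError:
            raise KeyError(f"unknown adduct {adduct!r}") from None
    if not neutral_mass > 0:
        raise ValueError("neutral_mass must be > 0")
    return (
        adduct.n_m * neutral_mass + adduct.shift_mass - adduct.charge * ELECTRON_MASS
    ) / adduct.charge


def neutral_from_adduct_mz(mz: float, adduct: Adduct | str) -> float:
    """Inverse of :func:`adduct_mz`: neutral mass implied by an observed m/z."""
    if isinstance(adduct, str):
        adduct = ADDUCTS[adduct]
    return (mz * adduct.charge - adduct.shift_mass + adduct.charge * ELECTRON_MASS) / adduct.n_m


# ---------------------------------------------------------------------------
# database pre-annotation
# ---------------------------------------------------------------------------

class _AdductIndex:
    """Vectorised (entry x adduct) m/z lookup over a metabolite database."""

    def __init__(self, database: list[LibraryEntry], adducts: dict[str, Adduct]):
        mzs, meta = [], []
        for e in database:
            for a in adducts.values():
                mzs.append(adduct_mz(e.neutral_mass, a))
                meta.append((e.metabolite_id, a.name))
        self.mz = np.array(mzs)
        self.meta = meta

    def query(self, mz: float, ppm_tol: float) -> list[tuple[str, str, float]]:
        err = 1e6 * (mz - self.mz) / self.mz
        idx = np.flatnonzero(np.abs(err) <= ppm_tol)
        hits = [(self.meta[i][0], self.meta[i][1], float(err[i])) for i in idx]
        hits.sort(key=lambda h: abs(h[2]))
        return hits


def preannotate(
    mz: float,
    database: list[LibraryEntry],
    adducts: dict[str, Adduct] | None = None,
    ppm_tol: float = 20.0,
    _index: _AdductIndex | None = None,
) -> list[tuple[str, str, float]]:
    """All (metabolite_id, adduct, ppm_error) whose adduct m/z matches within tolerance.

    Results are sorted by absolute ppm error; an empty list is a valid result.
    """
    if _index is None:
        if not database:
            raise ValueError("database must be non-empty")
        _index = _AdductIndex(database, adducts or ADDUCTS)
    return _index.query(mz, ppm_tol)


# ---------------------------------------------------------------------------
# inclusion lists
# ---------------------------------------------------------------------------

@dataclass
class InclusionEntry:
    """A targeted precursor: m/z with an RT window and its provenance."""

    mz: float
    rt: float
    rt_window: float
    feature_ref: str
    provenance: str  # 'informative' | 'preannotated'
    candidate_metabolites: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.provenance not in ("informative", "preannotated"):
            raise ValueError(f"unknown provenance {self.provenance!r}")
        if self.provenance == "preannotated" and not self.candidate_metabolites:
            raise ValueError("preannotated entries need at least one candidate")


def _screened(table: PeakTable, ratio_threshold: float) -> PeakTable:
    """Label + pcgroup + isotope-flag a conditioning batch if not already done."""
    from . import feature_screen as fs

    if any(f.label == "unlabeled" for f in table.features):
        table = fs.classify_informative(table, ratio_threshold)
    if all(f.pcgroup is None for f in table.features) and len(table.sample_ids()) - len(
        table.sample_ids("blank")
    ) >= 3:
        table = fs.group_pseudospectra(table)
        table = fs.flag_isotopologues(table)
    return table


def build_inclusion_informative(
    initial_batch: PeakTable,
    ratio_threshold: float = 6.0,
    rt_window: float = 0.1,
) -> list[InclusionEntry]:
    """Inclusion list of blank-ratio-informative features (13C isotopologues excluded)."""
    table = _screened(initial_batch, ratio_threshold)
    return [
        InclusionEntry(f.mz, f.rt, rt_window, f.feature_id, "informative")
        for f in table.features
        if f.label == "informative" and f.isotope_flag != "c13_isotopologue"
    ]


def build_inclusion_preannotated(
    initial_batch: PeakTable,
    database: list[LibraryEntry],
    adducts: dict[str, Adduct] | None = None,
    ppm_tol: float = 20.0,
    rt_window: float = 0.1,
) -> list[InclusionEntry]:
    """Inclusion list of blank-absent, database-preannotatable features.

    A feature qualifies only if its intensity is 0 in *every* blank and its
    m/z matches at least one (metabolite, adduct) pair within ``ppm_tol``.
    """
    blanks = initial_batch.sample_ids("blank")
    qcs = initial_batch.sample_ids("qc")
    if not blanks or not qcs:
        raise ValueError("initial batch must contain blanks and QCs")
    table = _screened(initial_batch, 6.0)
    index = _AdductIndex(database, adducts or ADDUCTS)
    out = []
    for f in table.features:
        if f.isotope_flag == "c13_isotopologue":
            continue
        if any(f.intensity.get(b, 0.0) > 0 for b in blanks):
            continue
        hits = index.query(f.mz, ppm_tol)
        if not hits:
            continue
        out.append(
            InclusionEntry(
                f.mz,
                f.rt,
                rt_window,
                f.feature_id,
                "preannotated",
                [(m, a) for m, a, _ in hits],
            )
        )
    return out


def prune_inclusion(
    entries: list[InclusionEntry],
    acquired: list[MS2Spectrum],
    tol: ToleranceSpec = ToleranceSpec(),
) -> list[InclusionEntry]:
    """Drop entries covered by at least one acquired spectrum.

    A spectrum covers an entry when its precursor m/z is within ``tol.ppm``
    and its RT within the entry's own window.  Idempotent and monotone: the
    result is always a subset of the input.
    """
    if not acquired or not entries:
        return list(entries)
    smz = np.array([s.precursor_mz for s in acquired])
    srt = np.array([s.precursor_rt for s in acquired])
    kept = []
    for e in entries:
        err = np.abs(1e6 * (smz - e.mz) / e.mz)
        hit = (err <= tol.ppm) & (np.abs(srt - e.rt) <= e.rt_window)
        if not hit.any():
            kept.append(e)
    return kept
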