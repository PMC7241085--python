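"""Cycle-by-cycle in-silico data-dependent MS2 acquisition.

The engine replays an LC-MS run model (Gaussian chromatographic peaks) as a
sequence of survey scans and data-dependent MS2 events, mimicking a QTOF
operated at 5 Hz: each cycle takes one survey scan plus one scan per MS2
event, so the cycle clock advances by ``(1 + k) / scan_hz`` seconds.  Up to
five precursors are picked per cycle by descending intensity, subject to the
m/z working range (or the current i-DDA band), an optional inclusion list
(targeted modes), a minimum precursor intensity, and dynamic exclusion: a
precursor selected in two consecutive cycles is banned for 0.15 min.

Four strategies are provided:

* ``dda``      - untargeted, one run over the full 70-1500 m/z range;
* ``idda``     - untargeted iterated, one run per m/z band (seven bands);
* ``targeted`` - dynamic iterated acquisition from an inclusion list, the
                 list being pruned between consecutive runs (the xcms-DDA
                 and hmdb-DDA modes differ only in how the list was built).

Co-eluting ions inside the +/-2 Da isolation window co-fragment, producing
chimeric spectra whose ``truth_sources`` list every contributor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .model_io import FragmentPeak, MS2Spectrum, PeakTable, ToleranceSpec
from .precursor_targets import InclusionEntry, prune_inclusion
from .synthetic_data import RunModel

__all__ = [
    "MethodConfig",
    "AcquisitionEvent",
    "ExclusionRecord",
    "ExclusionState",
    "AcquisitionResult",
    "survey_scan",
    "select_precursors",
    "update_exclusion",
    "acquire_ms2",
    "run_strategy",
    "assign_events_to_features",
    "audit_acquisition",
]

DEFAULT_BANDS = [
    (70.0, 200.0),
    (200.0, 400.0),
    (400.0, 600.0),
    (600.0, 800.0),
    (800.0, 1000.0),
    (1000.0, 1250.0),
    (1250.0, 1500.0),
]

#: same-precursor identity for exclusion bookkeeping (ppm)
EXCLUSION_PPM = 20.0

#: ions below this survey intensity are not reported at all
SURVEY_FLOOR = 1.0


@dataclass
class MethodConfig:
    """Acquisition-method parameters (defaults follow the QTOF setup)."""

    strategy: str = "dda"  # 'dda' | 'idda' | 'targeted'
    mz_range: tuple[float, float] = (70.0, 1500.0)
    idda_bands: list[tuple[float, float]] = field(default_factory=lambda: list(DEFAULT_BANDS))
    top_n_per_cycle: int = 5
    scan_hz: float = 5.0
    isolation_halfwidth: float = 2.0  # Da; "medium" ~4 amu window
    exclusion_after_n_consecutive: int = 2
    exclusion_minutes: float = 0.15
    min_precursor_intensity: float = 3000.0
    inclusion: list[InclusionEntry] | None = None

    def __post_init__(self) -> None:
        if self.strategy not in ("dda", "idda", "targeted"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        bands = self.idda_bands
        if any(b[0] >= b[1] for b in bands):
            raise ValueError("i-DDA bands must be ascending ranges")
        if any(bands[i][1] > bands[i + 1][0] for i in range(len(bands) - 1)):
            raise ValueError("i-DDA bands must be non-overlapping and sorted")
        if self.strategy == "targeted" and self.inclusion is None:
            raise ValueError("targeted strategy requires an inclusion list")


@dataclass
class AcquisitionEvent:
    """One MS2 selection event in the acquisition log."""

    run_id: str
    cycle_index: int
    selection_rank: int
    precursor_mz: float
    rt_of_selection: float
    matched_inclusion_entry: str | None = None  # feature_ref of the entry
    spectrum: MS2Spectrum | None = None


@dataclass
class ExclusionRecord:
    mz: float
    consecutive_count: int = 1
    last_cycle: int = -1
    excluded_until: float | None = None


class ExclusionState:
    """Dynamic-exclusion bookkeeping over one run."""

    def __init__(self) -> None:
        self.records: list[ExclusionRecord] = []
        self._mz = np.empty(0)
        self._until = np.empty(0)

    def _append(self, rec: ExclusionRecord) -> None:
        self.records.append(rec)
        self._mz = np.append(self._mz, rec.mz)
        self._until = np.append(self._until, -np.inf)

    def _find_idx(self, mz: float) -> int | None:
        if not self.records:
            return None
        ppm = np.abs(1e6 * (mz - self._mz) / self._mz)
        i = int(np.argmin(ppm))
        return i if ppm[i] <= EXCLUSION_PPM else None

    def is_excluded(self, mz: float, t: float) -> bool:
        i = self._find_idx(mz)
        return i is not None and t < self._until[i]


def survey_scan(run: RunModel, t: float, floor: float = SURVEY_FLOOR) -> list[tuple[float, float]]:
    """Centroided MS1 scan at time ``t``: one (m/z, height) per eluting peak.

    Heights follow the Gaussian elution profiles; peaks below ``floor`` or
    outside the 70-1500 m/z range are dropped.
    """
    if not 0 <= t <= run.gradient_length:
        raise ValueError(f"scan time {t} outside run duration")
    out = []
    for p in run.peaks:
        h = p.height(t)
        if h >= floor and 70.0 <= p.mz <= 1500.0:
            out.append((p.mz, h))
    out.sort()
    return out


def select_precursors(
    scan: list[tuple[float, float]],
    t: float,
    state: ExclusionState,
    config: MethodConfig,
) -> list[tuple[float, float, str | None]]:
    """Pick up to ``top_n_per_cycle`` precursors from a survey scan.

    Candidates must lie in ``config.mz_range`` (run_strategy narrows this to
    the active band in i-DDA mode), match an inclusion entry in targeted
    mode (20 ppm and the entry's RT window), be above the minimum precursor
    intensity and not currently excluded.  Ranked by descending intensity,
    ties by ascending m/z.  Returns (mz, intensity, matched_entry_ref).
    """
    lo, hi = config.mz_range
    entries = config.inclusion if config.strategy == "targeted" else None
    if entries is not None:
        e_mz = np.array([e.mz for e in entries])
        e_rt = np.array([e.rt for e in entries])
        e_w = np.array([e.rt_window for e in entries])
    candidates = []
    for mz, inten in scan:
        if not lo <= mz <= hi or inten < config.min_precursor_intensity:
            continue
        entry_ref = None
        if entries is not None:
            if len(entries) == 0:
                continue
            ppm = np.abs(1e6 * (mz - e_mz) / e_mz)
            ok = (ppm <= 20.0) & (np.abs(t - e_rt) <= e_w)
            if not ok.any():
                continue
            entry_ref = entries[int(np.flatnonzero(ok)[np.argmin(ppm[ok])])].feature_ref
        if state.is_excluded(mz, t):
            continue
        candidates.append((mz, inten, entry_ref))
    candidates.sort(key=lambda c: (-c[1], c[0]))
    return candidates[: config.top_n_per_cycle]


def update_exclusion(
    state: ExclusionState,
    selected: list[float],
    t: float,
    config: MethodConfig,
    cycle_index: int = 0,
) -> ExclusionState:
    """Register selections; two consecutive-cycle selections trigger exclusion.

    Same-precursor identity is 20 ppm.  The consecutive count resets to 1
    when a cycle was skipped; once it reaches
    ``exclusion_after_n_consecutive`` the precursor is excluded until
    ``t + exclusion_minutes``.
    """
    for mz in selected:
        i = state._find_idx(mz)
        if i is None:
            rec = ExclusionRecord(mz=mz, consecutive_count=1)
            state._append(rec)
            i = len(state.records) - 1
        else:
            rec = state.records[i]
            if rec.last_cycle == cycle_index - 1:
                rec.consecutive_count += 1
            elif rec.last_cycle != cycle_index:
                rec.consecutive_count = 1
        rec.last_cycle = cycle_index
        if rec.consecutive_count >= config.exclusion_after_n_consecutive:
            rec.excluded_until = t + config.exclusion_minutes
            state._until[i] = rec.excluded_until
    return state


def _run_arrays(run: RunModel) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Cached (mz, apex_rt, sigma, apex_height) arrays for a run model."""
    cached = run.__dict__.get("_cached_arrays")
    if cached is None or len(cached[0]) != len(run.peaks):
        cached = (
            np.array([p.mz for p in run.peaks]),
            np.array([p.apex_rt for p in run.peaks]),
            np.array([p.sigma for p in run.peaks]),
            np.array([p.apex_height for p in run.peaks]),
        )
        run.__dict__["_cached_arrays"] = cached
    return cached


def acquire_ms2(
    run: RunModel,
    precursor_mz: float,
    t: float,
    isolation_halfwidth: float = 2.0,
    run_id: str | None = None,
    cycle_index: int = 0,
) -> MS2Spectrum:
    """Fragment everything inside the isolation window at time ``t``.

    The fragment list is the union of the co-isolated ions' reference
    spectra, each scaled by its elution height at selection time; chimeric
    spectra carry every contributor in ``truth_sources`` (most intense
    first).
    """
    mzs, apex, sigma, h0 = _run_arrays(run)
    idx = np.flatnonzero(np.abs(mzs - precursor_mz) <= isolation_halfwidth)
    contributors = []
    for i in idx:
        h = h0[i] * math.exp(-((t - apex[i]) ** 2) / (2 * sigma[i] ** 2))
        if h >= SURVEY_FLOOR:
            contributors.append((h, run.peaks[int(i)]))
    contributors.sort(key=lambda c: -c[0])
    merged: dict[float, float] = {}
    sources: list[str] = []
    for h, p in contributors:
        src = p.source_metabolite
        if src is None:
            continue
        template = run.fragment_truth.get(src)
        if template is None:
            continue
        if src not in sources:
            sources.append(src)
        for frag in template:
            merged[frag.mz] = merged.get(frag.mz, 0.0) + frag.intensity / 100.0 * h
    fragments = [FragmentPeak(m, i) for m, i in sorted(merged.items())]
    return MS2Spectrum(
        precursor_mz=precursor_mz,
        precursor_rt=t,
        run_id=run_id if run_id is not None else run.sample.sample_id,
        cycle_index=cycle_index,
        fragments=fragments,
        truth_sources=sources or None,
    )


def _simulate_run(run: RunModel, config: MethodConfig) -> tuple[list[AcquisitionEvent], list[MS2Spectrum]]:
    mzs, apex, sigma, h0 = _run_arrays(run)
    state = ExclusionState()
    events: list[AcquisitionEvent] = []
    spectra: list[MS2Spectrum] = []
    t = 0.0
    cycle = 0
    run_id = run.sample.sample_id
    while t < run.gradient_length:
        active = np.abs(t - apex) <= 6.0 * sigma
        if active.any():
            h = h0[active] * np.exp(-((t - apex[active]) ** 2) / (2 * sigma[active] ** 2))
            keep = (h >= SURVEY_FLOOR) & (mzs[active] >= 70.0) & (mzs[active] <= 1500.0)
            scan = sorted(zip(mzs[active][keep].tolist(), h[keep].tolist()))
        else:
            scan = []
        selected = select_precursors(scan, t, state, config)
        for rank, (pmz, _inten, entry_ref) in enumerate(selected, start=1):
            spec = acquire_ms2(
                run, pmz, t, config.isolation_halfwidth, run_id=run_id, cycle_index=cycle
            )
            spectra.append(spec)
            events.append(
                AcquisitionEvent(
                    run_id=run_id,
                    cycle_index=cycle,
                    selection_rank=rank,
                    precursor_mz=pmz,
                    rt_of_selection=t,
                    matched_inclusion_entry=entry_ref,
                    spectrum=spec,
                )
            )
        update_exclusion(state, [s[0] for s in selected], t, config, cycle_index=cycle)
        t += (1 + len(selected)) / config.scan_hz / 60.0
        cycle += 1
    return events, spectra


@dataclass
class AcquisitionResult:
    """Full acquisition log of one strategy across its runs."""

    strategy: str
    events_per_run: list[list[AcquisitionEvent]]
    spectra: list[MS2Spectrum]
    per_run_counts: list[int]
    run_ids: list[str]
    band_per_run: list[tuple[float, float] | None]
    inclusion_initial: list[InclusionEntry] | None = None
    inclusion_final: list[InclusionEntry] | None = None

    @property
    def events(self) -> list[AcquisitionEvent]:
        return [e for run in self.events_per_run for e in run]


def run_strategy(
    strategy: str,
    runs: list[RunModel],
    config: MethodConfig | None = None,
    inclusion: list[InclusionEntry] | None = None,
    tol: ToleranceSpec = ToleranceSpec(),
) -> AcquisitionResult:
    """Execute a DDA strategy over consecutive QC injections.

    ``dda`` uses the first run only; ``idda`` uses one run per m/z band;
    ``targeted`` iterates runs, pruning the inclusion list after each run
    and stopping early once it is empty.
    """
    config = replace(config) if config is not None else MethodConfig()
    config.strategy = strategy
    if inclusion is not None:
        config.inclusion = list(inclusion)
    if strategy == "targeted" and config.inclusion is None:
        raise ValueError("targeted strategy requires an inclusion list")

    events_per_run: list[list[AcquisitionEvent]] = []
    spectra: list[MS2Spectrum] = []
    run_ids: list[str] = []
    bands: list[tuple[float, float] | None] = []

    if strategy == "dda":
        plan = [(runs[0], config.mz_range)]
        for run, band in plan:
            ev, sp = _simulate_run(run, replace(config, mz_range=band))
            events_per_run.append(ev)
            spectra.extend(sp)
            run_ids.append(run.sample.sample_id)
            bands.append(None)
    elif strategy == "idda":
        if len(runs) < len(config.idda_bands):
            raise ValueError(
                f"i-DDA needs {len(config.idda_bands)} runs, got {len(runs)}"
            )
        for run, band in zip(runs, config.idda_bands):
            ev, sp = _simulate_run(run, replace(config, mz_range=band))
            events_per_run.append(ev)
            spectra.extend(sp)
            run_ids.append(run.sample.sample_id)
            bands.append(band)
    else:  # targeted
        current = list(config.inclusion or [])
        initial = list(current)
        for run in runs:
            if not current:
                break
            ev, sp = _simulate_run(run, replace(config, inclusion=current))
            events_per_run.append(ev)
            spectra.extend(sp)
            run_ids.append(run.sample.sample_id)
            bands.append(None)
            current = prune_inclusion(current, sp, tol)
        result = AcquisitionResult(
            strategy=strategy,
            events_per_run=events_per_run,
            spectra=spectra,
            per_run_counts=[len(e) for e in events_per_run],
            run_ids=run_ids,
            band_per_run=bands,
            inclusion_initial=initial,
            inclusion_final=current,
        )
        return result

    return AcquisitionResult(
        strategy=strategy,
        events_per_run=events_per_run,
        spectra=spectra,
        per_run_counts=[len(e) for e in events_per_run],
        run_ids=run_ids,
        band_per_run=bands,
    )


def assign_events_to_features(
    spectra: list[MS2Spectrum],
    table: PeakTable,
    tol: ToleranceSpec = ToleranceSpec(),
) -> tuple[list[str | None], dict[str, int]]:
    """Assign each spectrum to the nearest labeled feature within tolerance.

    A spectrum matches features within ``tol.ppm`` m/z and ``tol.rt`` RT;
    the nearest by combined normalised distance wins.  The summary
    partitions all spectra into informative / noise / unassigned counts.
    """
    fmz = table.mz_array()
    frt = table.rt_array()
    labels = [f.label for f in table.features]
    fids = [f.feature_id for f in table.features]
    assigned: list[str | None] = []
    summary = {"n_informative": 0, "n_noise": 0, "n_unassigned": 0, "n_total": 0}
    ppm_den = tol.ppm if tol.ppm > 0 else 1.0
    rt_den = tol.rt if tol.rt > 0 else 1.0
    for s in spectra:
        ppm = np.abs(1e6 * (s.precursor_mz - fmz) / fmz)
        drt = np.abs(s.precursor_rt - frt)
        ok = (ppm <= tol.ppm) & (drt <= tol.rt)
        summary["n_total"] += 1
        if not ok.any():
            assigned.append(None)
            summary["n_unassigned"] += 1
            continue
        idx = np.flatnonzero(ok)
        best = idx[np.argmin(ppm[idx] / ppm_den + drt[idx] / rt_den)]
        assigned.append(fids[best])
        if labels[best] == "informative":
            summary["n_informative"] += 1
        else:
            summary["n_noise"] += 1
    return assigned, summary


def audit_acquisition(result: AcquisitionResult, config: MethodConfig | None = None) -> list[str]:
    """Post-hoc audit of an acquisition log; returns human-readable violations.

    Independently re-checks, from the event stream alone: at most
    ``top_n_per_cycle`` events per cycle; band / m/z-range confinement;
    targeted-mode inclusion confinement; and the dynamic-exclusion rule (no
    re-selection within ``exclusion_minutes`` of a second consecutive
    selection).
    """
    config = config or MethodConfig()
    violations: list[str] = []
    for run_events, band in zip(result.events_per_run, result.band_per_run):
        per_cycle: dict[int, int] = {}
        for e in run_events:
            per_cycle[e.cycle_index] = per_cycle.get(e.cycle_index, 0) + 1
        for c, n in per_cycle.items():
            if n > config.top_n_per_cycle:
                violations.append(f"run {run_events[0].run_id}: {n} events in cycle {c}")
        lo, hi = band if band is not None else config.mz_range
        for e in run_events:
            if not lo <= e.precursor_mz <= hi:
                violations.append(
                    f"run {e.run_id} cycle {e.cycle_index}: precursor {e.precursor_mz:.4f} "
                    f"outside [{lo}, {hi}]"
                )
        if result.strategy == "targeted":
            for e in run_events:
                if e.matched_inclusion_entry is None:
                    violations.append(
                        f"run {e.run_id} cycle {e.cycle_index}: targeted selection "
                        f"{e.precursor_mz:.4f} matches no inclusion entry"
                    )
        # replay the exclusion rule from the log, cycle by cycle: exclusion
        # windows take effect at the end of the cycle that triggered them
        track: list[ExclusionRecord] = []

        def find(mz: float) -> ExclusionRecord | None:
            rec, best_ppm = None, EXCLUSION_PPM
            for r in track:
                p = abs(1e6 * (mz - r.mz) / r.mz)
                if p <= best_ppm:
                    rec, best_ppm = r, p
            return rec

        by_cycle: dict[int, list[AcquisitionEvent]] = {}
        for e in run_events:
            by_cycle.setdefault(e.cycle_index, []).append(e)
        for cycle in sorted(by_cycle):
            cycle_events = sorted(by_cycle[cycle], key=lambda e: e.selection_rank)
            for e in cycle_events:
                rec = find(e.precursor_mz)
                if (
                    rec is not None
                    and rec.excluded_until is not None
                    and e.rt_of_selection < rec.excluded_until
                ):
                    violations.append(
                        f"run {e.run_id} cycle {e.cycle_index}: {e.precursor_mz:.4f} "
                        f"selected while excluded until {rec.excluded_until:.3f}"
                    )
            for e in cycle_events:
                rec = find(e.precursor_mz)
                if rec is None:
                    rec = ExclusionRecord(mz=e.precursor_mz, consecutive_count=1)
                    track.append(rec)
                elif rec.last_cycle == cycle - 1:
                    rec.consecutive_count += 1
                elif rec.last_cycle != cycle:
                    rec.consecutive_count = 1
                rec.last_cycle = cycle
                if rec.consecutive_count >= config.exclusion_after_n_consecutive:
                    rec.excluded_until = e.rt_of_selection + config.exclusion_minutes
    return violations
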