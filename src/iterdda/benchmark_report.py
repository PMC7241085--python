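"""Strategy-comparison analytics and the end-to-end benchmark driver.

Ties the whole pipeline together: generate a synthetic batch, screen the
peak tables, build inclusion lists from the conditioning batch, execute the
four acquisition strategies (untargeted DDA, iterated i-DDA, and the two
targeted dynamic modes xcms-DDA / hmdb-DDA), assign spectra to features,
annotate them, and summarise coverage, overlap and selection bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .acquisition_sim import (
    AcquisitionResult,
    MethodConfig,
    assign_events_to_features,
    run_strategy,
)
from .feature_screen import classify_informative
from .model_io import Feature, PeakTable, ToleranceSpec
from .precursor_targets import (
    _AdductIndex,
    ADDUCTS,
    build_inclusion_informative,
    build_inclusion_preannotated,
)
from .spectral_annotation import AnnotationResult, MatchParameters, annotate_spectrum
from .synthetic_data import BatchDesign, GroundTruth, RunModel, generate_batch, generate_library

__all__ = [
    "StrategyOutcome",
    "BenchmarkResult",
    "run_benchmark",
    "strategy_summary",
    "overlap_sets",
    "coverage_curve",
    "bias_summary",
    "informative_coverage",
]


def _round_pct(part: float, total: float) -> int:
    """Percentage rounded half away from zero, as printed in reports (79%, 72%...)."""
    if total == 0:
        return 0
    x = 100.0 * part / total
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


@dataclass
class StrategyOutcome:
    """Everything measured for one acquisition strategy."""

    name: str
    acquisition: AcquisitionResult
    assigned: list[str | None]
    summary: dict[str, int]
    fragmented_features: set[str]
    annotations: list[AnnotationResult] = field(default_factory=list)
    annotated_per_run: list[list[str]] = field(default_factory=list)  # metabolite ids


@dataclass
class BenchmarkResult:
    design: BatchDesign
    library: list
    initial_table: PeakTable
    sample_table: PeakTable  # labeled
    runs: list[RunModel]
    truth: GroundTruth
    outcomes: dict[str, StrategyOutcome]


def run_benchmark(
    design: BatchDesign,
    library: list | None = None,
    strategies: Sequence[str] = ("dda", "idda", "xcms", "hmdb"),
    n_targeted_runs: int = 6,
    config: MethodConfig | None = None,
    annotate: bool = True,
    tol: ToleranceSpec = ToleranceSpec(),
    params: MatchParameters = MatchParameters(),
    database_coverage: float = 1.0,
) -> BenchmarkResult:
    """Generate one synthetic batch and run the full strategy comparison on it.

    ``database_coverage`` < 1 withholds a fraction of the metabolite library
    from the database used for hmdb-mode inclusion building and for
    annotation, emulating real databases that do not contain every compound
    in the sample.
    """
    if library is None:
        library = generate_library(design.n_metabolites, seed=design.seed)
    initial, sample_table, runs, truth = generate_batch(design, library)
    sample_table = classify_informative(sample_table)
    base_config = config or MethodConfig()
    database = library[: max(1, round(database_coverage * len(library)))]
    index = _AdductIndex(database, ADDUCTS) if annotate else None

    outcomes: dict[str, StrategyOutcome] = {}
    for name in strategies:
        if name == "dda":
            acq = run_strategy("dda", runs[:1], base_config)
        elif name == "idda":
            acq = run_strategy("idda", runs, base_config)
        elif name == "xcms":
            inc = build_inclusion_informative(initial)
            acq = run_strategy("targeted", runs[:n_targeted_runs], base_config, inclusion=inc)
        elif name == "hmdb":
            inc = build_inclusion_preannotated(initial, database)
            acq = run_strategy("targeted", runs[:n_targeted_runs], base_config, inclusion=inc)
        else:
            raise ValueError(f"unknown strategy {name!r}")
        assigned, summary = assign_events_to_features(acq.spectra, sample_table, tol)
        fragmented = {a for a in assigned if a is not None}
        outcome = StrategyOutcome(
            name=name,
            acquisition=acq,
            assigned=assigned,
            summary=summary,
            fragmented_features=fragmented,
        )
        if annotate:
            run_order = {rid: k for k, rid in enumerate(acq.run_ids)}
            per_run: list[list[str]] = [[] for _ in acq.run_ids]
            for spec in acq.spectra:
                res = annotate_spectrum(spec, database, params=params, _index=index)
                outcome.annotations.extend(res)
                for r in res:
                    per_run[run_order[spec.run_id]].append(r.metabolite_id)
            outcome.annotated_per_run = per_run
        outcomes[name] = outcome
    return BenchmarkResult(
        design=design,
        library=library,
        initial_table=initial,
        sample_table=sample_table,
        runs=runs,
        truth=truth,
        outcomes=outcomes,
    )


def informative_coverage(bench: BenchmarkResult) -> dict[str, float]:
    """Fraction of monoisotopic informative features fragmented, per strategy.

    13C isotopologue features are excluded from the denominator: fragmenting
    them is redundant by construction (they duplicate their monoisotopic
    partner's spectrum) and the targeted modes exclude them from inclusion
    lists on purpose, so counting them would penalise exactly the behaviour
    the strategies are designed for.
    """
    denom = {
        fid
        for fid, t in bench.truth.feature_truth.items()
        if t.source == "metabolite-adduct" and not t.is_isotopologue
    }
    table_ids = {f.feature_id for f in bench.sample_table.features}
    denom &= table_ids
    return {
        name: len(o.fragmented_features & denom) / len(denom) if denom else float("nan")
        for name, o in bench.outcomes.items()
    }


# ---------------------------------------------------------------------------
# report tables
# ---------------------------------------------------------------------------

def strategy_summary(outcomes: dict[str, StrategyOutcome]) -> pd.DataFrame:
    """Per-strategy spectra counts and informative/noise percentages.

    Counts are conserved (informative + noise + unassigned = total); the
    percentage columns are integers rounded half away from zero.  A
    strategy with zero spectra is flagged in the ``empty`` column.
    """
    rows = []
    for name, o in outcomes.items():
        total = o.summary["n_total"]
        rows.append(
            {
                "strategy": name,
                "runs": len(o.acquisition.events_per_run),
                "total_spectra": total,
                "per_run": list(o.acquisition.per_run_counts),
                "informative": o.summary["n_informative"],
                "noise": o.summary["n_noise"],
                "unassigned": o.summary["n_unassigned"],
                "pct_informative": _round_pct(o.summary["n_informative"], total),
                "pct_noise": _round_pct(o.summary["n_noise"], total),
                "empty": total == 0,
            }
        )
    return pd.DataFrame(rows)


def overlap_sets(
    fragmented: dict[str, Iterable[Feature | tuple[float, float]]],
    tol: ToleranceSpec = ToleranceSpec(ppm=20.0, rt=0.1),
) -> tuple[dict[frozenset[str], int], dict[tuple[str, str], float]]:
    """UpSet-style overlap of fragmented-feature sets across strategies.

    Features from different strategies are matched by tolerance (ppm m/z and
    RT); the pooled features are linked into clusters and each cluster
    contributes one count to the intersection pattern of the strategies it
    contains.  Also returns the containment percentage for every ordered
    strategy pair (how much of ``a`` is shared with ``b``).
    """
    if len(fragmented) < 2:
        raise ValueError("overlap needs at least 2 strategies")
    points: list[tuple[float, float, str]] = []
    for name, feats in fragmented.items():
        for f in feats:
            mz, rt = (f.mz, f.rt) if isinstance(f, Feature) else (f[0], f[1])
            points.append((mz, rt, name))
    n = len(points)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    order = sorted(range(n), key=lambda i: points[i][0])
    for a_pos, i in enumerate(order):
        mz_i, rt_i, _ = points[i]
        for j in order[a_pos + 1 :]:
            mz_j, rt_j, _ = points[j]
            if 1e6 * (mz_j - mz_i) / mz_i > tol.ppm:
                break
            if abs(rt_j - rt_i) <= tol.rt:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    clusters: dict[int, set[str]] = {}
    for i in range(n):
        clusters.setdefault(find(i), set()).add(points[i][2])
    patterns: dict[frozenset[str], int] = {}
    for members in clusters.values():
        key = frozenset(members)
        patterns[key] = patterns.get(key, 0) + 1
    names = list(fragmented)
    containment: dict[tuple[str, str], float] = {}
    for a in names:
        n_a = sum(c for k, c in patterns.items() if a in k)
        for b in names:
            if a == b:
                continue
            n_ab = sum(c for k, c in patterns.items() if a in k and b in k)
            containment[(a, b)] = 100.0 * n_ab / n_a if n_a else 0.0
    return patterns, containment


def coverage_curve(annotated_per_run: list[list[str]]) -> list[int]:
    """Cumulative count of distinct annotated metabolites after each run."""
    seen: set[str] = set()
    out = []
    for run in annotated_per_run:
        seen.update(run)
        out.append(len(seen))
    return out


def bias_summary(
    fragmented_ids: set[str],
    table: PeakTable,
    co_elution_window: float = 0.05,
    labels: tuple[str, ...] = ("informative",),
) -> dict:
    """Intensity / co-elution bias of precursor selection.

    For the features carrying one of ``labels``, reports the median (over
    features) of the median non-blank intensity, separately for fragmented
    and unfragmented features, their ratio (``bias_ratio`` > 1 means
    selection favours intense ions), and the mean number of co-eluting ions
    (features within the RT window) in each group.
    """
    non_blank = [s.sample_id for s in table.samples if s.cls != "blank"]
    feats = [f for f in table.features if f.label in labels]
    rts = np.array([f.rt for f in feats])
    med_int = np.array(
        [float(np.median([f.intensity.get(s, 0.0) for s in non_blank])) for f in feats]
    )
    all_rts = table.rt_array()
    n_coel = np.array(
        [int((np.abs(all_rts - f.rt) <= co_elution_window).sum() - 1) for f in feats]
    )
    is_frag = np.array([f.feature_id in fragmented_ids for f in feats])
    out: dict = {
        "n_fragmented": int(is_frag.sum()),
        "n_unfragmented": int((~is_frag).sum()),
    }
    med_f = float(np.median(med_int[is_frag])) if is_frag.any() else float("nan")
    med_u = float(np.median(med_int[~is_frag])) if (~is_frag).any() else float("nan")
    out["median_intensity_fragmented"] = med_f
    out["median_intensity_unfragmented"] = med_u
    if is_frag.all() or not is_frag.any():
        out["bias_ratio"] = 1.0 if is_frag.any() else float("nan")
    else:
        out["bias_ratio"] = med_f / med_u if med_u > 0 else float("inf")
    out["mean_coeluting_fragmented"] = float(n_coel[is_frag].mean()) if is_frag.any() else float("nan")
    out["mean_coeluting_unfragmented"] = (
        float(n_coel[~is_frag].mean()) if (~is_frag).any() else float("nan")
    )
    return out
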