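"""QA/QC screening of LC-MS peak tables.

Implements the blank-ratio rule used to separate informative from noise
features (a feature is informative when its minimum QC intensity exceeds six
times its maximum blank intensity), tolerance-based alignment of feature
tables across batches, a simplified pseudospectrum grouping (co-elution plus
cross-sample intensity correlation), and 13C-isotopologue flagging within
pseudospectra.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .model_io import Feature, PeakTable, ToleranceSpec

__all__ = [
    "classify_informative",
    "AlignmentResult",
    "align_feature_tables",
    "group_pseudospectra",
    "flag_isotopologues",
]

C13_C12_DELTA = 1.003355  # Da, 13C - 12C


def classify_informative(table: PeakTable, ratio_threshold: float = 6.0) -> PeakTable:
    """Label every feature informative or noise by the blank-ratio rule.

    informative  iff  min over QCs / max over blanks > ratio_threshold.
    A feature never detected in blanks (max blank = 0) but seen in every QC
    is informative; a feature missing from any QC (min QC = 0) is noise.
    Returns a new table; the partition is total (no feature stays unlabeled).
    """
    blanks = table.sample_ids("blank")
    qcs = table.sample_ids("qc")
    if not blanks or not qcs:
        raise ValueError("classification needs at least one blank and one QC")
    features = []
    for f in table.features:
        qc_min = min(f.intensity.get(s, 0.0) for s in qcs)
        blank_max = max(f.intensity.get(s, 0.0) for s in blanks)
        if qc_min <= 0:
            label = "noise"
        elif blank_max <= 0:
            label = "informative"
        else:
            label = "informative" if qc_min / blank_max > ratio_threshold else "noise"
        features.append(replace(f, intensity=dict(f.intensity), label=label))
    return PeakTable(samples=list(table.samples), features=features)


@dataclass
class AlignmentResult:
    """Outcome of aligning two feature tables."""

    matched: list[tuple[str, str]]  # (feature_id in a, feature_id in b)
    unique_a: list[str]
    unique_b: list[str]
    delta_mz: list[float]  # b - a, per matched pair
    delta_rt: list[float]


def align_feature_tables(
    a: PeakTable,
    b: PeakTable,
    tol: ToleranceSpec = ToleranceSpec(),
) -> AlignmentResult:
    """One-to-one greedy alignment of two tables within absolute m/z / RT tolerances.

    Candidate pairs (|dmz| <= tol.mz_abs and |drt| <= tol.rt) are consumed in
    ascending combined distance ``|dmz|/tol.mz_abs + |drt|/tol.rt``; each
    feature matches at most once.  Swapping the inputs swaps the unique sets
    and negates the deltas.
    """
    amz, art = a.mz_array(), a.rt_array()
    bmz, brt = b.mz_array(), b.rt_array()
    if len(amz) and len(bmz):
        dmz = bmz[None, :] - amz[:, None]
        drt = brt[None, :] - art[:, None]
        ok = (np.abs(dmz) <= tol.mz_abs) & (np.abs(drt) <= tol.rt)
        ii, jj = np.nonzero(ok)
        # guard the degenerate zero-tolerance case
        mz_den = tol.mz_abs if tol.mz_abs > 0 else 1.0
        rt_den = tol.rt if tol.rt > 0 else 1.0
        dist = np.abs(dmz[ii, jj]) / mz_den + np.abs(drt[ii, jj]) / rt_den
        order = np.argsort(dist, kind="stable")
    else:
        ii = jj = order = np.array([], dtype=int)
    used_a: set[int] = set()
    used_b: set[int] = set()
    matched, d_mz, d_rt = [], [], []
    for k in order:
        i, j = int(ii[k]), int(jj[k])
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        matched.append((a.features[i].feature_id, b.features[j].feature_id))
        d_mz.append(float(bmz[j] - amz[i]))
        d_rt.append(float(brt[j] - art[i]))
    unique_a = [f.feature_id for i, f in enumerate(a.features) if i not in used_a]
    unique_b = [f.feature_id for j, f in enumerate(b.features) if j not in used_b]
    return AlignmentResult(matched, unique_a, unique_b, d_mz, d_rt)


def group_pseudospectra(
    table: PeakTable,
    rt_tol: float = 0.05,
    min_corr: float = 0.75,
) -> PeakTable:
    """Assign pcgroups: connected components of the co-elution/correlation graph.

    Two features are linked when |dRT| <= rt_tol and the Pearson correlation
    of their log-intensities across non-blank samples is >= min_corr.  This
    is a deliberately simple stand-in for full pseudospectrum deconvolution
    (peak-shape analysis is out of scope; synthetic tables are pre-aligned).
    """
    non_blank = [s.sample_id for s in table.samples if s.cls != "blank"]
    if len(non_blank) < 3:
        raise ValueError("pseudospectrum grouping needs >= 3 non-blank samples")
    n = len(table.features)
    rts = table.rt_array()
    X = np.log1p(table.intensity_matrix(non_blank))
    # Pearson over rows; constant rows yield correlation 0 by convention
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.sqrt((Xc**2).sum(axis=1))
    safe = np.where(norms > 0, norms, 1.0)
    C = (Xc / safe[:, None]) @ (Xc / safe[:, None]).T
    C[norms == 0, :] = 0.0
    C[:, norms == 0] = 0.0
    adj = (np.abs(rts[None, :] - rts[:, None]) <= rt_tol) & (C >= min_corr)
    # union-find over the adjacency graph
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in zip(*np.nonzero(np.triu(adj, k=1))):
        ri, rj = find(int(i)), find(int(j))
        if ri != rj:
            parent[rj] = ri
    roots: dict[int, int] = {}
    features = []
    for i, f in enumerate(table.features):
        r = find(i)
        gid = roots.setdefault(r, len(roots) + 1)
        features.append(replace(f, intensity=dict(f.intensity), pcgroup=gid))
    return PeakTable(samples=list(table.samples), features=features)


def flag_isotopologues(
    table: PeakTable,
    charge_states: tuple[int, ...] = (1, 2),
    ppm_tol: float = 20.0,
) -> PeakTable:
    """Flag 13C isotopologues within pseudospectra.

    A feature is flagged when a same-pcgroup partner sits at
    ``mz - 1.003355/z`` within ``ppm_tol`` for some charge state and the
    feature's intensity never exceeds that partner's in any QC.  Everything
    else is flagged monoisotopic.
    """
    qcs = table.sample_ids("qc")
    features = [replace(f, intensity=dict(f.intensity)) for f in table.features]
    by_group: dict[int | None, list[Feature]] = {}
    for f in features:
        by_group.setdefault(f.pcgroup, []).append(f)
    for f in features:
        f.isotope_flag = "monoisotopic"
        group = by_group.get(f.pcgroup, []) if f.pcgroup is not None else [f]
        for partner in group:
            if partner is f:
                continue
            for z in charge_states:
                target = f.mz - C13_C12_DELTA / z
                if abs(1e6 * (partner.mz - target) / target) > ppm_tol:
                    continue
                if all(
                    f.intensity.get(s, 0.0) <= partner.intensity.get(s, 0.0)
                    for s in qcs
                ):
                    f.isotope_flag = "c13_isotopologue"
            if f.isotope_flag == "c13_isotopologue":
                break
    return PeakTable(samples=list(table.samples), features=features)
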