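"""Weighted dot-product scoring, ion matching and spectrum annotation."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from iterdda import (
    FragmentPeak,
    LibraryEntry,
    MS2Spectrum,
    adduct_mz,
    annotate_spectrum,
    dot_products,
    filter_peaks,
    label_fragments,
    match_ions,
    mean_score,
)
from iterdda.spectral_annotation import IonPairing, MatchParameters


def brute_force_dot_products(pairing, exp, ref, params):
    """Independent evaluation of the weighted-cosine formula via explicit vectors.

    Builds the union ion vectors literally: one coordinate per matched pair,
    per experimental-only ion and per reference-only ion, then applies
    dp = (sum a_e a_r)^2 / (sum a_e^2 * sum a_r^2) with A = I^m * mz^n.
    """
    if not exp or not ref:
        return 0.0, 0.0
    A_e, A_r = [], []
    for i, j in pairing.pairs:
        A_e.append(exp[i].intensity ** params.m * exp[i].mz ** params.n)
        A_r.append(ref[j].intensity ** params.m * ref[j].mz ** params.n)
    rA_e, rA_r = list(A_e), list(A_r)
    for i in pairing.exp_only:
        A_e.append((exp[i].intensity * params.unmatched_penalty) ** params.m * exp[i].mz ** params.n)
        A_r.append(0.0)
    for j in pairing.ref_only:
        A_e.append(0.0)
        A_r.append(ref[j].intensity ** params.m * ref[j].mz ** params.n)
    A_e, A_r = np.array(A_e), np.array(A_r)

    def formula(e, r):
        num = float(np.dot(e, r)) ** 2
        den = float(np.dot(e, e)) * float(np.dot(r, r))
        return num / den if den > 0 and num > 0 else 0.0

    return formula(A_e, A_r), formula(np.array(rA_e), np.array(rA_r))


def random_spectrum(rng, n_max=10):
    n = int(rng.integers(1, n_max + 1))
    mzs = np.sort(rng.uniform(50, 500, size=n))
    while np.any(np.diff(mzs) < 1e-3):
        mzs = np.sort(rng.uniform(50, 500, size=n))
    intens = rng.uniform(1, 1e5, size=n)
    return [FragmentPeak(float(m), float(i)) for m, i in zip(mzs, intens)]


class TestFilterPeaks:
    def test_all_below_absolute_floor(self):
        s = MS2Spectrum(300.0, 1.0, "r", 0, [FragmentPeak(100.0, 400.0), FragmentPeak(120.0, 499.0)])
        assert filter_peaks(s) == []

    def test_relative_floor(self):
        s = MS2Spectrum(300.0, 1.0, "r", 0, [FragmentPeak(100.0, 1e6), FragmentPeak(120.0, 50.0)])
        kept = filter_peaks(s)
        assert [p.mz for p in kept] == [100.0]

    def test_above_both_floors_kept(self):
        s = MS2Spectrum(300.0, 1.0, "r", 0, [FragmentPeak(100.0, 1e6), FragmentPeak(120.0, 600.0)])
        assert len(filter_peaks(s)) == 2


class TestMatchIons:
    def test_identical_lists_fully_matched(self):
        peaks = [FragmentPeak(100.0, 10.0), FragmentPeak(200.0, 20.0)]
        pairing = match_ions(peaks, list(peaks))
        assert pairing.pairs == [(0, 0), (1, 1)]
        assert pairing.exp_only == [] and pairing.ref_only == []

    def test_disjoint_lists_unmatched(self):
        a = [FragmentPeak(100.0, 10.0)]
        b = [FragmentPeak(100.1, 10.0)]  # 1000 ppm apart
        pairing = match_ions(a, b)
        assert pairing.pairs == []

    def test_nearest_wins_and_equals_min_total_ppm(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            exp = random_spectrum(rng, n_max=5)
            # refs perturbed within a few ppm so multiple pairings compete
            ref = [
                FragmentPeak(p.mz * (1 + float(rng.uniform(-15e-6, 15e-6))), p.intensity)
                for p in exp[: int(rng.integers(1, len(exp) + 1))]
            ]
            pairing = match_ions(exp, ref)

            def ppm(i, j):
                return abs(1e6 * (exp[i].mz - ref[j].mz) / ref[j].mz)

            # brute force minimum-total-ppm full assignment of the refs
            best = None
            for perm in itertools.permutations(range(len(exp)), len(ref)):
                if any(ppm(i, j) > 20 for j, i in enumerate(perm)):
                    continue
                cost = sum(ppm(i, j) for j, i in enumerate(perm))
                if best is None or cost < best:
                    best = cost
            greedy_cost = sum(ppm(i, j) for i, j in pairing.pairs)
            if best is not None and len(pairing.pairs) == len(ref):
                assert greedy_cost == pytest.approx(best, rel=1e-6)


class TestDotProducts:
    def test_identical_spectra_score_one(self):
        peaks = [FragmentPeak(100.0, 1000.0), FragmentPeak(200.0, 500.0), FragmentPeak(300.0, 2000.0)]
        pairing = match_ions(peaks, peaks)
        dp, rdp = dot_products(pairing, peaks, peaks)
        assert dp == pytest.approx(1.0, abs=1e-12)
        assert rdp == pytest.approx(1.0, abs=1e-12)

    def test_no_matches_scores_zero(self):
        a = [FragmentPeak(100.0, 10.0)]
        b = [FragmentPeak(200.0, 10.0)]
        dp, rdp = dot_products(match_ions(a, b), a, b)
        assert dp == 0.0 and rdp == 0.0

    def test_hand_computed_two_by_two(self):
        # exp {(100, 1000), (200, 500)}, ref {(100, 800), (300, 400)}, m=1.2, n=0.9
        exp = [FragmentPeak(100.0, 1000.0), FragmentPeak(200.0, 500.0)]
        ref = [FragmentPeak(100.0, 800.0), FragmentPeak(300.0, 400.0)]
        pairing = match_ions(exp, ref)
        dp, rdp = dot_products(pairing, exp, ref)
        m, n = 1.2, 0.9
        ae = 1000.0**m * 100.0**n
        ar = 800.0**m * 100.0**n
        ae2 = (500.0 * 0.5) ** m * 200.0**n  # exp-only, penalised
        ar2 = 400.0**m * 300.0**n  # ref-only
        dp_hand = (ae * ar) ** 2 / ((ae**2 + ae2**2) * (ar**2 + ar2**2))
        assert dp == pytest.approx(dp_hand, rel=1e-12)
        assert rdp == pytest.approx(1.0, abs=1e-12)  # single matched pair

    def test_empty_input_scores_zero(self):
        assert dot_products(IonPairing([], [], []), [], [FragmentPeak(1.0, 1.0)]) == (0.0, 0.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        params = MatchParameters()
        for _ in range(50):
            exp = random_spectrum(rng)
            ref = random_spectrum(rng)
            pairing = match_ions(exp, ref)
            got = dot_products(pairing, exp, ref, params)
            want = brute_force_dot_products(pairing, exp, ref, params)
            assert got[0] == pytest.approx(want[0], abs=1e-12)
            assert got[1] == pytest.approx(want[1], abs=1e-12)

    @given(scale=st.floats(1e-3, 1e3))
    @settings(max_examples=50, deadline=None)
    def test_scale_invariance(self, scale):
        rng = np.random.default_rng(42)
        exp = random_spectrum(rng)
        ref = random_spectrum(rng)
        pairing = match_ions(exp, ref)
        base = dot_products(pairing, exp, ref)
        scaled_exp = [FragmentPeak(p.mz, p.intensity * scale) for p in exp]
        got = dot_products(pairing, scaled_exp, ref)
        assert got[0] == pytest.approx(base[0], rel=1e-9)
        assert got[1] == pytest.approx(base[1], rel=1e-9)

    def test_lower_penalty_never_increases_dp(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            exp = random_spectrum(rng)
            ref = random_spectrum(rng, n_max=4)
            pairing = match_ions(exp, ref)
            if not pairing.exp_only or not pairing.pairs:
                continue
            dps = [
                dot_products(pairing, exp, ref, MatchParameters(unmatched_penalty=w))[0]
                for w in (1.0, 0.5, 0.1)
            ]
            assert dps[0] >= dps[1] >= dps[2]


class TestMeanScore:
    @pytest.mark.parametrize(
        "dp,rdp,expected", [(0.5, 0.5, 0.5), (1.0, 0.0, 0.0), (0.81, 0.49, 0.63)]
    )
    def test_values(self, dp, rdp, expected):
        assert mean_score(dp, rdp) == pytest.approx(expected, abs=1e-12)

    def test_below_arithmetic_mean_when_unequal(self):
        assert mean_score(0.81, 0.49) < (0.81 + 0.49) / 2


def _library_entry(met="MET_X", mass=250.0, n_frag=6):
    rng = np.random.default_rng(17)
    mzs = np.sort(rng.uniform(60, mass - 10, size=n_frag))
    intens = rng.uniform(20, 100, size=n_frag)
    intens[0] = 100.0
    return LibraryEntry(
        met, met, mass, "test", [FragmentPeak(float(m), float(i)) for m, i in zip(mzs, intens)]
    )


def _spectrum_from(entry, adduct="[M+H]+", scale=1e4, rt=1.0):
    return MS2Spectrum(
        adduct_mz(entry.neutral_mass, adduct),
        rt,
        "r",
        0,
        [FragmentPeak(p.mz, p.intensity * scale / 100.0 * 100.0) for p in entry.reference_spectrum],
    )


class TestAnnotateSpectrum:
    def test_self_match_is_perfect(self):
        entry = _library_entry()
        spec = _spectrum_from(entry)
        results = annotate_spectrum(spec, [entry])
        assert len(results) == 1
        r = results[0]
        assert r.metabolite_id == "MET_X" and r.adduct == "[M+H]+"
        assert r.dp == pytest.approx(1.0, abs=1e-12)
        assert r.rdp == pytest.approx(1.0, abs=1e-12)
        assert r.gmean == pytest.approx(1.0, abs=1e-12)
        assert r.matched_ions >= 4

    def test_no_adduct_hit_gives_empty(self):
        entry = _library_entry()
        spec = _spectrum_from(entry)
        other = _library_entry("MET_Y", mass=400.0)
        assert annotate_spectrum(spec, [other]) == []

    def test_isotopologue_precursor_skipped(self):
        entry = _library_entry()
        spec = _spectrum_from(entry)
        assert annotate_spectrum(spec, [entry], precursor_feature_isotope_flag="c13_isotopologue") == []

    def test_chimeric_dominant_recovered(self):
        a = _library_entry("MET_A", mass=250.0)
        # second entry close enough in precursor m/z to co-isolate in a real run;
        # here both preannotate isn't required - the chimera just pollutes fragments
        b = _library_entry("MET_B", mass=250.002)
        mix = {}
        for p in a.reference_spectrum:
            mix[p.mz] = mix.get(p.mz, 0.0) + 0.7 * p.intensity * 1e4 / 100
        for p in b.reference_spectrum:
            mix[p.mz] = mix.get(p.mz, 0.0) + 0.3 * p.intensity * 1e4 / 100
        spec = MS2Spectrum(
            adduct_mz(250.0, "[M+H]+"), 1.0, "r", 0,
            [FragmentPeak(m, i) for m, i in sorted(mix.items())],
        )
        results = annotate_spectrum(spec, [a, b], params=MatchParameters(top_n=2))
        assert results and results[0].metabolite_id == "MET_A"
        # scores agree with the independent formula evaluation
        exp = filter_peaks(spec)
        pairing = match_ions(exp, a.reference_spectrum)
        want = brute_force_dot_products(exp=exp, ref=a.reference_spectrum, pairing=pairing,
                                        params=MatchParameters())
        assert results[0].dp == pytest.approx(want[0], abs=1e-12)
        assert results[0].rdp == pytest.approx(want[1], abs=1e-12)


class TestLabelFragments:
    def _setup(self):
        from iterdda import Feature, PeakTable, SampleInfo

        entry = _library_entry()
        spec = _spectrum_from(entry, rt=1.0)
        frag_mz = entry.reference_spectrum[0].mz
        table = PeakTable(
            samples=[SampleInfo("q1", "qc", 1)],
            features=[
                Feature("Fmain", spec.precursor_mz, 1.0, {"q1": 1e5}, pcgroup=3),
                Feature("Ffrag", frag_mz, 1.0, {"q1": 2e4}, pcgroup=3),
                Feature("Fother", frag_mz + 30.0, 1.0, {"q1": 2e4}, pcgroup=3),
                Feature("Felse", frag_mz, 1.0, {"q1": 2e4}, pcgroup=9),
            ],
        )
        return entry, spec, table

    def test_shared_ion_partner_labeled(self):
        entry, spec, table = self._setup()
        result = annotate_spectrum(spec, [entry])[0]
        result = label_fragments(result, table, "Fmain", entry.reference_spectrum)
        assert "Ffrag" in result.labeled_fragment_features
        assert "Felse" not in result.labeled_fragment_features  # different pcgroup

    def test_non_shared_ion_partner_not_labeled(self):
        entry, spec, table = self._setup()
        result = annotate_spectrum(spec, [entry])[0]
        result = label_fragments(result, table, "Fmain", entry.reference_spectrum)
        assert "Fother" not in result.labeled_fragment_features

    def test_generated_in_source_fragments_recovered(self):
        """Pseudospectrum partners at shared exp/ref fragment m/z all get labeled."""
        from iterdda import Feature, PeakTable, SampleInfo

        entry, spec, _ = self._setup()
        feats = [Feature("Fmain", spec.precursor_mz, 1.0, {"q1": 1e5}, pcgroup=1)]
        expected = []
        for k, p in enumerate(entry.reference_spectrum[:3]):
            fid = f"Ffrag{k}"
            feats.append(Feature(fid, p.mz, 1.0, {"q1": 1e4}, pcgroup=1))
            expected.append(fid)
        table = PeakTable(samples=[SampleInfo("q1", "qc", 1)], features=feats)
        result = annotate_spectrum(spec, [entry])[0]
        result = label_fragments(result, table, "Fmain", entry.reference_spectrum)
        assert set(expected) <= set(result.labeled_fragment_features)
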