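"""Survey scans, precursor selection, dynamic exclusion and strategy execution."""

import math

import pytest

from iterdda import (
    ChromPeakModel,
    FragmentPeak,
    InclusionEntry,
    MethodConfig,
    RunModel,
    SampleInfo,
    acquire_ms2,
    assign_events_to_features,
    audit_acquisition,
    classify_informative,
    run_strategy,
    select_precursors,
    survey_scan,
    update_exclusion,
)
from iterdda.acquisition_sim import ExclusionState


def _run(peaks, fragment_truth=None, gradient=5.0):
    return RunModel(
        sample=SampleInfo("qc_run", "qc", 1),
        scan_interval=0.2,
        gradient_length=gradient,
        peaks=peaks,
        fragment_truth=fragment_truth or {},
    )


def _peak(mz, apex, height, sigma=0.05, src="metabolite-adduct", met="M1"):
    return ChromPeakModel(
        feature_id=f"f_{mz}", mz=mz, apex_rt=apex, sigma=sigma, apex_height=height,
        source=src, source_metabolite=met, source_adduct="[M+H]+",
    )


class TestSurveyScan:
    def test_far_from_apex_is_empty(self):
        run = _run([_peak(300.0, 2.0, 1e6, sigma=0.05)])
        assert survey_scan(run, 4.0) == []

    def test_apex_height_reported(self):
        run = _run([_peak(300.0, 2.0, 1e6)])
        assert survey_scan(run, 2.0) == [(300.0, 1e6)]

    def test_gaussian_height_one_sigma_off(self):
        run = _run([_peak(300.0, 2.0, 1e6, sigma=0.05), _peak(400.0, 2.0, 2e5, sigma=0.02)])
        scan = dict(survey_scan(run, 2.05))
        assert scan[300.0] == pytest.approx(1e6 * math.exp(-0.5), rel=1e-12)
        assert scan[400.0] == pytest.approx(2e5 * math.exp(-0.5 * 2.5**2), rel=1e-12)

    def test_out_of_run_time_rejected(self):
        run = _run([_peak(300.0, 2.0, 1e6)])
        with pytest.raises(ValueError):
            survey_scan(run, 6.0)


class TestSelectPrecursors:
    def test_top_5_of_7_by_intensity(self):
        scan = [(100.0 + i, 1e4 * (i + 1)) for i in range(7)]
        got = select_precursors(scan, 1.0, ExclusionState(), MethodConfig())
        assert [mz for mz, _, _ in got] == [106.0, 105.0, 104.0, 103.0, 102.0]

    def test_tie_broken_by_ascending_mz(self):
        scan = [(200.0, 5e4), (150.0, 5e4)]
        got = select_precursors(scan, 1.0, ExclusionState(), MethodConfig(top_n_per_cycle=1))
        assert got[0][0] == 150.0

    def test_below_min_intensity_ignored(self):
        scan = [(100.0, 2999.0), (200.0, 3000.0)]
        got = select_precursors(scan, 1.0, ExclusionState(), MethodConfig())
        assert [mz for mz, _, _ in got] == [200.0]

    def test_targeted_requires_inclusion_match(self):
        entries = [InclusionEntry(200.0, 1.0, 0.1, "F1", "informative")]
        config = MethodConfig(strategy="targeted", inclusion=entries)
        scan = [(200.000001, 1e5), (300.0, 1e6)]
        got = select_precursors(scan, 1.05, ExclusionState(), config)
        assert [mz for mz, _, _ in got] == [200.000001]
        assert got[0][2] == "F1"
        # outside the RT window nothing is eligible
        assert select_precursors(scan, 1.5, ExclusionState(), config) == []

    def test_band_confinement(self):
        config = MethodConfig(mz_range=(400.0, 600.0))
        scan = [(399.0, 1e6), (450.0, 1e4), (601.0, 1e6)]
        got = select_precursors(scan, 1.0, ExclusionState(), config)
        assert [mz for mz, _, _ in got] == [450.0]


class TestExclusion:
    def test_first_selection_no_exclusion(self):
        state = ExclusionState()
        update_exclusion(state, [300.0], 1.0, MethodConfig(), cycle_index=0)
        assert state.records[0].consecutive_count == 1
        assert state.records[0].excluded_until is None
        assert not state.is_excluded(300.0, 1.01)

    def test_second_consecutive_triggers_window(self):
        state = ExclusionState()
        config = MethodConfig()
        update_exclusion(state, [300.0], 1.98, config, cycle_index=0)
        update_exclusion(state, [300.0], 2.00, config, cycle_index=1)
        assert state.records[0].excluded_until == pytest.approx(2.15)
        assert state.is_excluded(300.0, 2.10)
        assert not state.is_excluded(300.0, 2.16)

    def test_gap_cycle_resets_count(self):
        state = ExclusionState()
        config = MethodConfig()
        update_exclusion(state, [300.0], 1.0, config, cycle_index=0)
        update_exclusion(state, [300.0], 1.1, config, cycle_index=2)  # cycle 1 skipped
        assert state.records[0].consecutive_count == 1
        assert state.records[0].excluded_until is None

    def test_three_cycle_hand_trace(self):
        """An ion intense in 3 consecutive cycles is selected twice then banned."""
        peak = _peak(300.0, 1.0, 1e6, sigma=0.5)
        run = _run([peak], {"M1": [FragmentPeak(100.0, 100.0)] * 1}, gradient=1.2)
        config = MethodConfig()
        state = ExclusionState()
        t, cycle, chosen = 0.98, 0, []
        for _ in range(3):
            scan = survey_scan(run, t)
            sel = select_precursors(scan, t, state, config)
            chosen.append([mz for mz, _, _ in sel])
            update_exclusion(state, [s[0] for s in sel], t, config, cycle_index=cycle)
            t += (1 + len(sel)) / config.scan_hz / 60.0
            cycle += 1
        assert chosen[0] == [300.0]
        assert chosen[1] == [300.0]
        assert chosen[2] == []  # within 0.15 min of the exclusion start


class TestAcquireMs2:
    def _truth(self):
        return {
            "M1": [FragmentPeak(80.0, 100.0), FragmentPeak(120.0, 50.0)],
            "M2": [FragmentPeak(90.0, 100.0)],
        }

    def test_lone_precursor_scaled_reference(self):
        run = _run([_peak(300.0, 2.0, 1e6)], self._truth())
        spec = acquire_ms2(run, 300.0, 2.0)
        assert spec.truth_sources == ["M1"]
        assert [(p.mz, p.intensity) for p in spec.fragments] == [
            (80.0, pytest.approx(1e6)),
            (120.0, pytest.approx(5e5)),
        ]

    def test_coeluting_within_window_is_chimeric(self):
        run = _run(
            [_peak(300.0, 2.0, 1e6), _peak(301.5, 2.0, 1e5, met="M2")], self._truth()
        )
        spec = acquire_ms2(run, 300.0, 2.0)
        assert spec.truth_sources == ["M1", "M2"]
        assert any(p.mz == 90.0 for p in spec.fragments)

    def test_coeluting_outside_window_excluded(self):
        run = _run(
            [_peak(300.0, 2.0, 1e6), _peak(302.5, 2.0, 1e5, met="M2")], self._truth()
        )
        spec = acquire_ms2(run, 300.0, 2.0)
        assert spec.truth_sources == ["M1"]


class TestRunStrategy:
    def test_idda_band_confinement(self, small_batch):
        _, _, runs, _ = small_batch
        result = run_strategy("idda", runs)
        for events, band in zip(result.events_per_run, result.band_per_run):
            lo, hi = band
            assert all(lo <= e.precursor_mz <= hi for e in events)
        # run 3 covers [400, 600]
        assert result.band_per_run[2] == (400.0, 600.0)

    def test_targeted_empty_list_no_spectra(self, small_batch):
        _, _, runs, _ = small_batch
        result = run_strategy("targeted", runs, inclusion=[])
        assert result.spectra == [] and result.events_per_run == []

    def test_targeted_without_list_rejected(self, small_batch):
        _, _, runs, _ = small_batch
        with pytest.raises(ValueError):
            run_strategy("targeted", runs)

    def test_targeted_counts_decay(self, small_batch):
        from iterdda import build_inclusion_informative

        initial, _, runs, _ = small_batch
        entries = build_inclusion_informative(initial)
        result = run_strategy("targeted", runs, inclusion=entries)
        counts = result.per_run_counts
        assert counts[0] == max(counts)
        assert counts[0] > sum(counts[1:])  # sharp first-run decay

    def test_never_more_than_five_per_cycle(self, small_batch):
        _, _, runs, _ = small_batch
        result = run_strategy("dda", runs)
        per_cycle = {}
        for e in result.events:
            per_cycle[e.cycle_index] = per_cycle.get(e.cycle_index, 0) + 1
        assert max(per_cycle.values()) <= 5

    def test_audit_clean_on_all_strategies(self, small_batch):
        from iterdda import build_inclusion_informative

        initial, _, runs, _ = small_batch
        entries = build_inclusion_informative(initial)
        for strat, kw in [
            ("dda", {}),
            ("idda", {}),
            ("targeted", {"inclusion": entries}),
        ]:
            result = run_strategy(strat, runs, **kw)
            assert audit_acquisition(result) == []


class TestAssign:
    def test_exact_feature_assignment(self, small_batch):
        _, sample, runs, truth = small_batch
        table = classify_informative(sample)
        result = run_strategy("dda", runs)
        assigned, summary = assign_events_to_features(result.spectra, table)
        assert summary["n_informative"] + summary["n_noise"] + summary["n_unassigned"] == summary["n_total"]
        # assigned features really are near the precursor
        feats = {f.feature_id: f for f in table.features}
        for spec, fid in zip(result.spectra, assigned):
            if fid is None:
                continue
            f = feats[fid]
            assert abs(1e6 * (spec.precursor_mz - f.mz) / f.mz) <= 20
            assert abs(spec.precursor_rt - f.rt) <= 0.1

    def test_far_spectrum_unassigned(self, small_batch):
        from iterdda import MS2Spectrum

        _, sample, _, _ = small_batch
        table = classify_informative(sample)
        ghost = MS2Spectrum(max(f.mz for f in table.features) + 50.0, 0.0, "r", 0, [])
        assigned, summary = assign_events_to_features([ghost], table)
        assert assigned == [None]
        assert summary["n_unassigned"] == 1

    def test_assignment_matches_ground_truth_sources(self, small_batch):
        _, sample, runs, truth = small_batch
        table = classify_informative(sample)
        result = run_strategy("dda", runs)
        assigned, _ = assign_events_to_features(result.spectra, table)
        agree = total = 0
        for spec, fid in zip(result.spectra, assigned):
            if fid is None or not spec.truth_sources:
                continue
            t = truth.feature_truth[fid]
            total += 1
            agree += t.metabolite_id in spec.truth_sources
        assert total > 0
        assert agree / total >= 0.9
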