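"""Synthetic flow-cell generator: determinism, planted-signal fidelity,
hybridisation arithmetic and cohort structure."""

import numpy as np
import pandas as pd
import pytest

from nanobracket import calling, events, synth

from .helpers import count_dips_below


class TestSimulateTrace:
    def test_baseline_only_has_no_detectable_event(self, rng):
        tr = synth.simulate_trace(220.0, 4.4, [], n_samples=3000, rng=rng)
        x = tr.samples
        assert np.min(x) / np.median(x) > 0.6

    def test_single_dip_has_requested_depth_and_length(self):
        tr = synth.simulate_trace(
            200.0, 0.0, [(100, 10, 0.15)], n_samples=1000,
            rng=np.random.default_rng(0),
        )
        below = tr.samples < 0.55 * 200.0
        assert below.sum() == 10
        assert below[100:110].all()
        assert tr.samples[100] == pytest.approx(0.15 * 200.0)

    def test_overlapping_dips_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            synth.simulate_trace(
                200.0, 0.0, [(100, 10, 0.15), (105, 10, 0.3)], n_samples=1000
            )

    def test_out_of_bounds_dip_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            synth.simulate_trace(200.0, 0.0, [(995, 10, 0.15)], n_samples=1000)

    def test_two_population_dips_recovered_and_histogram_maxima(self, rng):
        # 25 probe-population dips near 0.15, 25 background dips near 0.30
        dips = []
        cursor = 50
        for i in range(50):
            ratio = float(np.clip(
                rng.normal(0.15 if i % 2 == 0 else 0.30, 0.02), 0.06, 0.54
            ))
            dur = int(rng.integers(6, 40))
            dips.append((cursor, dur, ratio))
            cursor += dur + 30
        tr = synth.simulate_trace(220.0, 2.2, dips, n_samples=cursor + 100, rng=rng)
        tr.open_current = 220.0
        assert count_dips_below(tr.samples, 220.0) == 50
        found = events.extract_events(tr)
        assert len(found) == 50
        hist = calling.build_histogram(events.events_to_frame(found))
        assert abs(hist.early_max[0] - 0.15) <= 0.05
        assert abs(hist.late_max[0] - 0.30) <= 0.05


class TestSimulateExperiment:
    def test_seed_determinism_is_bitwise(self):
        truth = synth.TruthSpec("let-7b", 12000, 16.0, 30.0, 5.0, 8.0)
        a = synth.simulate_experiment(truth, seed=42)
        b = synth.simulate_experiment(truth, seed=42)
        for ra, rb in zip(a, b):
            assert ra.events.to_csv().encode() == rb.events.to_csv().encode()
        c = synth.simulate_experiment(truth, seed=43)
        assert not a[1].events.equals(c[1].events)

    def test_control_run_is_background_only(self):
        truth = synth.TruthSpec("let-7b", 12000, 16.0, 30.0, 50.0, 8.0)
        control, run1, _ = synth.simulate_experiment(truth, seed=0)
        # huge probe excess inflates the sample runs but never the control
        assert len(run1.events) > 2 * len(control.events)
        hist = calling.build_histogram(
            events.filter_event_table(control.events)
        )
        assert hist.r_factor > 1.0  # background is late-dominated

    def test_free_probe_arithmetic(self):
        t = synth.TruthSpec("x", 10000, 16.0, 30.0, probe_vol=10.0, rna_vol=9.0)
        assert t.probe_copies == 600 * 10 * 30
        assert t.free_probe == 600 * 10 * 30 - 10000 * 9
        t0 = synth.TruthSpec("x", 10**9, 16.0, 30.0, 2.0, 2.0)
        assert t0.free_probe == 0.0

    def test_detection_when_probe_in_excess(self):
        truth = synth.TruthSpec(
            "x", 10000, 16.0, 30.0,
            probe_vol=2 * 10000 * 8 / (600 * 30), rna_vol=8.0,
        )
        runs = synth.simulate_experiment(truth, seed=5)
        hists = [
            calling.build_histogram(events.filter_event_table(r.events))
            for r in runs
        ]
        assert hists[1].r_factor < hists[0].r_factor
        assert hists[2].r_factor < hists[0].r_factor
        assert calling.call_triplet(*hists).call == calling.DETECTION

    def test_silencing_when_probe_below_target(self):
        truth = synth.TruthSpec(
            "x", 10000, 16.0, 30.0,
            probe_vol=0.5 * 10000 * 8 / (600 * 30), rna_vol=8.0,
        )
        runs = synth.simulate_experiment(truth, seed=5)
        hists = [
            calling.build_histogram(events.filter_event_table(r.events))
            for r in runs
        ]
        control_total = hists[0].total_events
        assert hists[1].total_events < 0.6 * control_total  # shielding
        assert calling.call_triplet(*hists).call == calling.SILENCING

    def test_expected_probe_events_monotone_in_free_probe(self):
        cfg = synth.SimulatorConfig()
        fc = synth.FlowCellState()
        prev = -1.0
        for copies in [30000, 20000, 12000, 8000, 1000, 0]:
            truth = synth.TruthSpec("x", copies, 16.0, 30.0, 5.0, 8.0)
            early, late = synth._expected_counts(truth, fc, cfg, run_index=1)
            assert truth.free_probe >= 0
            if truth.free_probe > 0:
                assert early > prev
                prev = early

    def test_event_counts_shrink_with_pore_decay(self):
        fc = synth.FlowCellState(per_run_decay=0.15)
        assert fc.active_at(2) == pytest.approx(0.85**2)
        truth = synth.TruthSpec("x", 100, 16.0, 30.0, 5.0, 8.0)  # probe excess
        cfg = synth.SimulatorConfig()
        e1 = sum(synth._expected_counts(truth, fc, cfg, 1))
        e2 = sum(synth._expected_counts(truth, fc, cfg, 2))
        assert e2 < e1

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            synth.TruthSpec("x", 100, 16.0, 30.0, probe_vol=-1.0, rna_vol=8.0)
        with pytest.raises(ValueError):
            synth.TruthSpec("x", -5, 16.0, 30.0, 5.0, 8.0)
        with pytest.raises(ValueError):
            synth.FlowCellState(active_fraction=0.0)


class TestCohort:
    def test_large_sample_means(self):
        df = synth.generate_cohort(400, 400, seed=1)
        healthy = df[(df.condition == "healthy") & (df.marker != "miR-15b")].hl
        cancer = df[(df.condition == "cancer") & (df.marker != "miR-15b")].hl
        se_h = 0.17 / np.sqrt(len(healthy))
        se_c = 1.83 * 0.09 / np.sqrt(len(cancer))
        assert abs(healthy.mean() - 1.0) < 3 * se_h
        assert abs(cancer.mean() - 1.83) < 3 * se_c
        m15 = df[df.marker == "miR-15b"].hl
        assert abs(m15.mean() - 0.96) < 3 * 0.96 * 0.14 / np.sqrt(len(m15))
        assert (df.hl > 0).all()

    def test_mir15b_is_cancer_independent(self):
        df = synth.generate_cohort(300, 300, seed=2)
        m15 = df[df.marker == "miR-15b"]
        h = m15[m15.condition == "healthy"].hl.mean()
        c = m15[m15.condition == "cancer"].hl.mean()
        assert abs(h - c) < 0.05

    def test_single_subject_cohort(self):
        df = synth.generate_cohort(1, 0, markers=["miR-21"], seed=0)
        assert len(df) == 1
        assert (df.condition == "healthy").all()

    def test_unknown_marker_rejected(self):
        with pytest.raises(ValueError, match="unknown marker"):
            synth.generate_cohort(2, 2, markers=["miR-9999"], seed=0)

    def test_determinism(self):
        a = synth.generate_cohort(10, 10, seed=9)
        b = synth.generate_cohort(10, 10, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_threshold_separation_on_large_cohort(self):
        df = synth.generate_cohort(500, 500, seed=3)
        bio = df[df.marker != "miR-15b"]
        calls = bio.hl > 1.5
        truth = bio.condition == "cancer"
        sens = (calls & truth).sum() / truth.sum()
        spec = (~calls & ~truth).sum() / (~truth).sum()
        assert sens > 0.95
        assert spec > 0.95
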