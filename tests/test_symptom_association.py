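import numpy as np
import pytest

from refluxsap import (
    ContingencyTable2x2,
    SymptomEventLog,
    ValidationError,
    associate,
    build_table,
    detect_reflux_episodes,
    label_reflux_windows,
    label_symptom_windows,
    partition_windows,
    sap,
    symptom_index,
    symptom_sensitivity_index,
)
from refluxsap.synthetic_data import (
    SymptomSimConfig,
    TraceSimConfig,
    simulate_symptoms,
    simulate_trace,
)
from conftest import make_trace
from _oracles import brute_force_reflux_labels, count_table, fisher_enum


class TestPartitionWindows:
    def test_48h_gives_1440_windows(self):
        assert partition_windows(172800.0).n_windows == 1440

    def test_ceil_rule_short_last_window(self):
        grid = partition_windows(172830.0)
        assert grid.n_windows == 1441
        assert grid.ends[-1] - grid.starts[-1] == pytest.approx(30.0)

    def test_exactly_one_window(self):
        assert partition_windows(120.0).n_windows == 1

    def test_too_short_recording(self):
        with pytest.raises(ValidationError):
            partition_windows(100.0)

    def test_windows_tile_without_overlap(self):
        grid = partition_windows(3630.0)
        ws = grid.windows()
        assert ws[0][0] == 0.0
        assert ws[-1][1] == pytest.approx(3630.0)
        for (s1, e1), (s2, _) in zip(ws, ws[1:]):
            assert e1 == pytest.approx(s2)


class TestRefluxLabeling:
    def test_constant_ph_negative(self, flat_trace):
        grid = partition_windows(flat_trace)
        assert not label_reflux_windows(flat_trace, grid).any()

    def test_two_sub4_samples_positive_via_criterion_a(self):
        # 2 consecutive sub-4 samples cover 12 s >= 5 s
        ph = [6.8] * 5 + [3.5, 3.5] + [6.8] * 13
        tr = make_trace(ph)
        grid = partition_windows(tr)
        labels = label_reflux_windows(tr, grid)
        assert labels[0]

    def test_single_sub4_sample_positive_at_6s_sampling(self):
        # one sample carries its 6-s interval: 6 >= 5
        ph = [6.8] * 5 + [3.9] + [6.8] * 14
        tr = make_trace(ph)
        assert label_reflux_windows(tr, partition_windows(tr))[0]

    def test_criterion_b_span_semantics(self):
        # pH steps 6.5 -> 5.2 across one 6-s gap: drop of 1.3 units but the
        # pair is 6 s apart, so span 5 s cannot fire; span >= 6 s can.
        ph = [6.5] * 10 + [5.2] + [5.2] * 9
        tr = make_trace(ph)
        grid = partition_windows(tr)
        assert not label_reflux_windows(tr, grid, drop_span_s=5.0).any()
        assert label_reflux_windows(tr, grid, drop_span_s=6.0)[0]

    def test_criterion_b_fine_sampling(self):
        # at 2-s sampling a >1-unit drop within 5 s is detectable
        ph = [6.5] * 70 + [5.2] + [5.3] * 79
        tr = make_trace(ph, dt=2.0)  # 300 s -> 3 windows; drop at t=140
        grid = partition_windows(tr)
        labels = label_reflux_windows(tr, grid)
        assert labels[1] and not labels[0] and not labels[2]

    def test_run_straddling_window_boundary(self):
        # sub-4 run covering [114, 126): 6 s in window 0, 6 s in window 1
        ph = [6.8] * 19 + [3.5, 3.5] + [6.8] * 19
        tr = make_trace(ph)
        labels = label_reflux_windows(tr, partition_windows(tr))
        assert labels[0] and labels[1]

    def test_straddling_run_needs_sustained_inside_each_window(self):
        # run covers [114, 126): only 6 s lie in window 0; with
        # sustained_s=10 neither side reaches 10 s inside its window
        ph = [6.8] * 19 + [3.5, 3.5] + [6.8] * 19
        tr = make_trace(ph)
        labels = label_reflux_windows(tr, partition_windows(tr), sustained_s=10.0)
        assert not labels.any()

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(8):
            ph = np.clip(rng.normal(4.6, 1.2, 600), 0, 9)
            tr = make_trace(ph)
            grid = partition_windows(tr)
            fast = label_reflux_windows(tr, grid)
            slow = brute_force_reflux_labels(tr.times.tolist(), ph.tolist(),
                                             6.0, 120.0, tr.duration_s)
            assert fast.tolist() == slow

    def test_matches_brute_force_oracle_fine_sampling(self, rng):
        for _ in range(4):
            ph = np.clip(rng.normal(5.0, 1.0, 900), 0, 9)
            tr = make_trace(ph, dt=2.0)
            grid = partition_windows(tr)
            fast = label_reflux_windows(tr, grid)
            slow = brute_force_reflux_labels(tr.times.tolist(), ph.tolist(),
                                             2.0, 120.0, tr.duration_s)
            assert fast.tolist() == slow


class TestSymptomLabeling:
    def test_zero_events_all_negative(self):
        log = SymptomEventLog("t", ("heartburn",))
        grid = partition_windows(600.0)
        assert not label_symptom_windows(grid, log, "heartburn").any()

    def test_boundary_event_in_later_window(self):
        log = SymptomEventLog("t", ("heartburn",), events=[(120.0, "heartburn")])
        grid = partition_windows(600.0)
        labels = label_symptom_windows(grid, log, "heartburn")
        assert not labels[0] and labels[1]

    def test_multiple_events_no_multiplicity(self):
        log = SymptomEventLog("t", ("heartburn",),
                              events=[(10.0, "heartburn"), (20.0, "heartburn"),
                                      (30.0, "heartburn")])
        grid = partition_windows(600.0)
        labels = label_symptom_windows(grid, log, "heartburn")
        assert labels.sum() == 1

    def test_untracked_symptom_rejected(self, simple_log):
        grid = partition_windows(600.0)
        with pytest.raises(ValidationError, match="not tracked"):
            label_symptom_windows(grid, simple_log, "nausea")


class TestBuildTable:
    def test_enumeration_example(self):
        t = build_table([1, 1, 0, 0], [1, 0, 1, 0])
        assert (t.a, t.b, t.c, t.d) == (1, 1, 1, 1)

    def test_all_negative_symptoms(self):
        t = build_table([1, 0, 1, 0], [0, 0, 0, 0])
        assert t.a == 0 and t.b == 0
        assert t.total == 4

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            build_table([1, 0], [1, 0, 1])

    def test_random_vectors_vs_counting_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(1, 100))
            r = rng.uniform(size=n) < 0.3
            s = rng.uniform(size=n) < 0.2
            t = build_table(r, s)
            assert (t.a, t.b, t.c, t.d) == count_table(r, s)


class TestSAP:
    def test_positive_example(self):
        res = sap(ContingencyTable2x2(6, 0, 4, 10))
        assert res.p_value == pytest.approx(420 / 38760, rel=1e-9)
        assert res.sap_pct == pytest.approx(100 * (1 - 420 / 38760))
        assert res.positive

    def test_negative_example(self):
        res = sap(ContingencyTable2x2(4, 0, 6, 10))
        assert res.p_value == pytest.approx(420 / 4845, rel=1e-9)
        assert res.sap_pct == pytest.approx(91.33, abs=0.01)
        assert not res.positive

    def test_empty_symptom_margin(self):
        res = sap(ContingencyTable2x2(0, 0, 7, 13))
        assert res.p_value == 1.0
        assert res.sap_pct == 0.0
        assert not res.positive

    def test_oracle_equivalence_sampled(self, rng):
        for _ in range(100):
            a, b, c, d = (int(x) for x in rng.integers(0, 8, size=4))
            res = sap(ContingencyTable2x2(a, b, c, d))
            assert res.p_value == pytest.approx(
                float(fisher_enum(a, b, c, d)), rel=1e-9, abs=1e-12)

    def test_row_column_swap_invariance(self, rng):
        for _ in range(30):
            a, b, c, d = (int(x) for x in rng.integers(0, 10, size=4))
            p1 = sap(ContingencyTable2x2(a, b, c, d)).p_value
            p2 = sap(ContingencyTable2x2(a, c, b, d)).p_value
            assert p1 == pytest.approx(p2, rel=1e-9)

    def test_monotonicity_moving_mass_off_diagonal(self):
        # positive-association orientation: moving a -> b weakens association
        prev = sap(ContingencyTable2x2(8, 0, 2, 10))
        for a in (7, 6, 5, 4):
            cur = sap(ContingencyTable2x2(a, 8 - a, 2, 10))
            assert cur.sap_pct < prev.sap_pct
            prev = cur

    def test_one_sided_option(self):
        t = ContingencyTable2x2(6, 0, 4, 10)
        res = sap(t, sidedness="greater")
        assert res.p_value == pytest.approx(
            float(fisher_enum(6, 0, 4, 10, "greater")), rel=1e-9)


class TestSIAndSSI:
    def _setup(self):
        # reflux in windows 0 and 2 of five 120-s windows
        ph = [3.5] * 20 + [6.8] * 20 + [3.5] * 20 + [6.8] * 40
        tr = make_trace(ph)
        grid = partition_windows(tr)
        reflux = label_reflux_windows(tr, grid)
        episodes = detect_reflux_episodes(tr)
        return tr, grid, reflux, episodes

    def test_all_events_in_reflux_windows(self):
        tr, grid, reflux, _ = self._setup()
        log = SymptomEventLog("t", ("heartburn",),
                              events=[(10.0, "heartburn"), (250.0, "heartburn")])
        pct, pos = symptom_index(log, "heartburn", reflux, grid)
        assert pct == 100.0 and pos

    def test_no_events_associated(self):
        tr, grid, reflux, _ = self._setup()
        # events in windows 4 (well past reflux + lag)
        log = SymptomEventLog("t", ("heartburn",),
                              events=[(500.0, "heartburn"), (510.0, "heartburn"),
                                      (520.0, "heartburn"), (530.0, "heartburn")])
        pct, pos = symptom_index(log, "heartburn", reflux, grid)
        assert pct == 0.0 and pos is False

    def test_zero_events_missing_not_zero(self):
        tr, grid, reflux, episodes = self._setup()
        log = SymptomEventLog("t", ("heartburn",))
        assert symptom_index(log, "heartburn", reflux, grid) == (None, None)

    def test_ssi_counts_episodes_with_events(self):
        tr, grid, reflux, episodes = self._setup()
        assert len(episodes) == 2
        log = SymptomEventLog("t", ("heartburn",),
                              events=[(30.0, "heartburn")])
        pct, pos = symptom_sensitivity_index(log, "heartburn", episodes)
        assert pct == 50.0 and pos

    def test_ssi_zero_episodes_missing(self, flat_trace):
        log = SymptomEventLog("t", ("heartburn",), events=[(30.0, "heartburn")])
        assert symptom_sensitivity_index(log, "heartburn", []) == (None, None)

    def test_full_coupling_gives_si_100(self):
        trace, eps = simulate_trace(TraceSimConfig(seed=3, duration_s=43200))
        cfg = SymptomSimConfig(symptoms={"heartburn": 15}, coupling=1.0, seed=4)
        log = simulate_symptoms(trace, eps, cfg)
        grid = partition_windows(trace)
        reflux = label_reflux_windows(trace, grid)
        pct, pos = symptom_index(log, "heartburn", reflux, grid)
        assert pct == 100.0 and pos


class TestAssociate:
    def test_aggregation_rule(self):
        trace, eps = simulate_trace(TraceSimConfig(seed=5, duration_s=43200))
        cfg = SymptomSimConfig(
            symptoms={"heartburn": 25, "cough": 8, "nausea": 8},
            coupling=0.0, seed=6)
        log = simulate_symptoms(trace, eps, cfg)
        # force heartburn to be strongly coupled by moving its events into
        # reflux-positive windows
        grid = partition_windows(trace)
        reflux = label_reflux_windows(trace, grid)
        pos_w = np.flatnonzero(reflux)
        events = [(t, s) for t, s in log.events if s != "heartburn"]
        for i in range(25):
            w = pos_w[i % len(pos_w)]
            events.append((float(grid.starts[w] + 1.0 + 0.001 * i), "heartburn"))
        log = SymptomEventLog("t", log.tracked_symptoms, events)
        summary = associate(trace, log)
        assert summary.results["heartburn"].positive
        assert summary.patient_sap_positive
        assert summary.n_sap_positive >= 1

    def test_no_positive_symptom_patient_negative(self, flat_trace):
        log = SymptomEventLog("t", ("heartburn",), events=[(30.0, "heartburn")])
        summary = associate(flat_trace, log)
        assert not summary.patient_sap_positive
        assert summary.n_sap_positive == 0

    def test_zero_event_symptom_not_assessable(self, flat_trace):
        log = SymptomEventLog("t", ("heartburn", "cough"),
                              events=[(30.0, "heartburn")])
        summary = associate(flat_trace, log)
        assert not summary.results["cough"].assessable
        assert summary.n_assessable == 1

    def test_compositionality(self):
        trace, eps = simulate_trace(TraceSimConfig(seed=7, duration_s=43200))
        cfg = SymptomSimConfig(symptoms={"heartburn": 20, "cough": 10},
                               coupling=0.7, seed=8)
        log = simulate_symptoms(trace, eps, cfg)
        summary = associate(trace, log)
        grid = partition_windows(trace)
        reflux = label_reflux_windows(trace, grid)
        for symptom in log.tracked_symptoms:
            vec = label_symptom_windows(grid, log, symptom)
            expected = sap(build_table(reflux, vec), symptom=symptom)
            got = summary.results[symptom]
            assert got.p_value == expected.p_value
            assert got.table == expected.table
            assert got.positive == expected.positive
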