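"""Decision table, online monitoring, baseline and cohort comparison."""

import dataclasses
import math

import numpy as np
import pytest

import ecochg_monitor as em
from conftest import make_tracing


def _group(shifts, freqs=None):
    freqs = freqs or [2011.0, 1015.0, 507.0, 253.0][: len(shifts)]
    events = tuple(
        em.DropEvent(
            frequency=f, t_peak=9.5, t_drop=10.5, peak_index=9, drop_index=10,
            magnitude_db=8.0, phase_shift=s,
        )
        for f, s in zip(freqs, shifts)
    )
    return em.EventGroup(events)


class TestClassifyGroup:
    @pytest.mark.parametrize(
        "shifts,expected",
        [
            ([3.5, 3.6, 3.4, 3.5], em.Label.TRAUMA_ALARM),      # all large
            ([0.2, 0.3, 0.1, 0.25], em.Label.HAIR_CELL_PATCH),  # all small
            ([math.pi], em.Label.TONOTOPIC_PASSAGE),            # lone reversal
            ([3.5, 3.5, 0.1, 0.2], em.Label.AMBIGUOUS),         # mixed evidence
            ([3.5, 3.5], em.Label.AMBIGUOUS),                   # two-frequency case
            ([0.1], em.Label.AMBIGUOUS),                        # lone small drop
            ([None, None, None, 0.1], em.Label.AMBIGUOUS),      # indeterminate
        ],
    )
    def test_decision_table(self, config, shifts, expected):
        c = em.classify_group(_group(shifts), 4, config)
        assert c.label is expected
        assert c.rationale["n_freqs_dropped"] == len(shifts)

    def test_pi_exactly_counts_as_large(self, config):
        """The threshold is inclusive: a 180° shift is a reversal."""
        c = em.classify_group(_group([math.pi, math.pi, math.pi]), 4, config)
        assert c.label is em.Label.TRAUMA_ALARM

    def test_koka_mode_alarms_on_drop_without_phase_change(self, config):
        cfg = dataclasses.replace(config, koka_mode=True)
        assert (
            em.classify_group(_group([0.2, 0.3, 0.1, 0.25]), 4, cfg).label
            is em.Label.TRAUMA_ALARM
        )
        assert (
            em.classify_group(_group([math.pi]), 4, cfg).label
            is em.Label.TONOTOPIC_PASSAGE
        )

    def test_purity(self, config):
        g = _group([3.5, 3.5, 3.5])
        a = em.classify_group(g, 4, config)
        b = em.classify_group(g, 4, config)
        assert a.label is b.label and a.t == b.t


class TestRunMonitor:
    def test_flat_bundle_yields_empty_log(self, config):
        t = (np.arange(30) + 0.5).astype(float)
        bundle = em.TracingBundle(
            tuple(
                em.CMTracing(f, t, np.full(30, 5.0), np.zeros(30))
                for f in (507.0, 1015.0)
            )
        )
        assert len(em.run_monitor(bundle, config)) == 0

    def test_short_bundle_yields_empty_log(self, config):
        bundle = em.TracingBundle(
            (em.CMTracing(507.0, [0.5], [5.0], [0.0]),)
        )
        assert len(em.run_monitor(bundle, config)) == 0

    def test_passage_only_run(self, config):
        bundle, truth = em.simulate_insertion(em.panel_a_scenario())
        log = em.run_monitor(bundle, config)
        counts = log.counts()
        assert counts["TONOTOPIC_PASSAGE"] == 4
        assert counts["TRAUMA_ALARM"] == 0
        # passage order follows tonotopy: high to low frequency
        passages = [
            c for c in log.classifications if c.label is em.Label.TONOTOPIC_PASSAGE
        ]
        assert [c.group.frequencies[0] for c in passages] == [2011.0, 1015.0, 507.0, 253.0]

    def test_single_trauma_alarms_once(self, config):
        bundle, _ = em.simulate_insertion(em.panel_c_scenario())
        assert em.run_monitor(bundle, config).n_alarms == 1

    def test_determinism(self, config):
        bundle, _ = em.simulate_insertion(em.panel_c_scenario(seed=3, noise_sigma=0.02))
        a = em.run_monitor(bundle, config)
        b = em.run_monitor(bundle, config)
        assert [(c.label, c.t) for c in a.classifications] == [
            (c.label, c.t) for c in b.classifications
        ]

    def test_online_equals_batch(self, config):
        bundle, _ = em.simulate_insertion(
            em.panel_c_scenario(seed=1, noise_sigma=0.02)
        )
        batch = em.run_monitor(bundle, config)
        om = em.OnlineMonitor(bundle, config)
        seen = []
        for i in range(bundle.n_frames):
            seen += om.push(
                float(bundle.frame_times[i]),
                {tr.frequency: (float(tr.amplitude[i]), float(tr.phase[i]))
                 for tr in bundle.tracings},
            )
        assert seen, "alarm must be emitted during streaming, not only at finalize"
        online = om.finalize()
        assert [(c.label, c.t, c.group.frequencies) for c in batch.classifications] == [
            (c.label, c.t, c.group.frequencies) for c in online.classifications
        ]

    def test_online_latency_is_bounded(self, config):
        """The trauma alarm surfaces within the coincidence window plus two
        smoothing windows of the triggering frame."""
        bundle, _ = em.simulate_insertion(em.panel_c_scenario())
        om = em.OnlineMonitor(bundle, config)
        dt = float(np.diff(bundle.frame_times).mean())
        horizon = (
            config.coincidence_window_s
            + (2 * config.smoothing_frames + 1) * dt
        )
        for i in range(bundle.n_frames):
            out = om.push(
                float(bundle.frame_times[i]),
                {tr.frequency: (float(tr.amplitude[i]), float(tr.phase[i]))
                 for tr in bundle.tracings},
            )
            for c in out:
                trigger = max(e.t_drop for e in c.group.events)
                assert bundle.frame_times[i] - trigger <= horizon + 1e-9


class TestBaselineAndComparison:
    def test_three_drops_three_alarms(self, config):
        amp = [10, 10, 4, 4, 10, 10, 4, 4, 10, 10, 4, 4]
        t = (np.arange(12) * 2.0).astype(float)  # 2 s frames: clear of refractory
        tr = em.CMTracing(507.0, t, np.array(amp, float), np.zeros(12))
        bundle = em.TracingBundle((tr,))
        cfg = dataclasses.replace(config, smoothing_frames=1)
        log = em.single_freq_baseline(bundle, cfg)
        assert len(log.classifications) == 3

    def test_constant_tracing_no_alarms(self, config):
        t = (np.arange(20) + 0.5).astype(float)
        bundle = em.TracingBundle(
            (em.CMTracing(507.0, t, np.full(20, 5.0), np.zeros(20)),)
        )
        assert len(em.single_freq_baseline(bundle, config)) == 0

    def test_missing_baseline_frequency_errors(self, config):
        t = (np.arange(5) + 0.5).astype(float)
        bundle = em.TracingBundle(
            (em.CMTracing(2011.0, t, np.ones(5), np.zeros(5)),)
        )
        with pytest.raises(ValueError, match="20%"):
            em.single_freq_baseline(bundle, config)

    def test_passage_at_507_alarms_baseline_but_not_monitor(self, config):
        """The central contrast: a tonotopic passage alarms the conventional
        single-frequency scheme but not the multi-frequency classifier."""
        bundle, _ = em.simulate_insertion(em.panel_a_scenario())
        single = em.single_freq_baseline(bundle, config)
        multi = em.run_monitor(bundle, config)
        assert len(single.classifications) >= 1
        assert multi.n_alarms == 0

    def test_reference_counts_reproduce_published_means(self):
        summary = em.summary_from_counts(em.REFERENCE_COHORT_COUNTS)
        assert summary.mean_single == pytest.approx(2.8)
        assert summary.mean_multi == pytest.approx(0.5)

    def test_compare_alarms_and_subject_mismatch(self, config):
        bundle, _ = em.simulate_insertion(em.panel_a_scenario())
        single = em.single_freq_baseline(bundle, config, subject="s1")
        multi = em.run_monitor(bundle, config, subject="s1")
        summary = em.compare_alarms({"s1": single}, {"s1": multi})
        assert summary.mean_single == len(single.classifications)
        assert summary.mean_multi == 0
        with pytest.raises(ValueError, match="mismatch"):
            em.compare_alarms({"s1": single}, {"s2": multi})

    def test_empty_logs_give_zero_means(self, config):
        empty = em.AlarmLog([], config, "s1")
        summary = em.compare_alarms({"s1": empty}, {"s1": empty})
        assert summary.mean_single == 0.0 and summary.mean_multi == 0.0
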