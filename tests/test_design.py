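"""HRF kernel and design-matrix construction: structure, supports, VIF."""

import numpy as np
import pytest

from threatdyn import (
    build_blocks_design,
    build_boxcar_design,
    build_osp_design,
    canonical_hrf,
    compute_vif,
    generate_timeline,
)
from threatdyn.design import (
    convolve_and_sample,
    legendre_drift,
    microtime_length,
    n_blocks_for,
    rasterize_events,
)
from threatdyn.exceptions import RankDeficiencyError


class TestCanonicalHRF:
    def test_zero_at_origin(self, hrf):
        assert hrf.values[0] == 0.0

    def test_peak_location(self):
        # dense evaluation pins the positive-lobe peak near 5 s
        fine = canonical_hrf(dt_s=0.01)
        assert 4.5 <= np.argmax(fine.values) * fine.dt_s <= 5.5

    def test_positive_integral_and_single_sign_change(self, hrf):
        assert hrf.values.sum() * hrf.dt_s > 0
        signs = np.sign(hrf.values[np.abs(hrf.values) > 1e-12])
        changes = np.sum(np.diff(signs) != 0)
        assert changes == 1

    @pytest.mark.parametrize("bad", [dict(dt_s=0), dict(peak_delay=-1),
                                     dict(peak_undershoot_ratio=0)])
    def test_invalid_parameters(self, bad):
        with pytest.raises(ValueError):
            canonical_hrf(**bad)


class TestBoxcarDesign:
    def test_reference_condition_omitted(self, timeline, hrf):
        d = build_boxcar_design(timeline, hrf)
        assert not d.has_column("certain_safety", "boxcar")
        assert ("certain_safety", "boxcar") in d.reference_record
        for cond in ("certain_threat", "uncertain_threat", "uncertain_safety"):
            assert d.has_column(cond, "boxcar")

    def test_reinforcer_and_mask_columns_present(self, timeline, hrf):
        d = build_boxcar_design(timeline, hrf)
        for cond in ("certain_threat", "certain_safety",
                     "uncertain_threat", "uncertain_safety"):
            assert d.has_column(cond, "reinforcer")
        assert d.has_column("mask", "mask")

    def test_boxcar_support_matches_trial_windows(self, small_timeline, hrf):
        # pre-convolution support of a certain-threat indicator equals the
        # union of that condition's [onset, onset + 18.75) windows
        scan = small_timeline.scans[0]
        n_micro = microtime_length(scan.n_volumes, scan.tr_s, hrf.dt_s)
        events = [(t.onset_s, t.antic_dur_s, 1.0) for t in scan.trials
                  if t.condition == "certain_threat"]
        ind = rasterize_events(events, n_micro, hrf.dt_s)
        expected = np.zeros(n_micro)
        for t in scan.trials:
            if t.condition == "certain_threat":
                i0 = int(round(t.onset_s / hrf.dt_s))
                i1 = int(round((t.onset_s + 18.75) / hrf.dt_s))
                expected[i0:i1] = 1.0
        assert np.array_equal(ind, expected)


class TestOSPDesign:
    def test_default_phasic_duration(self, timeline, hrf):
        from threatdyn import PHASIC_DUR_S
        assert PHASIC_DUR_S == 6.15
        d = build_osp_design(timeline, hrf)
        assert d.model == "osp"

    def test_reference_handling(self, timeline, hrf):
        d = build_osp_design(timeline, hrf)
        assert not d.has_column("certain_safety", "sustained")
        assert d.has_column("certain_safety", "onset")
        assert d.has_column("certain_safety", "phasic")

    def test_phasic_support_is_offset_locked(self, hrf):
        # a certain trial starting at t0 has phasic support
        # [t0 + 18.75 - 6.15, t0 + 18.75)
        t0, dur, ph = 10.0, 18.75, 6.15
        dt = hrf.dt_s
        n_micro = 640
        ind = rasterize_events([(t0 + dur - ph, ph, 1.0)], n_micro, dt)
        nz = np.flatnonzero(ind)
        assert nz[0] == int(round((t0 + dur - ph) / dt))
        assert nz[-1] == int(round((t0 + dur) / dt)) - 1

    def test_phasic_longer_than_shortest_epoch_rejected(self, timeline, hrf):
        with pytest.raises(ValueError):
            build_osp_design(timeline, hrf, phasic_dur_s=9.0)

    def test_osp_component_identities(self, small_timeline, hrf):
        # per epoch: sustained = full boxcar, phasic contained in it, onset
        # a single microtime sample
        scan = small_timeline.scans[0]
        trial = scan.trials[0]
        dt = hrf.dt_s
        n_micro = microtime_length(scan.n_volumes, scan.tr_s, dt)
        sus = rasterize_events([(trial.onset_s, trial.antic_dur_s, 1.0)], n_micro, dt)
        pha = rasterize_events(
            [(trial.offset_s - 6.15, 6.15, 1.0)], n_micro, dt)
        ons = rasterize_events([(trial.onset_s, 0.0, 1.0)], n_micro, dt)
        assert np.all(sus[pha > 0] == 1.0)
        assert np.count_nonzero(ons) == 1
        assert ons.sum() * dt == pytest.approx(1.0)


class TestBlocksDesign:
    @pytest.mark.parametrize("dur,expected", [(8.75, 2), (15.0, 3), (18.75, 3),
                                              (25.0, 4), (30.0, 5)])
    def test_block_counts(self, dur, expected):
        assert n_blocks_for(dur) == expected

    def test_block_counts_within_2_to_5(self):
        for dur in np.arange(8.75, 30.0 + 1e-9, 1.25):
            assert 2 <= n_blocks_for(float(dur)) <= 5

    def test_reference_block_omitted(self, timeline, hrf):
        d = build_blocks_design(timeline, hrf)
        assert not d.has_column("certain_safety", "block2")
        assert d.has_column("certain_safety", "block1")
        assert d.has_column("certain_safety", "block3")
        assert d.has_column("certain_threat", "block2")

    def test_block_partition_of_epoch(self, small_timeline, hrf):
        # unconvolved block indicators of one epoch sum to its boxcar
        trial = small_timeline.scans[0].trials[0]
        dt = hrf.dt_s
        n_micro = microtime_length(478, 1.25, dt)
        total = np.zeros(n_micro)
        for k in range(1, n_blocks_for(trial.antic_dur_s) + 1):
            start = trial.onset_s + (k - 1) * 6.25
            dur = min(6.25, trial.offset_s - start)
            total += rasterize_events([(start, dur, 1.0)], n_micro, dt)
        boxcar = rasterize_events(
            [(trial.onset_s, trial.antic_dur_s, 1.0)], n_micro, dt)
        assert np.array_equal(total, boxcar)


class TestConvolutionProperties:
    def test_linearity_over_event_sets(self, hrf):
        n_micro = 2000
        ev1 = [(5.0, 10.0, 1.0)]
        ev2 = [(40.0, 0.0, 1.0), (60.0, 6.25, 1.0)]
        f = lambda ev: convolve_and_sample(
            rasterize_events(ev, n_micro, hrf.dt_s), hrf, 100, 1.25)
        np.testing.assert_allclose(f(ev1 + ev2), f(ev1) + f(ev2), atol=1e-12)

    def test_shift_equivariance(self, hrf):
        n_micro = 4000
        k = 8  # TRs
        ev = [(12.5, 6.25, 1.0), (50.0, 0.0, 1.0)]
        shifted = [(o + k * 1.25, d, a) for o, d, a in ev]
        a = convolve_and_sample(rasterize_events(ev, n_micro, hrf.dt_s),
                                hrf, 200, 1.25)
        b = convolve_and_sample(rasterize_events(shifted, n_micro, hrf.dt_s),
                                hrf, 200, 1.25)
        np.testing.assert_allclose(b[k:], a[:-k], atol=1e-10)

    def test_drift_columns_are_legendre(self):
        D = legendre_drift(101, order=4)
        assert D.shape == (101, 5)
        x = np.linspace(-1, 1, 101)
        np.testing.assert_allclose(D[:, 2], 0.5 * (3 * x**2 - 1), atol=1e-12)


class TestVIF:
    def test_orthogonal_columns_have_unit_vif(self, timeline, hrf):
        d = build_osp_design(timeline, hrf)
        # replace task columns with orthogonal ones
        task = d.task_indices
        n = d.X.shape[0]
        rng = np.random.default_rng(0)
        Q, _ = np.linalg.qr(rng.normal(size=(n, len(task))))
        d.X[:, task] = Q
        d.X[:, d.drift_indices] = 0.0
        rep = compute_vif(d)
        for v in rep.per_column.values():
            assert v == pytest.approx(1.0, abs=1e-8)

    def test_duplicated_column_raises(self, timeline, hrf):
        d = build_osp_design(timeline, hrf)
        task = d.task_indices
        d.X[:, task[1]] = d.X[:, task[0]]
        with pytest.raises(RankDeficiencyError):
            compute_vif(d)

    def test_all_vifs_at_least_one(self, timeline, hrf):
        rep = compute_vif(build_blocks_design(timeline, hrf))
        assert all(v >= 1.0 for v in rep.per_column.values())

    def test_mean_conditionwise_vif_below_printed_bounds(self, hrf):
        # spot check on a few sessions; the 200-session average is exercised
        # by the acceptance suite
        osp, blk = [], []
        for seed in range(1, 6):
            tl = generate_timeline(seed=seed)
            osp.append(compute_vif(build_osp_design(tl, hrf)).mean_conditionwise)
            blk.append(compute_vif(build_blocks_design(tl, hrf)).mean_conditionwise)
        assert np.mean(osp) < 1.93
        assert np.mean(blk) < 1.91
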